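"""Synthetic cohort generator.

Emulates the statistical structure of a small, deeply phenotyped propionic
acidemia natural-history cohort: a latent two-class severity (mild /
severe), 12 clinical variables (two of them binary sequelae), 2 established
biochemical biomarkers, a large block of candidate laboratory variables of
which only a few carry signal, heavy missingness in part of the candidate
block, an imperfect three-judge expert panel, and a liver-transplant
subgroup whose biochemical — but not clinical — profile shifts toward the
mild class.

Defaults reproduce the study shape: 40 participants (5 transplanted),
12 + 2 + 459 = 473 variables, 172 of them with >70% missingness so the
downstream filter retains 301.

All randomness flows from ``SimConfig.seed`` through per-stage child
streams, so identical (config, seed) pairs reproduce cohorts bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .breath import R_VPDB, BreathSeries
from .cohort import CohortTable
from .judges import JudgePanel

# The 12 clinical + 2 biochemical model variables, with the sign of the
# severe-class shift (severe PA: lower IQ/growth/cardiac/renal function,
# higher transaminases and propionate metabolites, more sequelae).
CLINICAL_VARIABLES: dict[str, tuple[str, str, int]] = {
    # name: (type, units, severe-shift sign)
    "FSIQ": ("continuous", "IQ points", -1),
    "optic_nerve_abnormality": ("binary", "0/1", +1),
    "SNHL": ("binary", "0/1", +1),
    "height_zscore": ("continuous", "z", -1),
    "ALT": ("continuous", "U/L", +1),
    "WBC": ("continuous", "k/uL", -1),
    "RBC": ("continuous", "m/uL", -1),
    "platelets": ("continuous", "k/uL", -1),
    "LVEF": ("continuous", "%", -1),
    "cystatin_c_egfr": ("continuous", "mL/min/1.73m2", -1),
    "total_protein_intake": ("continuous", "%RDA", +1),
    "incomplete_protein_intake": ("continuous", "%RDA", +1),
}
BIOCHEMICAL_VARIABLES: dict[str, tuple[str, str, int]] = {
    "C3": ("continuous", "umol/L", +1),
    "total_2MC": ("continuous", "nmol/L", +1),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the study conditions."""

    n_participants: int = 40
    n_transplant: int = 5
    n_clinical: int = 12
    n_biochemical: int = 2
    n_candidates: int = 459
    n_informative_candidates: int = 5
    effect_size: float = 1.5          # standardized mean difference, SD units
    missing_rate_range: tuple[float, float] = (0.0, 0.3)
    n_high_missing_vars: int = 172
    judge_error_rate: float = 0.1
    n_judges: int = 3
    seed: int = 0
    heavy_tails: bool = False         # log-normal instead of Gaussian continuous
    mnar: bool = False                # missingness probability rises with severity
    binary_prevalence_mild: float = 0.15

    def __post_init__(self) -> None:
        counts = (
            self.n_participants, self.n_transplant, self.n_clinical,
            self.n_biochemical, self.n_candidates,
            self.n_informative_candidates, self.n_high_missing_vars,
            self.n_judges,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_transplant > self.n_participants:
            raise ValueError("n_transplant cannot exceed n_participants")
        if self.n_informative_candidates > self.n_candidates:
            raise ValueError("informative count exceeds candidate count")
        if not (0.0 <= self.judge_error_rate <= 1.0):
            raise ValueError("judge_error_rate must be a probability")
        lo, hi = self.missing_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("missing_rate_range must be within [0,1]")
        if self.n_clinical > len(CLINICAL_VARIABLES):
            raise ValueError(f"n_clinical capped at {len(CLINICAL_VARIABLES)}")
        if self.n_biochemical > len(BIOCHEMICAL_VARIABLES):
            raise ValueError(f"n_biochemical capped at {len(BIOCHEMICAL_VARIABLES)}")


@dataclass
class LatentTruth:
    """Ground truth behind a synthetic cohort (the unobserved severity that
    the judge panel estimates)."""

    participant_id: list[str]
    true_class: np.ndarray            # "mild"/"severe" per participant
    transplant: np.ndarray            # bool per participant
    informative_vars: dict[str, float]  # variable -> signed effect size (SD units)
    oxidation_capacity_true: np.ndarray  # fraction of dose per 2 h

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.true_class, index=self.participant_id)

    @property
    def transplant_series(self) -> pd.Series:
        return pd.Series(self.transplant, index=self.participant_id)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
def generate_cohort(config: SimConfig) -> tuple[CohortTable, LatentTruth]:
    """Draw a complete (pre-missingness) cohort plus its latent truth.

    Continuous variables are Gaussian class-conditional (log-normal when
    ``heavy_tails``); the severe-class mean is shifted by the planted effect
    size in SD units.  Binary sequelae use a logistic prevalence shift.
    Transplanted participants are drawn from the severe class; their
    biochemical and candidate variables are generated from the mild-class
    distribution while clinical sequela variables keep severe-class values.
    """
    rng = _stage_rng(config.seed, 0)
    n = config.n_participants
    ids = [f"P{i+1:03d}" for i in range(n)]

    # Balanced two-class design: the class prior is 1/2 and the cohort is
    # split as evenly as n allows (keeps the no-signal pipeline calibrated
    # at accuracy 0.5 instead of drifting to a majority-class fraction).
    n_severe = max(n // 2, min(n, max(2, config.n_transplant)))
    severe = np.zeros(n, dtype=bool)
    severe[rng.choice(n, size=n_severe, replace=False)] = True
    transplant = np.zeros(n, dtype=bool)
    severe_idx = np.flatnonzero(severe)
    transplant[rng.choice(severe_idx, size=config.n_transplant, replace=False)] = True

    clin_names = list(CLINICAL_VARIABLES)[: config.n_clinical]
    bio_names = list(BIOCHEMICAL_VARIABLES)[: config.n_biochemical]
    cand_names = [f"candidate_{i+1:04d}" for i in range(config.n_candidates)]
    informative_cand = sorted(
        rng.choice(cand_names, size=config.n_informative_candidates, replace=False)
    )

    meta_rows, informative = [], {}
    columns: dict[str, np.ndarray] = {}
    severe_eff_clinical = severe  # clinical sequelae are not reset by transplant
    severe_eff_biochem = severe & ~transplant  # transplant moves these to mild

    def draw_continuous(rng, name, eff, severe_eff):
        mu = rng.uniform(10.0, 100.0)
        sigma = rng.uniform(1.0, 10.0)
        z = rng.normal(size=n) + eff * severe_eff
        if config.heavy_tails:
            # log-normal with the planted shift on the log scale
            return np.exp(np.log(mu) + 0.25 * z)
        return mu + sigma * z

    def draw_binary(rng, eff, severe_eff):
        p0 = config.binary_prevalence_mild
        logit = np.log(p0 / (1 - p0)) + eff * severe_eff
        p = 1.0 / (1.0 + np.exp(-logit))
        return (rng.random(n) < p).astype(float)

    for name in clin_names:
        vtype, units, sign = CLINICAL_VARIABLES[name]
        eff = sign * config.effect_size
        informative[name] = eff
        if vtype == "binary":
            columns[name] = draw_binary(rng, eff, severe_eff_clinical)
        else:
            columns[name] = draw_continuous(rng, name, eff, severe_eff_clinical)
        meta_rows.append((name, "clinical", vtype, units))

    for name in bio_names:
        vtype, units, sign = BIOCHEMICAL_VARIABLES[name]
        eff = sign * config.effect_size
        informative[name] = eff
        columns[name] = draw_continuous(rng, name, eff, severe_eff_biochem)
        meta_rows.append((name, "biochemical", vtype, units))

    for name in cand_names:
        if name in informative_cand:
            eff = float(rng.choice([-1.0, 1.0])) * config.effect_size
            informative[name] = eff
        else:
            eff = 0.0
        columns[name] = draw_continuous(rng, name, eff, severe_eff_biochem)
        meta_rows.append((name, "candidate", "continuous", "arbitrary"))

    # Propionate oxidation capacity: higher residual oxidation in mild PA;
    # transplantation restores hepatic oxidation (mild-like values).
    mild_like = ~severe | transplant
    capacity = np.where(
        mild_like,
        rng.normal(0.18, 0.04, size=n),
        rng.normal(0.05, 0.015, size=n),
    ).clip(0.005, 0.95)

    values = pd.DataFrame(columns, index=ids)
    meta = pd.DataFrame(
        meta_rows, columns=["name", "kind", "type", "units"]
    ).set_index("name")
    truth = LatentTruth(
        participant_id=ids,
        true_class=np.where(severe, "severe", "mild"),
        transplant=transplant,
        informative_vars=informative,
        oxidation_capacity_true=capacity,
    )
    return CohortTable(values, meta), truth


# ---------------------------------------------------------------------------
def inject_missingness(table: CohortTable, config: SimConfig,
                       truth: LatentTruth | None = None) -> CohortTable:
    """Plant missingness: ``n_high_missing_vars`` candidate variables get a
    missing fraction strictly above 0.70 (so the downstream filter removes
    them); every other variable gets a fraction drawn from
    ``missing_rate_range``.  MCAR by default; with ``config.mnar`` (and a
    truth object) severe participants are twice as likely to be missing.
    Never produces a completely missing participant.
    """
    if table.mask.to_numpy().any():
        raise ValueError("table already carries missingness")
    rng = _stage_rng(config.seed, 1)
    n = table.n_participants
    candidates = table.variables_of_kind("candidate")
    if config.n_high_missing_vars > len(candidates):
        raise ValueError(
            f"n_high_missing_vars={config.n_high_missing_vars} exceeds the "
            f"{len(candidates)} candidate variables available"
        )
    high = set(rng.choice(candidates, size=config.n_high_missing_vars, replace=False))

    if config.mnar and truth is not None:
        weights = np.where(truth.true_class == "severe", 2.0, 1.0)
        weights = weights / weights.sum()
    else:
        weights = None

    floor70 = int(np.floor(0.70 * n))
    lo, hi = config.missing_rate_range
    mask = table.mask.copy()
    for name in table.variables:
        if name in high:
            m = int(rng.integers(floor70 + 1, n))  # strictly >0.70, never all
        else:
            m = int(np.floor(rng.uniform(lo, hi) * n))
        if m == 0:
            continue
        rows = rng.choice(n, size=m, replace=False, p=weights)
        mask.iloc[rows, table.variables.index(name)] = True

    # no completely-missing participants
    arr = mask.to_numpy()
    frac = arr.mean(axis=0)
    for i in np.flatnonzero(arr.all(axis=1)):
        j = int(np.argmin(frac))
        arr[i, j] = False
    out = table.copy()
    out.mask = pd.DataFrame(arr, index=table.values.index, columns=table.values.columns)
    return out


# ---------------------------------------------------------------------------
def simulate_judges(truth: LatentTruth, config: SimConfig) -> JudgePanel:
    """Each judge independently flips the true class with
    ``judge_error_rate``; all calls are stored (consensus is resolved by
    :func:`pa_sevmod.judges.majority_vote`)."""
    if config.n_judges < 1:
        raise ValueError("need at least one judge")
    rng = _stage_rng(config.seed, 2)
    n = len(truth.participant_id)
    calls = {}
    for j in range(config.n_judges):
        flip = rng.random(n) < config.judge_error_rate
        other = np.where(truth.true_class == "severe", "mild", "severe")
        calls[f"judge_{j+1}"] = np.where(flip, other, truth.true_class)
    return JudgePanel(pd.DataFrame(calls, index=truth.participant_id))


# ---------------------------------------------------------------------------
BREATH_TIMES = np.array([0.0, 30.0, 60.0, 120.0])  # min
_RISE_TAU = 40.0  # min; rise-to-plateau time constant of breath enrichment


def simulate_breath_series(
    truth: LatentTruth,
    noise_sd: float = 0.3,          # permil on delta-13C
    seed: int = 0,
    baseline_delta: float = -25.0,  # permil, typical breath CO2
    dose: float = 5e-4,             # mol 1-13C-propionate
) -> dict[str, BreathSeries]:
    """One breath series per participant, scaled so that noiseless trapezoid
    recovery over 0..120 min returns ``oxidation_capacity_true`` exactly.

    Enrichment follows a rise-to-plateau curve 1 - exp(-t/tau); Gaussian
    delta noise (sd ``noise_sd``) is applied to post-dose samples only, so
    the t=0 sample always equals the baseline.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if np.any(truth.oxidation_capacity_true < 0) or np.any(
        truth.oxidation_capacity_true > 1
    ):
        raise ValueError("oxidation_capacity_true must lie in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    t = BREATH_TIMES
    shape = 1.0 - np.exp(-t / _RISE_TAU)
    shape_integral = float(np.trapezoid(shape, t))  # min

    base_atom = 100.0 * (R_VPDB * (baseline_delta / 1000.0 + 1.0)) / (
        1.0 + R_VPDB * (baseline_delta / 1000.0 + 1.0)
    )
    out: dict[str, BreathSeries] = {}
    for i, pid in enumerate(truth.participant_id):
        vco2 = float(np.clip(rng.normal(0.008, 0.001), 0.004, 0.015))  # mol/min
        capacity = float(truth.oxidation_capacity_true[i])
        rate = capacity / shape_integral * shape      # fraction of dose / min
        ape = rate * dose / vco2 * 100.0              # atom-percent excess
        atom = base_atom + ape
        r = atom / (100.0 - atom)
        delta = 1000.0 * (r / R_VPDB - 1.0)
        if noise_sd > 0:
            delta[1:] = delta[1:] + rng.normal(0.0, noise_sd, size=len(t) - 1)
        out[pid] = BreathSeries(
            times=t.copy(),
            delta13c=delta,
            baseline_delta=baseline_delta,
            vco2=vco2,
            dose=dose,
            participant_id=pid,
        )
    return out


def default_config(**overrides) -> SimConfig:
    """Study-shaped configuration with keyword overrides."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()
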