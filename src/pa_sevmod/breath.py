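"""1-13C-propionate breath test: percent dose recovery and oxidation capacity.

An oral dose of 1-13C-propionate is oxidized to 13CO2, which appears in
expired breath.  Isotope ratio mass spectrometry reports breath CO2
enrichment as delta-13C (permil vs the VPDB standard); together with the CO2
production rate VCO2 from indirect calorimetry and the administered dose,
the instantaneous fraction of the dose excreted per minute is

    rate(t) = VCO2 * APE(t) / 100 / dose        [1/min]

where APE is the atom-percent excess above the pre-dose baseline.  The
cumulative percent dose recovery over a window is the trapezoidal integral
of rate(t) times 100; truncating the integral at 60 min gives the propionate
oxidation capacity used as a severity biomarker.

The delta -> APE conversion uses the standard VPDB ratio; VCO2 is treated as
constant at its resting measurement over the 2 h window.  No bicarbonate
retention correction is applied (``retention_factor`` is exposed should one
be wanted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 13C/12C isotope ratio of the VPDB standard.
R_VPDB = 0.0112372

#: Tolerance (permil) within which delta at t=0 must match the baseline.
BASELINE_TOL = 1e-6


def delta_to_ape(delta: np.ndarray | float, baseline: np.ndarray | float) -> np.ndarray | float:
    """Convert delta-13C (permil vs VPDB) to atom-percent excess over baseline.

    R = R_VPDB * (delta/1000 + 1); atom% = 100 * R / (1 + R);
    APE = atom%(delta) - atom%(baseline).
    """
    delta = np.asarray(delta, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(delta <= -1000.0) or np.any(baseline <= -1000.0):
        raise ValueError("delta-13C must exceed -1000 permil (R must stay positive)")
    ape = _atom_percent(delta) - _atom_percent(baseline)
    return ape if ape.ndim else float(ape)


def _atom_percent(delta: np.ndarray) -> np.ndarray:
    r = R_VPDB * (delta / 1000.0 + 1.0)
    return 100.0 * r / (1.0 + r)


@dataclass
class BreathSeries:
    """Timed breath-enrichment measurements for one participant.

    times are minutes post-dose and must include 0 (the baseline sample);
    vco2 is the resting CO2 production rate and dose the moles of
    1-13C-propionate administered, in any consistent unit system (the
    recovery is a dose fraction, so mol/min with mol and mmol/min with mmol
    give identical results).
    """

    times: np.ndarray            # min
    delta13c: np.ndarray         # permil vs VPDB
    baseline_delta: float        # permil
    vco2: float                  # mol CO2 / min
    dose: float                  # mol tracer
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta13c = np.asarray(self.delta13c, dtype=float)
        if self.times.shape != self.delta13c.shape:
            raise ValueError("times and delta13c must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0.0:
            raise ValueError("series must include a t=0 baseline sample")
        if self.dose <= 0 or self.vco2 <= 0:
            raise ValueError("dose and vco2 must be positive")
        if abs(self.delta13c[0] - self.baseline_delta) > max(
            BASELINE_TOL, 1e-9 * abs(self.baseline_delta)
        ):
            raise ValueError("delta at time 0 must equal the baseline")


@dataclass
class RecoveryResult:
    times: np.ndarray                 # min
    rate_percent_per_hour: np.ndarray  # instantaneous % dose / h at each time
    cumulative_percent: float          # % dose over the integrated window
    window: tuple[float, float]
    partial: bool = field(default=False)  # True if the window was clipped


def recovery_percent(series: BreathSeries, retention_factor: float = 1.0) -> RecoveryResult:
    """Percent 13CO2 dose recovery from a breath series.

    Returns the instantaneous excretion rate at each sampled time
    (% dose / hour) and the cumulative trapezoidal recovery (% dose) over
    the full sampled window (0 to the last time, nominally 120 min).
    """
    ape = np.asarray(delta_to_ape(series.delta13c, series.baseline_delta))
    rate_per_min = series.vco2 * (ape / 100.0) / series.dose / retention_factor
    cumulative = float(np.trapezoid(rate_per_min, series.times)) * 100.0
    return RecoveryResult(
        times=series.times.copy(),
        rate_percent_per_hour=rate_per_min * 60.0 * 100.0,
        cumulative_percent=cumulative,
        window=(float(series.times[0]), float(series.times[-1])),
    )


def oxidation_capacity(series: BreathSeries, at: float = 60.0,
                       retention_factor: float = 1.0) -> float:
    """Cumulative percent dose recovery truncated at ``at`` minutes.

    The 60-minute value is the scalar fed to the subset-SVM search as a
    candidate severity biomarker.  ``at`` must lie within the sampled
    window; if it falls between samples the enrichment is interpolated
    linearly in time.
    """
    if at < series.times[0] or at > series.times[-1]:
        raise ValueError(f"at={at} outside sampled window {series.times[0]}..{series.times[-1]}")
    if at == series.times[0]:
        return 0.0
    ape = np.asarray(delta_to_ape(series.delta13c, series.baseline_delta))
    rate_per_min = series.vco2 * (ape / 100.0) / series.dose / retention_factor
    keep = series.times <= at
    t = series.times[keep]
    r = rate_per_min[keep]
    if t[-1] < at:
        r_at = float(np.interp(at, series.times, rate_per_min))
        t = np.append(t, at)
        r = np.append(r, r_at)
    return float(np.trapezoid(r, t)) * 100.0
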