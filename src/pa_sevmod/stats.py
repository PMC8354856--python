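"""Group comparisons, associations, and transplant-validation overlap.

Test selection follows the usual clinical-table rules: per-group normality
is assessed by Shapiro-Wilk at alpha = 0.05 (a group too small to assess is
routed non-parametric); two normal groups get a Student t-test (paired or
unpaired), otherwise Mann-Whitney U (Wilcoxon signed-rank when paired);
three or more normal groups get one-way ANOVA with Tukey's post hoc,
otherwise Kruskal-Wallis with Dunn's post hoc (Bonferroni-adjusted; no
maintained Python implementation of Dunn's rank comparison exists in the
stack, so the standard z-statistic with tie correction is computed here).

Significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

NORMALITY_ALPHA = 0.05


def significance_stars(p: float) -> str:
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return "ns"


@dataclass
class ComparisonResult:
    groups: list[str]
    test_used: str
    statistic: float
    p_value: float
    post_hoc: pd.DataFrame | None = None   # pairwise adjusted p-values
    normal: bool = False
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of range")
        self.stars = significance_stars(self.p_value)


def _groups_normal(groups: list[np.ndarray]) -> bool:
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            return False
        if sps.shapiro(g).pvalue < NORMALITY_ALPHA:
            return False
    return True


def compare_groups(values, group_labels, paired: bool = False) -> ComparisonResult:
    """Compare a variable across groups with automatic test selection."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    names = [str(g) for g in pd.unique(labels)]
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    if paired and len(groups) == 2 and len(groups[0]) != len(groups[1]):
        raise ValueError("paired comparison requires equal group sizes")

    if paired and len(groups) == 2:
        diffs = groups[0] - groups[1]
        normal = _groups_normal([diffs])
        if normal:
            res = sps.ttest_rel(groups[0], groups[1])
            return ComparisonResult(names, "paired t-test", float(res.statistic),
                                    float(res.pvalue), normal=True)
        if np.all(diffs == 0):
            return ComparisonResult(names, "wilcoxon signed-rank", 0.0, 1.0)
        res = sps.wilcoxon(groups[0], groups[1])
        return ComparisonResult(names, "wilcoxon signed-rank",
                                float(res.statistic), float(res.pvalue))

    normal = _groups_normal(groups)
    if len(groups) == 2:
        if normal:
            res = sps.ttest_ind(groups[0], groups[1])
            return ComparisonResult(names, "t-test", float(res.statistic),
                                    float(res.pvalue), normal=True)
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return ComparisonResult(names, "mann-whitney U", float(res.statistic),
                                float(res.pvalue))

    if normal:
        res = sps.f_oneway(*groups)
        tk = pairwise_tukeyhsd(values, labels)
        rows = tk.summary().data[1:]
        post = pd.DataFrame(
            {
                "group_a": [str(r[0]) for r in rows],
                "group_b": [str(r[1]) for r in rows],
                "p_adj": np.asarray(tk.pvalues, dtype=float),
            }
        )
        return ComparisonResult(names, "anova+tukey", float(res.statistic),
                                float(res.pvalue), post_hoc=post, normal=True)
    res = sps.kruskal(*groups)
    post = _dunn_posthoc(groups, names)
    return ComparisonResult(names, "kruskal-wallis+dunn", float(res.statistic),
                            float(res.pvalue), post_hoc=post)


def _dunn_posthoc(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's rank comparison with tie correction, Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * sps.norm.sf(abs(z))
        rows.append((names[i], names[j], z, min(1.0, p * len(pairs))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_adj"])


# ---------------------------------------------------------------------------
@dataclass
class AssociationResult:
    y_type: str                 # continuous | binary
    slope: float                # slope (OLS) or log-odds coefficient (logit)
    p_value: float
    r: float = float("nan")             # Pearson r (continuous y)
    adjusted_r2: float = float("nan")
    odds_ratio: float = float("nan")    # binary y
    pseudo_r2: float = float("nan")
    converged: bool = True
    prediction_band: pd.DataFrame | None = None  # x, fit, lo, hi (95%)


def association(x, y, y_type: str = "continuous", band_points: int = 50) -> AssociationResult:
    """Simple linear (continuous y) or logistic (binary y) association."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must be equal length with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    X = sm.add_constant(x)
    if y_type == "continuous":
        fit = sm.OLS(y, X).fit()
        grid = np.linspace(x.min(), x.max(), band_points)
        pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
        band = pd.DataFrame(
            {
                "x": grid,
                "fit": pred["mean"],
                "lo": pred["obs_ci_lower"],
                "hi": pred["obs_ci_upper"],
            }
        )
        sd_x, sd_y = x.std(), y.std()
        r = float(fit.params[1] * sd_x / sd_y) if sd_y > 0 else float("nan")
        return AssociationResult(
            y_type="continuous",
            slope=float(fit.params[1]),
            p_value=float(fit.pvalues[1]),
            r=r,
            adjusted_r2=float(fit.rsquared_adj),
            prediction_band=band,
        )
    if y_type == "binary":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binary y must be 0/1")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
            converged = bool(fit.mle_retvals.get("converged", True))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            return AssociationResult(
                y_type="binary", slope=float("nan"), p_value=float("nan"),
                converged=False,
            )
        if not converged:
            return AssociationResult(
                y_type="binary", slope=float(fit.params[1]),
                p_value=float("nan"), converged=False,
            )
        return AssociationResult(
            y_type="binary",
            slope=float(fit.params[1]),
            p_value=float(fit.pvalues[1]),
            odds_ratio=float(np.exp(fit.params[1])),
            pseudo_r2=float(fit.prsquared),
        )
    raise ValueError("y_type must be 'continuous' or 'binary'")


# ---------------------------------------------------------------------------
@dataclass
class OverlapReport:
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    b_in_a: int
    a_in_b: int
    frac_b_in_a: float
    frac_a_in_b: float
    no_overlap: bool


def range_overlap(group_a, group_b) -> OverlapReport:
    """Count values of each group falling inside the other group's range.

    "No overlap" is declared iff neither group has a value inside the
    other's [min, max] — the criterion used to call a biomarker cleanly
    separating between severity groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ra, rb = (a.min(), a.max()), (b.min(), b.max())
    b_in_a = int(((b >= ra[0]) & (b <= ra[1])).sum())
    a_in_b = int(((a >= rb[0]) & (a <= rb[1])).sum())
    return OverlapReport(
        range_a=(float(ra[0]), float(ra[1])),
        range_b=(float(rb[0]), float(rb[1])),
        b_in_a=b_in_a,
        a_in_b=a_in_b,
        frac_b_in_a=b_in_a / b.size,
        frac_a_in_b=a_in_b / a.size,
        no_overlap=(b_in_a == 0 and a_in_b == 0),
    )
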