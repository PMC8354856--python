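"""Exhaustive subset search with a polynomial-kernel SVM.

The severity model is a wrapper feature selection: every non-empty subset of
a variable pool is scored by the mean test-set accuracy of a polynomial
kernel SVM, K(x,z) = (gamma <x,z> + c0)^d, over repeated stratified
train/test repartitions of the cohort.  Subsets are ranked by mean accuracy
(ties: smaller subset first, then lexicographic — the minimum-parameter
reading), and the unweighted mean accuracy over all evaluated subsets of a
pool ("pool mean accuracy") summarizes how informative the pool is.

Candidate biomarkers are screened by re-running the search on the clinical
pool plus one candidate at a time and ranking candidates by the resulting
pool mean accuracy against a cutoff defined by established biomarkers.

Hyperparameters (train fraction, kernel degree, C) are not dictated by the
procedure; defaults are stratified 75/25 splits and d=3, gamma=1/p, c0=1,
C=1, with an optional small inner grid.

Implementation note: model fits go through scikit-learn's libsvm binding
directly (``sklearn.svm._libsvm``) because the search performs 10^4-10^6
fits on tiny matrices and the estimator-object overhead dominates
otherwise; predictions are identical to ``sklearn.svm.SVC`` with the same
parameters (asserted in the test suite), and ``SVC`` is kept as a fallback
backend.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortTable

log = logging.getLogger(__name__)

try:  # fast path: raw libsvm binding
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - exercised only on foreign sklearn
    _libsvm = None

POSITIVE_CLASS = "severe"

#: Exhaustive enumeration refuses pools beyond this size unless overridden
#: (2^p subsets; beyond 14 variables the search belongs on a cluster).
DEFAULT_POOL_CAP = 14


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SVMParams:
    """Polynomial-kernel SVM hyperparameters; ``gamma=None`` means 1/p."""

    degree: int = 3
    gamma: float | None = None
    coef0: float = 1.0
    C: float = 1.0
    tune: bool = False   # inner grid over degree x C by resampled accuracy
    tune_degrees: tuple[int, ...] = (1, 2, 3)
    tune_C: tuple[float, ...] = (0.25, 1.0, 4.0)


@dataclass(frozen=True)
class Resampler:
    """Repeated stratified train/test repartitioning."""

    n_rep: int = 200
    train_frac: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rep < 1 or not (0.0 < self.train_frac < 1.0):
            raise ValueError("need n_rep >= 1 and train_frac in (0,1)")


@dataclass
class ConfusionCounts:
    """Test-set confusion counts; positive class = severe."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class SubsetModelResult:
    subset: tuple[str, ...]
    per_resample: list[ConfusionCounts]
    predictions: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None
    # (test indices, y_true, y_pred) per resample when recorded

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([c.accuracy for c in self.per_resample]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([c.sensitivity for c in self.per_resample]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([c.specificity for c in self.per_resample]))


# ---------------------------------------------------------------------------
# label / feature coercion
def _coerce_features(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, CohortTable):
        if not features.is_complete():
            raise ValueError("features must be imputed before modeling")
        return features.values.to_numpy(float), features.variables
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(float), list(features.columns)
    raise TypeError("features must be a CohortTable or DataFrame")


def _coerce_labels(labels, n: int) -> np.ndarray:
    y = np.asarray(labels if not isinstance(labels, pd.Series) else labels.to_numpy())
    if y.shape != (n,):
        raise ValueError("labels must align with participants")
    if y.dtype.kind in "UO":
        y = (y == POSITIVE_CLASS).astype(np.float64)
    else:
        y = y.astype(np.float64)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present in labels")
    return y


def make_splits(y: np.ndarray, resampler: Resampler) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pre-draw stratified train/test index pairs shared across subsets.

    Per class, floor(train_frac * n_class) participants (at least one) go to
    training; the remainder is the test set.  A draw whose test set lacks a
    class is redrawn with the next random state (logged); with per-class
    allocation this only triggers for degenerate fractions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(resampler.seed, spawn_key=(0,)))
    idx0 = np.flatnonzero(y == 0.0)
    idx1 = np.flatnonzero(y == 1.0)
    if min(len(idx0), len(idx1)) < 2:
        raise ValueError("each class needs at least 2 participants")
    splits = []
    redraws = 0
    while len(splits) < resampler.n_rep:
        tr, te = [], []
        for idx in (idx0, idx1):
            perm = rng.permutation(idx)
            n_tr = max(1, int(np.floor(resampler.train_frac * len(idx))))
            n_tr = min(n_tr, len(idx) - 1)
            tr.append(perm[:n_tr])
            te.append(perm[n_tr:])
        test = np.concatenate(te)
        if len(np.unique(y[test])) < 2:  # pragma: no cover - guarded above
            redraws += 1
            if redraws > 100 * resampler.n_rep:
                raise RuntimeError("cannot draw a two-class test split")
            continue
        splits.append((np.concatenate(tr), test))
    if redraws:
        log.info("redrew %d degenerate resamples", redraws)
    return splits


# ---------------------------------------------------------------------------
def _fit_predict(Xtr, ytr, Xte, degree, gamma, coef0, C) -> np.ndarray:
    if _libsvm is not None:
        model = _libsvm.fit(
            Xtr, ytr, svm_type=0, kernel="poly",
            degree=degree, gamma=gamma, coef0=coef0, C=C,
        )
        return _libsvm.predict(
            Xte, *model[:7], kernel="poly", degree=degree, gamma=gamma, coef0=coef0
        )
    from sklearn.svm import SVC  # pragma: no cover

    svc = SVC(kernel="poly", degree=degree, gamma=gamma, coef0=coef0, C=C)
    return svc.fit(Xtr, ytr).predict(Xte)


def _tuned_params(Xtr, ytr, params: SVMParams, gamma: float,
                  seed: int) -> tuple[int, float]:
    """Pick (degree, C) by inner resampled accuracy on the training set."""
    if min(int(ytr.sum()), len(ytr) - int(ytr.sum())) < 2:
        return params.degree, params.C  # too few per class for inner splits
    inner = Resampler(n_rep=10, train_frac=0.75, seed=seed)
    splits = make_splits(ytr, inner)
    best, best_acc = (params.degree, params.C), -1.0
    for d, C in itertools.product(params.tune_degrees, params.tune_C):
        acc = 0.0
        for tr, te in splits:
            pred = _fit_predict(
                np.ascontiguousarray(Xtr[tr]), ytr[tr],
                np.ascontiguousarray(Xtr[te]), d, gamma, params.coef0, C,
            )
            acc += float((pred == ytr[te]).mean())
        acc /= len(splits)
        if acc > best_acc:
            best, best_acc = (d, C), acc
    return best


def _evaluate_columns(
    X: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    params: SVMParams,
    record_predictions: bool = False,
) -> tuple[list[ConfusionCounts], list | None]:
    Xs = np.ascontiguousarray(X[:, cols], dtype=np.float64)
    gamma = params.gamma if params.gamma is not None else 1.0 / len(cols)
    counts, preds = [], [] if record_predictions else None
    for i, (tr, te) in enumerate(splits):
        Xtr = np.ascontiguousarray(Xs[tr])
        Xte = np.ascontiguousarray(Xs[te])
        ytr, yte = y[tr], y[te]
        if params.tune:
            degree, C = _tuned_params(Xtr, ytr, params, gamma, seed=i)
        else:
            degree, C = params.degree, params.C
        pred = _fit_predict(Xtr, ytr, Xte, degree, gamma, params.coef0, C)
        pos = yte == 1.0
        tp = int((pred[pos] == 1.0).sum())
        fn = int(pos.sum()) - tp
        tn = int((pred[~pos] == 0.0).sum())
        fp = int((~pos).sum()) - tn
        counts.append(ConfusionCounts(tp, tn, fp, fn))
        if record_predictions:
            preds.append((te.copy(), yte.copy(), np.asarray(pred).copy()))
    return counts, preds


def evaluate_subset(
    features,
    labels,
    subset: list[str] | tuple[str, ...],
    resampler: Resampler = Resampler(),
    svm_params: SVMParams = SVMParams(),
    record_predictions: bool = False,
    _splits=None,
) -> SubsetModelResult:
    """Mean accuracy / sensitivity / specificity of one variable subset
    under repeated stratified repartitioning."""
    X, names = _coerce_features(features)
    y = _coerce_labels(labels, X.shape[0])
    if not subset:
        raise ValueError("subset must be non-empty")
    missing = [s for s in subset if s not in names]
    if missing:
        raise ValueError(f"subset references unavailable variables: {missing}")
    cols = np.array([names.index(s) for s in subset])
    splits = _splits if _splits is not None else make_splits(y, resampler)
    counts, preds = _evaluate_columns(
        X, y, cols, splits, svm_params, record_predictions
    )
    return SubsetModelResult(tuple(subset), counts, preds)


# ---------------------------------------------------------------------------
@dataclass
class SearchResult:
    results: list[SubsetModelResult]      # sorted: best first
    pool_mean_accuracy: float             # unweighted mean over all subsets
    pool: tuple[str, ...]

    @property
    def best(self) -> SubsetModelResult:
        return self.results[0]


def _sort_key(r: SubsetModelResult):
    return (-r.mean_accuracy, len(r.subset), r.subset)


def exhaustive_search(
    features,
    labels,
    pool: list[str],
    resampler: Resampler = Resampler(),
    svm_params: SVMParams = SVMParams(),
    pool_cap: int = DEFAULT_POOL_CAP,
    override_cap: bool = False,
) -> SearchResult:
    """Evaluate all 2^p - 1 non-empty subsets of ``pool``.

    Results are sorted by mean accuracy, ties broken toward smaller subsets
    then lexicographically.  ``pool_mean_accuracy`` is the unweighted mean
    over all evaluated subsets.
    """
    if len(pool) > pool_cap and not override_cap:
        raise ValueError(
            f"pool of {len(pool)} variables implies {2**len(pool)-1} subsets; "
            "pass override_cap=True to proceed"
        )
    X, names = _coerce_features(features)
    y = _coerce_labels(labels, X.shape[0])
    cols = np.array([names.index(s) for s in pool])
    splits = make_splits(y, resampler)
    results = []
    for mask in range(1, 1 << len(pool)):
        sel = [i for i in range(len(pool)) if mask >> i & 1]
        counts, _ = _evaluate_columns(X, y, cols[sel], splits, svm_params)
        results.append(SubsetModelResult(tuple(pool[i] for i in sel), counts))
    pool_mean = float(np.mean([r.mean_accuracy for r in results]))
    results.sort(key=_sort_key)
    return SearchResult(results, pool_mean, tuple(pool))


# ---------------------------------------------------------------------------
@dataclass
class NullCalibration:
    pool_mean_accuracy: float
    per_subset: pd.Series    # mean null accuracy per subset (index "a+b+c")
    n_rep: int


def permutation_null(
    features,
    labels,
    pool: list[str],
    resampler: Resampler = Resampler(),
    svm_params: SVMParams = SVMParams(),
    pool_cap: int = DEFAULT_POOL_CAP,
) -> NullCalibration:
    """Pool mean accuracy under the label-permutation null.

    Each resample permutes the class labels across participants before the
    stratified repartition, breaking any label-feature association while
    preserving the class balance; averaging over resamples estimates the
    chance-level accuracy of the whole subset search (~0.5 for a balanced
    two-class cohort).  The permutation and split sequence is shared across
    subsets.
    """
    if len(pool) > pool_cap:
        raise ValueError(f"pool of {len(pool)} exceeds cap {pool_cap}")
    X, names = _coerce_features(features)
    y0 = _coerce_labels(labels, X.shape[0])
    cols = np.array([names.index(s) for s in pool])
    rng = np.random.default_rng(np.random.SeedSequence(resampler.seed, spawn_key=(2,)))
    reps = []
    for _ in range(resampler.n_rep):
        y = rng.permutation(y0)
        idx0, idx1 = np.flatnonzero(y == 0.0), np.flatnonzero(y == 1.0)
        tr, te = [], []
        for idx in (idx0, idx1):
            perm = rng.permutation(idx)
            n_tr = min(max(1, int(np.floor(resampler.train_frac * len(idx)))),
                       len(idx) - 1)
            tr.append(perm[:n_tr])
            te.append(perm[n_tr:])
        reps.append((y, np.concatenate(tr), np.concatenate(te)))

    subset_names, subset_accs = [], []
    for mask in range(1, 1 << len(pool)):
        sel = [i for i in range(len(pool)) if mask >> i & 1]
        Xs = np.ascontiguousarray(X[:, cols[sel]], dtype=np.float64)
        gamma = svm_params.gamma if svm_params.gamma is not None else 1.0 / len(sel)
        acc = 0.0
        for y, tr, te in reps:
            pred = _fit_predict(
                np.ascontiguousarray(Xs[tr]), y[tr], np.ascontiguousarray(Xs[te]),
                svm_params.degree, gamma, svm_params.coef0, svm_params.C,
            )
            acc += float((pred == y[te]).mean())
        subset_names.append("+".join(pool[i] for i in sel))
        subset_accs.append(acc / resampler.n_rep)
    per_subset = pd.Series(subset_accs, index=subset_names)
    return NullCalibration(
        pool_mean_accuracy=float(per_subset.mean()),
        per_subset=per_subset,
        n_rep=resampler.n_rep,
    )


# ---------------------------------------------------------------------------
@dataclass
class RankingTable:
    """Candidates ranked by the pool mean accuracy of their 12+1 search."""

    entries: pd.DataFrame   # columns: candidate, score, rank, above_cutoff
    cutoff: float           # best score among the reference biomarkers (NaN if none)
    reference: tuple[str, ...]
    n_subsets_evaluated: int

    def rank_of(self, name: str) -> int:
        row = self.entries.loc[self.entries["candidate"] == name, "rank"]
        if row.empty:
            raise KeyError(name)
        return int(row.iloc[0])


def screen_candidates(
    features,
    labels,
    clinical_pool: list[str],
    candidates: list[str],
    resampler: Resampler = Resampler(),
    svm_params: SVMParams = SVMParams(),
    budget: int | None = None,
    reference: tuple[str, ...] = (),
) -> RankingTable:
    """Score each candidate by the pool mean accuracy of clinical_pool + {v}.

    With ``budget=None`` all non-empty subsets of the (p+1)-variable pool
    are evaluated; otherwise a seeded random sample of ``budget`` subset
    patterns is drawn once and reused for every candidate, so scores stay
    comparable.  Subsets that do not include the candidate slot are shared
    across candidates and evaluated once.  The cutoff is the highest score
    among the ``reference`` variables (established biomarkers screened as
    candidates); candidates above it are flagged as the novel-biomarker
    tier.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    overlap = set(candidates) & set(clinical_pool)
    if overlap:
        raise ValueError(f"candidates must be disjoint from the pool: {sorted(overlap)}")
    missing_ref = set(reference) - set(candidates)
    if missing_ref:
        raise ValueError(f"reference variables must be screened candidates: {sorted(missing_ref)}")
    X, names = _coerce_features(features)
    y = _coerce_labels(labels, X.shape[0])
    p = len(clinical_pool)
    n_patterns_all = (1 << (p + 1)) - 1
    if budget is None or budget >= n_patterns_all:
        patterns = np.arange(1, n_patterns_all + 1)
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence(resampler.seed, spawn_key=(1,))
        )
        patterns = rng.choice(n_patterns_all, size=budget, replace=False) + 1
    splits = make_splits(y, resampler)
    clin_cols = np.array([names.index(s) for s in clinical_pool])

    shared_accs = []
    inclusion_sels = []
    for mask in patterns:
        sel = [i for i in range(p) if mask >> i & 1]
        if mask >> p & 1:
            inclusion_sels.append(sel)
        else:
            counts, _ = _evaluate_columns(X, y, clin_cols[sel], splits, svm_params)
            shared_accs.append(float(np.mean([c.accuracy for c in counts])))
    if not inclusion_sels:
        raise ValueError("subset budget sampled no candidate-containing subsets")

    scores = {}
    for v in candidates:
        v_col = names.index(v)
        accs = list(shared_accs)
        for sel in inclusion_sels:
            cols = np.append(clin_cols[sel], v_col)
            counts, _ = _evaluate_columns(X, y, cols, splits, svm_params)
            accs.append(float(np.mean([c.accuracy for c in counts])))
        scores[v] = float(np.mean(accs))

    entries = pd.DataFrame(
        sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["candidate", "score"],
    )
    entries["rank"] = np.arange(1, len(entries) + 1)
    cutoff = max((scores[r] for r in reference), default=float("nan"))
    entries["above_cutoff"] = entries["score"] > cutoff if reference else False
    return RankingTable(
        entries=entries,
        cutoff=float(cutoff),
        reference=tuple(reference),
        n_subsets_evaluated=len(patterns),
    )


# ---------------------------------------------------------------------------
@dataclass
class ImportanceProfile:
    """Per-variable importance on a 0-100 scale, averaged over resamples.

    Raw importance is the single-variable ROC AUC against the labels,
    folded above 0.5 (a filter importance: kernel SVMs expose no
    coefficients), averaged over stratified resamples, then min-max scaled
    so the most influential variable reads 100.
    """

    scores: pd.Series    # scaled to [0, 100]
    raw: pd.Series       # mean folded AUC in [0.5, 1]
    n_rep: int


def variable_importance(
    features,
    labels,
    pool: list[str],
    n_rep: int = 1000,
    seed: int = 0,
    train_frac: float = 0.75,
) -> ImportanceProfile:
    X, names = _coerce_features(features)
    y = _coerce_labels(labels, X.shape[0])
    cols = np.array([names.index(s) for s in pool])
    Xp = X[:, cols]
    constant = Xp.std(axis=0) == 0.0
    if constant.any():
        log.warning(
            "constant variable(s) %s: importance fixed at the null AUC",
            [pool[i] for i in np.flatnonzero(constant)],
        )
    splits = make_splits(y, Resampler(n_rep=n_rep, train_frac=train_frac, seed=seed))
    total = np.zeros(len(pool))
    for tr, _ in splits:
        ysub = y[tr]
        n1 = int(ysub.sum())
        n0 = len(ysub) - n1
        ranks = rankdata(Xp[tr], axis=0)
        auc = (ranks[ysub == 1.0].sum(axis=0) - n1 * (n1 + 1) / 2) / (n0 * n1)
        total += np.maximum(auc, 1.0 - auc)
    raw = total / len(splits)
    raw[constant] = 0.5
    lo, hi = raw.min(), raw.max()
    scaled = np.zeros_like(raw) if hi == lo else 100.0 * (raw - lo) / (hi - lo)
    return ImportanceProfile(
        scores=pd.Series(scaled, index=pool),
        raw=pd.Series(raw, index=pool),
        n_rep=n_rep,
    )


# ---------------------------------------------------------------------------
@dataclass
class LearningCurvePoint:
    n: int
    mean_accuracy: float
    best_subset: tuple[str, ...]


def learning_curve(
    features,
    labels,
    enrollment_order: list,
    pool: list[str],
    resampler: Resampler = Resampler(),
    svm_params: SVMParams = SVMParams(),
    n_min: int | None = None,
) -> tuple[list[LearningCurvePoint], list[int]]:
    """Best-subset accuracy as participants accrue in enrollment order.

    For each prefix of ``enrollment_order`` the exhaustive search is re-run
    on the prefix cohort and the best subset's mean accuracy reported.
    Prefixes with fewer than two participants of either class are skipped
    (returned in the second element).
    """
    X, names = _coerce_features(features)
    if isinstance(features, CohortTable):
        index = features.participants
    else:
        index = list(features.index)
    pos = [index.index(e) for e in enrollment_order]
    y_all = _coerce_labels(labels, X.shape[0])
    lo = n_min if n_min is not None else 4
    points, skipped = [], []
    for n in range(lo, len(pos) + 1):
        rows = np.array(pos[:n])
        y = y_all[rows]
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            skipped.append(n)
            log.info("prefix n=%d skipped: a class has <2 participants", n)
            continue
        sub = pd.DataFrame(X[rows][:, :], columns=names)
        search = exhaustive_search(sub, y, pool, resampler, svm_params)
        points.append(
            LearningCurvePoint(n, search.best.mean_accuracy, search.best.subset)
        )
    return points, skipped


# ---------------------------------------------------------------------------
def count_planned_fits(pool_size: int, n_rep: int) -> int:
    """Number of SVM fits an exhaustive run will launch: 2^p * R.

    Counts every subset including the empty one, which maps to a
    majority-class baseline model; exact big-integer arithmetic.
    """
    if pool_size < 0 or n_rep < 1:
        raise ValueError("need pool_size >= 0 and n_rep >= 1")
    return (1 << int(pool_size)) * int(n_rep)
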