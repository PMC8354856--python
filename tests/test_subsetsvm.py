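"""Subset-SVM search: metrics, enumeration, screening, importance,
learning curve, scheduler, and determinism."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

import pa_sevmod as pm
from pa_sevmod.subsetsvm import ConfusionCounts, _fit_predict, make_splits


def test_confusion_metric_formulas():
    c = ConfusionCounts(tp=3, tn=4, fp=1, fn=2)
    assert c.accuracy == pytest.approx(0.7)
    assert c.sensitivity == pytest.approx(0.6)
    assert c.specificity == pytest.approx(0.8)
    assert c.total == 10


def test_fast_backend_matches_svc(rng):
    """The libsvm fast path must reproduce sklearn.svm.SVC predictions
    exactly for the same polynomial-kernel parameters."""
    for _ in range(20):
        n, p = rng.integers(12, 30), rng.integers(1, 8)
        X = rng.normal(size=(n, p))
        y = np.zeros(n)
        y[rng.choice(n, size=n // 2, replace=False)] = 1.0
        Xt = rng.normal(size=(7, p))
        gamma = 1.0 / p
        pred = _fit_predict(np.ascontiguousarray(X), y,
                            np.ascontiguousarray(Xt), 3, gamma, 1.0, 1.0)
        svc = SVC(kernel="poly", degree=3, gamma=gamma, coef0=1.0, C=1.0)
        ref = svc.fit(X, y).predict(Xt)
        assert np.array_equal(np.asarray(pred), ref)


def test_separable_feature_perfect_accuracy():
    x = np.concatenate([np.linspace(-12, -10, 10), np.linspace(10, 12, 10)])
    features = pd.DataFrame({"marker": x})
    labels = np.array(["mild"] * 10 + ["severe"] * 10)
    res = pm.evaluate_subset(features, labels, ["marker"],
                             pm.Resampler(n_rep=50, seed=0))
    assert res.mean_accuracy == 1.0
    assert res.mean_sensitivity == 1.0
    assert res.mean_specificity == 1.0


def test_evaluate_subset_validations(small_processed):
    _, processed, _, labels = small_processed
    with pytest.raises(ValueError, match="non-empty"):
        pm.evaluate_subset(processed, labels, [])
    with pytest.raises(ValueError, match="unavailable"):
        pm.evaluate_subset(processed, labels, ["nope"])
    with pytest.raises(ValueError, match="classes"):
        pm.evaluate_subset(processed, pd.Series("severe", index=labels.index),
                           ["FSIQ"])


def test_metrics_match_brute_force_recount(small_processed):
    """Accuracy/sensitivity/specificity recomputed from raw predictions on
    every resample must equal the reported confusion-based values."""
    _, processed, _, labels = small_processed
    res = pm.evaluate_subset(processed, labels, ["FSIQ", "ALT", "C3"],
                             pm.Resampler(n_rep=40, seed=3),
                             record_predictions=True)
    y = (labels.to_numpy() == "severe").astype(float)
    for counts, (te, yte, pred) in zip(res.per_resample, res.predictions):
        assert np.array_equal(yte, y[te])
        tp = int(((pred == 1) & (yte == 1)).sum())
        tn = int(((pred == 0) & (yte == 0)).sum())
        fp = int(((pred == 1) & (yte == 0)).sum())
        fn = int(((pred == 0) & (yte == 1)).sum())
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
        assert counts.accuracy == (tp + tn) / len(te)


def test_exhaustive_search_enumerates_all_subsets(small_processed):
    _, processed, _, labels = small_processed
    pool = processed.variables_of_kind("clinical")[:4]
    search = pm.exhaustive_search(processed, labels, pool,
                                  pm.Resampler(n_rep=10, seed=1))
    assert len(search.results) == 2**4 - 1
    accs = [r.mean_accuracy for r in search.results]
    assert accs == sorted(accs, reverse=True)
    assert search.pool_mean_accuracy == pytest.approx(np.mean(accs))
    assert all(0.0 <= a <= 1.0 for a in accs)


def test_exhaustive_search_pool_cap():
    features = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 16)),
                            columns=[f"v{i}" for i in range(16)])
    labels = np.array(["mild", "severe"] * 10)
    with pytest.raises(ValueError, match="override_cap"):
        pm.exhaustive_search(features, labels, list(features.columns),
                             pm.Resampler(n_rep=2, seed=0))


def test_search_determinism_bit_for_bit(small_processed):
    _, processed, _, labels = small_processed
    pool = processed.variables_of_kind("clinical")[:3]
    a = pm.exhaustive_search(processed, labels, pool, pm.Resampler(30, 0.75, 9))
    b = pm.exhaustive_search(processed, labels, pool, pm.Resampler(30, 0.75, 9))
    for ra, rb in zip(a.results, b.results):
        assert ra.subset == rb.subset
        assert [c.accuracy for c in ra.per_resample] == \
               [c.accuracy for c in rb.per_resample]


def test_single_informative_variable_found(rng):
    """A planted informative variable among noise lands in the best subset
    in nearly all seeds."""
    hits = 0
    for seed in range(20):
        g = np.random.default_rng(seed)
        n = 30
        y = np.array([0.0, 1.0] * 15)
        X = g.normal(size=(n, 6))
        X[:, 2] += 2.5 * y
        features = pd.DataFrame(X, columns=[f"v{i}" for i in range(6)])
        search = pm.exhaustive_search(features, y, list(features.columns),
                                      pm.Resampler(n_rep=30, seed=seed))
        hits += "v2" in search.best.subset
    assert hits >= 19


def test_pool_mean_accuracy_monotone_in_effect_size():
    accs = []
    for es in [0.0, 0.5, 1.0, 2.0, 3.0]:
        cfg = pm.SimConfig(n_participants=30, n_transplant=0, n_clinical=3,
                           n_biochemical=0, n_candidates=0,
                           n_informative_candidates=0, effect_size=es,
                           n_high_missing_vars=0,
                           missing_rate_range=(0.0, 0.0), seed=7)
        cohort, truth = pm.generate_cohort(cfg)
        processed, _ = pm.preprocess_cohort(cohort)
        labels = pd.Series(truth.true_class, index=truth.participant_id)
        s = pm.exhaustive_search(processed, labels,
                                 processed.variables_of_kind("clinical"),
                                 pm.Resampler(n_rep=50, seed=9))
        accs.append(s.pool_mean_accuracy)
    assert all(b >= a - 0.05 for a, b in zip(accs, accs[1:]))
    assert accs[-1] > accs[0] + 0.2


def test_permutation_null_centered_at_half(small_processed):
    _, processed, _, labels = small_processed
    pool = processed.variables_of_kind("clinical")[:4]
    null = pm.permutation_null(processed, labels, pool,
                               pm.Resampler(n_rep=100, seed=17))
    assert null.pool_mean_accuracy == pytest.approx(0.5, abs=0.06)


def test_screening_identical_candidates_get_identical_scores(small_processed):
    """Two candidates with identical columns must tie exactly (same subset
    sample, same splits)."""
    _, processed, _, labels = small_processed
    df = processed.values.copy()
    df["dup_a"] = df["C3"] * 0.5 + 0.25   # affine copies of the same signal
    df["dup_b"] = df["C3"] * 0.5 + 0.25
    clin = processed.variables_of_kind("clinical")[:5]
    rk = pm.screen_candidates(df, labels, clin, ["dup_a", "dup_b"],
                              pm.Resampler(n_rep=20, seed=3), budget=10)
    scores = rk.entries.set_index("candidate")["score"]
    assert scores["dup_a"] == scores["dup_b"]


def test_screening_reference_defines_cutoff(small_processed):
    _, processed, _, labels = small_processed
    clin = processed.variables_of_kind("clinical")[:5]
    cands = processed.variables_of_kind("biochemical") + \
        processed.variables_of_kind("candidate")
    rk = pm.screen_candidates(processed, labels, clin, cands,
                              pm.Resampler(n_rep=20, seed=5), budget=12,
                              reference=("C3", "total_2MC"))
    scores = rk.entries.set_index("candidate")["score"]
    assert rk.cutoff == pytest.approx(max(scores["C3"], scores["total_2MC"]))
    flagged = rk.entries[rk.entries["above_cutoff"]]["candidate"]
    assert set(flagged) == set(scores.index[scores > rk.cutoff])
    assert sorted(rk.entries["rank"]) == list(range(1, len(cands) + 1))


def test_screening_validations(small_processed):
    _, processed, _, labels = small_processed
    clin = processed.variables_of_kind("clinical")[:3]
    with pytest.raises(ValueError, match="empty"):
        pm.screen_candidates(processed, labels, clin, [])
    with pytest.raises(ValueError, match="disjoint"):
        pm.screen_candidates(processed, labels, clin, [clin[0]])


def test_importance_perfect_variable_scores_100(rng):
    n = 40
    y = np.array([0.0, 1.0] * (n // 2))
    X = rng.normal(size=(n, 4))
    X[:, 0] = y * 10 + rng.normal(scale=0.01, size=n)   # perfect separator
    X[:, 3] = X[:, 0]                                   # identical twin
    features = pd.DataFrame(X, columns=["sep", "n1", "n2", "twin"])
    prof = pm.variable_importance(features, y, list(features.columns),
                                  n_rep=100, seed=0)
    assert prof.scores.max() == 100.0
    assert prof.scores["sep"] == pytest.approx(prof.scores["twin"], abs=1e-9)
    assert prof.raw["sep"] == pytest.approx(1.0, abs=1e-9)
    # label-independent variables sit near the profile minimum
    assert prof.scores[["n1", "n2"]].max() < 30.0


def test_importance_constant_variable_zero(rng):
    n = 30
    y = np.array([0.0, 1.0] * 15)
    features = pd.DataFrame({
        "flat": np.ones(n),
        "signal": y + rng.normal(scale=0.2, size=n),
    })
    prof = pm.variable_importance(features, y, ["flat", "signal"],
                                  n_rep=50, seed=1)
    assert prof.scores["flat"] == 0.0
    assert prof.raw["flat"] == 0.5


def test_learning_curve_plateau_and_consistency(small_processed):
    _, processed, truth, labels = small_processed
    # continuous-only pool: a separable cohort plateaus early
    pool = ["FSIQ", "height_zscore", "ALT", "WBC"]
    order = list(processed.participants)
    points, skipped = pm.learning_curve(processed, labels, order, pool,
                                        pm.Resampler(n_rep=50, seed=5))
    by_n = {p.n: p.mean_accuracy for p in points}
    full = pm.exhaustive_search(processed, labels, pool,
                                pm.Resampler(n_rep=50, seed=5))
    assert by_n[len(order)] == full.best.mean_accuracy
    assert abs(by_n[15] - by_n[len(order)]) <= 0.05  # plateau by n=15


def test_learning_curve_dips_on_mislabeled_participant(small_processed):
    _, processed, _, labels = small_processed
    pool = ["FSIQ", "height_zscore", "ALT", "WBC"]
    order = list(processed.participants)
    flipped = labels.copy()
    pid = order[9]
    flipped[pid] = "mild" if flipped[pid] == "severe" else "severe"
    pts, _ = pm.learning_curve(processed, flipped, order, pool,
                               pm.Resampler(n_rep=50, seed=5))
    by_n = {p.n: p.mean_accuracy for p in pts}
    assert by_n[10] < by_n[9]


@pytest.mark.parametrize(
    "p, reps, expected",
    [(13, 1000, 8_192_000), (2, 1, 4), (0, 5, 5), (40, 1000, 2**40 * 1000)],
)
def test_count_planned_fits(p, reps, expected):
    assert pm.count_planned_fits(p, reps) == expected


def test_count_planned_fits_validates():
    with pytest.raises(ValueError):
        pm.count_planned_fits(-1, 10)
    with pytest.raises(ValueError):
        pm.count_planned_fits(3, 0)


def test_splits_are_stratified(small_processed):
    _, processed, _, labels = small_processed
    y = (labels.to_numpy() == "severe").astype(float)
    splits = make_splits(y, pm.Resampler(n_rep=25, train_frac=0.75, seed=2))
    for tr, te in splits:
        assert len(np.unique(y[tr])) == 2
        assert len(np.unique(y[te])) == 2
        assert len(tr) + len(te) == len(y)
        assert not set(tr) & set(te)
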