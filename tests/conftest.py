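import numpy as np
import pandas as pd
import pytest

import pa_sevmod as pm


@pytest.fixture(scope="session")
def study_cohort():
    """Full study-shaped cohort: 40 participants, 473 variables, 5 LT."""
    cfg = pm.default_config(seed=0)
    cohort, truth = pm.generate_cohort(cfg)
    cohort = pm.inject_missingness(cohort, cfg, truth)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_processed():
    """Small complete cohort with strong signal for supervised tests."""
    cfg = pm.SimConfig(
        n_participants=30, n_transplant=0, n_clinical=6, n_biochemical=2,
        n_candidates=4, n_informative_candidates=2, effect_size=2.5,
        n_high_missing_vars=0, missing_rate_range=(0.0, 0.0), seed=2,
    )
    cohort, truth = pm.generate_cohort(cfg)
    processed, _ = pm.preprocess_cohort(cohort)
    labels = pd.Series(truth.true_class, index=truth.participant_id)
    return cfg, processed, truth, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
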