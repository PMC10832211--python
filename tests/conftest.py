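import numpy as np
import pytest

from mmgrowth import CohortConfig, GrowthSeries, MMParams, generate_cohort, mm_value

VISIT_AGES = np.array([1, 60, 120, 240, 365, 545, 730, 1095], dtype=float)


def make_series(params, ages=VISIT_AGES, noise_sd=0.0, rng=None,
                subject_id="S0", sex="male", measure="weight"):
    """Series lying on (or noisily around) a known growth curve."""
    values = mm_value(params, ages)
    if noise_sd:
        values = values + (rng or np.random.default_rng(0)).normal(0, noise_sd, ages.size)
    return GrowthSeries.from_arrays(subject_id, sex, measure, ages, values)


@pytest.fixture(scope="session")
def exact_series():
    return make_series(MMParams(15.0, 400.0, 3.3))


@pytest.fixture(scope="session")
def small_cohort():
    """200 noisy weight subjects, complete visits, no linear growers."""
    cfg = CohortConfig(n_subjects=200, seed=20240201, linear_grower_fraction=0.0)
    cohort, truths = generate_cohort(cfg)
    return cohort, truths, cfg
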