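import numpy as np
import pytest

from negprog import CohortConfig, add_outcome_labels, generate_cohort, make_lso_scheme


@pytest.fixture(scope="session")
def signal_cohort():
    """Planted-signal 7-site cohort (700 subjects, 8 signal ROIs at d=0.8)."""
    generated = generate_cohort(
        CohortConfig(n_per_site=100, seed=7, n_signal_rois=8, roi_effect=0.8,
                     clinical_effect=0.6)
    )
    table = add_outcome_labels(generated.table)
    return table, generated.metadata


@pytest.fixture(scope="session")
def signal_scheme(signal_cohort):
    table, _ = signal_cohort
    y = table["negsym_bad"].to_numpy()
    return make_lso_scheme(table, y, inner_k=5, inner_r=2, seed=7)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort (94 subjects across 7 sites, 40% target prevalence)."""
    generated = generate_cohort(CohortConfig(seed=11))
    return add_outcome_labels(generated.table), generated.metadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
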