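import numpy as np
import pytest

from lfqdx import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort: 4 groups, 2 pairs/patient."""
    spec = CohortSpec(
        n_patients_per_group={"D": 4, "G": 4, "H": 2, "N": 4},
        n_pairs_per_patient=2,
        n_proteins=80,
        n_informative=24,
        effect_size=2.0,
        detection_rate=0.9,
        seed=11,
    )
    matrix, meta = generate_cohort(spec)
    return spec, matrix, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
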