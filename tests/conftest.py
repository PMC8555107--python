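import numpy as np
import pandas as pd
import pytest

from peptidome_dx.cohort import CohortConfig, cohort_to_frame, generate_cohort
from peptidome_dx.peptidome import PeptidomeConfig, generate_peptidome


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(CohortConfig(), seed=7)


@pytest.fixture(scope="session")
def workers(cohort):
    return cohort_to_frame(cohort)


@pytest.fixture(scope="session")
def small_synth(cohort):
    """A reduced peptidome keeping the planted class structure."""
    cfg = PeptidomeConfig(
        n_features=1200, n_responsive=180, n_top_discriminant=15, n_nuisance=12
    )
    return generate_peptidome(cohort, cfg, seed=11)


def toy_matrix(values, workers=None, loq=1.0):
    """Build a QuantMatrix from a nested list / array quickly."""
    from peptidome_dx.quant import QuantMatrix

    arr = np.asarray(values, dtype=float)
    cols = workers or [f"w{i}" for i in range(arr.shape[1])]
    frame = pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=cols)
    return QuantMatrix(values=frame, intensity_loq=loq)
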