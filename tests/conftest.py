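import numpy as np
import pytest

from depimpute import PairedExpressionSet, CovariateTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_bundle():
    """N=5 subjects, G=4 features, S=2 missing, 2 continuous + 1 binary covariates."""
    rng = np.random.default_rng(7)
    normal = rng.normal(2.0, 1.0, size=(5, 4))
    tumor = rng.normal(2.0, 1.0, size=(5, 4))
    normal[1] = np.nan
    normal[4] = np.nan
    subjects = [f"s{i}" for i in range(1, 6)]
    features = [f"g{j}" for j in range(1, 5)]
    pes = PairedExpressionSet.from_matrices(normal, tumor, subjects, features)
    cov = CovariateTable(
        continuous=rng.normal(size=(5, 2)),
        binary=rng.integers(0, 2, size=(5, 1)).astype(float),
        continuous_names=["age", "bmi"],
        binary_names=["gender"],
        subject_ids=subjects,
    )
    return pes, cov
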