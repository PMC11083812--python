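import numpy as np
import pytest

from nanoform import bbd_design
from nanoform.datasets import (
    load_cbd_sln_design,
    load_cbd_sln_factors,
)


@pytest.fixture(scope="session")
def factors():
    return load_cbd_sln_factors()


@pytest.fixture(scope="session")
def study_design():
    """The packaged 15-run formulation study with all four responses."""
    return load_cbd_sln_design()


@pytest.fixture(scope="session")
def empty_bbd(factors):
    """A freshly generated 12+3 BBD with no responses."""
    return bbd_design(factors, n_center=3)


def ols_oracle(X, y):
    """Brute-force normal-equations solution (independent of the package)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
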