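import numpy as np
import pytest

from circtargets.fixtures import make_standard_fixture
from circtargets.scanner import scan_circ


@pytest.fixture(scope="session")
def bundle():
    """The standard synthetic fixture: one circRNA, 20 miRNAs, ground truth."""
    return make_standard_fixture(seed=1)


@pytest.fixture(scope="session")
def scan_results(bundle):
    return scan_circ(bundle.circ, bundle.mirnas)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def rand_rna(rng, n: int) -> str:
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))
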