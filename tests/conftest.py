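import numpy as np
import pytest

from genewise.simgeno import GenotypeMatrix, HaplotypePanel
from genewise.simpheno import CaseControlSample, PhenotypeVector


@pytest.fixture(scope="session")
def coalescent_panel():
    """One fixed coalescent panel (100 sequences, full 10 kb region)."""
    from genewise.simgeno import CoalescentParams, simulate_coalescent_panel

    return simulate_coalescent_panel(CoalescentParams(), seed=20240917)


@pytest.fixture
def synthetic_panel():
    """Deterministic synthetic 25-site panel (no coalescent machinery)."""
    rng = np.random.default_rng(5)
    alleles = rng.integers(0, 2, size=(40, 25))
    # force every site polymorphic
    alleles[0] = 0
    alleles[1] = 1
    return HaplotypePanel(alleles, np.arange(25, dtype=float) * 10 + 5, 260)


def make_sample(dosages, labels) -> CaseControlSample:
    return CaseControlSample(
        GenotypeMatrix(np.asarray(dosages)),
        PhenotypeVector(np.asarray(labels)),
    )


@pytest.fixture
def tiny_sample():
    """The 8-individual worked instance used by the score-test oracle."""
    x = np.array([2, 1, 1, 0, 1, 1, 0, 0]).reshape(-1, 1)
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    return make_sample(x, y)
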