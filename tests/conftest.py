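import numpy as np
import pytest

from epibench.cohort import PairTable
from epibench.panel import LocusInfo, TemplatePanel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel():
    """Deterministic 8-template, 12-locus panel on two chromosomes."""
    rng = np.random.default_rng(5)
    g = rng.integers(0, 3, size=(8, 12)).astype(np.int8)
    loci = [LocusInfo(f"c1_{i}", 1, 1000 * (i + 1)) for i in range(6)] + [
        LocusInfo(f"c2_{i}", 2, 1000 * (i + 1)) for i in range(6)
    ]
    return TemplatePanel(g, loci)


def random_dense_table(rng, n=2000, conc=5.0) -> PairTable:
    """A random 2x3x3 table with no empty cells (resampled until dense)."""
    while True:
        probs = rng.dirichlet(np.full(9, conc), size=2)
        ctrl = rng.multinomial(n, probs[0]).reshape(3, 3)
        case = rng.multinomial(n, probs[1]).reshape(3, 3)
        if (ctrl > 0).all() and (case > 0).all():
            return PairTable(np.stack([ctrl, case]))
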