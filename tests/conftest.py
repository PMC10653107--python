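import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cvxray.integrals import IntegralSet, OrbitalSpace, symmetrize_eri


def random_integrals(n_orb: int, seed: int, with_soc: bool = True, with_dip: bool = True,
                     e_core: float = 0.0) -> IntegralSet:
    """Random but symmetry-correct integrals for property tests."""
    rng = np.random.default_rng(seed)
    h1 = rng.normal(size=(n_orb, n_orb))
    h1 = 0.5 * (h1 + h1.T)
    eri = symmetrize_eri(0.3 * rng.normal(size=(n_orb,) * 4))
    soc = np.zeros((3, n_orb, n_orb), dtype=complex)
    if with_soc:
        for c in range(3):
            a = 0.2 * rng.normal(size=(n_orb, n_orb))
            soc[c] = 1j * (a - a.T)
    dip = np.zeros((3, n_orb, n_orb))
    if with_dip:
        for c in range(3):
            a = rng.normal(size=(n_orb, n_orb))
            dip[c] = 0.5 * (a + a.T)
    return IntegralSet(OrbitalSpace.default(n_orb), e_core, h1, eri, soc, dip)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
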