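import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from modict import CaTrace, DomainSet, RmsdProfile, make_backbone


@pytest.fixture
def helix10() -> CaTrace:
    return make_backbone(10)


@pytest.fixture
def whole_domain():
    def _make(n: int) -> DomainSet:
        return DomainSet(((1, n),))

    return _make


@pytest.fixture
def random_profile():
    """Factory for seeded random profiles with consistent overall RMSD."""

    def _make(n: int, seed: int) -> RmsdProfile:
        rng = np.random.default_rng(seed)
        dev = rng.uniform(0.0, 3.0, size=n)
        return RmsdProfile.from_deviations(dev)

    return _make


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.800   5.228  -4.237  1.00  0.00           C
ATOM      4  CA  GLY A   2      10.513   4.009  -2.038  1.00  0.00           C
ATOM      5  CA  SER A   3       9.034   1.982   0.469  1.00  0.00           C
END
"""


@pytest.fixture
def three_residue_pdb() -> str:
    return THREE_RESIDUE_PDB
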