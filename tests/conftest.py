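import numpy as np
import pytest

from pathweaver.fixtures import FixtureSpec, build_peptide, make_transition_pair, two_domain_pair
from pathweaver.structure import pair_residues


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue poly-alanine alpha-helix (phi=-57, psi=-47)."""
    return build_peptide(FixtureSpec(12, phi=-57.0, psi=-47.0))


@pytest.fixture(scope="session")
def hinge8_pair():
    """8-residue helix whose goal differs by a single 40-degree psi hinge."""
    spec = FixtureSpec(8, phi=-57.0, psi=-47.0, hinge_residues=frozenset({4}))
    start, goal = make_transition_pair(spec, {4: (None, 40.0)})
    return start, goal, pair_residues(start.structure, goal.structure)


@pytest.fixture(scope="session")
def two_domain():
    """20-residue two-helical-domain toy with a 3-residue glycine hinge."""
    start, goal, hinge = two_domain_pair()
    return start, goal, hinge, pair_residues(start.structure, goal.structure)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


MINIMAL_ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.004   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.100  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.030  -0.750  -1.200  1.00  0.00           C
TER
END
"""


@pytest.fixture()
def minimal_ala_pdb():
    return MINIMAL_ALA_PDB
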