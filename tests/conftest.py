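import numpy as np
import pytest

from atdqc import synthetic as synth


@pytest.fixture(scope="session")
def atd_dimer():
    return synth.build_deacylase_dimer("ATD", seed=0)


@pytest.fixture(scope="session")
def dtd_dimer():
    return synth.build_deacylase_dimer("DTD", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 20.00           C
ATOM      3  C   ALA A   1       2.010   1.420   0.000  1.00 20.00           C
ATOM      4  O   ALA A   1       1.250   2.390   0.000  1.00 20.00           O
ATOM      5  N   GLY A   2       3.330   1.540   0.000  1.00 21.00           N
ATOM      6  CA  GLY A   2       3.960   2.860   0.000  1.00 21.00           C
ATOM      7  C   GLY A   2       5.480   2.800   0.000  1.00 21.00           C
ATOM      8  O   GLY A   2       6.100   1.740   0.000  1.00 21.00           O
ATOM      9  N   PRO A   3       6.100   3.980   0.000  1.00 22.00           N
ATOM     10  CA  PRO A   3       7.560   4.080   0.000  1.00 22.00           C
ATOM     11  C   PRO A   3       8.100   5.500   0.000  1.00 22.00           C
ATOM     12  O   PRO A   3       7.350   6.480   0.000  1.00 22.00           O
TER
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00 30.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00 30.00           O
TER
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture()
def water_only_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_ONLY_PDB)
    return p
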