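import textwrap

import numpy as np
import pytest

from strainscope import synthetic


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ANISOU    1  N   ALA A   1      380    380    380      0      0      0       N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ANISOU    2  CA  ALA A   1      400    300    440      0      0      0       C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM      6  CA  GLY A   2       3.988   2.830   0.000  1.00 11.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00 11.00           C
ATOM      8  O   GLY A   2       6.052   1.590   0.000  1.00 11.00           O
ATOM      9  N   SER A   3       6.191   3.831   0.000  1.00 12.00           N
ATOM     10  CA  SER A   3       7.646   3.855   0.000  1.00 12.00           C
ATOM     11  C   SER A   3       8.200   5.270   0.000  1.00 12.00           C
ATOM     12  O   SER A   3       7.452   6.248   0.000  1.00 12.00           O
HETATM   13  O   HOH A 101      12.000  12.000  12.000  1.00 20.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB ASER A   1       2.000  -1.000   1.000  0.70 10.00           C
ATOM      6  CB BSER A   1       2.000  -1.000  -1.000  0.30 10.00           C
ATOM      7  OG ASER A   1       3.400  -1.100   1.000  0.70 10.00           O
ATOM      8  OG BSER A   1       3.400  -1.100  -1.000  0.30 10.00           O
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00 20.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00 21.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def water_only_pdb(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_ONLY_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def helix_model():
    model, truth = synthetic.build_element("helix", 12)
    return model, truth


@pytest.fixture
def sheet_model():
    model, truth = synthetic.build_element("antiparallel_sheet", 6)
    return model, truth


@pytest.fixture
def turn_model():
    model, truth = synthetic.build_element(
        "beta_turn_I", 6, sequence=["ALA", "ALA", "ALA", "ILE", "ALA", "ALA"]
    )
    return model, truth


def random_rigid_transform(rng):
    """A uniformly random rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rotation = Rotation.random(rng=rng).as_matrix()
    translation = rng.uniform(-50.0, 50.0, size=3)
    return rotation, translation
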