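"""Shared fixtures: literal PDB snippets with hand-countable content and
small generated structures."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import settings

from contactpot.fixtures import ToySpec, make_toy_structure

# property tests must replay identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# 2 standard residues (ALA: 5 heavy atoms, GLY: 4), one hydrogen to drop,
# one altloc pair (occupancies 0.60/0.40) and one water to exclude.
ALA_GLY_PDB = textwrap.dedent(
    """\
    HEADER    TEST PEPTIDE                            01-JAN-00   XXXX
    EXPDTA    X-RAY DIFFRACTION
    REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
    ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
    ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
    ATOM      5  CB  ALA A   1       2.000  -0.750  -1.200  1.00  0.00           C
    ATOM      6  H   ALA A   1       0.500   0.500   0.800  1.00  0.00           H
    ATOM      7  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
    ATOM      8  CA AGLY A   2       4.000   2.800   0.000  0.60  0.00           C
    ATOM      9  CA BGLY A   2       4.100   2.900   0.000  0.40  0.00           C
    ATOM     10  C   GLY A   2       5.500   2.700   0.000  1.00  0.00           C
    ATOM     11  O   GLY A   2       6.100   1.600   0.000  1.00  0.00           O
    HETATM   12  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O
    END
    """
)

HETATM_ONLY_PDB = textwrap.dedent(
    """\
    HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
    HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
    END
    """
)

# Three models of a one-residue chain; only MODEL 1 coordinates must be kept.
MULTI_MODEL_PDB = textwrap.dedent(
    """\
    MODEL        1
    ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
    ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
    ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
    ENDMDL
    MODEL        2
    ATOM      1  N   GLY A   1      10.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  GLY A   1      11.458   0.000   0.000  1.00  0.00           C
    ATOM      3  C   GLY A   1      12.009   1.420   0.000  1.00  0.00           C
    ATOM      4  O   GLY A   1      11.251   2.390   0.000  1.00  0.00           O
    ENDMDL
    MODEL        3
    ATOM      1  N   GLY A   1      20.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  GLY A   1      21.458   0.000   0.000  1.00  0.00           C
    ATOM      3  C   GLY A   1      22.009   1.420   0.000  1.00  0.00           C
    ATOM      4  O   GLY A   1      21.251   2.390   0.000  1.00  0.00           O
    ENDMDL
    END
    """
)


@pytest.fixture
def ala_gly_pdb(tmp_path):
    path = tmp_path / "ala_gly.pdb"
    path.write_text(ALA_GLY_PDB)
    return path


@pytest.fixture
def hetatm_only_pdb(tmp_path):
    path = tmp_path / "hetatm_only.pdb"
    path.write_text(HETATM_ONLY_PDB)
    return path


@pytest.fixture
def multi_model_pdb(tmp_path):
    path = tmp_path / "multi_model.pdb"
    path.write_text(MULTI_MODEL_PDB)
    return path


@pytest.fixture(scope="session")
def helix10():
    """10-residue ideal helix with assigned radii."""
    return make_toy_structure(ToySpec(10, "helix", "random", rng_seed=3))


@pytest.fixture(scope="session")
def extended10():
    """10-residue extended chain with assigned radii."""
    return make_toy_structure(ToySpec(10, "extended", "random", rng_seed=4))
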