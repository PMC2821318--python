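"""Amino-acid tables and method defaults shared across the package."""

from __future__ import annotations

#: One-letter codes of the 20 standard amino acids, in the fixed order used
#: to index the 20x20 potential matrices.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
N_AA = len(AA_ORDER)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

#: Residues whose ring atoms take the aromatic-carbon group radius.
AROMATIC_RESIDUES = frozenset({"PHE", "TYR", "TRP", "HIS"})

#: Heavy-atom composition of each standard residue (backbone + side chain,
#: hydrogens and the terminal OXT excluded).  Used by the training-set
#: completeness filter.
BACKBONE_ATOMS = ("N", "CA", "C", "O")
SIDE_CHAIN_ATOMS = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

def expected_heavy_atoms(resname: str) -> frozenset[str]:
    """Full expected heavy-atom name set for a standard residue."""
    return frozenset(BACKBONE_ATOMS) | frozenset(SIDE_CHAIN_ATOMS[resname])

#: Probe radii (Angstrom) the potential is tabulated for.
SUPPORTED_PROBE_RADII = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5)

#: Defaults for scoring: smallest probe and nearest-neighbour separation
#: give the best native/decoy discrimination.
DEFAULT_PROBE_RADIUS = 0.25
DEFAULT_N_POINTS = 1024
DEFAULT_D_FILTER = frozenset({1})

#: Sequence-separation bins: d = 1..9 kept distinct, d >= 10 pooled into
#: the last bin (labelled 10).
D_BIN_POOL = 10
DEFAULT_D_BINS = tuple(range(1, D_BIN_POOL + 1))

def bin_separation(d: int, pool: int = D_BIN_POOL) -> int:
    """Map a sequence separation d >= 1 to its bin label (pool = last bin)."""
    if d < 1:
        raise ValueError(f"sequence separation must be >= 1, got {d}")
    return min(d, pool)
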