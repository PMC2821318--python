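"""Protein structure model, PDB input/output, group-radius assignment and
training-set curation.

Structures are reduced to what the contact-area potential needs: standard
residues, heavy atoms, one conformation.  Hydrogens are never kept; in their
absence each heavy atom carries a *group* Van der Waals radius (the united
radius of the atom plus its implicit hydrogens), read from the packaged
radius table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .constants import (
    AROMATIC_RESIDUES,
    ONE_TO_THREE,
    STANDARD_RESIDUES,
    THREE_TO_ONE,
    expected_heavy_atoms,
)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBFormatError",
    "EmptyStructureError",
    "UnknownAtomError",
    "parse_pdb",
    "write_pdb",
    "load_radius_table",
    "assign_radii",
    "curate_training_set",
]


class PDBFormatError(ValueError):
    """Raised when a file cannot be interpreted as PDB text."""


class EmptyStructureError(ValueError):
    """Raised when a file yields no standard protein residues."""


class UnknownAtomError(KeyError):
    """Raised when no radius-table entry (explicit or wildcard) matches."""


@dataclass
class Atom:
    """A heavy atom: PDB name, element, coordinates (A) and group radius (A).

    ``vdw_radius`` is 0.0 until :func:`assign_radii` has run.
    """

    name: str
    element: str
    coord: np.ndarray
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")


@dataclass
class Residue:
    """One standard amino acid: type, chain, gap-free chain position, atoms."""

    aa_type: str  # one-letter code
    chain_id: str
    seq_index: int  # consecutive position within the chain (1-based)
    atoms: list[Atom] = field(default_factory=list)

    @property
    def resname(self) -> str:
        return ONE_TO_THREE[self.aa_type]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.resname} {self.chain_id}{self.seq_index}: no atom {name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """An ordered collection of residues grouped by chain, plus metadata."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    resolution: float | None = None
    experiment_method: str | None = None

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.residues:
            out.setdefault(res.chain_id, []).append(res)
        return out

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def ca_coords(self) -> np.ndarray:
        """C-alpha coordinates in residue order, (n, 3)."""
        return np.array([r.atom("CA").coord for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)


# ---------------------------------------------------------------------------
# PDB input

def _pick_altloc(bp_atom):
    """Resolve a (possibly disordered) Bio.PDB atom to a single conformer:
    highest occupancy, ties broken toward altloc 'A'."""
    if not bp_atom.is_disordered():
        return bp_atom
    children = sorted(
        bp_atom.child_dict.values(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def parse_pdb(path: str | Path, model_policy: str = "first") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Keeps heavy atoms of standard amino acids only: hydrogens/deuteriums are
    dropped, HETATM records (waters, ligands, modified residues) are
    excluded, alternate locations are resolved to the highest-occupancy
    conformer, and only the first MODEL of multi-model files is read.
    Residues are renumbered consecutively per chain (1-based) so author
    numbering gaps and insertion codes never inflate sequence separations.

    Resolution and experiment method are taken from the header when present.
    """
    from Bio.PDB import PDBParser

    if model_policy != "first":
        raise ValueError(f"unsupported model_policy: {model_policy!r}")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        bp_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises a mix of exception types
        raise PDBFormatError(f"{path}: not parseable as PDB ({exc})") from exc

    models = list(bp_structure)
    if not models:
        raise EmptyStructureError(f"{path}: no models")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        seq_index = 0
        for bp_res in chain:
            hetflag, _resseq, _icode = bp_res.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            resname = bp_res.get_resname().strip()
            if resname not in STANDARD_RESIDUES:
                continue
            atoms: list[Atom] = []
            for bp_atom in bp_res.get_list():
                bp_atom = _pick_altloc(bp_atom)
                element = (bp_atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=bp_atom.get_name().strip(),
                        element=element or bp_atom.get_name().strip()[0],
                        coord=np.asarray(bp_atom.get_coord(), dtype=float),
                    )
                )
            if not atoms:
                continue
            seq_index += 1
            residues.append(
                Residue(
                    aa_type=THREE_TO_ONE[resname],
                    chain_id=chain.get_id(),
                    seq_index=seq_index,
                    atoms=atoms,
                )
            )

    if not residues:
        raise EmptyStructureError(f"{path}: no standard protein residues")

    header = bp_structure.header or {}
    resolution = header.get("resolution")
    method = header.get("structure_method") or None
    if method is not None:
        method = method.strip() or None
    return Structure(
        id=path.stem,
        residues=residues,
        resolution=float(resolution) if resolution is not None else None,
        experiment_method=method,
    )


# ---------------------------------------------------------------------------
# PDB output

def _pdb_atom_name(name: str) -> str:
    # Names of < 4 characters start in column 14 per wwPDB convention.
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write ATOM records (wwPDB v3.3 fixed columns) for a structure."""
    path = Path(path)
    lines: list[str] = []
    serial = 0
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {_pdb_atom_name(atom.name)} {res.resname:<3s} "
                f"{res.chain_id:1s}{res.seq_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2s}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Radius assignment

def load_radius_table() -> Mapping[tuple[str, str], float]:
    """Load the packaged group-radius table as {(context, atom_name): radius}.

    Contexts are "*" (any residue) and "aromatic" (ring-bearing residues);
    names ending in "**" are element wildcards.
    """
    table: dict[tuple[str, str], float] = {}
    ref = importlib.resources.files("contactpot.data").joinpath("vdw_radii.tsv")
    for line in ref.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("context"):
            continue
        context, name, radius = line.split("\t")
        table[(context, name)] = float(radius)
    return table


_RADIUS_TABLE: Mapping[tuple[str, str], float] | None = None


def _default_radius_table() -> Mapping[tuple[str, str], float]:
    global _RADIUS_TABLE
    if _RADIUS_TABLE is None:
        _RADIUS_TABLE = load_radius_table()
    return _RADIUS_TABLE


def lookup_radius(
    resname: str, atom_name: str, element: str,
    table: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Group radius for one atom; aromatic-context rows win in PHE/TYR/TRP/HIS,
    then exact-name rows, then the element wildcard."""
    table = table if table is not None else _default_radius_table()
    if resname in AROMATIC_RESIDUES and ("aromatic", atom_name) in table:
        return table[("aromatic", atom_name)]
    if ("*", atom_name) in table:
        return table[("*", atom_name)]
    wildcard = ("*", f"{element.upper()}**")
    if wildcard in table:
        return table[wildcard]
    raise UnknownAtomError(
        f"no radius for atom {atom_name!r} (element {element!r}) in {resname}"
    )


def assign_radii(
    structure: Structure,
    radius_table: Mapping[tuple[str, str], float] | None = None,
) -> Structure:
    """Return a copy of the structure with every atom's group radius set."""
    new_residues = []
    for res in structure.residues:
        new_atoms = [
            replace(a, coord=a.coord.copy(),
                    vdw_radius=lookup_radius(res.resname, a.name, a.element, radius_table))
            for a in res.atoms
        ]
        new_residues.append(replace(res, atoms=new_atoms))
    return replace(structure, residues=new_residues)


# ---------------------------------------------------------------------------
# Training-set curation

def _is_nmr(method: str | None) -> bool:
    return method is not None and "NMR" in method.upper()


def has_complete_side_chains(structure: Structure) -> bool:
    """True when every residue carries its full expected heavy-atom set
    (extra atoms such as the terminal OXT are allowed)."""
    for res in structure.residues:
        names = {a.name for a in res.atoms}
        if not expected_heavy_atoms(res.resname) <= names:
            return False
    return True


def curate_training_set(
    structures: Iterable[Structure], max_resolution: float = 2.5
) -> list[Structure]:
    """Apply the training-set quality filters.

    Keeps structures that (a) do not report a resolution above
    ``max_resolution``, (b) are not NMR models, and (c) have complete heavy
    side chains in every residue.  Structures without resolution or method
    metadata (e.g. generated ones) pass filters (a) and (b).  Idempotent.
    """
    kept = []
    for s in structures:
        if s.resolution is not None and s.resolution > max_resolution:
            continue
        if _is_nmr(s.experiment_method):
            continue
        if not has_complete_side_chains(s):
            continue
        kept.append(s)
    return kept
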