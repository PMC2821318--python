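"""Pairwise residue contact areas by probe-sphere point sampling.

The contact area between two residues is the part of the probe-expanded
Van der Waals sphere surface of one residue's atoms that overlaps the
probe-expanded spheres of the other residue's atoms.  For an atom of radius
``Ra`` and a probe of radius ``Rp``, quasi-uniform sample points are placed
on the sphere of radius ``Ra + Rp``; a point is in contact with a partner
atom of radius ``Rb`` when it lies within ``Rb + Rp`` of that atom's centre.
Two atoms can be in contact at all only when their centres are within
``Ra + Rb + 2*Rp``.  Each sample point carries the area
``4*pi*(Ra+Rp)**2 / n`` and is credited at most once per partner residue.

Areas are orientation dependent: moving a side chain changes which sample
points overlap, even at a fixed centre-centre distance — this is what
distinguishes the contact-area statistic from centre-distance contact
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import DEFAULT_D_BINS, DEFAULT_N_POINTS, bin_separation
from .structure_io import Atom, Residue, Structure

__all__ = [
    "SpherePointSet",
    "ContactRecord",
    "ContactTable",
    "generate_sphere_points",
    "atoms_in_contact",
    "atom_pair_contact_area",
    "residue_pair_contact_area",
    "structure_contact_table",
]

_EPS = 1e-12  # absolute slack so exact boundary geometries count as contact


@dataclass(frozen=True)
class SpherePointSet:
    """Deterministic quasi-uniform directions on the unit sphere.

    ``point_weight(R)`` is the surface area represented by one point on a
    sphere of radius R; the weights sum to the full sphere area 4*pi*R**2 by
    construction.
    """

    n_points: int
    directions: np.ndarray  # (n, 3), unit norm

    def point_weight(self, radius: float) -> float:
        return 4.0 * np.pi * radius * radius / self.n_points


def generate_sphere_points(n: int) -> SpherePointSet:
    """Golden-spiral (Fibonacci) lattice of ``n`` points on the unit sphere.

    The same ``n`` always yields the identical point set.
    """
    if n < 16:
        raise ValueError(f"need at least 16 sphere points, got {n}")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    directions = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    directions.setflags(write=False)
    return SpherePointSet(n_points=n, directions=directions)


def atoms_in_contact(atom_a: Atom, atom_b: Atom, probe_radius: float) -> bool:
    """Spheres overlap: centre distance <= Ra + Rb + 2*Rp."""
    cutoff = atom_a.vdw_radius + atom_b.vdw_radius + 2.0 * probe_radius
    dist = float(np.linalg.norm(atom_a.coord - atom_b.coord))
    return dist <= cutoff + _EPS


def _contact_mask(
    points: np.ndarray, centers: np.ndarray, radii: np.ndarray, probe_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n_points, n_partners) boolean: point within Rb + Rp of partner b."""
    diff = points[:, None, :] - centers[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    limit = (radii + probe_radius) ** 2
    return d2 <= limit[None, :] + _EPS, d2


def _local_frame(center: np.ndarray, partner_centers: np.ndarray) -> np.ndarray:
    """Orthonormal frame (rows x, y, z) tied to the partner geometry.

    The sample lattice is expressed in this frame — z points at the partner
    centroid, x along the in-plane component of a partner offset — so that
    rigidly moving the whole structure moves the lattice with it and leaves
    every sampled area unchanged.  Aligning z with the contact axis also
    centres the quadrature on the cap being measured.
    """
    v = partner_centers.mean(axis=0) - center
    nv = np.linalg.norm(v)
    if nv < 1e-8:
        for c in partner_centers:
            v = c - center
            nv = np.linalg.norm(v)
            if nv >= 1e-8:
                break
        else:
            return np.eye(3)
    z = v / nv
    x = None
    for c in partner_centers:
        u = c - center
        u = u - (u @ z) * z
        nu = np.linalg.norm(u)
        if nu >= 1e-8:
            x = u / nu
            break
    if x is None:
        # single collinear partner: the contact cap is symmetric about z,
        # so any perpendicular works
        u = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = u - (u @ z) * z
        x = u / np.linalg.norm(u)
    return np.stack([x, np.cross(z, x), z])


def atom_pair_contact_area(
    atom_a: Atom,
    partner_atoms: Sequence[Atom],
    probe_radius: float,
    points: SpherePointSet,
) -> np.ndarray:
    """Directed contact areas (A^2) from ``atom_a`` onto each partner atom.

    Sample points are placed on the sphere of radius ``Ra + Rp`` around
    ``atom_a``; a point touching several partners is credited once, to the
    nearest contacting partner (ties to the lowest partner index), so the
    returned areas never double-count surface and sum to at most the full
    sphere area.
    """
    r1 = atom_a.vdw_radius + probe_radius
    centers = np.array([b.coord for b in partner_atoms], dtype=float)
    radii = np.array([b.vdw_radius for b in partner_atoms], dtype=float)
    frame = _local_frame(atom_a.coord, centers)
    sample = atom_a.coord[None, :] + r1 * (points.directions @ frame)
    mask, d2 = _contact_mask(sample, centers, radii, probe_radius)
    any_contact = mask.any(axis=1)
    areas = np.zeros(len(partner_atoms))
    if not any_contact.any():
        return areas
    d2 = np.where(mask, d2, np.inf)
    nearest = np.argmin(d2[any_contact], axis=1)  # argmin ties -> lowest index
    counts = np.bincount(nearest, minlength=len(partner_atoms))
    areas[:] = counts * points.point_weight(r1)
    return areas


def _directed_residue_area(
    source: Residue, target: Residue, probe_radius: float, points: SpherePointSet
) -> float:
    """Sum over source atoms of the area whose sample points touch any
    target atom (each point counted once toward the target residue)."""
    total = 0.0
    t_centers = np.array([b.coord for b in target.atoms], dtype=float)
    t_radii = np.array([b.vdw_radius for b in target.atoms], dtype=float)
    for atom in source.atoms:
        # prefilter: keep target atoms whose spheres can overlap this atom's
        cutoff = atom.vdw_radius + t_radii + 2.0 * probe_radius
        sel = np.linalg.norm(t_centers - atom.coord, axis=1) <= cutoff + _EPS
        if not sel.any():
            continue
        r1 = atom.vdw_radius + probe_radius
        frame = _local_frame(atom.coord, t_centers[sel])
        sample = atom.coord[None, :] + r1 * (points.directions @ frame)
        mask, _ = _contact_mask(sample, t_centers[sel], t_radii[sel], probe_radius)
        n_hit = int(mask.any(axis=1).sum())
        total += n_hit * points.point_weight(r1)
    return total


def residue_pair_contact_area(
    res_i: Residue,
    res_j: Residue,
    probe_radius: float,
    points: SpherePointSet,
) -> float:
    """Symmetric residue-residue contact area (A^2).

    The two directed areas (sampling i's atom spheres against j, and j's
    against i) differ slightly because the sampled spheres have different
    radii; the reported area is their mean, which makes the operation
    exactly symmetric in its arguments.
    """
    if res_i is res_j:
        raise ValueError("contact area of a residue with itself is undefined")
    a_ij = _directed_residue_area(res_i, res_j, probe_radius, points)
    a_ji = _directed_residue_area(res_j, res_i, probe_radius, points)
    return 0.5 * (a_ij + a_ji)


@dataclass(frozen=True)
class ContactRecord:
    """One residue-pair observation: unordered type pair, separation bin,
    contact area and the probe used."""

    aa_i: str
    aa_j: str
    d_bin: int
    area: float
    probe_radius: float
    # provenance within the source structure (not serialized)
    chain: str = ""
    seq_i: int = -1
    seq_j: int = -1

    def __post_init__(self) -> None:
        if self.aa_i > self.aa_j:  # canonical unordered pair
            lo, hi = self.aa_j, self.aa_i
            object.__setattr__(self, "aa_i", lo)
            object.__setattr__(self, "aa_j", hi)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.aa_i, self.aa_j)


@dataclass
class ContactTable:
    """All nonzero residue-pair contact areas of one structure."""

    structure_id: str
    probe_radius: float
    n_points: int
    records: list[ContactRecord] = field(default_factory=list)

    def totals(self) -> dict[tuple[str, str, int], float]:
        """Total area per (aa_i, aa_j, d_bin), unordered pair semantics."""
        out: dict[tuple[str, str, int], float] = {}
        for rec in self.records:
            key = (rec.aa_i, rec.aa_j, rec.d_bin)
            out[key] = out.get(key, 0.0) + rec.area
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "structure_id": self.structure_id,
                    "aa_i": r.aa_i,
                    "aa_j": r.aa_j,
                    "d_bin": r.d_bin,
                    "probe_radius": r.probe_radius,
                    "area_A2": r.area,
                }
                for r in self.records
            ],
            columns=["structure_id", "aa_i", "aa_j", "d_bin", "probe_radius", "area_A2"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ContactTable":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValueError(f"{path}: empty contact table")
        probe = float(df["probe_radius"].iloc[0])
        table = cls(
            structure_id=str(df["structure_id"].iloc[0]),
            probe_radius=probe,
            n_points=0,
            records=[
                ContactRecord(
                    aa_i=row.aa_i, aa_j=row.aa_j, d_bin=int(row.d_bin),
                    area=float(row.area_A2), probe_radius=float(row.probe_radius),
                )
                for row in df.itertuples()
            ],
        )
        return table


def _candidate_residue_pairs(
    structure: Structure, probe_radius: float, use_grid: bool
) -> Iterable[tuple[int, int]]:
    """Indices (into structure.residues) of intra-chain residue pairs that
    may have nonzero contact area.  The KD-tree pass only prunes pairs whose
    atoms all exceed the largest possible contact cutoff, so grid and
    brute-force enumeration yield identical areas.
    """
    residues = structure.residues
    n = len(residues)
    if not use_grid:
        for i in range(n):
            for j in range(i + 1, n):
                if residues[i].chain_id == residues[j].chain_id:
                    yield i, j
        return

    coords = []
    owner = []
    max_r = 0.0
    for idx, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            owner.append(idx)
            max_r = max(max_r, atom.vdw_radius)
    tree = cKDTree(np.asarray(coords))
    cutoff = 2.0 * max_r + 2.0 * probe_radius + 1e-9
    pairs = set()
    for ai, aj in tree.query_pairs(r=cutoff):
        ri, rj = owner[ai], owner[aj]
        if ri == rj:
            continue
        i, j = (ri, rj) if ri < rj else (rj, ri)
        if residues[i].chain_id == residues[j].chain_id:
            pairs.add((i, j))
    yield from sorted(pairs)


def structure_contact_table(
    structure: Structure,
    probe_radius: float,
    d_bins: Sequence[int] = DEFAULT_D_BINS,
    n_points: int = DEFAULT_N_POINTS,
    use_grid: bool = True,
) -> ContactTable:
    """Contact areas of every intra-chain residue pair of a structure.

    One record per pair (i, j), j > i in chain order, with nonzero area;
    sequence separation d = seq_index(j) - seq_index(i) is reduced to its
    bin (the last bin pools d >= its label).  ``use_grid=False`` forces the
    all-pairs enumeration (same result, for verification).
    """
    pool = max(d_bins)
    points = generate_sphere_points(n_points)
    records: list[ContactRecord] = []
    residues = structure.residues
    for i, j in _candidate_residue_pairs(structure, probe_radius, use_grid):
        d = residues[j].seq_index - residues[i].seq_index
        if d < 1:
            continue
        d_bin = bin_separation(d, pool)
        if d_bin not in d_bins:
            continue
        area = residue_pair_contact_area(residues[i], residues[j], probe_radius, points)
        if area > 0.0:
            records.append(
                ContactRecord(
                    aa_i=residues[i].aa_type,
                    aa_j=residues[j].aa_type,
                    d_bin=d_bin,
                    area=area,
                    probe_radius=probe_radius,
                    chain=residues[i].chain_id,
                    seq_i=residues[i].seq_index,
                    seq_j=residues[j].seq_index,
                )
            )
    return ContactTable(
        structure_id=structure.id,
        probe_radius=probe_radius,
        n_points=n_points,
        records=records,
    )
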