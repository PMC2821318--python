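"""Synthetic structures, corpora and decoy ensembles.

Everything the pipeline consumes can be generated here, deterministically
from a seed: idealized peptide backbones (helical or extended, side chains
through C-beta), contact-table corpora with planted pair preferences, and
decoy ensembles made by Gaussian coordinate perturbation of a native.

These generators emulate the statistical shape of the real inputs — they
are not physically realistic protein models.  See docs/methods.md for what
that implies about test coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import AA_ORDER, N_AA
from .contact_area import ContactRecord, ContactTable
from .structure_io import Atom, Residue, Structure, assign_radii

__all__ = [
    "ToySpec",
    "PlantedCorpusSpec",
    "make_toy_structure",
    "make_planted_corpus",
    "make_decoy_ensemble",
    "make_demo_corpus",
    "make_demo_native",
]

# Ideal backbone geometry: bond lengths (A) and angles (degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0
_PHI_PSI = {"helix": (-57.0, -47.0), "extended": (-120.0, 120.0)}

#: Residues favoured in the helical / extended halves of the demo corpus.
HYDROPHOBIC = "AVILMFWY"
POLAR = "GSTNQDEKRH"


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one idealized peptide."""

    n_residues: int
    backbone_geometry: str = "helix"  # or "extended"
    sequence: str = "random"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.backbone_geometry not in _PHI_PSI:
            raise ValueError(f"unknown geometry {self.backbone_geometry!r}")
        if self.sequence != "random" and len(self.sequence) != self.n_residues:
            raise ValueError("explicit sequence length must match n_residues")


@dataclass(frozen=True)
class PlantedCorpusSpec:
    """Recipe for a synthetic contact-table corpus with known preferences.

    Per structure, the total contact area of the unordered pair (a, b) is
    drawn as ``total_area * p_a * p_b * enrichment[a, b] * lognormal noise``
    with unit-mean noise of the given coefficient of variation, so that the
    trained preference K recovers ``enrichment`` (up to the marginal
    renormalisation inherent in the reference state).
    """

    n_structures: int
    pair_enrichment: np.ndarray  # (20, 20) symmetric positive
    area_noise_cv: float = 0.0
    rng_seed: int = 0
    type_weights: np.ndarray | None = None  # default uniform
    total_area: float = 4000.0  # A^2 per structure before enrichment
    d_bin: int = 1
    probe_radius: float = 0.25

    def __post_init__(self) -> None:
        e = np.asarray(self.pair_enrichment, dtype=float)
        if e.shape != (N_AA, N_AA) or not np.allclose(e, e.T) or np.any(e <= 0):
            raise ValueError("pair_enrichment must be symmetric positive (20, 20)")
        object.__setattr__(self, "pair_enrichment", e)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: position d with |cd| = bond,
    angle(b,c,d) = angle and torsion(a,b,c,d) = torsion."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """C-beta at ideal tetrahedral geometry from the backbone frame."""
    b = ca - n
    v = c - ca
    a = np.cross(b, v)
    return ca + (-0.58273431 * a + 0.56802827 * b - 0.54067466 * v)


def make_toy_structure(spec: ToySpec) -> Structure:
    """Build an idealized single-chain peptide with assigned group radii.

    Backbone atoms N, CA, C, O at standard bond lengths/angles with the
    requested (phi, psi); side chains are represented by C-beta only
    (glycine has none).  Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.sequence == "random":
        seq = "".join(rng.choice(list(AA_ORDER), size=spec.n_residues))
    else:
        seq = spec.sequence
    phi, psi = _PHI_PSI[spec.backbone_geometry]

    residues: list[Residue] = []
    prev_n = prev_ca = prev_c = None
    for i, aa in enumerate(seq):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = math.radians(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            n = _place_atom(prev_n, prev_ca, prev_c, _B_C_N, _A_CA_C_N, psi)
            ca = _place_atom(prev_ca, prev_c, n, _B_N_CA, _A_C_N_CA, _OMEGA)
            c = _place_atom(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi)
        o = _place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        atoms = [
            Atom("N", "N", n),
            Atom("CA", "C", ca),
            Atom("C", "C", c),
            Atom("O", "O", o),
        ]
        if aa != "G":
            atoms.append(Atom("CB", "C", _ideal_cb(n, ca, c)))
        residues.append(Residue(aa_type=aa, chain_id="A", seq_index=i + 1, atoms=atoms))
        prev_n, prev_ca, prev_c = n, ca, c

    structure = Structure(
        id=f"toy_{spec.backbone_geometry}_{spec.n_residues}_{spec.rng_seed}",
        residues=residues,
    )
    return assign_radii(structure)


def make_planted_corpus(spec: PlantedCorpusSpec) -> list[ContactTable]:
    """Synthetic contact tables with planted pair enrichments (see
    :class:`PlantedCorpusSpec`)."""
    rng = np.random.default_rng(spec.rng_seed)
    p = (np.full(N_AA, 1.0 / N_AA) if spec.type_weights is None
         else np.asarray(spec.type_weights, dtype=float))
    p = p / p.sum()
    cv = spec.area_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    tables = []
    for s in range(spec.n_structures):
        records = []
        for i in range(N_AA):
            for j in range(i, N_AA):
                base = spec.total_area * p[i] * p[j] * spec.pair_enrichment[i, j]
                noise = math.exp(rng.normal(-0.5 * sigma * sigma, sigma)) if sigma else 1.0
                records.append(
                    ContactRecord(
                        aa_i=AA_ORDER[i], aa_j=AA_ORDER[j], d_bin=spec.d_bin,
                        area=base * noise, probe_radius=spec.probe_radius,
                    )
                )
        tables.append(
            ContactTable(
                structure_id=f"planted_{spec.rng_seed}_{s}",
                probe_radius=spec.probe_radius,
                n_points=0,
                records=records,
            )
        )
    return tables


def _relax_clashes(
    coords: np.ndarray,
    radii: np.ndarray,
    residue_ids: np.ndarray,
    native_distances: np.ndarray,
    factor: float = 0.9,
    max_iter: int = 60,
) -> np.ndarray:
    """Push apart inter-residue atom pairs that interpenetrate.

    A pair may not sit closer than ``factor * (Ra + Rb)`` — except that the
    pair's native distance is always allowed (peptide-bonded and tightly
    packed native pairs are legitimate), so unperturbed coordinates are a
    fixed point.  Violating pairs are displaced symmetrically along their
    axis, iterating until clash-free or the iteration cap.
    """
    limits = factor * (radii[:, None] + radii[None, :])
    limits = np.minimum(limits, native_distances)
    limits[residue_ids[:, None] == residue_ids[None, :]] = 0.0
    coords = coords.copy()
    for _ in range(max_iter):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(dist, np.inf)
        violating = np.argwhere(np.triu(dist < limits - 1e-9))
        if violating.size == 0:
            break
        displacement = np.zeros_like(coords)
        for i, j in violating:
            axis = diff[i, j] / max(dist[i, j], 1e-6)
            push = 0.55 * (limits[i, j] - dist[i, j])
            displacement[i] += push * axis
            displacement[j] -= push * axis
        coords += displacement
    return coords


def make_decoy_ensemble(
    native: Structure,
    n_decoys: int,
    perturbation_scale: float,
    rng_seed: int = 0,
    relax_clashes: bool = True,
):
    """Decoys by per-atom Gaussian coordinate noise.

    Side-chain atoms are perturbed at the full per-axis scale and backbone
    atoms (N, CA, C, O) at half scale: the contact-area score reacts most
    strongly to side-chain orientation, and real decoys distort side-chain
    packing more than the backbone trace.  By default steric overlaps
    introduced by the noise are then relaxed away (published decoy sets are
    energy-minimised and clash-free; without this step random noise can
    interpenetrate Van der Waals spheres and *inflate* contact areas, which
    no physical decoy generator produces).  Deterministic for a given seed.
    """
    from .evaluation import DecoySet

    if n_decoys < 1:
        raise ValueError("need at least one decoy")
    rng = np.random.default_rng(rng_seed)
    backbone = {"N", "CA", "C", "O"}
    flat_atoms = [(ri, a) for ri, res in enumerate(native.residues) for a in res.atoms]
    coords0 = np.array([a.coord for _, a in flat_atoms])
    radii = np.array([a.vdw_radius for _, a in flat_atoms])
    residue_ids = np.array([ri for ri, _ in flat_atoms])
    scales = np.array(
        [perturbation_scale * (0.5 if a.name in backbone else 1.0) for _, a in flat_atoms]
    )
    diff0 = coords0[:, None, :] - coords0[None, :, :]
    native_distances = np.sqrt(np.einsum("ijk,ijk->ij", diff0, diff0))

    decoys = []
    for k in range(n_decoys):
        noise = rng.normal(0.0, 1.0, size=coords0.shape) * scales[:, None]
        coords = coords0 + noise
        if relax_clashes and perturbation_scale > 0:
            coords = _relax_clashes(coords, radii, residue_ids, native_distances)
        new_residues = []
        idx = 0
        for res in native.residues:
            new_atoms = [
                replace(atom, coord=coords[idx + m]) for m, atom in enumerate(res.atoms)
            ]
            idx += len(res.atoms)
            new_residues.append(replace(res, atoms=new_atoms))
        decoys.append(replace(native, id=f"{native.id}_decoy{k}", residues=new_residues))
    return DecoySet(name=f"{native.id}_ensemble", native=native, decoys=decoys)


def _biased_sequence(rng: np.random.Generator, n: int, favored: str,
                     favored_mass: float = 0.8) -> str:
    """Sequence with most probability mass on a favoured residue subset."""
    others = [aa for aa in AA_ORDER if aa not in favored]
    w = np.empty(N_AA)
    for aa in AA_ORDER:
        w[AA_ORDER.index(aa)] = (
            favored_mass / len(favored) if aa in favored
            else (1.0 - favored_mass) / len(others)
        )
    return "".join(rng.choice(list(AA_ORDER), size=n, p=w))


def make_demo_corpus(
    n_structures: int = 120,
    n_residues: int = 24,
    rng_seed: int = 0,
) -> list[Structure]:
    """Training corpus with a built-in residue-type/packing association.

    Alternates helical peptides carrying hydrophobic-biased sequences with
    extended peptides carrying polar-biased sequences.  Helical neighbours
    bury more mutual surface, so hydrophobic-hydrophobic pairs accumulate
    larger d = 1 contact areas than polar-polar pairs — a toy analogue of
    hydrophobic packing preference that gives the trained potential a real
    signal to discriminate with.
    """
    rng = np.random.default_rng(rng_seed)
    corpus = []
    for s in range(n_structures):
        helical = s % 2 == 0
        seq = _biased_sequence(rng, n_residues, HYDROPHOBIC if helical else POLAR)
        corpus.append(
            make_toy_structure(
                ToySpec(
                    n_residues=n_residues,
                    backbone_geometry="helix" if helical else "extended",
                    sequence=seq,
                    rng_seed=int(rng.integers(2**31)),
                )
            )
        )
    return corpus


def make_demo_native(n_residues: int = 24, rng_seed: int = 10_000) -> Structure:
    """A held-out helical, hydrophobic-biased peptide drawn from the same
    process as the demo corpus, for use as a synthetic 'native'."""
    rng = np.random.default_rng(rng_seed)
    seq = _biased_sequence(rng, n_residues, HYDROPHOBIC)
    native = make_toy_structure(
        ToySpec(n_residues=n_residues, backbone_geometry="helix",
                sequence=seq, rng_seed=rng_seed)
    )
    return replace(native, id=f"demo_native_{rng_seed}")
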