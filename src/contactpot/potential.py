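"""Contact-area mean-force potential: training and scoring.

Training converts observed per-structure contact-area totals into a
preference coefficient ``K(a, b, d)`` and a Boltzmann-inverted energy
``E(a, b, d) = -T * ln K`` for every unordered residue-type pair (a, b) and
sequence-separation bin d, at one probe radius.

Reference state.  Let ``A_ab(d)`` be the mean (over training structures) of
the per-structure total contact area between types a and b at separation d,
arranged as a symmetric 20x20 matrix whose off-diagonal cells both hold the
unordered pair total.  The marginal ``A_a(d)`` is the row sum of that
matrix and ``A_all(d)`` its full sum, so that

    K(a, b, d) = A_ab(d) * A_all(d) / (A_a(d) * A_b(d))

equals 1 identically when pair areas factorise into type marginals (no
pairing preference).  K > 1 marks pairs that bury more mutual surface than
their overall contact propensities predict; the corresponding energy is
negative.

The score of a structure is the sum over its residue pairs (restricted to a
separation filter, by default d = 1 only) of contact area times E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    AA_INDEX,
    AA_ORDER,
    DEFAULT_D_BINS,
    DEFAULT_D_FILTER,
    DEFAULT_N_POINTS,
    N_AA,
)
from .contact_area import ContactTable, structure_contact_table
from .structure_io import Structure

__all__ = [
    "TrainingAverages",
    "PotentialTable",
    "ScoreResult",
    "accumulate_averages",
    "compute_K",
    "compute_E",
    "train_potential",
    "score_structure",
    "save_potential",
    "load_potential",
]


@dataclass
class TrainingAverages:
    """Mean contact-area statistics of a training corpus at one probe radius.

    ``A_ab[d]`` is the symmetric (20, 20) matrix of mean per-structure pair
    totals; ``A_a[d]`` its row sums; ``A_all[d]`` its full sum; ``counts[d]``
    the number of structures contributing a nonzero observation per pair.
    """

    probe_radius: float
    d_bins: tuple[int, ...]
    A_ab: dict[int, np.ndarray]
    A_a: dict[int, np.ndarray]
    A_all: dict[int, float]
    counts: dict[int, np.ndarray]
    n_structures: int


@dataclass
class PotentialTable:
    """Trained preference (K) and energy (E) grids per separation bin."""

    probe_radius: float
    d_bins: tuple[int, ...]
    K: dict[int, np.ndarray]
    E: dict[int, np.ndarray]
    counts: dict[int, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for d in self.d_bins:
            for name, M in (("K", self.K[d]), ("E", self.E[d])):
                if M.shape != (N_AA, N_AA):
                    raise ValueError(f"{name}[{d}]: wrong shape {M.shape}")
                if not np.allclose(M, M.T, equal_nan=True):
                    raise ValueError(f"{name}[{d}] is not symmetric")
            if np.any(self.K[d] < 0):
                raise ValueError(f"K[{d}] has negative entries")


@dataclass
class ScoreResult:
    """Total contact-area energy of one structure plus its per-pair terms."""

    structure_id: str
    total_energy: float
    contributions: list[tuple[str, int, int, int, float, float, float]]
    # (chain, seq_i, seq_j, d_bin, area, E, area*E)


def accumulate_averages(
    tables: Iterable[ContactTable],
    d_bins: Sequence[int] = DEFAULT_D_BINS,
    probe_radius: float | None = None,
) -> TrainingAverages:
    """Pool per-structure contact tables into training averages.

    Every structure contributes its pair totals once (structures with no
    observation of a pair contribute zero to that pair's mean), so large
    proteins do not dominate.  All tables must share one probe radius.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("empty training corpus")
    probes = {t.probe_radius for t in tables}
    if probe_radius is not None:
        probes.add(probe_radius)
    if len(probes) != 1:
        raise ValueError(f"mixed probe radii in corpus: {sorted(probes)}")
    probe = probes.pop()

    d_bins = tuple(d_bins)
    sums = {d: np.zeros((N_AA, N_AA)) for d in d_bins}
    counts = {d: np.zeros((N_AA, N_AA), dtype=int) for d in d_bins}
    for table in tables:
        for (aa_i, aa_j, d), area in table.totals().items():
            if d not in sums:
                continue
            i, j = AA_INDEX[aa_i], AA_INDEX[aa_j]
            sums[d][i, j] += area
            counts[d][i, j] += 1
            if i != j:
                sums[d][j, i] += area
                counts[d][j, i] += 1

    n = len(tables)
    A_ab = {d: sums[d] / n for d in d_bins}
    return TrainingAverages(
        probe_radius=probe,
        d_bins=d_bins,
        A_ab=A_ab,
        A_a={d: A_ab[d].sum(axis=1) for d in d_bins},
        A_all={d: float(A_ab[d].sum()) for d in d_bins},
        counts=counts,
        n_structures=n,
    )


def compute_K(avgs: TrainingAverages) -> dict[int, np.ndarray]:
    """Preference coefficients K(a, b, d) = A_ab * A_all / (A_a * A_b).

    Pairs (or bins) with no observed area get K = 0 here; smoothing toward
    the neutral K = 1 happens in :func:`compute_E`.
    """
    K: dict[int, np.ndarray] = {}
    for d in avgs.d_bins:
        denom = np.outer(avgs.A_a[d], avgs.A_a[d])
        with np.errstate(divide="ignore", invalid="ignore"):
            k = avgs.A_ab[d] * avgs.A_all[d] / denom
        k[~np.isfinite(k)] = 0.0
        K[d] = k
    return K


def compute_E(
    K: Mapping[int, np.ndarray],
    counts: Mapping[int, np.ndarray] | None,
    temperature_factor: float = 1.0,
) -> dict[int, np.ndarray]:
    """Boltzmann inversion E = -T * ln(K~) with pseudocount smoothing
    K~ = (K * n_obs + 1) / (n_obs + 1).

    Unobserved pairs (n_obs = 0) smooth to K~ = 1, i.e. E = 0 (neutral);
    well-observed pairs keep essentially their raw preference.  Passing
    ``counts=None`` disables smoothing (raw -T ln K; K must then be
    positive wherever it will be used).
    """
    E: dict[int, np.ndarray] = {}
    for d, k in K.items():
        if counts is None:
            k_smooth = k
        else:
            n = counts[d].astype(float)
            k_smooth = (k * n + 1.0) / (n + 1.0)
        with np.errstate(divide="ignore"):
            E[d] = -temperature_factor * np.log(k_smooth)
    return E


def train_potential(
    tables: Iterable[ContactTable],
    d_bins: Sequence[int] = DEFAULT_D_BINS,
    temperature_factor: float = 1.0,
    n_points: int = DEFAULT_N_POINTS,
    metadata: dict | None = None,
) -> PotentialTable:
    """Full training pipeline: averages -> K -> E -> PotentialTable."""
    avgs = accumulate_averages(tables, d_bins=d_bins)
    K = compute_K(avgs)
    E = compute_E(K, avgs.counts, temperature_factor)
    meta = {
        "n_training_structures": avgs.n_structures,
        "n_points": n_points,
        "temperature_factor": temperature_factor,
    }
    if metadata:
        meta.update(metadata)
    pot = PotentialTable(
        probe_radius=avgs.probe_radius,
        d_bins=avgs.d_bins,
        K=K,
        E=E,
        counts=avgs.counts,
        metadata=meta,
    )
    pot.validate()
    return pot


def score_structure(
    structure: Structure,
    potential: PotentialTable,
    d_filter: Sequence[int] | frozenset[int] = DEFAULT_D_FILTER,
    n_points: int | None = None,
    use_preference: bool = False,
) -> ScoreResult:
    """Total contact-area energy of a structure under a trained potential.

    Sum over residue pairs (restricted to separation bins in ``d_filter``,
    default d = 1 only) of contact area times the pair's E — or times K
    when ``use_preference`` is set.  Radii must already be assigned.
    """
    if len(structure.residues) < 2:
        raise ValueError(f"{structure.id}: need at least 2 residues to score")
    d_filter = frozenset(d_filter)
    if not d_filter <= set(potential.d_bins):
        raise ValueError(f"d_filter {sorted(d_filter)} outside potential bins")
    n_pts = n_points or int(potential.metadata.get("n_points", DEFAULT_N_POINTS))
    table = structure_contact_table(
        structure,
        probe_radius=potential.probe_radius,
        d_bins=potential.d_bins,
        n_points=n_pts,
    )
    grids = potential.K if use_preference else potential.E
    contributions = []
    total = 0.0
    for rec in table.records:
        if rec.d_bin not in d_filter:
            continue
        e = float(grids[rec.d_bin][AA_INDEX[rec.aa_i], AA_INDEX[rec.aa_j]])
        term = rec.area * e
        total += term
        contributions.append((rec.chain, rec.seq_i, rec.seq_j, rec.d_bin, rec.area, e, term))
    return ScoreResult(
        structure_id=structure.id, total_energy=total, contributions=contributions
    )


# ---------------------------------------------------------------------------
# Serialization (TSV with a commented header block; unordered pairs stored
# once with aa_i <= aa_j)

_FORMAT_TAG = "contactpot-potential v1"


def save_potential(potential: PotentialTable, path: str | Path) -> None:
    """Write a potential to TSV, losslessly (full float precision)."""
    potential.validate()
    path = Path(path)
    lines = [
        f"# format: {_FORMAT_TAG}",
        f"# probe_radius: {float(potential.probe_radius)!r}",
        f"# d_bins: {','.join(str(d) for d in potential.d_bins)}",
    ]
    for key in sorted(potential.metadata):
        lines.append(f"# {key}: {potential.metadata[key]}")
    lines.append("d_bin\taa_i\taa_j\tK\tE\tn_obs")
    for d in potential.d_bins:
        for i, aa_i in enumerate(AA_ORDER):
            for j in range(i, N_AA):
                aa_j = AA_ORDER[j]
                lines.append(
                    f"{d}\t{aa_i}\t{aa_j}\t{float(potential.K[d][i, j])!r}"
                    f"\t{float(potential.E[d][i, j])!r}\t{int(potential.counts[d][i, j])}"
                )
    path.write_text("\n".join(lines) + "\n")


def load_potential(path: str | Path) -> PotentialTable:
    """Read a potential written by :func:`save_potential`, validating the
    format tag, bin completeness and pair ordering."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith(f"# format: {_FORMAT_TAG}"):
        raise ValueError(f"{path}: not a {_FORMAT_TAG} file")
    meta: dict = {}
    probe_radius = None
    d_bins: tuple[int, ...] | None = None
    body_start = 0
    for idx, line in enumerate(lines):
        if line.startswith("# "):
            key, _, value = line[2:].partition(": ")
            if key == "format":
                continue
            if key == "probe_radius":
                probe_radius = float(value)
            elif key == "d_bins":
                d_bins = tuple(int(v) for v in value.split(","))
            else:
                meta[key] = value
        elif line.startswith("d_bin\t"):
            body_start = idx + 1
            break
    if probe_radius is None or d_bins is None:
        raise ValueError(f"{path}: missing probe_radius or d_bins header")

    K = {d: np.full((N_AA, N_AA), np.nan) for d in d_bins}
    E = {d: np.full((N_AA, N_AA), np.nan) for d in d_bins}
    counts = {d: np.zeros((N_AA, N_AA), dtype=int) for d in d_bins}
    seen: set[tuple[int, int, int]] = set()
    for line in lines[body_start:]:
        if not line.strip():
            continue
        d_s, aa_i, aa_j, k_s, e_s, n_s = line.split("\t")
        d = int(d_s)
        if d not in K:
            raise ValueError(f"{path}: row for d bin {d} not in header d_bins")
        if aa_i > aa_j:
            raise ValueError(f"{path}: pair ({aa_i},{aa_j}) violates aa_i <= aa_j")
        i, j = AA_INDEX[aa_i], AA_INDEX[aa_j]
        if (d, i, j) in seen:
            raise ValueError(f"{path}: duplicate row for d={d} pair ({aa_i},{aa_j})")
        seen.add((d, i, j))
        K[d][i, j] = K[d][j, i] = float(k_s)
        E[d][i, j] = E[d][j, i] = float(e_s)
        counts[d][i, j] = counts[d][j, i] = int(n_s)
    for d in d_bins:
        if np.isnan(K[d]).any():
            raise ValueError(f"{path}: incomplete or missing rows for d bin {d}")

    for int_key in ("n_training_structures", "n_points"):
        if int_key in meta:
            meta[int_key] = int(meta[int_key])
    if "temperature_factor" in meta:
        meta["temperature_factor"] = float(meta["temperature_factor"])
    pot = PotentialTable(
        probe_radius=probe_radius, d_bins=d_bins, K=K, E=E, counts=counts, metadata=meta
    )
    pot.validate()
    return pot
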