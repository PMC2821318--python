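"""Decoy-set discrimination statistics.

A scoring function is judged by whether the experimentally determined
(native) conformation scores below computer-generated alternatives
(decoys).  Three measures are reported per set:

* native rank — 1 + number of decoys with strictly lower energy (ties do
  not worsen the native's rank);
* Z-score — (E_native - <E_decoy>) / sigma_decoy with the population
  (divide-by-N) standard deviation; more negative is better;
* Pe — ln(rank / N_structures), a rank-based score whose worst possible
  value is 0 (native ranked last) and which improves (grows more negative)
  with set size when the native stays on top.

Structural similarity to the native is the C-alpha coordinate RMSD after
optimal rigid-body superposition (Kabsch).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .potential import PotentialTable, ScoreResult, score_structure
from .structure_io import Structure

__all__ = [
    "DecoySet",
    "DecoyEvaluation",
    "ZeroSpreadError",
    "kabsch_rmsd",
    "rank_native",
    "z_score",
    "pe_score",
    "evaluate_decoy_set",
    "write_report",
    "write_decoy_csv",
    "plot_energy_vs_rmsd",
]

logger = logging.getLogger(__name__)


class ZeroSpreadError(ValueError):
    """Raised when decoy energies have no spread, leaving Z undefined."""


@dataclass
class DecoySet:
    """A native structure with its decoy ensemble."""

    name: str
    native: Structure
    decoys: list[Structure]

    def __post_init__(self) -> None:
        if not self.decoys:
            raise ValueError(f"decoy set {self.name!r} has no decoys")


@dataclass
class DecoyEvaluation:
    """Per-set discrimination results."""

    set_name: str
    e_native: float
    decoy_energies: list[float]
    rank: int
    z: float
    pe: float
    rmsd_energy_pairs: list[tuple[float, float]] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def n_structures(self) -> int:
        return 1 + len(self.decoy_energies)


def kabsch_rmsd(coords_a: Sequence, coords_b: Sequence) -> float:
    """Coordinate RMSD (A) after optimal rigid-body superposition.

    The proper rotation (determinant +1) and translation minimising the
    RMSD between the two equal-length point sets are applied before the
    deviation is measured.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {a.shape}, {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    rotation, _ = Rotation.align_vectors(a_c, b_c)
    # measure the residual explicitly: the solver's reported rssd loses
    # precision to sqrt cancellation when the fit is near-exact
    residual = a_c - rotation.apply(b_c)
    return float(math.sqrt(np.mean(np.sum(residual * residual, axis=1))))


def rank_native(e_native: float, decoy_energies: Sequence[float]) -> int:
    """1 + number of decoys strictly below the native energy (ties favor
    the native)."""
    if len(decoy_energies) == 0:
        raise ValueError("no decoy energies")
    return 1 + sum(1 for e in decoy_energies if e < e_native)


def z_score(e_native: float, decoy_energies: Sequence[float]) -> float:
    """(E_native - mean(decoys)) / population std(decoys)."""
    e = np.asarray(decoy_energies, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 decoy energies for a Z-score")
    sigma = float(e.std(ddof=0))
    if sigma == 0.0:
        raise ZeroSpreadError("decoy energies have zero spread; Z undefined")
    return float((e_native - e.mean()) / sigma)


def pe_score(rank: int, n_structures: int) -> float:
    """Pe = ln(rank / N_structures); 0 (rank last) is the worst value."""
    if not 1 <= rank <= n_structures:
        raise ValueError(f"rank {rank} outside [1, {n_structures}]")
    return math.log(rank / n_structures)


def evaluate_decoy_set(
    decoy_set: DecoySet,
    potential: PotentialTable,
    d_filter=None,
    n_points: int | None = None,
) -> DecoyEvaluation:
    """Score a native and its decoys and assemble rank, Z, Pe and
    energy-vs-RMSD pairs (C-alpha RMSD to native, length-matched decoys
    only; mismatched decoys keep their energy but are flagged in the log).
    Decoys that fail scoring are skipped and counted."""
    kwargs = {}
    if d_filter is not None:
        kwargs["d_filter"] = d_filter
    if n_points is not None:
        kwargs["n_points"] = n_points
    native_result: ScoreResult = score_structure(decoy_set.native, potential, **kwargs)
    native_ca = decoy_set.native.ca_coords()

    energies: list[float] = []
    pairs: list[tuple[float, float]] = []
    n_skipped = 0
    for decoy in decoy_set.decoys:
        try:
            result = score_structure(decoy, potential, **kwargs)
        except Exception as exc:
            logger.warning("set %s: decoy %s unscorable (%s); skipped",
                           decoy_set.name, decoy.id, exc)
            n_skipped += 1
            continue
        energies.append(result.total_energy)
        decoy_ca = decoy.ca_coords()
        if decoy_ca.shape == native_ca.shape:
            pairs.append((kabsch_rmsd(native_ca, decoy_ca), result.total_energy))
        else:
            logger.warning("set %s: decoy %s length mismatch; excluded from RMSD",
                           decoy_set.name, decoy.id)

    rank = rank_native(native_result.total_energy, energies)
    z = z_score(native_result.total_energy, energies)
    pe = pe_score(rank, 1 + len(energies))
    pairs.insert(0, (0.0, native_result.total_energy))
    return DecoyEvaluation(
        set_name=decoy_set.name,
        e_native=native_result.total_energy,
        decoy_energies=energies,
        rank=rank,
        z=z,
        pe=pe,
        rmsd_energy_pairs=pairs,
        n_skipped=n_skipped,
    )


def write_report(evaluations: Sequence[DecoyEvaluation], path: str | Path) -> None:
    """One TSV row per decoy set: set, counts, native rank, Z, Pe."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "set": ev.set_name,
                "n_structures": ev.n_structures,
                "n_decoys": len(ev.decoy_energies),
                "n_skipped": ev.n_skipped,
                "rank_native": ev.rank,
                "z_score": ev.z,
                "pe": ev.pe,
            }
            for ev in evaluations
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_decoy_csv(evaluation: DecoyEvaluation, path: str | Path) -> None:
    """Per-structure (native first) energy and C-alpha RMSD pairs."""
    import pandas as pd

    rows = [
        {"rmsd_A": rmsd, "energy": energy}
        for rmsd, energy in evaluation.rmsd_energy_pairs
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def plot_energy_vs_rmsd(evaluation: DecoyEvaluation, path: str | Path) -> None:
    """Scatter of contact-area energy against C-alpha RMSD to the native
    (native drawn as a distinct marker at RMSD 0)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if len(evaluation.rmsd_energy_pairs) > 1:
        rmsd, energy = zip(*evaluation.rmsd_energy_pairs[1:])
        ax.scatter(rmsd, energy, s=12, alpha=0.6, label="decoys")
    ax.scatter([0.0], [evaluation.e_native], marker="*", s=120, color="crimson",
               label="native", zorder=3)
    ax.set_xlabel(r"C$\alpha$ RMSD to native ($\mathrm{\AA}$)")
    ax.set_ylabel("contact-area energy")
    ax.set_title(evaluation.set_name)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
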