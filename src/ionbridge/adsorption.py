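"""Surface radial distributions, contact counting and the adsorption index.

The adsorption index for residue i and a given buffer charge state is
``-ln(N_avg_i / N_max)`` in units of k_B*T, where ``N_max`` is the largest
time-averaged contact count over *all* charge states of the species, so all
states of one buffer share a free-energy origin.  Residues with zero
time-averaged contacts get an infinite sentinel and are excluded from
averages and distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_model import SelectionGroup, Trajectory, wrap_coordinates
from .structure_metrics import SasaResult

logger = logging.getLogger(__name__)

__all__ = [
    "RDFProfile",
    "ContactCountMatrix",
    "BAIResult",
    "surface_rdf",
    "cumulative_count",
    "count_contacts",
    "contact_count_matrix",
    "average_contacts",
    "compute_bai",
    "species_average_bai",
    "bai_distribution",
]

DEFAULT_CONTACT_CUTOFF = 0.4  # nm
DEFAULT_BIN_WIDTH = 0.005  # nm
DEFAULT_R_MAX = 2.5  # nm


@dataclass
class RDFProfile:
    """Histogram of nearest-surface distances, counts / (frames * bin width).

    Bins are left-closed, right-open; integrating density over the full range
    recovers the mean number of target atoms within ``r_max``.
    """

    bin_edges: np.ndarray  # nm, length n_bins + 1
    density: np.ndarray  # counts / nm
    reference: str
    target: str
    n_frames: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def r_max(self) -> float:
        return float(self.bin_edges[-1])

    def total_count(self) -> float:
        return float(np.sum(self.density) * self.bin_width)


@dataclass
class ContactCountMatrix:
    """Instantaneous per-residue contact counts for one buffer state."""

    residue_indices: np.ndarray  # (n_res,)
    residue_names: list[str]
    counts: np.ndarray  # (n_frames, n_res) nonnegative ints
    state: str
    cutoff: float

    def time_average(self) -> np.ndarray:
        return self.counts.mean(axis=0)


@dataclass
class BAIResult:
    """Adsorption index table plus its normalization constant."""

    table: pd.DataFrame  # columns: residue_index, residue_name, state, n_avg, bai
    n_max: float
    temperature: float
    zero_contact_flags: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    def finite(self) -> pd.DataFrame:
        return self.table[np.isfinite(self.table["bai"])]


def _default_skip(n_frames: int) -> int:
    # drop the first 5% of frames as equilibration
    return int(0.05 * n_frames)


def surface_rdf(
    trajectory: Trajectory,
    reference: SelectionGroup,
    target: SelectionGroup,
    box_length: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_R_MAX,
    skip: int | None = None,
) -> RDFProfile:
    """Distribution of target atoms binned by distance to the nearest
    reference atom (minimum image), counts divided by frames and bin width."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not reference.atom_ids or not target.atom_ids:
        raise ValueError("reference and target groups must be nonempty")
    if skip is None:
        skip = _default_skip(trajectory.n_frames)
    if skip >= trajectory.n_frames:
        raise ValueError(f"skip={skip} leaves no frames out of {trajectory.n_frames}")
    n_bins = int(np.ceil(r_max / bin_width - 1e-12))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    ref_idx, tgt_idx = reference.indices(), target.indices()
    counts = np.zeros(n_bins)
    used = 0
    for f in range(skip, trajectory.n_frames):
        frame = wrap_coordinates(trajectory.coordinates[f], box_length)
        tree = cKDTree(frame[ref_idx], boxsize=box_length)
        dist, _ = tree.query(frame[tgt_idx], k=1)
        hist, _ = np.histogram(dist, bins=edges)
        counts += hist
        used += 1
    density = counts / (used * bin_width)
    return RDFProfile(
        bin_edges=edges,
        density=density,
        reference=reference.name,
        target=target.name,
        n_frames=used,
    )


def cumulative_count(profile: RDFProfile, r: float) -> float:
    """Mean number of target atoms within distance ``r`` of the surface.

    Sums ``density * bin_width`` over bins whose right edge is <= r;
    nondecreasing in r and equal to the total mean count at ``r_max``.
    """
    if r < -1e-12 or r > profile.r_max + 1e-12:
        raise ValueError(f"r={r} outside profile range [0, {profile.r_max}]")
    included = profile.bin_edges[1:] <= r + 1e-12
    return float(np.sum(profile.density[included]) * profile.bin_width)


def count_contacts(
    frame_coordinates: np.ndarray,
    residue_atoms: Mapping[int, np.ndarray],
    buffer_atoms: np.ndarray,
    box_length: float,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> dict[int, int]:
    """Atomic-pair contact counts per residue.

    A contact is any (protein atom, buffer atom) pair with minimum-image
    distance <= cutoff; the count is over pairs, not distinct molecules.
    """
    if cutoff >= box_length / 2:
        raise ValueError("cutoff must be below half the box length")
    frame = wrap_coordinates(np.asarray(frame_coordinates, float), box_length)
    buffer_idx = np.asarray(buffer_atoms, dtype=int)
    if buffer_idx.size == 0:
        raise ValueError("buffer group is empty")
    tree = cKDTree(frame[buffer_idx], boxsize=box_length)
    out: dict[int, int] = {}
    for res, atoms in residue_atoms.items():
        atoms = np.asarray(atoms, dtype=int)
        if atoms.size == 0:
            raise ValueError(f"residue {res} has no atoms")
        neighbour_counts = tree.query_ball_point(
            frame[atoms], cutoff, return_length=True
        )
        out[int(res)] = int(np.sum(neighbour_counts))
    return out


def contact_count_matrix(
    trajectory: Trajectory,
    residue_atoms: Mapping[int, np.ndarray],
    residue_names: Mapping[int, str],
    buffer_group: SelectionGroup,
    box_length: float,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    skip: int = 0,
) -> ContactCountMatrix:
    """Per-frame contact counts of one buffer state against every residue."""
    res_order = sorted(residue_atoms)
    counts = np.zeros((trajectory.n_frames - skip, len(res_order)), dtype=int)
    for k, f in enumerate(range(skip, trajectory.n_frames)):
        per_res = count_contacts(
            trajectory.coordinates[f],
            residue_atoms,
            buffer_group.indices(),
            box_length,
            cutoff=cutoff,
        )
        counts[k] = [per_res[r] for r in res_order]
    return ContactCountMatrix(
        residue_indices=np.array(res_order, dtype=int),
        residue_names=[residue_names[r] for r in res_order],
        counts=counts,
        state=buffer_group.name,
        cutoff=cutoff,
    )


def average_contacts(per_trajectory_counts: Sequence[np.ndarray]) -> np.ndarray:
    """Time-average within each trajectory, then unweighted mean across them.

    Each element is an ``(n_frames_k, n_res)`` array; trajectories may have
    different frame counts (ragged), but must agree on residues.
    """
    if len(per_trajectory_counts) == 0:
        raise ValueError("need at least one trajectory")
    per_traj = [np.asarray(c, dtype=float).mean(axis=0) for c in per_trajectory_counts]
    shapes = {p.shape for p in per_traj}
    if len(shapes) != 1:
        raise ValueError("trajectories disagree on residue count")
    return np.mean(per_traj, axis=0)


def compute_bai(n_avg: pd.DataFrame, temperature: float = 300.0) -> BAIResult:
    """Adsorption index ``-ln(N_avg / N_max)`` in k_B*T units.

    ``n_avg`` must have columns residue_index, residue_name, state, n_avg.
    ``N_max`` is taken over all states present, giving every state of a
    species the same free-energy origin.  Residues with ``n_avg == 0`` are
    flagged and reported as +inf.
    """
    required = {"residue_index", "residue_name", "state", "n_avg"}
    missing = required - set(n_avg.columns)
    if missing:
        raise ValueError(f"n_avg table missing columns: {sorted(missing)}")
    if (n_avg["n_avg"] < 0).any():
        raise ValueError("contact averages must be nonnegative")
    n_max = float(n_avg["n_avg"].max())
    if n_max <= 0:
        raise ValueError("all contact averages are zero; BAI undefined")
    table = n_avg.copy()
    with np.errstate(divide="ignore"):
        table["bai"] = -np.log(table["n_avg"].to_numpy() / n_max)
    flags = table["n_avg"] == 0.0
    return BAIResult(
        table=table,
        n_max=n_max,
        temperature=temperature,
        zero_contact_flags=flags,
    )


def species_average_bai(bai: BAIResult, sasa: SasaResult) -> pd.DataFrame:
    """Unweighted mean adsorption index per (amino-acid species, state).

    Only residues with nonzero time-averaged SASA and a finite index are
    eligible; species with no eligible residue are omitted and logged.
    """
    missing = set(bai.table["residue_index"]) - set(sasa.per_residue_area)
    if missing:
        raise ValueError(f"SASA missing for residues: {sorted(missing)[:5]}")
    exposed = sasa.nonzero_residues()
    eligible = bai.table[
        bai.table["residue_index"].isin(exposed) & np.isfinite(bai.table["bai"])
    ]
    skipped = set(zip(bai.table["residue_name"], bai.table["state"])) - set(
        zip(eligible["residue_name"], eligible["state"])
    )
    for name, state in sorted(skipped):
        logger.info("species %s/%s has no exposed residue with finite BAI; omitted", name, state)
    grouped = (
        eligible.groupby(["residue_name", "state"], as_index=False)["bai"]
        .mean()
        .rename(columns={"bai": "mean_bai"})
    )
    return grouped


def bai_distribution(
    bai: BAIResult, bin_width: float = 0.5, state: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram (edges, probability density) of finite indices."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    table = bai.finite()
    if state is not None:
        table = table[table["state"] == state]
    values = table["bai"].to_numpy()
    if values.size == 0:
        raise ValueError("no finite BAI values to histogram")
    upper = np.ceil(values.max() / bin_width + 1e-12) * bin_width
    n_bins = max(1, int(round(upper / bin_width)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    hist, _ = np.histogram(values, bins=edges)
    p = hist / (values.size * bin_width)
    return edges, p
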