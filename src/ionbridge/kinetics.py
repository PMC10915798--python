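"""Contact survival kinetics and ionic-bridge detection between two proteins.

Survival is strict by default: a contact present at a time origin survives a
lag t only if it is occupied at every intermediate frame.  Brief
interruptions can be forgiven via ``gap_tolerance`` (in frames), which fills
unoccupied gaps of at most that length when they are flanked by occupancy.
Origins are pooled: S(t) = (surviving origins) / (occupied origins valid for
that lag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_model import (
    SelectionGroup,
    Trajectory,
    pairwise_min_image_distances,
    wrap_coordinates,
)

__all__ = [
    "ContactSeries",
    "SurvivalCurve",
    "BridgeRecord",
    "build_contact_series",
    "survival_probability",
    "detect_bridges",
    "bridge_lifetimes",
    "bridge_anchor_residues",
]

DEFAULT_CUTOFF = 0.4  # nm


@dataclass
class ContactSeries:
    """Boolean occupancy for a set of contact channels over all frames."""

    entities: list[tuple[str, str]]  # (ion id, partner id) per channel
    occupancy: np.ndarray  # (n_channels, n_frames) bool
    frame_spacing: float  # ps

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be (n_channels, n_frames)")
        if len(self.entities) != self.occupancy.shape[0]:
            raise ValueError("entities and occupancy disagree on channel count")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.occupancy.shape[1])


@dataclass
class SurvivalCurve:
    lags: np.ndarray  # ps
    S: np.ndarray  # in [0, 1], S[0] == 1, nonincreasing where defined

    def at(self, lag_ps: float) -> float:
        i = int(round(lag_ps / (self.lags[1] - self.lags[0]))) if len(self.lags) > 1 else 0
        return float(self.S[i])


@dataclass
class BridgeRecord:
    """One maximal interval during which an ion bridges both proteins."""

    ion_id: str
    start_frame: int
    end_frame: int  # inclusive
    d_min_A: np.ndarray  # nm, one per frame of the interval
    d_min_B: np.ndarray
    anchors: list[tuple[int, int]]  # (residue on A, residue on B) per frame

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_ps(self, frame_spacing: float) -> float:
        return self.n_frames * frame_spacing


def build_contact_series(
    trajectory: Trajectory,
    ions: Mapping[str, Sequence[int]],
    protein: SelectionGroup,
    box_length: float,
    cutoff: float = DEFAULT_CUTOFF,
    granularity: str = "ion-protein",
    residue_atoms: Mapping[int, Sequence[int]] | None = None,
) -> ContactSeries:
    """Occupancy series: true when any atomic pair is within ``cutoff``.

    ``granularity`` is ``ion-protein`` (one channel per ion molecule) or
    ``ion-residue`` (one channel per ion/residue pair; requires
    ``residue_atoms``).
    """
    if not ions:
        raise ValueError("no ion molecules given")
    if granularity not in ("ion-protein", "ion-residue"):
        raise ValueError(f"unknown granularity {granularity!r}")
    if granularity == "ion-residue" and residue_atoms is None:
        raise ValueError("ion-residue granularity requires residue_atoms")
    dt = trajectory.frame_spacing or 1.0
    prot_idx = protein.indices()
    ion_items = [(str(k), np.asarray(v, dtype=int)) for k, v in ions.items()]

    if granularity == "ion-protein":
        entities = [(ion_id, protein.name) for ion_id, _ in ion_items]
        occ = np.zeros((len(ion_items), trajectory.n_frames), dtype=bool)
        for f in range(trajectory.n_frames):
            frame = wrap_coordinates(trajectory.coordinates[f], box_length)
            tree = cKDTree(frame[prot_idx], boxsize=box_length)
            for c, (_, atoms) in enumerate(ion_items):
                counts = tree.query_ball_point(frame[atoms], cutoff, return_length=True)
                occ[c, f] = bool(np.any(counts))
        return ContactSeries(entities=entities, occupancy=occ, frame_spacing=dt)

    res_items = [(int(r), np.asarray(a, dtype=int)) for r, a in sorted(residue_atoms.items())]
    entities = [
        (ion_id, str(res)) for ion_id, _ in ion_items for res, _ in res_items
    ]
    occ = np.zeros((len(entities), trajectory.n_frames), dtype=bool)
    for f in range(trajectory.n_frames):
        frame = wrap_coordinates(trajectory.coordinates[f], box_length)
        c = 0
        for _, ion_atoms in ion_items:
            for _, res_atoms in res_items:
                d = pairwise_min_image_distances(frame[ion_atoms], frame[res_atoms], box_length)
                occ[c, f] = bool(np.any(d <= cutoff))
                c += 1
    return ContactSeries(entities=entities, occupancy=occ, frame_spacing=dt)


def _fill_gaps(occupancy: np.ndarray, gap_tolerance: int) -> np.ndarray:
    """Fill unoccupied gaps of length <= gap_tolerance flanked by occupancy."""
    if gap_tolerance <= 0:
        return occupancy
    filled = occupancy.copy()
    for row in filled:
        occupied = np.flatnonzero(row)
        if occupied.size < 2:
            continue
        gaps = np.diff(occupied) - 1
        for start, gap in zip(occupied[:-1], gaps):
            if 0 < gap <= gap_tolerance:
                row[start + 1 : start + 1 + gap] = True
    return filled


def _suffix_run_lengths(occupancy: np.ndarray) -> np.ndarray:
    """run[c, t] = number of consecutive occupied frames starting at t."""
    n_channels, n_frames = occupancy.shape
    run = np.zeros((n_channels, n_frames), dtype=np.int64)
    run[:, -1] = occupancy[:, -1]
    for t in range(n_frames - 2, -1, -1):
        run[:, t] = np.where(occupancy[:, t], run[:, t + 1] + 1, 0)
    return run


def survival_probability(
    series: ContactSeries,
    max_lag_ps: float,
    gap_tolerance: int = 0,
) -> SurvivalCurve:
    """Pooled-origin survival probability of contacts.

    Every frame at which a channel is occupied is a time origin; the origin
    survives lag t when the (gap-filled) occupancy is continuous through
    origin + t.  Normalization at each lag uses only origins for which the
    lag fits inside the series.
    """
    dt = series.frame_spacing
    span = (series.n_frames - 1) * dt
    n_lags = int(round(max_lag_ps / dt))
    if n_lags > series.n_frames - 1:
        raise ValueError(f"max_lag {max_lag_ps} ps exceeds the series span {span} ps")
    occ = series.occupancy
    if not occ.any():
        raise ValueError("no occupied origins in the series")
    filled = _fill_gaps(occ, gap_tolerance)
    run = _suffix_run_lengths(filled)
    s = np.empty(n_lags + 1)
    n_frames = series.n_frames
    for lag in range(n_lags + 1):
        origins = occ[:, : n_frames - lag]
        denominator = int(origins.sum())
        if denominator == 0:
            s[lag:] = np.nan
            break
        survivors = origins & (run[:, : n_frames - lag] >= lag + 1)
        s[lag] = survivors.sum() / denominator
    return SurvivalCurve(lags=np.arange(n_lags + 1) * dt, S=s)


def _ion_group_min(
    frame: np.ndarray,
    ion_atoms: np.ndarray,
    group_idx: np.ndarray,
    box_length: float,
) -> tuple[float, int]:
    """(min distance, 0-based index into group_idx of the closest group atom)."""
    d = pairwise_min_image_distances(frame[ion_atoms], frame[group_idx], box_length)
    flat = int(np.argmin(d))
    return float(d.flat[flat]), flat % d.shape[1]


def detect_bridges(
    frame_coordinates: np.ndarray,
    ion_molecules: Mapping[str, Sequence[int]],
    protein_a: SelectionGroup,
    protein_b: SelectionGroup,
    box_length: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> set[str]:
    """Ions whose minimum atomic distance to *both* proteins is < cutoff."""
    if protein_a.atom_ids & protein_b.atom_ids:
        raise ValueError("protein groups must be disjoint")
    frame = wrap_coordinates(np.asarray(frame_coordinates, float), box_length)
    ia, ib = protein_a.indices(), protein_b.indices()
    bridging = set()
    for ion_id, atoms in ion_molecules.items():
        atoms = np.asarray(atoms, dtype=int)
        da, _ = _ion_group_min(frame, atoms, ia, box_length)
        if da >= cutoff:
            continue
        db, _ = _ion_group_min(frame, atoms, ib, box_length)
        if db < cutoff:
            bridging.add(str(ion_id))
    return bridging


def _nearest_residue(
    frame: np.ndarray,
    ion_atoms: np.ndarray,
    group_idx: np.ndarray,
    atom_to_residue: np.ndarray,
    box_length: float,
) -> int:
    """Residue of the group atom closest to the ion; ties -> lower residue index."""
    d = pairwise_min_image_distances(frame[ion_atoms], frame[group_idx], box_length)
    d_min = d.min()
    cols = np.unique(np.nonzero(d == d_min)[1])
    return int(atom_to_residue[cols].min())


def bridge_lifetimes(
    trajectory: Trajectory,
    ion_molecules: Mapping[str, Sequence[int]],
    protein_a: SelectionGroup,
    protein_b: SelectionGroup,
    residue_of_atom: Mapping[int, int],
    box_length: float,
    cutoff: float = DEFAULT_CUTOFF,
    gap_tolerance: int = 0,
    max_lag_ps: float | None = None,
) -> tuple[list[BridgeRecord], SurvivalCurve | None]:
    """Maximal bridging intervals per ion plus the bridge survival curve.

    ``residue_of_atom`` maps 0-based atom index to residue index for both
    protein groups.  Gap tolerance merges interruptions of at most that many
    frames into a single record.  A system with no bridge at any frame
    yields no records and no curve.
    """
    if protein_a.atom_ids & protein_b.atom_ids:
        raise ValueError("protein groups must be disjoint")
    ia, ib = protein_a.indices(), protein_b.indices()
    res_a = np.array([residue_of_atom[int(i)] for i in ia], dtype=int)
    res_b = np.array([residue_of_atom[int(i)] for i in ib], dtype=int)
    ion_items = [(str(k), np.asarray(v, dtype=int)) for k, v in ion_molecules.items()]
    n_frames = trajectory.n_frames
    occ = np.zeros((len(ion_items), n_frames), dtype=bool)
    d_a = np.zeros((len(ion_items), n_frames))
    d_b = np.zeros((len(ion_items), n_frames))
    anchors: list[list[tuple[int, int]]] = [[(-1, -1)] * n_frames for _ in ion_items]
    for f in range(n_frames):
        frame = wrap_coordinates(trajectory.coordinates[f], box_length)
        for c, (_, atoms) in enumerate(ion_items):
            da, _ = _ion_group_min(frame, atoms, ia, box_length)
            db, _ = _ion_group_min(frame, atoms, ib, box_length)
            d_a[c, f], d_b[c, f] = da, db
            if da < cutoff and db < cutoff:
                occ[c, f] = True
                anchors[c][f] = (
                    _nearest_residue(frame, atoms, ia, res_a, box_length),
                    _nearest_residue(frame, atoms, ib, res_b, box_length),
                )
    filled = _fill_gaps(occ, gap_tolerance)
    records: list[BridgeRecord] = []
    for c, (ion_id, _) in enumerate(ion_items):
        row = filled[c]
        f = 0
        while f < n_frames:
            if not row[f]:
                f += 1
                continue
            start = f
            while f + 1 < n_frames and row[f + 1]:
                f += 1
            end = f
            records.append(
                BridgeRecord(
                    ion_id=ion_id,
                    start_frame=start,
                    end_frame=end,
                    d_min_A=d_a[c, start : end + 1].copy(),
                    d_min_B=d_b[c, start : end + 1].copy(),
                    anchors=anchors[c][start : end + 1],
                )
            )
            f += 1
    dt = trajectory.frame_spacing or 1.0
    if not occ.any():
        return [], None
    series = ContactSeries(
        entities=[(ion_id, "bridge") for ion_id, _ in ion_items],
        occupancy=occ,
        frame_spacing=dt,
    )
    if max_lag_ps is None:
        max_lag_ps = (n_frames - 1) * dt / 2
    curve = survival_probability(series, max_lag_ps, gap_tolerance=gap_tolerance)
    return records, curve


def bridge_anchor_residues(record: BridgeRecord, frame: int) -> tuple[int, int]:
    """Anchor residues (on A, on B) of a bridge at an absolute frame index."""
    if frame < record.start_frame or frame > record.end_frame:
        raise ValueError(
            f"frame {frame} outside record [{record.start_frame}, {record.end_frame}]"
        )
    pair = record.anchors[frame - record.start_frame]
    if pair == (-1, -1):
        raise ValueError(f"frame {frame} lies in a forgiven gap; no anchors recorded")
    return pair
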