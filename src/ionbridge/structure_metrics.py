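"""Geometric observables: Shrake-Rupley SASA and radius of gyration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_model import MolecularSystem, Trajectory

__all__ = [
    "SasaResult",
    "sphere_points",
    "sasa_per_residue",
    "time_averaged_sasa",
    "radius_of_gyration",
]


@dataclass
class SasaResult:
    """Per-residue solvent-accessible surface area in nm^2."""

    per_residue_area: dict[int, float]
    residue_names: dict[int, str]
    probe_radius: float
    n_points: int

    @property
    def total_area(self) -> float:
        return float(sum(self.per_residue_area.values()))

    def nonzero_residues(self) -> set[int]:
        return {i for i, a in self.per_residue_area.items() if a > 0.0}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_per_residue(
    system: MolecularSystem,
    coordinates: np.ndarray,
    probe_radius: float = 0.14,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley quadrature SASA, summed per residue.

    For each atom, the fraction of ``n_points`` sphere points at radius
    ``r_atom + probe`` not inside any other inflated atom, times the inflated
    sphere area.  The molecule is treated as non-periodic (an isolated
    solute).
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    coords = np.asarray(coordinates, dtype=float)
    if coords.shape != (system.n_atoms, 3):
        raise ValueError("coordinates shape does not match the system")
    radii = system.radii()
    if np.any(radii <= 0):
        raise ValueError("all atoms must carry a positive radius for SASA")
    inflated = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    areas = np.zeros(system.n_atoms)
    for i in range(system.n_atoms):
        neighbours = [
            j
            for j in tree.query_ball_point(coords[i], max_reach)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < inflated[i] + inflated[j]
        ]
        pts = coords[i] + inflated[i] * unit
        if neighbours:
            nb = np.array(neighbours, dtype=int)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < (inflated[nb] ** 2)[None, :], axis=1)
            exposed_fraction = 1.0 - buried.mean()
        else:
            exposed_fraction = 1.0
        areas[i] = exposed_fraction * 4.0 * np.pi * inflated[i] ** 2
    per_residue: dict[int, float] = {}
    names: dict[int, str] = {}
    for atom, area in zip(system.atoms, areas):
        per_residue[atom.residue_index] = per_residue.get(atom.residue_index, 0.0) + float(area)
        names[atom.residue_index] = atom.residue_name
    return SasaResult(
        per_residue_area=per_residue,
        residue_names=names,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def time_averaged_sasa(
    trajectory: Trajectory,
    system: MolecularSystem,
    stride: int = 1,
    probe_radius: float = 0.14,
    n_points: int = 960,
) -> SasaResult:
    """Arithmetic mean of per-frame per-residue SASA over sampled frames."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = range(0, trajectory.n_frames, stride)
    accumulated: dict[int, float] = {}
    names: dict[int, str] = {}
    count = 0
    for f in frames:
        result = sasa_per_residue(
            system, trajectory.coordinates[f], probe_radius=probe_radius, n_points=n_points
        )
        for res, area in result.per_residue_area.items():
            accumulated[res] = accumulated.get(res, 0.0) + area
        names.update(result.residue_names)
        count += 1
    return SasaResult(
        per_residue_area={r: a / count for r, a in accumulated.items()},
        residue_names=names,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def radius_of_gyration(coordinates: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration sqrt(sum m |r - r_com|^2 / sum m), in nm."""
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    m = np.asarray(masses, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("need at least one atom")
    if np.any(m < 0) or m.sum() <= 0:
        raise ValueError("masses must be nonnegative with positive total")
    com = np.average(coords, axis=0, weights=m)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=m)))
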