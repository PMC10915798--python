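"""Core domain types, file readers/writers and the periodic distance engine.

Units follow the package convention: lengths in nm, times in ps, charges in
elementary-charge units.  Atom indices are 1-based on every file interface
(PDB serials, reported atom pairs) and 0-based internally; the readers and
writers are the only place where the conversion happens.

Only cubic periodic boxes are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "MolecularSystem",
    "Trajectory",
    "SelectionGroup",
    "ExperimentManifest",
    "ManifestRow",
    "StructureParseError",
    "TrajectoryParseError",
    "ELEMENT_RADII_NM",
    "read_structure",
    "read_structure_coordinates",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_manifest",
    "write_manifest",
    "minimum_image_distance",
    "minimum_image_displacement",
    "wrap_coordinates",
    "group_min_distance",
]

#: van der Waals radii (nm) used when a structure file does not carry radii.
#: The first six entries are the documented defaults for protein atoms; the
#: remainder covers common ions found in formulation systems.
ELEMENT_RADII_NM: dict[str, float] = {
    "C": 0.17,
    "N": 0.155,
    "O": 0.152,
    "S": 0.18,
    "P": 0.18,
    "H": 0.12,
    "Na": 0.227,
    "Cl": 0.175,
    "K": 0.275,
    "Mg": 0.173,
    "Ca": 0.231,
    "F": 0.147,
    "Zn": 0.139,
}

#: atomic masses (u) for convenience when computing mass-weighted observables
ELEMENT_MASSES_U: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "Cl": 35.45,
    "K": 39.098,
    "Mg": 24.305,
    "Ca": 40.078,
    "F": 18.998,
    "Zn": 65.38,
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file violates the plain-text dialect."""


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``atom_id`` is the 1-based serial from the source file; ``formal_charge``
    is in elementary-charge units and ``radius`` in nm.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    formal_charge: float = 0.0
    radius: float = 0.0


@dataclass
class MolecularSystem:
    """Atoms plus the (cubic) periodic box they live in.

    ``reference_coordinates`` optionally carries one canonical frame (nm),
    used by generators and single-frame observables; time-resolved
    coordinates belong to :class:`Trajectory`.
    """

    atoms: list[Atom]
    box_length: float
    periodic: bool = True
    reference_coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError(f"box_length must be positive, got {self.box_length}")
        for atom in self.atoms:
            if atom.radius < 0:
                raise ValueError(f"atom {atom.atom_id} has negative radius")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        """Sum of formal charges (elementary-charge units)."""
        return float(sum(a.formal_charge for a in self.atoms))

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.formal_charge for a in self.atoms], dtype=float)

    def residue_atom_indices(self, indices: Iterable[int] | None = None) -> dict[int, np.ndarray]:
        """Map residue_index -> 0-based atom indices, optionally restricted."""
        allowed = None if indices is None else set(int(i) for i in indices)
        out: dict[int, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            if allowed is not None and i not in allowed:
                continue
            out.setdefault(atom.residue_index, []).append(i)
        return {k: np.array(v, dtype=int) for k, v in out.items()}


@dataclass
class Trajectory:
    """Time-stamped coordinates for every atom of a system.

    ``times`` are in ps and strictly increasing; ``coordinates`` has shape
    ``(n_frames, n_atoms, 3)`` in nm.  Coordinates are stored as read --
    wrapping into the box is applied on demand by the distance engine.
    """

    times: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coordinates.shape[0]:
            raise ValueError("times and coordinates disagree on frame count")
        if len(self.times) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValueError("frame spacing is not uniform within 1e-9 ps")

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[1])

    @property
    def frame_spacing(self) -> float:
        """Time between consecutive frames in ps (0 for single-frame data)."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


_ROLES = {"protein_A", "protein_B", "buffer_state", "cation", "anion"}


@dataclass
class SelectionGroup:
    """A named set of 0-based atom indices with a semantic role."""

    name: str
    atom_ids: frozenset[int]
    role: str

    def __post_init__(self) -> None:
        self.atom_ids = frozenset(int(i) for i in self.atom_ids)
        if not self.atom_ids:
            raise ValueError(f"selection group {self.name!r} is empty")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(_ROLES)}")

    def indices(self) -> np.ndarray:
        return np.array(sorted(self.atom_ids), dtype=int)

    def validate_against(self, system: MolecularSystem) -> None:
        bad = [i for i in self.atom_ids if i < 0 or i >= system.n_atoms]
        if bad:
            raise ValueError(f"group {self.name!r} references atoms outside the system: {sorted(bad)[:5]}")


@dataclass(frozen=True)
class ManifestRow:
    system_name: str
    pH: float
    buffer_mM: float
    nacl_mM: float
    run_ns: float
    n_runs: int

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError(f"{self.system_name}: n_runs must be >= 1")
        if self.run_ns <= 0:
            raise ValueError(f"{self.system_name}: run_ns must be positive")


@dataclass
class ExperimentManifest:
    """Bookkeeping table for a simulation campaign (one row per system)."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed columns)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, record: str) -> str | None:
    """Guess the element from an atom name when columns 77-78 are blank.

    For ATOM records the one-letter reading is preferred (CA is an alpha
    carbon, not calcium); for HETATM records the two-letter reading wins
    (NA is sodium).
    """
    stripped = "".join(ch for ch in atom_name.strip() if ch.isalpha())
    if not stripped:
        return None
    one = stripped[0].upper()
    two = stripped[:2].capitalize() if len(stripped) >= 2 else None
    if record == "ATOM":
        candidates = [one, two]
    else:
        candidates = [two, one]
    for cand in candidates:
        if cand and cand in ELEMENT_RADII_NM:
            return cand
    return None


def _parse_formal_charge(text: str) -> float:
    text = text.strip()
    if not text:
        return 0.0
    # PDB writes e.g. "2-" or "1+"; tolerate "+2"/"-1" as well.
    if text[-1] in "+-":
        magnitude, sign = text[:-1] or "1", text[-1]
    elif text[0] in "+-":
        magnitude, sign = text[1:] or "1", text[0]
    else:
        magnitude, sign = text, "+"
    try:
        value = float(magnitude)
    except ValueError:
        return 0.0
    return value if sign == "+" else -value


def _parse_pdb(path: str | Path) -> tuple[list[Atom], list[list[float]], float | None]:
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    box: float | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "CRYST1":
                try:
                    box = float(line[6:15]) / 10.0  # Angstrom -> nm
                except ValueError as exc:
                    raise StructureParseError(f"line {lineno}: malformed CRYST1 record") from exc
                continue
            if record not in ("ATOM", "HETATM"):
                continue  # TER / CONECT / REMARK etc. are ignored
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(f"line {lineno}: ATOM/HETATM record too short")
            try:
                serial = int(line[6:11])
                atom_name = line[12:16].strip()
                residue_name = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                residue_index = int(line[22:26])
                x = float(line[30:38]) / 10.0
                y = float(line[38:46]) / 10.0
                z = float(line[46:54]) / 10.0
            except ValueError as exc:
                raise StructureParseError(f"line {lineno}: malformed fixed-column fields") from exc
            element_field = line[76:78].strip() if len(line) >= 78 else ""
            if element_field:
                element = element_field.capitalize()
            else:
                inferred = _infer_element(atom_name, record)
                if inferred is None:
                    raise StructureParseError(
                        f"line {lineno}: cannot infer element for atom "
                        f"{serial} {atom_name!r} in residue {residue_name}"
                    )
                element = inferred
            if element not in ELEMENT_RADII_NM:
                raise StructureParseError(
                    f"line {lineno}: unknown element {element!r} for atom {serial} {atom_name!r}"
                )
            charge = _parse_formal_charge(line[78:80] if len(line) >= 80 else "")
            atoms.append(
                Atom(
                    atom_id=serial,
                    atom_name=atom_name,
                    element=element,
                    residue_index=residue_index,
                    residue_name=residue_name,
                    chain_id=chain_id,
                    formal_charge=charge,
                    radius=ELEMENT_RADII_NM[element],
                )
            )
            coords.append([x, y, z])
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return atoms, coords, box


def read_structure(path: str | Path, box_length: float | None = None) -> MolecularSystem:
    """Read a fixed-column PDB file into a :class:`MolecularSystem`.

    The box length is taken from the CRYST1 record when present (converted
    Angstrom -> nm); otherwise ``box_length`` must be supplied.
    """
    atoms, _, box = _parse_pdb(path)
    if box_length is not None:
        box = box_length
    if box is None:
        raise StructureParseError(
            f"{path}: no CRYST1 record and no box_length given; a cubic box is required"
        )
    return MolecularSystem(atoms=atoms, box_length=box)


def read_structure_coordinates(path: str | Path) -> np.ndarray:
    """Return the (n_atoms, 3) nm coordinates stored in a PDB file."""
    _, coords, _ = _parse_pdb(path)
    return np.array(coords, dtype=float)


def _format_charge(q: float) -> str:
    qi = int(round(q))
    if qi == 0 or abs(qi) > 9 or abs(q - qi) > 1e-9:
        return "  "
    return f"{abs(qi)}{'+' if qi > 0 else '-'}"


def write_structure(path: str | Path, system: MolecularSystem, coordinates: np.ndarray) -> None:
    """Write a fixed-column PDB (with CRYST1) for ``system``."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (system.n_atoms, 3):
        raise ValueError("coordinates shape does not match the system")
    box_a = system.box_length * 10.0
    lines = [
        f"CRYST1{box_a:9.3f}{box_a:9.3f}{box_a:9.3f}  90.00  90.00  90.00 P 1           1"
    ]
    for atom, xyz in zip(system.atoms, coordinates):
        x, y, z = (xyz * 10.0).tolist()
        name = atom.atom_name
        # standard PDB alignment: short names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"ATOM  {atom.atom_id:5d} {name_field}"
            f" {atom.residue_name:<3s} {atom.chain_id[:1]}{atom.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}{_format_charge(atom.formal_charge)}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Plain-text trajectory dialect
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, system: MolecularSystem) -> Trajectory:
    """Read the plain-text trajectory dialect.

    Per frame: a header line ``natoms time_ps box_nm`` followed by ``natoms``
    lines of ``x y z`` in nm.
    """
    times: list[float] = []
    frames: list[np.ndarray] = []
    with open(path) as handle:
        lines = [ln for ln in (raw.strip() for raw in handle) if ln]
    if not lines:
        raise TrajectoryParseError(f"{path}: no frames")
    pos = 0
    frame_index = 0
    while pos < len(lines):
        header = lines[pos].split()
        if len(header) != 3:
            raise TrajectoryParseError(
                f"frame {frame_index}: expected header 'natoms time_ps box_nm', got {lines[pos]!r}"
            )
        natoms, t, box = int(header[0]), float(header[1]), float(header[2])
        if natoms != system.n_atoms:
            raise TrajectoryParseError(
                f"frame {frame_index}: atom count {natoms} does not match system ({system.n_atoms})"
            )
        if abs(box - system.box_length) > 1e-6:
            raise TrajectoryParseError(
                f"frame {frame_index}: box {box} nm does not match system ({system.box_length} nm)"
            )
        if times and t <= times[-1]:
            raise TrajectoryParseError(f"frame {frame_index}: non-increasing time {t} ps")
        if pos + 1 + natoms > len(lines):
            raise TrajectoryParseError(f"frame {frame_index}: truncated coordinate block")
        block = lines[pos + 1 : pos + 1 + natoms]
        try:
            xyz = np.array([[float(v) for v in ln.split()] for ln in block], dtype=float)
        except ValueError as exc:
            raise TrajectoryParseError(f"frame {frame_index}: malformed coordinate line") from exc
        if xyz.shape != (natoms, 3):
            raise TrajectoryParseError(f"frame {frame_index}: expected {natoms}x3 coordinates")
        times.append(t)
        frames.append(xyz)
        pos += 1 + natoms
        frame_index += 1
    return Trajectory(times=np.array(times), coordinates=np.stack(frames))


def write_trajectory(path: str | Path, trajectory: Trajectory, system: MolecularSystem) -> None:
    """Write a trajectory in the plain-text dialect (1e-6 nm precision)."""
    parts: list[str] = []
    for t, frame in zip(trajectory.times, trajectory.coordinates):
        parts.append(f"{system.n_atoms} {t:.6f} {system.box_length:.6f}")
        for x, y, z in frame:
            parts.append(f"{x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(parts) + "\n")


# ---------------------------------------------------------------------------
# Manifest TSV
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["system_name", "pH", "buffer_mM", "nacl_mM", "run_ns", "n_runs"]


def read_manifest(path: str | Path) -> ExperimentManifest:
    """Read a manifest TSV with headers system_name, pH, buffer_mM, nacl_mM, run_ns, n_runs."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    rows = [
        ManifestRow(
            system_name=str(r.system_name),
            pH=float(r.pH),
            buffer_mM=float(r.buffer_mM),
            nacl_mM=float(r.nacl_mM),
            run_ns=float(r.run_ns),
            n_runs=int(r.n_runs),
        )
        for r in df.itertuples()
    ]
    return ExperimentManifest(rows=rows)


def write_manifest(path: str | Path, manifest: ExperimentManifest) -> None:
    manifest.to_frame()[_MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Periodic distance engine
# ---------------------------------------------------------------------------

def wrap_coordinates(coords: np.ndarray, box_length: float) -> np.ndarray:
    """Map coordinates into [0, box_length) per axis."""
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    return np.mod(coords, box_length)


def minimum_image_displacement(p: np.ndarray, q: np.ndarray, box_length: float) -> np.ndarray:
    """Minimum-image displacement vector(s) p - q (broadcasting allowed)."""
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    delta = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    return delta - box_length * np.round(delta / box_length)


def minimum_image_distance(p: Sequence[float], q: Sequence[float], box_length: float) -> float:
    """Euclidean distance under the minimum-image convention (cubic box).

    The result never exceeds ``box_length * sqrt(3) / 2``.
    """
    delta = minimum_image_displacement(np.asarray(p, float), np.asarray(q, float), box_length)
    return float(np.linalg.norm(delta))


def pairwise_min_image_distances(
    a: np.ndarray, b: np.ndarray, box_length: float
) -> np.ndarray:
    """All minimum-image distances between rows of ``a`` and rows of ``b``.

    Returns an (len(a), len(b)) matrix.  Exact (no neighbour-list pruning);
    intended for modest group sizes.
    """
    delta = minimum_image_displacement(a[:, None, :], b[None, :, :], box_length)
    return np.sqrt(np.sum(delta * delta, axis=-1))


def group_min_distance(
    a: SelectionGroup,
    b: SelectionGroup,
    frame_coordinates: np.ndarray,
    box_length: float,
) -> tuple[float, tuple[int, int]]:
    """Smallest minimum-image atomic-pair distance between two groups.

    Returns ``(d_min, (id_a, id_b))`` where the ids are 1-based atom indices
    into the frame.  Ties are broken by the lowest ``(id_a, id_b)`` pair.
    """
    if a.atom_ids & b.atom_ids:
        raise ValueError(f"groups {a.name!r} and {b.name!r} overlap")
    ia, ib = a.indices(), b.indices()
    dmat = pairwise_min_image_distances(
        frame_coordinates[ia], frame_coordinates[ib], box_length
    )
    d_min = float(dmat.min())
    rows, cols = np.nonzero(dmat == d_min)
    # candidate 1-based id pairs; lexicographic minimum wins
    pairs = sorted((int(ia[r]) + 1, int(ib[c]) + 1) for r, c in zip(rows, cols))
    return d_min, pairs[0]


def half_diagonal(box_length: float) -> float:
    """Upper bound of any minimum-image distance in a cubic box."""
    return box_length * math.sqrt(3.0) / 2.0
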