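"""Shared data model and file formats.

Defines the four containers the pipeline passes around — fixed-atom
structures, regular scalar grids, mobile-particle trajectories and ion
species descriptors — together with readers/writers for the exchange
formats: PQR (free-whitespace), OpenDX scalar grids (APBS dialect, z
axis fastest on disk) and a minimal extended-XYZ trajectory dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from gridData import Grid as _DXGrid

__all__ = [
    "StructureModel",
    "GridMap",
    "GridSpec",
    "IonTrajectory",
    "SpeciesSpec",
    "FormatError",
    "read_pqr",
    "write_pqr",
    "read_pdb_coords",
    "read_dx",
    "write_dx",
    "read_trajectory",
    "write_trajectory",
]

#: Species labels used in the trajectory dialect.
SPECIES_LABELS = ("CAT", "ANI", "WAT", "PRO")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class StructureModel:
    """Fixed atoms: positions (Å), partial charges (e) and radii (Å)."""

    positions: np.ndarray  # (n, 3) float
    charges: np.ndarray  # (n,) float
    radii: np.ndarray  # (n,) float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if self.charges.shape != (n,) or self.radii.shape != (n,):
            raise ValueError("charges and radii must match the atom count")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii < 0):
            raise ValueError("negative atomic radius")
        if not self.labels:
            self.labels = [f"A{i}" for i in range(n)]

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        """Net fixed charge Z in protonic units."""
        return float(self.charges.sum())


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: corner origin, per-axis spacing, node counts."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(d < 2 for d in self.dims):
            raise ValueError("grids need at least 2 nodes per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @classmethod
    def cube(cls, center: Sequence[float], extent: float, spacing: float) -> "GridSpec":
        """Cubic grid of edge length *extent* centred on *center*."""
        n = int(round(extent / spacing)) + 1
        half = (n - 1) * spacing / 2.0
        origin = tuple(float(c) - half for c in center)
        return cls(origin, (spacing,) * 3, (n, n, n))

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a])
            for a in range(3)
        )

    def node_positions(self) -> np.ndarray:
        """All node coordinates as an (nx*ny*nz, 3) array, C order."""
        ax = self.axes()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


@dataclass
class GridMap:
    """A scalar field on a regular grid.

    ``values[i, j, k]`` lives at ``origin + (i*sx, j*sy, k*sz)``; each node
    represents one voxel of volume ``sx*sy*sz`` in region integrals.  The
    ``units`` tag is one of ``{"M", "kT/e", "A", "A^-3", "mask"}``.
    """

    spec: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.spec.dims):
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.spec.dims}"
            )
        if self.units == "mask":
            bad = ~np.isin(self.values, (0.0, 1.0))
            if bad.any():
                raise ValueError("mask values must be 0 or 1")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite grid values")

    @property
    def voxel_volume(self) -> float:
        return self.spec.voxel_volume

    def like(self, values: np.ndarray, units: str | None = None) -> "GridMap":
        """A new map on the same grid."""
        return GridMap(self.spec, values, self.units if units is None else units)


@dataclass
class IonTrajectory:
    """Frames of mobile-particle positions tagged by species.

    ``species`` holds one label per particle (constant across frames);
    ``frames`` is a (n_frames, n_particles, 3) array in Å; ``box`` the
    rectangular box edge lengths in Å.
    """

    frames: np.ndarray
    species: np.ndarray
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_particles, 3)")
        if self.frames.shape[1] != len(self.species):
            raise ValueError("species labels must match particle count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def select(self, label: str) -> np.ndarray:
        """Positions of one species, shape (n_frames, n_label, 3)."""
        mask = self.species == label
        return self.frames[:, mask, :]

    def counts(self) -> dict[str, int]:
        labels, n = np.unique(self.species.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))


@dataclass(frozen=True)
class SpeciesSpec:
    """An ionic species: integer valence and bulk concentration (M)."""

    valence: int
    bulk_concentration: float

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError("ionic species must have nonzero valence")
        if self.bulk_concentration <= 0:
            raise ValueError("bulk concentration must be positive")


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> StructureModel:
    """Read a free-whitespace PQR file.

    ATOM/HETATM records are split on whitespace and the last five numeric
    fields are taken as x, y, z, charge, radius; all other lines are ignored.
    """
    positions, charges, radii, labels = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            if len(rec) < 6:
                raise FormatError(f"{path}:{lineno}: too few fields in atom record")
            try:
                x, y, z, q, r = (float(v) for v in rec[-5:])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric trailing fields"
                ) from exc
            positions.append((x, y, z))
            charges.append(q)
            radii.append(r)
            labels.append(rec[2] if len(rec) > 2 else f"A{len(labels)}")
    if not positions:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return StructureModel(np.array(positions), np.array(charges), np.array(radii), labels)


def write_pqr(structure: StructureModel, path: str | Path) -> None:
    """Write a structure as whitespace-delimited PQR."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            x, y, z = structure.positions[i]
            fh.write(
                f"ATOM {i + 1:6d} {structure.labels[i]:<4s} MOL     1 "
                f"{x:12.6f} {y:12.6f} {z:12.6f} {structure.charges[i]:10.6f} "
                f"{structure.radii[i]:8.6f}\n"
            )


def read_pdb_coords(path: str | Path) -> np.ndarray:
    """Coordinates only from a PDB file (fixed columns 31-54)."""
    coords = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
    if not coords:
        raise FormatError(f"{path}: no coordinates")
    return np.array(coords)


# ---------------------------------------------------------------------------
# OpenDX scalar grids (APBS dialect)
# ---------------------------------------------------------------------------

def read_dx(path: str | Path) -> GridMap:
    """Read an OpenDX scalar grid (APBS dialect; z axis varies fastest)."""
    try:
        g = _DXGrid(str(path))
    except Exception as exc:  # gridData raises various types on bad input
        raise FormatError(f"{path}: not a readable OpenDX grid: {exc}") from exc
    deltas = np.atleast_1d(g.delta)
    if deltas.ndim == 2:
        deltas = np.diag(deltas)
    spec = GridSpec(
        tuple(float(v) for v in g.origin),
        tuple(float(v) for v in deltas),
        tuple(int(v) for v in g.grid.shape),
    )
    return GridMap(spec, np.asarray(g.grid, dtype=float))


def write_dx(grid: GridMap, path: str | Path) -> None:
    """Write a grid as OpenDX, z fastest, APBS header layout."""
    g = _DXGrid(
        grid.values,
        origin=np.asarray(grid.spec.origin, dtype=float),
        delta=np.asarray(grid.spec.spacing, dtype=float),
    )
    g.export(str(path), file_format="dx")


# ---------------------------------------------------------------------------
# Extended-XYZ trajectory dialect
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path) -> IonTrajectory:
    """Read the extended-XYZ dialect.

    Per frame: a particle-count line; a comment line containing
    ``box=Lx,Ly,Lz`` (Å); then ``label x y z`` lines with labels in
    {CAT, ANI, WAT, PRO}.  Species must be constant across frames.
    """
    frames: list[np.ndarray] = []
    species_ref: list[str] | None = None
    box: tuple[float, float, float] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: expected particle count at line {pos + 1}") from exc
        if pos + 1 >= len(lines):
            raise FormatError(f"{path}: truncated frame header")
        comment = lines[pos + 1]
        this_box = _parse_box(comment, path)
        if box is None:
            box = this_box
        elif not np.allclose(box, this_box):
            raise FormatError(f"{path}: box changed between frames")
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise FormatError(f"{path}: frame at line {pos + 1} truncated")
        labels, xyz = [], []
        for off, row in enumerate(body):
            rec = row.split()
            if len(rec) < 4 or rec[0] not in SPECIES_LABELS:
                raise FormatError(
                    f"{path}:{pos + 3 + off}: expected 'label x y z' with label "
                    f"in {SPECIES_LABELS}"
                )
            labels.append(rec[0])
            xyz.append([float(rec[1]), float(rec[2]), float(rec[3])])
        if species_ref is None:
            species_ref = labels
        elif labels != species_ref:
            raise FormatError(f"{path}: species changed across frames")
        frames.append(np.array(xyz))
        pos += 2 + n
    if not frames:
        raise FormatError(f"{path}: empty trajectory")
    assert box is not None and species_ref is not None
    return IonTrajectory(np.stack(frames), np.array(species_ref, dtype=object), box)


def _parse_box(comment: str, path: str | Path) -> tuple[float, float, float]:
    for token in comment.replace(";", " ").split():
        if token.startswith("box="):
            parts = token[4:].split(",")
            if len(parts) != 3:
                raise FormatError(f"{path}: malformed box token {token!r}")
            return tuple(float(p) for p in parts)  # type: ignore[return-value]
    raise FormatError(f"{path}: comment line lacks a box=Lx,Ly,Lz token")


def write_trajectory(traj: IonTrajectory, path: str | Path) -> None:
    """Write a trajectory in the extended-XYZ dialect."""
    bx, by, bz = traj.box
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.frames.shape[1]}\n")
            fh.write(f"box={bx:.6f},{by:.6f},{bz:.6f}\n")
            for lab, (x, y, z) in zip(traj.species, traj.frames[f]):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
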