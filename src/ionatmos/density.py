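"""Trajectory-derived concentration maps and grid geometry utilities.

Ion concentration maps are built by depositing an isotropic radial
triangular kernel for every ion sample on a regular grid; distances to
the fixed structure are evaluated per node against the closest atom
center, which defines the region geometry used by all profile
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import PER_A3_PER_MOLAR
from .io import GridMap, GridSpec, IonTrajectory, StructureModel

__all__ = [
    "KDEConfig",
    "AlignmentResult",
    "align_frames",
    "kde_concentration_map",
    "distance_map",
    "region_mask",
    "kabsch",
]


@dataclass(frozen=True)
class KDEConfig:
    """Kernel density estimation settings.

    ``bandwidth`` is the compact support radius of the radial triangular
    (cone) kernel K(d) ∝ max(0, 1 − d/h); each sample's weights are
    renormalized on-grid so it contributes a total count of exactly one.
    """

    spacing: float = 1.0  # Å grid mesh
    bandwidth: float = 2.0  # Å kernel support radius
    kernel: str = "triangular"

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.bandwidth <= 0:
            raise ValueError("spacing and bandwidth must be positive")
        if self.kernel != "triangular":
            raise ValueError("only the radial triangular kernel is implemented")


@dataclass
class AlignmentResult:
    """Per-frame rigid-body fit: proper rotations, translations, RMSDs."""

    rotations: np.ndarray  # (F, 3, 3), det = +1
    translations: np.ndarray  # (F, 3)
    rmsd: np.ndarray  # (F,) Å, after fitting


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R·x + t ≈ ref.

    Least-squares rigid superposition by SVD of the covariance matrix;
    a reflection in the SVD solution is corrected to a proper rotation
    (det = +1).
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def align_frames(
    traj: IonTrajectory,
    protein_ref: StructureModel,
    protein_coords_per_frame: np.ndarray,
) -> tuple[IonTrajectory, AlignmentResult]:
    """Superpose each frame's protein onto the reference and carry the ions along.

    ``protein_coords_per_frame`` must be (n_frames, n_atoms, 3) in
    one-to-one atom correspondence with the reference structure.  The
    per-frame rigid transform fitted on the protein is applied to every
    mobile particle of the frame.
    """
    coords = np.asarray(protein_coords_per_frame, dtype=float)
    if coords.ndim == 2:
        coords = np.broadcast_to(coords, (traj.n_frames,) + coords.shape)
    if coords.shape[0] != traj.n_frames:
        raise ValueError("need protein coordinates for every frame")
    if coords.shape[1] != protein_ref.n_atoms:
        raise ValueError(
            f"atom-count mismatch: frames have {coords.shape[1]} protein atoms, "
            f"reference has {protein_ref.n_atoms}"
        )
    ref = protein_ref.positions
    rots = np.empty((traj.n_frames, 3, 3))
    trans = np.empty((traj.n_frames, 3))
    rmsd = np.empty(traj.n_frames)
    new_frames = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, t = kabsch(coords[f], ref)
        rots[f] = rot
        trans[f] = t
        fitted = coords[f] @ rot.T + t
        rmsd[f] = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
        new_frames[f] = traj.frames[f] @ rot.T + t
    aligned = IonTrajectory(new_frames, traj.species.copy(), traj.box)
    return aligned, AlignmentResult(rots, trans, rmsd)


def kde_concentration_map(
    traj: IonTrajectory,
    species: str,
    cfg: KDEConfig,
    gridspec: GridSpec,
    on_outside: str = "drop",
) -> GridMap:
    """Concentration map (M) of one ion species by triangular-kernel KDE.

    Every retained sample deposits K(d) = max(0, 1 − d/h) on nodes
    within h, renormalized so the sample's total on-grid count is one;
    the per-frame mean count density (Å⁻³) is converted to molarity, so
    integrating the map over the grid recovers the mean number of
    retained particles per frame.

    Samples falling outside the grid are dropped with a warning
    (``on_outside="drop"``) or raise (``on_outside="error"``).
    """
    if on_outside not in ("drop", "error"):
        raise ValueError("on_outside must be 'drop' or 'error'")
    pts = traj.select(species).reshape(-1, 3)
    counts = np.zeros(gridspec.dims)
    n_frames = traj.n_frames
    if len(pts):
        origin = np.asarray(gridspec.origin)
        spacing = np.asarray(gridspec.spacing)
        dims = np.asarray(gridspec.dims)
        h = cfg.bandwidth
        # stencil of node offsets potentially within the kernel support
        reach = np.ceil(h / spacing).astype(int)
        offs = np.stack(
            np.meshgrid(*(np.arange(-r, r + 1) for r in reach), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        frac = (pts - origin) / spacing
        base = np.round(frac).astype(int)
        inside = np.all((frac >= 0) & (frac <= dims - 1), axis=1)
        if not inside.all():
            if on_outside == "error":
                raise ValueError(
                    f"{np.count_nonzero(~inside)} samples fall outside the grid"
                )
            warnings.warn(
                f"dropping {np.count_nonzero(~inside)} samples outside the grid",
                stacklevel=2,
            )
        for p, b in zip(frac[inside], base[inside]):
            idx = b + offs
            ok = np.all((idx >= 0) & (idx < dims), axis=1)
            idx = idx[ok]
            d = np.linalg.norm((idx - p) * spacing, axis=1)
            w = np.maximum(0.0, 1.0 - d / h)
            tot = w.sum()
            if tot <= 0.0:  # kernel narrower than the mesh: nearest node
                j = np.argmin(d)
                counts[tuple(idx[j])] += 1.0
                continue
            np.add.at(counts, tuple(idx.T), w / tot)
    density = counts / (n_frames * gridspec.voxel_volume)  # Å⁻³, per frame
    conc = density / PER_A3_PER_MOLAR
    return GridMap(gridspec, conc, units="M")


def distance_map(gridspec: GridSpec, structure: StructureModel) -> GridMap:
    """Distance (Å) from each node to the closest atom center."""
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    tree = cKDTree(structure.positions)
    d, _ = tree.query(gridspec.node_positions())
    return GridMap(gridspec, d.reshape(gridspec.dims), units="A")


def region_mask(
    distmap: GridMap, cutoff: float, max_distance: float = np.inf
) -> GridMap:
    """Binary mask of nodes within *cutoff* of the closest atom.

    ``max_distance`` is the boundary-exclusion limit: the analysis
    region never extends beyond it, and *cutoff* may not exceed it.
    """
    if distmap.units != "A":
        raise ValueError("expected a distance map (units 'A')")
    if cutoff > max_distance:
        raise ValueError("cutoff exceeds the boundary-exclusion distance")
    mask = (distmap.values <= cutoff).astype(float)
    return GridMap(distmap.spec, mask, units="mask")
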