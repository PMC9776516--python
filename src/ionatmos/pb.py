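"""Finite-difference Poisson–Boltzmann solver and Boltzmann inversion.

Solves the linear and nonlinear PB equations on a regular grid for a
fixed structure,

    ∇·(ε ∇ϕ) − κ̄² a(r) f(ϕ) = −4π lB₀ ρ_f,      f(ϕ) = ϕ or sinh ϕ,

with ϕ in kT/e, lengths in Å, fixed charge density ρ_f in e/Å³ and
lB₀ the vacuum Bjerrum length at the run temperature.  ε is the
relative dielectric (harmonic-mean averaged on cell faces), a(r) the
ion-accessibility mask (zero within atom radius + Stern layer) and
κ̄² = ε_s κ² the modified screening coefficient of a 1:1 salt.

The mobile-ion term uses sinh (1:1 salt) in the nonlinear form; the
linear form keeps the first Taylor term only.  Inverting a potential
map back to per-species concentrations with the full exponential is
exact for NLPB potentials and deliberately reproduces the known
inconsistency when applied to LPB potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .constants import PER_A3_PER_MOLAR, bjerrum_length, debye_kappa
from .io import GridMap, GridSpec, SpeciesSpec, StructureModel

__all__ = [
    "PBConfig",
    "CoefficientGrids",
    "ConvergenceError",
    "assign_coefficients",
    "solve_lpb",
    "solve_nlpb",
    "focus",
    "boltzmann_concentration",
]


class ConvergenceError(RuntimeError):
    """Solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float, iterations: int) -> None:
        super().__init__(f"{message} (residual {residual:.3e} after {iterations} iterations)")
        self.residual = residual
        self.iterations = iterations


@dataclass(frozen=True)
class PBConfig:
    """Poisson–Boltzmann run parameters (defaults: aqueous 1:1 salt)."""

    interior_dielectric: float = 4.0
    solvent_dielectric: float = 80.0
    temperature: float = 300.0  # K
    ionic_strength: float = 0.1  # M
    probe_radius: float = 1.4  # Å solvent probe for the molecular surface
    stern: float = 2.0  # Å ion-exclusion layer beyond the atom radius
    tol: float = 1e-6  # relative residual
    max_iter: int = 20000
    form: str = "nonlinear"  # "linear" | "nonlinear"
    sor_omega: float = 1.6  # over-relaxation for the linear solve
    nl_relax: float = 1.5  # relaxation for the nonlinear Newton-Gauss-Seidel

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.stern < 0:
            raise ValueError("Stern thickness must be non-negative")
        if self.form not in ("linear", "nonlinear"):
            raise ValueError("form must be 'linear' or 'nonlinear'")


@dataclass
class CoefficientGrids:
    """Discretized PB coefficients on a grid.

    ``eps_x/y/z`` hold face dielectrics between node i and i+1 along
    each axis; ``accessibility`` the {0,1} mobile-ion mask on nodes;
    ``charge`` the fixed charge per node in e (trilinear spreading).
    """

    spec: GridSpec
    eps_x: np.ndarray
    eps_y: np.ndarray
    eps_z: np.ndarray
    accessibility: np.ndarray
    charge: np.ndarray
    structure: StructureModel
    config: PBConfig


def _mark_within(spec: GridSpec, structure: StructureModel, extra: float) -> np.ndarray:
    """Boolean node grid: within (atom radius + extra) of any atom center."""
    out = np.zeros(spec.dims, dtype=bool)
    origin = np.asarray(spec.origin)
    spacing = np.asarray(spec.spacing)
    dims = np.asarray(spec.dims)
    axes = spec.axes()
    for pos, rad in zip(structure.positions, structure.radii):
        reach = rad + extra
        if reach <= 0:
            continue
        lo = np.maximum(np.ceil((pos - reach - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.floor((pos - origin + reach) / spacing).astype(int), dims - 1)
        if np.any(lo > hi):
            continue
        dx = axes[0][lo[0] : hi[0] + 1] - pos[0]
        dy = axes[1][lo[1] : hi[1] + 1] - pos[1]
        dz = axes[2][lo[2] : hi[2] + 1] - pos[2]
        d2 = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= reach**2
    return out


def assign_coefficients(
    structure: StructureModel, cfg: PBConfig, gridspec: GridSpec
) -> CoefficientGrids:
    """Dielectric, accessibility and source coefficients for a structure.

    The molecular interior is classified by a two-pass approximation of
    the probe-rolled surface: nodes within (atom radius + probe) of any
    atom are tentatively interior, then tentative-interior nodes within
    one probe radius of a definitely-exterior node are re-classified
    exterior (first-order re-entrant correction).  Face dielectrics are
    harmonic means of the adjacent node values.  Ion accessibility is
    zero within (atom radius + Stern) of any atom.  Atom charges spread
    to the eight surrounding nodes by trilinear weights.
    """
    from scipy import ndimage

    origin = np.asarray(gridspec.origin)
    spacing = np.asarray(gridspec.spacing)
    dims = np.asarray(gridspec.dims)
    top = origin + spacing * (dims - 1)
    pad = structure.radii + cfg.stern
    if np.any(structure.positions - pad[:, None] < origin) or np.any(
        structure.positions + pad[:, None] > top
    ):
        raise ValueError("grid does not enclose the structure plus its Stern layer")

    tentative = _mark_within(gridspec, structure, cfg.probe_radius)
    if cfg.probe_radius > 0 and tentative.any():
        # node distance to the nearest definitely-exterior node
        d_ext = ndimage.distance_transform_edt(tentative, sampling=spacing)
        interior = tentative & (d_ext > cfg.probe_radius)
    else:
        interior = tentative
    eps_node = np.where(interior, cfg.interior_dielectric, cfg.solvent_dielectric)

    def harm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return 2.0 * a * b / (a + b)

    eps_x = harm(eps_node[:-1, :, :], eps_node[1:, :, :])
    eps_y = harm(eps_node[:, :-1, :], eps_node[:, 1:, :])
    eps_z = harm(eps_node[:, :, :-1], eps_node[:, :, 1:])

    accessibility = (~_mark_within(gridspec, structure, cfg.stern)).astype(float)

    charge = np.zeros(gridspec.dims)
    frac = (structure.positions - origin) / spacing
    base = np.floor(frac).astype(int)
    base = np.clip(base, 0, dims - 2)
    t = frac - base
    for b, w, q in zip(base, t, structure.charges):
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = (
                        (w[0] if dx else 1 - w[0])
                        * (w[1] if dy else 1 - w[1])
                        * (w[2] if dz else 1 - w[2])
                    )
                    charge[b[0] + dx, b[1] + dy, b[2] + dz] += q * wgt
    return CoefficientGrids(
        gridspec, eps_x, eps_y, eps_z, accessibility, charge, structure, cfg
    )


def _dh_boundary(coeffs: CoefficientGrids) -> np.ndarray:
    """Dirichlet boundary: superposed per-charge Debye–Hückel monopoles."""
    cfg = coeffs.config
    spec = coeffs.spec
    lb = bjerrum_length(cfg.solvent_dielectric, cfg.temperature)
    kappa = debye_kappa(cfg.ionic_strength, cfg.solvent_dielectric, cfg.temperature)
    phi = np.zeros(spec.dims)
    face = np.zeros(spec.dims, dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = 0
        face[tuple(sl)] = True
        sl[axis] = -1
        face[tuple(sl)] = True
    nodes = spec.node_positions().reshape(spec.dims + (3,))[face]
    vals = np.zeros(len(nodes))
    st = coeffs.structure
    for pos, q, a in zip(st.positions, st.charges, st.radii):
        d = np.linalg.norm(nodes - pos, axis=1)
        d = np.maximum(d, max(a, 1e-6))
        vals += q * lb * np.exp(-kappa * (d - a)) / ((1 + kappa * a) * d)
    phi[face] = vals
    return phi


def _solver_arrays(coeffs: CoefficientGrids):
    cfg = coeffs.config
    spec = coeffs.spec
    hx, hy, hz = spec.spacing
    lb0 = bjerrum_length(1.0, cfg.temperature)
    kbar2 = 8 * np.pi * lb0 * cfg.ionic_strength * PER_A3_PER_MOLAR
    source = 4 * np.pi * lb0 * coeffs.charge / spec.voxel_volume
    # interior-node views (boundary handled as Dirichlet)
    i = (slice(1, -1),) * 3
    ex_lo = coeffs.eps_x[:-1, 1:-1, 1:-1] / hx**2
    ex_hi = coeffs.eps_x[1:, 1:-1, 1:-1] / hx**2
    ey_lo = coeffs.eps_y[1:-1, :-1, 1:-1] / hy**2
    ey_hi = coeffs.eps_y[1:-1, 1:, 1:-1] / hy**2
    ez_lo = coeffs.eps_z[1:-1, 1:-1, :-1] / hz**2
    ez_hi = coeffs.eps_z[1:-1, 1:-1, 1:] / hz**2
    diag = ex_lo + ex_hi + ey_lo + ey_hi + ez_lo + ez_hi
    screen = kbar2 * coeffs.accessibility[i]
    return source, i, (ex_lo, ex_hi, ey_lo, ey_hi, ez_lo, ez_hi), diag, screen


def _neighbor_sum(phi: np.ndarray, eps) -> np.ndarray:
    ex_lo, ex_hi, ey_lo, ey_hi, ez_lo, ez_hi = eps
    return (
        ex_lo * phi[:-2, 1:-1, 1:-1]
        + ex_hi * phi[2:, 1:-1, 1:-1]
        + ey_lo * phi[1:-1, :-2, 1:-1]
        + ey_hi * phi[1:-1, 2:, 1:-1]
        + ez_lo * phi[1:-1, 1:-1, :-2]
        + ez_hi * phi[1:-1, 1:-1, 2:]
    )


def _checkerboard(dims: tuple[int, int, int]) -> np.ndarray:
    ii, jj, kk = np.indices(tuple(d - 2 for d in dims))
    return (ii + jj + kk) % 2 == 0


def _solve(
    coeffs: CoefficientGrids,
    cfg: PBConfig,
    nonlinear: bool,
    boundary: np.ndarray | None,
) -> tuple[GridMap, dict]:
    source, i, eps, diag, screen = _solver_arrays(coeffs)
    phi = _dh_boundary(coeffs) if boundary is None else boundary.copy()
    phi[i] = 0.0
    red = _checkerboard(coeffs.spec.dims)
    src_i = source[i]
    scale = np.linalg.norm(src_i)
    if scale == 0:
        scale = max(np.abs(phi).max(), 1.0) * np.mean(diag)
    prev_res = np.inf
    grow = 0
    for it in range(1, cfg.max_iter + 1):
        for color in (red, ~red):
            nb = _neighbor_sum(phi, eps)
            if nonlinear:
                p = np.clip(phi[i], -60.0, 60.0)
                ch = np.cosh(p)
                sh = np.sinh(p)
                num = nb + src_i + screen * (p * ch - sh)
                den = diag + screen * ch
                new = num / den
                upd = phi[i]
                upd[color] += cfg.nl_relax * (new - phi[i])[color]
            else:
                new = (nb + src_i) / (diag + screen)
                upd = phi[i]
                upd[color] += cfg.sor_omega * (new - phi[i])[color]
            phi[i] = upd
        nb = _neighbor_sum(phi, eps)
        if nonlinear:
            p = np.clip(phi[i], -60.0, 60.0)
            res = src_i + nb - diag * phi[i] - screen * np.sinh(p)
        else:
            res = src_i + nb - (diag + screen) * phi[i]
        resnorm = np.linalg.norm(res) / scale
        if resnorm <= cfg.tol:
            return (
                GridMap(coeffs.spec, phi, units="kT/e"),
                {"iterations": it, "residual": float(resnorm)},
            )
        if resnorm > prev_res * (1 + 1e-12):
            grow += 1
            if grow >= 25:
                raise ConvergenceError("solver diverging", float(resnorm), it)
        else:
            grow = 0
        prev_res = resnorm
    raise ConvergenceError("solver did not converge", float(resnorm), cfg.max_iter)


def solve_lpb(
    coeffs: CoefficientGrids,
    cfg: PBConfig | None = None,
    boundary: np.ndarray | None = None,
) -> tuple[GridMap, dict]:
    """Linear PB by red-black successive over-relaxation.

    Returns the potential (kT/e) and a report with iteration count and
    final relative residual.  The Dirichlet boundary defaults to the
    superposition of per-charge Debye–Hückel monopoles.
    """
    return _solve(coeffs, cfg or coeffs.config, nonlinear=False, boundary=boundary)


def solve_nlpb(
    coeffs: CoefficientGrids,
    cfg: PBConfig | None = None,
    boundary: np.ndarray | None = None,
) -> tuple[GridMap, dict]:
    """Nonlinear (sinh, 1:1 salt) PB by relaxed Newton–Gauss–Seidel.

    The per-node Newton linearization of the sinh term keeps the local
    update stable even at strong potentials; the relaxation factor is
    halved (twice, at most) and the solve restarted if the residual
    diverges.
    """
    cfg = cfg or coeffs.config
    relax = cfg.nl_relax
    for attempt in range(3):
        try:
            return _solve(
                coeffs,
                _replace(cfg, nl_relax=relax),
                nonlinear=True,
                boundary=boundary,
            )
        except ConvergenceError as err:
            if "diverging" not in str(err) or attempt == 2:
                raise
            relax /= 2.0
    raise AssertionError("unreachable")


def focus(
    coarse: GridMap,
    fine_spec: GridSpec,
    coeffs_fine: CoefficientGrids,
    cfg: PBConfig | None = None,
) -> tuple[GridMap, dict]:
    """Two-level focusing: fine-grid boundary interpolated from a coarse solve.

    The fine grid must lie strictly inside the coarse one; boundary
    values are trilinearly interpolated from the coarse potential and
    the fine problem is solved with them as Dirichlet conditions.
    """
    cfg = cfg or coeffs_fine.config
    c_origin = np.asarray(coarse.spec.origin)
    c_top = c_origin + np.asarray(coarse.spec.spacing) * (
        np.asarray(coarse.spec.dims) - 1
    )
    f_origin = np.asarray(fine_spec.origin)
    f_top = f_origin + np.asarray(fine_spec.spacing) * (np.asarray(fine_spec.dims) - 1)
    if np.any(f_origin < c_origin - 1e-9) or np.any(f_top > c_top + 1e-9):
        raise ValueError("fine grid must lie inside the coarse grid")
    interp = RegularGridInterpolator(coarse.spec.axes(), coarse.values)
    boundary = np.zeros(fine_spec.dims)
    face = np.zeros(fine_spec.dims, dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = 0
        face[tuple(sl)] = True
        sl[axis] = -1
        face[tuple(sl)] = True
    nodes = fine_spec.node_positions().reshape(fine_spec.dims + (3,))[face]
    boundary[face] = interp(np.clip(nodes, c_origin, c_top))
    return _solve(coeffs_fine, cfg, nonlinear=(cfg.form == "nonlinear"), boundary=boundary)


def boltzmann_concentration(
    potential: GridMap, species: SpeciesSpec, accessibility: GridMap | np.ndarray
) -> GridMap:
    """Invert a potential map to a species concentration map (M).

    ``c_i(r) = c_i^bulk · exp(−z_i ϕ(r))`` with ϕ in kT/e, and zero
    wherever the accessibility mask is zero (no mobile ions below the
    Stern layer).  Applied to an NLPB potential this is the model's own
    mobile-ion density; applied to an LPB potential it knowingly
    reintroduces the exponential the linearization discarded.
    """
    if potential.units != "kT/e":
        raise ValueError(f"expected a potential in kT/e, got units {potential.units!r}")
    acc = accessibility.values if isinstance(accessibility, GridMap) else accessibility
    if acc.shape != potential.values.shape:
        raise ValueError("accessibility grid does not match the potential grid")
    arg = np.clip(-species.valence * potential.values, -500.0, 500.0)
    conc = species.bulk_concentration * np.exp(arg) * (acc > 0)
    return GridMap(potential.spec, conc, units="M")
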