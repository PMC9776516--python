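"""Synthetic systems with known statistical structure.

Generates the inputs every downstream stage needs without external
data: charged-sphere oracle structures, compact random bead "proteins"
with an irregular charge pattern, the closed-form Debye–Hückel
potential of a charged sphere, and Metropolis Monte Carlo sampling of
mobile ions in the screened field of a fixed structure.

The sampler emulates an equilibrated ionic atmosphere: monovalent
cations and anions interacting through screened-Coulomb (Yukawa) pair
potentials — carrying the Debye–Hückel excluded-sphere contact factor —
with the fixed bead charges and (optionally) with each other, plus
hard-sphere exclusion, inside a hard-walled rectangular box.  An ideal uniform water background is co-generated per frame so
molality-based statistics have a denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import bjerrum_length, debye_kappa
from .io import GridMap, GridSpec, IonTrajectory, SpeciesSpec, StructureModel

__all__ = [
    "BeadProteinSpec",
    "MCSamplerConfig",
    "PlacementError",
    "GeometryError",
    "make_charged_sphere",
    "make_bead_protein",
    "analytic_dh_potential",
    "sample_ion_configurations",
    "MCSampler",
]


class PlacementError(RuntimeError):
    """Bead placement failed after the allowed number of attempts."""


class GeometryError(ValueError):
    """Box geometry violates a sampler precondition."""


def make_charged_sphere(radius: float, charge: float) -> StructureModel:
    """A single spherical 'atom' at the origin — the analytic oracle geometry."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return StructureModel(
        positions=np.zeros((1, 3)),
        charges=np.array([charge]),
        radii=np.array([radius]),
        labels=["SPH"],
    )


@dataclass(frozen=True)
class BeadProteinSpec:
    """A compact random cluster of charged hard beads.

    Stands in for a protein with multiple positive and negative surface
    patches.  ``charge_pattern`` is either "uniform" (total charge split
    evenly) or "patches" (zero-mean normal draws of scale
    ``patch_charge_scale`` shifted so the total matches exactly).
    """

    n_beads: int
    total_charge: float
    bead_radius: float = 2.0
    cluster_radius: float = 8.0
    min_separation: float = 2.0
    charge_pattern: str = "uniform"
    patch_charge_scale: float = 1.0
    seed: int = 0
    max_attempts: int = 20000


def make_bead_protein(spec: BeadProteinSpec) -> StructureModel:
    """Place beads uniformly in a sphere, rejecting overlapping pairs."""
    if spec.n_beads < 1:
        raise ValueError("need at least one bead")
    rng = np.random.default_rng(spec.seed)
    if spec.n_beads == 1:
        return make_charged_sphere(spec.bead_radius, spec.total_charge)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < spec.n_beads:
        if attempts >= spec.max_attempts:
            raise PlacementError(
                f"could not place {spec.n_beads} beads with separation "
                f"{spec.min_separation} Å in radius {spec.cluster_radius} Å "
                f"after {attempts} attempts"
            )
        attempts += 1
        # uniform point in a sphere of cluster_radius
        p = rng.normal(size=3)
        p *= spec.cluster_radius * rng.random() ** (1 / 3) / np.linalg.norm(p)
        if positions and np.min(
            np.linalg.norm(np.asarray(positions) - p, axis=1)
        ) < spec.min_separation:
            continue
        positions.append(p)
    pos = np.asarray(positions)
    if spec.charge_pattern == "uniform":
        charges = np.full(spec.n_beads, spec.total_charge / spec.n_beads)
    elif spec.charge_pattern == "patches":
        charges = rng.normal(scale=spec.patch_charge_scale, size=spec.n_beads)
        charges += (spec.total_charge - charges.sum()) / spec.n_beads
    else:
        raise ValueError(f"unknown charge_pattern {spec.charge_pattern!r}")
    labels = [f"B{i}" for i in range(spec.n_beads)]
    return StructureModel(pos, charges, np.full(spec.n_beads, spec.bead_radius), labels)


def analytic_dh_potential(
    sphere: StructureModel,
    species: SpeciesSpec,
    temperature: float,
    eps_s: float,
    gridspec: GridSpec,
) -> GridMap:
    """Closed-form Debye–Hückel potential of a charged sphere, in kT/e.

    For a sphere of charge q and ion-exclusion radius a in a 1:1 salt,

        ϕ(r) = q · lB · exp(−κ(r−a)) / ((1+κa) · r)      for r ≥ a,

    with lB the Bjerrum length of the solvent and κ the inverse Debye
    length.  Nodes inside r < a carry the r = a surface value.
    """
    if sphere.n_atoms != 1:
        raise ValueError("analytic potential is defined for a single sphere")
    q = sphere.total_charge
    a = float(sphere.radii[0])
    lb = bjerrum_length(eps_s, temperature)
    kappa = debye_kappa(species.bulk_concentration, eps_s, temperature)
    nodes = gridspec.node_positions()
    r = np.linalg.norm(nodes - sphere.positions[0], axis=1)
    r_eff = np.maximum(r, a)
    phi = q * lb * np.exp(-kappa * (r_eff - a)) / ((1 + kappa * a) * r_eff)
    return GridMap(gridspec, phi.reshape(gridspec.dims), units="kT/e")


@dataclass(frozen=True)
class MCSamplerConfig:
    """Metropolis sampling parameters for the mobile-ion generator."""

    n_cations: int
    n_anions: int
    ionic_strength: float = 0.1  # M; sets the Yukawa screening length
    ion_radius: float = 1.5  # Å hard-sphere radius of mobile ions
    temperature: float = 300.0  # K
    eps_s: float = 80.0
    n_sweeps: int = 2000
    equilibration_sweeps: int | None = None  # None -> first 30% discarded
    stride: int = 10  # record every this many production sweeps
    step_size: float = 4.0  # Å max displacement per trial move
    teleport_prob: float = 0.1  # fraction of box-uniform reinsertion moves
    n_water: int = 0  # ideal uniform water sites per frame
    ion_ion: bool = True  # include ion-ion Yukawa interactions
    seed: int = 0

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.eps_s, self.temperature)


class MCSampler:
    """Metropolis Monte Carlo of mobile ions around a fixed structure.

    Energies are in kT.  Pair interactions are screened Coulomb with the
    excluded-sphere correction of Debye–Hückel theory,

        u(r) = lB z_i z_j exp(κ a) / (1 + κ a) · exp(-κ r) / r,

    where a is the pair contact radius (bead radius + ion radius for
    bead-ion pairs, two ion radii for ion-ion pairs): outside contact
    this is the exact linearized mean-field potential around a charged
    hard sphere, so the implicit-screening field and the explicit
    exclusion are mutually consistent.  Overlaps inside the contact
    radius (hard spheres) are rejected.
    The box has hard walls (no periodicity): the downstream analyses all
    operate on a nonperiodic rectangular grid, so a hard-walled box
    avoids a periodicity mismatch by construction.

    The total energy is tracked incrementally across accepted moves;
    :meth:`total_energy` recomputes it from scratch for verification.
    """

    def __init__(
        self,
        structure: StructureModel,
        config: MCSamplerConfig,
        box: tuple[float, float, float],
    ) -> None:
        self.structure = structure
        self.cfg = config
        self.box = np.asarray(box, dtype=float)
        if np.any(self.box <= 0):
            raise GeometryError("box lengths must be positive")
        margin = 2.0 / config.kappa
        lo = structure.positions.min(axis=0) - structure.radii.max()
        hi = structure.positions.max(axis=0) + structure.radii.max()
        center = self.box / 2.0
        # structure is placed relative to the box center
        if np.any(center + lo < margin - 1e-9) or np.any(
            self.box - (center + hi) < margin - 1e-9
        ):
            raise GeometryError(
                "box must enclose the structure with a margin of at least "
                f"two screening lengths ({margin:.1f} Å)"
            )
        self.lb = bjerrum_length(config.eps_s, config.temperature)
        self.kappa = config.kappa
        self.rng = np.random.default_rng(config.seed)
        n = config.n_cations + config.n_anions
        self.charges = np.concatenate(
            [np.ones(config.n_cations), -np.ones(config.n_anions)]
        )
        self.species = np.array(
            ["CAT"] * config.n_cations + ["ANI"] * config.n_anions, dtype=object
        )
        # bead coordinates in box frame (structure centred in the box)
        self.bead_pos = structure.positions + center
        self.bead_q = structure.charges
        self.bead_r = structure.radii
        # DH excluded-sphere prefactors at the pair contact radii
        a_bead = self.bead_r + config.ion_radius
        self._bead_pref = np.exp(self.kappa * a_bead) / (1 + self.kappa * a_bead)
        a_ion = 2 * config.ion_radius
        self._ion_pref = np.exp(self.kappa * a_ion) / (1 + self.kappa * a_ion)
        self.pos = self._random_insertions(n)
        self.energy = self.total_energy()
        self._moves = 0

    # -- energetics ---------------------------------------------------------

    def _particle_energy(self, i: int, p: np.ndarray) -> float:
        """Energy of ion i at position p; +inf on hard overlap."""
        d_bead = np.linalg.norm(self.bead_pos - p, axis=1)
        if np.any(d_bead < self.bead_r + self.cfg.ion_radius):
            return np.inf
        qq = self.bead_q * self.charges[i]
        e = float(
            np.sum(self.lb * qq * self._bead_pref * np.exp(-self.kappa * d_bead) / d_bead)
        )
        if self.cfg.ion_ion and len(self.pos) > 1:
            others = np.arange(len(self.pos)) != i
            d = np.linalg.norm(self.pos[others] - p, axis=1)
            if np.any(d < 2 * self.cfg.ion_radius):
                return np.inf
            qq2 = self.charges[others] * self.charges[i]
            e += float(
                np.sum(self.lb * qq2 * self._ion_pref * np.exp(-self.kappa * d) / d)
            )
        return e

    def _bead_energy(self, i: int) -> float:
        d = np.linalg.norm(self.bead_pos - self.pos[i], axis=1)
        qq = self.bead_q * self.charges[i]
        return float(
            np.sum(self.lb * qq * self._bead_pref * np.exp(-self.kappa * d) / d)
        )

    def total_energy(self) -> float:
        """Recompute the configuration energy from scratch (kT)."""
        e = 0.0
        for i in range(len(self.pos)):
            e += self._particle_energy(i, self.pos[i])
        if self.cfg.ion_ion:
            # particle sums double-count ion-ion pairs but not ion-bead terms
            e_bead = sum(self._bead_energy(i) for i in range(len(self.pos)))
            e = e_bead + (e - e_bead) / 2.0
        return e

    # -- moves --------------------------------------------------------------

    def _random_insertions(self, n: int) -> np.ndarray:
        out = np.empty((n, 3))
        placed = 0
        tries = 0
        while placed < n:
            if tries > 200000:
                raise PlacementError("could not insert initial ion configuration")
            tries += 1
            p = self.rng.random(3) * self.box
            d_bead = np.linalg.norm(self.bead_pos - p, axis=1)
            if np.any(d_bead < self.bead_r + self.cfg.ion_radius):
                continue
            if placed and np.any(
                np.linalg.norm(out[:placed] - p, axis=1) < 2 * self.cfg.ion_radius
            ):
                continue
            out[placed] = p
            placed += 1
        return out

    def sweep(self) -> None:
        """One sweep: one trial move per mobile ion."""
        n = len(self.pos)
        for _ in range(n):
            i = int(self.rng.integers(n))
            old = self.pos[i].copy()
            if self.rng.random() < self.cfg.teleport_prob:
                new = self.rng.random(3) * self.box
            else:
                new = old + (self.rng.random(3) - 0.5) * 2 * self.cfg.step_size
                if np.any(new < 0) or np.any(new >= self.box):
                    self._moves += 1
                    continue  # hard wall: reject
            e_old = self._particle_energy(i, old)
            e_new = self._particle_energy(i, new)
            if e_new <= e_old or self.rng.random() < np.exp(-(e_new - e_old)):
                self.pos[i] = new
                self.energy += e_new - e_old
            self._moves += 1

    # -- trajectory generation ---------------------------------------------

    def run(self) -> IonTrajectory:
        cfg = self.cfg
        n_eq = (
            cfg.equilibration_sweeps
            if cfg.equilibration_sweeps is not None
            else int(round(0.3 * cfg.n_sweeps))
        )
        frames = []
        for s in range(cfg.n_sweeps):
            self.sweep()
            if s >= n_eq and (s - n_eq) % cfg.stride == 0:
                frame = self.pos.copy()
                if cfg.n_water:
                    frame = np.vstack([frame, self._water_frame()])
                frames.append(frame)
        if not frames:
            raise ValueError("no frames recorded; increase n_sweeps or lower stride")
        species = self.species
        if cfg.n_water:
            species = np.concatenate(
                [species, np.array(["WAT"] * cfg.n_water, dtype=object)]
            )
        return IonTrajectory(np.stack(frames), species, tuple(self.box))

    def _water_frame(self) -> np.ndarray:
        """Ideal water: uniform in box, outside bead hard cores."""
        out = np.empty((self.cfg.n_water, 3))
        placed = 0
        while placed < self.cfg.n_water:
            m = self.cfg.n_water - placed
            p = self.rng.random((m, 3)) * self.box
            d = np.linalg.norm(p[:, None, :] - self.bead_pos[None, :, :], axis=2)
            ok = np.all(d >= self.bead_r[None, :], axis=1)
            k = int(ok.sum())
            out[placed : placed + k] = p[ok]
            placed += k
        return out


def sample_ion_configurations(
    structure: StructureModel,
    config: MCSamplerConfig,
    box: tuple[float, float, float],
) -> IonTrajectory:
    """Equilibrium ion configurations around *structure* in a hard-walled box.

    The structure is centred in the box.  Returned frames are recorded
    every ``config.stride`` sweeps after equilibration; water sites (if
    requested) are redrawn uniformly each frame.
    """
    return MCSampler(structure, config, box).run()
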