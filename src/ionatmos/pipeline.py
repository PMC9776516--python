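"""End-to-end runs: configuration, staging, provenance.

A run takes (or synthesizes) a structure and an ion trajectory,
builds trajectory- and PB-derived concentration maps, and writes the
profile statistics, RDF and summary tables into a run directory,
together with a resolved-configuration echo and a log carrying the
package version, the seed and input checksums — enough to re-execute
the run byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import LITRE_PER_A3
from .density import KDEConfig, distance_map, kde_concentration_map, region_mask
from .io import (
    GridSpec,
    SpeciesSpec,
    read_pqr,
    read_trajectory,
    write_dx,
    write_pqr,
    write_trajectory,
)
from .pb import PBConfig, assign_coefficients, boltzmann_concentration, solve_lpb, solve_nlpb
from .stats import (
    dispersion_summary,
    ion_addition,
    ionic_strength_profile,
    iso_concentration_mask,
    molality_rdf,
    total_charge_profile,
)
from .synth import BeadProteinSpec, MCSamplerConfig, make_bead_protein, sample_ion_configurations

__all__ = ["RunConfig", "ConfigError", "run", "load_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run.

    Defaults mirror the standard analysis conditions: 1 Å mesh, 2 Å
    kernel bandwidth, ionic strength 0.1 M, 300 K, dielectrics 4/80,
    1.4 Å probe, 2.0 Å Stern layer, 15 Å boundary-exclusion distance
    and a 0.5–5.0 Å bound-ion cutoff ladder.
    """

    structure: str | None = None  # PQR path; None -> synthesize
    trajectory: str | None = None  # extended-XYZ path; None -> synthesize
    stages: list[str] = field(
        default_factory=lambda: ["synth", "kde", "pb", "profiles", "rdf", "addions",
                                 "dispersion", "isomask"]
    )
    seed: int = 0
    # synthesis
    n_beads: int = 8
    total_charge: float = 4.0
    bead_radius: float = 2.0
    cluster_radius: float = 6.0
    box: float = 60.0
    n_water: int = 2000
    n_sweeps: int = 1500
    stride: int = 10
    # shared physics / grids
    spacing: float = 1.0
    bandwidth: float = 2.0
    ionic_strength: float = 0.1
    temperature: float = 300.0
    interior_dielectric: float = 4.0
    solvent_dielectric: float = 80.0
    probe_radius: float = 1.4
    stern: float = 2.0
    max_distance: float = 15.0
    pb_form: str = "nonlinear"
    pb_tol: float = 1e-6
    grid_extent: float | None = None  # Å edge; None -> box size
    cutoffs: list[float] = field(
        default_factory=lambda: [round(0.5 * k, 1) for k in range(1, 11)]
    )
    profile_cutoffs: list[float] = field(
        default_factory=lambda: [float(k) for k in range(2, 16)]
    )
    iso_levels: list[float] = field(default_factory=lambda: [0.2, 0.4])


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages into *outdir*; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"ionatmos {__version__}", f"seed {config.seed}"]
    summary: dict = {"seed": config.seed}
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    stage = "setup"
    try:
        box = (config.box,) * 3
        center = np.array(box) / 2.0

        # --- structure ---------------------------------------------------
        if config.structure is not None:
            stage = "read-structure"
            structure = read_pqr(config.structure)
            log.append(f"structure {config.structure} sha256 {_sha256(Path(config.structure))}")
        else:
            stage = "synth"
            structure = make_bead_protein(
                BeadProteinSpec(
                    n_beads=config.n_beads,
                    total_charge=config.total_charge,
                    bead_radius=config.bead_radius,
                    cluster_radius=config.cluster_radius,
                    charge_pattern="uniform" if config.n_beads == 1 else "patches",
                    seed=config.seed,
                )
            )
            write_pqr(structure, out / "structure.pqr")
        summary["protein_charge"] = structure.total_charge

        # solvent volume: box minus bead volumes (overlaps ignored)
        v_solvent_A3 = float(np.prod(box)) - float(
            np.sum(4.0 / 3.0 * np.pi * structure.radii**3)
        )
        addition = ion_addition(
            structure.total_charge, config.ionic_strength, v_solvent_A3 * LITRE_PER_A3
        )
        summary["ion_addition"] = {
            "n_plus": addition.n_plus,
            "n_minus": addition.n_minus,
            "n_plus_int": addition.n_plus_int,
            "n_minus_int": addition.n_minus_int,
            "excess_plus": addition.excess_plus,
            "excess_minus": addition.excess_minus,
        }

        # --- trajectory ---------------------------------------------------
        if config.trajectory is not None:
            stage = "read-trajectory"
            traj = read_trajectory(config.trajectory)
            log.append(f"trajectory {config.trajectory} sha256 {_sha256(Path(config.trajectory))}")
            protein_coords = structure.positions
        elif "synth" in config.stages or "kde" in config.stages or "rdf" in config.stages:
            stage = "synth"
            traj = sample_ion_configurations(
                structure,
                MCSamplerConfig(
                    n_cations=addition.n_plus_int,
                    n_anions=addition.n_minus_int,
                    ionic_strength=config.ionic_strength,
                    temperature=config.temperature,
                    eps_s=config.solvent_dielectric,
                    n_sweeps=config.n_sweeps,
                    stride=config.stride,
                    n_water=config.n_water,
                    seed=config.seed,
                ),
                box,
            )
            write_trajectory(traj, out / "trajectory.xyz")
            protein_coords = structure.positions + center
        else:
            traj = None
            protein_coords = structure.positions

        # --- grids --------------------------------------------------------
        extent = config.grid_extent or config.box
        if traj is not None and config.trajectory is None:
            grid_center = center  # synthesized system: structure sits at box center
        else:
            grid_center = protein_coords.mean(axis=0)
        gridspec = GridSpec.cube(grid_center, extent - config.spacing, config.spacing)
        shifted = structure.__class__(
            protein_coords, structure.charges, structure.radii, list(structure.labels)
        )
        dmap = distance_map(gridspec, shifted)
        write_dx(dmap, out / "distance.dx")

        species = {
            "CAT": SpeciesSpec(1, config.ionic_strength),
            "ANI": SpeciesSpec(-1, config.ionic_strength),
        }
        maps: dict[str, dict] = {}

        if "kde" in config.stages and traj is not None:
            stage = "kde"
            kcfg = KDEConfig(spacing=config.spacing, bandwidth=config.bandwidth)
            maps["md"] = {}
            for lab in ("CAT", "ANI"):
                m = kde_concentration_map(traj, lab, kcfg, gridspec)
                maps["md"][lab] = m
                write_dx(m, out / f"conc_md_{lab.lower()}.dx")

        if "pb" in config.stages:
            stage = "pb"
            pbcfg = PBConfig(
                interior_dielectric=config.interior_dielectric,
                solvent_dielectric=config.solvent_dielectric,
                temperature=config.temperature,
                ionic_strength=config.ionic_strength,
                probe_radius=config.probe_radius,
                stern=config.stern,
                tol=config.pb_tol,
                form=config.pb_form,
            )
            coeffs = assign_coefficients(shifted, pbcfg, gridspec)
            solver = solve_nlpb if config.pb_form == "nonlinear" else solve_lpb
            pot, rep = solver(coeffs)
            log.append(
                f"pb {config.pb_form} iterations {rep['iterations']} "
                f"residual {rep['residual']:.3e}"
            )
            write_dx(pot, out / "potential.dx")
            maps["pb"] = {}
            for lab in ("CAT", "ANI"):
                m = boltzmann_concentration(pot, species[lab], coeffs.accessibility)
                maps["pb"][lab] = m
                write_dx(m, out / f"conc_pb_{lab.lower()}.dx")

        if "profiles" in config.stages:
            stage = "profiles"
            for route, pair in maps.items():
                prof = total_charge_profile(
                    structure.total_charge,
                    pair["CAT"],
                    pair["ANI"],
                    dmap,
                    config.profile_cutoffs,
                    config.ionic_strength,
                    config.max_distance,
                )
                prof.to_csv(out / f"profile_charge_{route}.tsv", sep="\t", index=False)
                isp = ionic_strength_profile(
                    pair["CAT"], pair["ANI"], dmap, config.profile_cutoffs,
                    config.max_distance,
                )
                isp.to_csv(out / f"profile_ionic_strength_{route}.tsv", sep="\t", index=False)
                summary[f"profile_{route}"] = prof.to_dict(orient="list")

        if "rdf" in config.stages and traj is not None:
            stage = "rdf"
            for lab in ("CAT", "ANI"):
                curve = molality_rdf(traj, protein_coords, lab, r_max=config.max_distance)
                curve.as_frame().to_csv(
                    out / f"rdf_{lab.lower()}.tsv", sep="\t", index=False
                )
                summary[f"rdf_bulk_molality_{lab.lower()}"] = curve.bulk_molality

        if "dispersion" in config.stages and maps:
            stage = "dispersion"
            disp = {}
            for route, pair in maps.items():
                for lab, m in pair.items():
                    s = dispersion_summary(m, dmap, config.max_distance)
                    disp[f"{route}_{lab.lower()}"] = {
                        "median": s.median, "q1": s.q1, "q3": s.q3,
                        "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
                        "n_outliers": int(len(s.outliers)),
                        "zero_fraction": s.zero_fraction,
                    }
            summary["dispersion"] = disp

        if "isomask" in config.stages and maps:
            stage = "isomask"
            route = "pb" if "pb" in maps else "md"
            for lab, m in maps[route].items():
                for level in config.iso_levels:
                    mask = iso_concentration_mask(m, level)
                    write_dx(
                        mask,
                        out / f"isomask_{route}_{lab.lower()}_{int(level * 1000)}mM.dx",
                    )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
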