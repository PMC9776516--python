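"""Scalar and profile statistics of the ion atmosphere.

Everything downstream of the maps: region ion counts, ion excess,
the neutrality + ionic-strength ion-addition protocol, bound-ion
counts from trajectories, total-charge and ionic-strength profiles
versus cutoff distance, the molality-based radial distribution
function, dispersion (boxplot) summaries, node scatter tables and
iso-concentration masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import LITRE_PER_A3, M_WATER, N_A
from .io import GridMap, IonTrajectory

__all__ = [
    "IonAdditionProblem",
    "RDFCurve",
    "DispersionSummary",
    "InfeasibleError",
    "region_ion_count",
    "region_volume",
    "ion_excess",
    "ion_addition",
    "bound_ion_count_md",
    "total_charge_profile",
    "ionic_strength_profile",
    "molality_rdf",
    "dispersion_summary",
    "scatter_table",
    "iso_concentration_mask",
]

#: Named cutoff presets bracketing the first RDF peaks (Å).
RDF_PEAK_CUTOFFS = {"first_peak": 3.5, "second_peak": 5.0}


class InfeasibleError(ValueError):
    """The requested (Z, I, V) admits no non-negative ion counts."""


def _check_commensurate(a: GridMap, b: GridMap) -> None:
    if a.spec != b.spec:
        raise ValueError("grids are not commensurate")


def region_ion_count(conc: GridMap, mask: GridMap) -> float:
    """Number of ions in the masked region: N = N_A ∫ c dr.

    Each node represents one voxel; concentrations in M are converted
    through 1 Å³ = 1e-27 L.
    """
    _check_commensurate(conc, mask)
    if conc.units != "M":
        raise ValueError("expected a concentration map in M")
    return float(
        N_A * np.sum(conc.values * mask.values) * conc.voxel_volume * LITRE_PER_A3
    )


def region_volume(mask: GridMap) -> float:
    """Masked volume in Å³ (node-as-voxel convention)."""
    return float(mask.values.sum() * mask.voxel_volume)


def ion_excess(conc: GridMap, mask: GridMap, bulk: float) -> float:
    """Ions in the region minus what an equal bulk volume would hold."""
    v_litre = region_volume(mask) * LITRE_PER_A3
    return region_ion_count(conc, mask) - N_A * bulk * v_litre


@dataclass(frozen=True)
class IonAdditionProblem:
    """Solution of the neutrality + ionic-strength ion-addition conditions.

    For a protein of average charge Z in solvent volume V at bulk ionic
    strength I (1:1 salt), the pre-rounding counts solve

        N₊ + N₋ = 2 I N_A V      and      Z + N₊ − N₋ = 0,

    giving N± = I N_A V ∓ Z/2 and whole-box excesses ΔN± = ∓Z/2.
    Integer counts round half away from zero.
    """

    protein_charge: float  # Z, e
    ionic_strength: float  # I, M
    solvent_volume: float  # V, L
    n_plus: float
    n_minus: float
    n_plus_int: int
    n_minus_int: int
    excess_plus: float
    excess_minus: float


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def ion_addition(Z: float, I: float, V: float) -> IonAdditionProblem:
    """Ion counts enforcing charge neutrality and bulk ionic strength.

    Parameters are the average protein charge Z (e), the bulk ionic
    strength I (M) and the solvent volume V (L).
    """
    if I <= 0 or V <= 0:
        raise ValueError("ionic strength and volume must be positive")
    n_bulk = I * N_A * V
    n_plus = n_bulk - Z / 2.0
    n_minus = n_bulk + Z / 2.0
    if n_plus < 0 or n_minus < 0:
        raise InfeasibleError(
            f"|Z| = {abs(Z)} exceeds the available 2·I·N_A·V = {2 * n_bulk}"
        )
    return IonAdditionProblem(
        protein_charge=Z,
        ionic_strength=I,
        solvent_volume=V,
        n_plus=n_plus,
        n_minus=n_minus,
        n_plus_int=_round_half_away(n_plus),
        n_minus_int=_round_half_away(n_minus),
        excess_plus=n_plus - n_bulk,
        excess_minus=n_minus - n_bulk,
    )


def _protein_trees(
    protein_coords_per_frame: np.ndarray, n_frames: int
) -> list[cKDTree]:
    coords = np.asarray(protein_coords_per_frame, dtype=float)
    if coords.ndim == 2:
        tree = cKDTree(coords)
        return [tree] * n_frames
    if coords.shape[0] != n_frames:
        raise ValueError("need protein coordinates for every frame")
    return [cKDTree(c) for c in coords]


def bound_ion_count_md(
    traj: IonTrajectory,
    protein_coords_per_frame: np.ndarray,
    species: str,
    cutoff: float,
) -> float:
    """Mean per-frame count of ions within *cutoff* of the closest atom."""
    trees = _protein_trees(protein_coords_per_frame, traj.n_frames)
    pts = traj.select(species)
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if pts.shape[1] == 0:
            counts[f] = 0.0
            continue
        d, _ = trees[f].query(pts[f])
        counts[f] = np.count_nonzero(d <= cutoff)
    return float(counts.mean())


def total_charge_profile(
    Z: float,
    conc_plus: GridMap,
    conc_minus: GridMap,
    distmap: GridMap,
    cutoffs,
    bulk: float,
    max_distance: float = np.inf,
) -> pd.DataFrame:
    """Total charge and per-species excess versus cutoff distance.

    The total charge at cutoff d is the fixed charge Z plus the
    (signed) mobile ions within d of the closest atom; companion
    columns carry the ion excesses relative to *bulk*.
    """
    from .density import region_mask

    _check_commensurate(conc_plus, conc_minus)
    _check_commensurate(conc_plus, distmap)
    rows = []
    for d in cutoffs:
        mask = region_mask(distmap, d, max_distance)
        np_ = region_ion_count(conc_plus, mask)
        nm = region_ion_count(conc_minus, mask)
        rows.append(
            {
                "cutoff": float(d),
                "n_plus": np_,
                "n_minus": nm,
                "total_charge": Z + np_ - nm,
                "excess_plus": ion_excess(conc_plus, mask, bulk),
                "excess_minus": ion_excess(conc_minus, mask, bulk),
            }
        )
    return pd.DataFrame(rows)


def ionic_strength_profile(
    conc_plus: GridMap,
    conc_minus: GridMap,
    distmap: GridMap,
    cutoffs,
    max_distance: float = np.inf,
) -> pd.DataFrame:
    """Region ionic strength I(≤d) = (N₊ + N₋) / (2 N_A V) versus cutoff."""
    from .density import region_mask

    _check_commensurate(conc_plus, conc_minus)
    _check_commensurate(conc_plus, distmap)
    rows = []
    for d in cutoffs:
        mask = region_mask(distmap, d, max_distance)
        v_litre = region_volume(mask) * LITRE_PER_A3
        if v_litre == 0:
            i_val = np.nan
        else:
            i_val = (
                region_ion_count(conc_plus, mask) + region_ion_count(conc_minus, mask)
            ) / (2 * N_A * v_litre)
        rows.append({"cutoff": float(d), "ionic_strength": i_val})
    return pd.DataFrame(rows)


@dataclass
class RDFCurve:
    """Molality-based radial distribution function in closest-atom distance.

    ``h`` is the ensemble-averaged per-frame particle count in each
    distance bin, ``h_water`` the per-molecule water count (atomistic
    water averages its site histograms), ``molality`` = h/(h_water·M_w)
    in mol/kg and ``g`` = molality / bulk molality.  Bins with no water
    are flagged NaN (undefined), not zero.
    """

    r: np.ndarray  # bin centers, Å
    h: np.ndarray
    h_water: np.ndarray
    molality: np.ndarray
    g: np.ndarray
    bulk_molality: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r,
                "h": self.h,
                "h_water": self.h_water,
                "molality": self.molality,
                "g": self.g,
            }
        )


def molality_rdf(
    traj: IonTrajectory,
    protein_coords_per_frame: np.ndarray,
    species: str,
    bin_width: float = 0.2,
    r_max: float | None = None,
    water_sites_per_molecule: int = 1,
) -> RDFCurve:
    """Molality-based RDF of one ion species versus closest-atom distance.

    Shell volumes never enter: the ion histogram is normalized by the
    local water histogram (converted to molality with the molar mass of
    water) and by the whole-box bulk molality, which makes the curve
    well defined for arbitrarily irregular structures.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    ions = traj.select(species)
    water = traj.select("WAT")
    if water.shape[1] == 0:
        raise ValueError("trajectory has no water sites for molality normalization")
    trees = _protein_trees(protein_coords_per_frame, traj.n_frames)
    d_ion = np.concatenate(
        [trees[f].query(ions[f])[0] for f in range(traj.n_frames)]
    ) if ions.shape[1] else np.empty(0)
    d_wat = np.concatenate([trees[f].query(water[f])[0] for f in range(traj.n_frames)])
    if r_max is None:
        r_max = float(max(d_wat.max(), d_ion.max() if len(d_ion) else 0.0))
    nbins = max(1, int(np.ceil(r_max / bin_width)))
    edges = np.arange(nbins + 1) * bin_width
    h_ion = np.histogram(d_ion, bins=edges)[0] / traj.n_frames
    h_wat_sites = np.histogram(d_wat, bins=edges)[0] / traj.n_frames
    h_wat = h_wat_sites / water_sites_per_molecule
    n_wat_mol = water.shape[1] / water_sites_per_molecule
    bulk_molality = ions.shape[1] / (n_wat_mol * M_WATER)
    with np.errstate(divide="ignore", invalid="ignore"):
        molality = np.where(h_wat > 0, h_ion / (h_wat * M_WATER), np.nan)
        g = molality / bulk_molality
    return RDFCurve(
        r=(edges[:-1] + edges[1:]) / 2.0,
        h=h_ion,
        h_water=h_wat,
        molality=molality,
        g=g,
        bulk_molality=float(bulk_molality),
    )


@dataclass(frozen=True)
class DispersionSummary:
    """Boxplot-style dispersion of node concentrations near the structure.

    Whiskers enclose the central 0.999 fraction of the values (the
    0.0005 and 0.9995 empirical quantiles); values outside them are
    outliers.  ``zero_fraction`` is the fraction of exactly-zero nodes.
    """

    n_nodes: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    zero_fraction: float


def _retained_values(
    conc: GridMap, distmap: GridMap, max_distance: float
) -> np.ndarray:
    _check_commensurate(conc, distmap)
    return conc.values[distmap.values <= max_distance]


def dispersion_summary(
    conc: GridMap, distmap: GridMap, max_distance: float = 15.0
) -> DispersionSummary:
    """Quantile summary of concentrations within *max_distance* of the atoms."""
    vals = _retained_values(conc, distmap, max_distance)
    if len(vals) == 0:
        raise ValueError("no nodes within max_distance")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # linear interpolation
    wlo, whi = np.quantile(vals, [0.0005, 0.9995])
    outliers = vals[(vals < wlo) | (vals > whi)]
    return DispersionSummary(
        n_nodes=int(len(vals)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(wlo),
        whisker_high=float(whi),
        outliers=np.sort(outliers),
        zero_fraction=float(np.mean(vals == 0.0)),
    )


def scatter_table(
    conc: GridMap, distmap: GridMap, max_distance: float = 15.0
) -> pd.DataFrame:
    """One (distance, concentration) row per retained node; no aggregation."""
    _check_commensurate(conc, distmap)
    keep = distmap.values <= max_distance
    return pd.DataFrame(
        {
            "distance": distmap.values[keep].ravel(),
            "concentration": conc.values[keep].ravel(),
        }
    )


def iso_concentration_mask(conc: GridMap, level: float) -> GridMap:
    """Binary mask of nodes with concentration at or above *level* (M)."""
    if level <= 0:
        raise ValueError("iso level must be positive")
    return GridMap(conc.spec, (conc.values >= level).astype(float), units="mask")
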