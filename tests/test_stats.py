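"""Region counts, excesses, ion addition, profiles, RDF, dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionatmos import (
    GridMap,
    GridSpec,
    InfeasibleError,
    IonTrajectory,
    StructureModel,
    bound_ion_count_md,
    dispersion_summary,
    distance_map,
    ion_addition,
    ion_excess,
    ionic_strength_profile,
    iso_concentration_mask,
    molality_rdf,
    region_ion_count,
    region_mask,
    scatter_table,
    total_charge_profile,
)
from ionatmos.constants import LITRE_PER_A3, M_WATER, N_A


def _map(spec, values, units="M"):
    return GridMap(spec, np.asarray(values, dtype=float), units)


def _full_mask(spec):
    return GridMap(spec, np.ones(spec.dims), "mask")


class TestRegionCount:
    def test_uniform_100mM_1000A3(self):
        """0.1 M over 1000 Å³ holds 0.1·N_A·1e-24 ≈ 0.0602 ions."""
        spec = GridSpec((0, 0, 0), (1, 1, 1), (10, 10, 10))
        conc = _map(spec, np.full((10, 10, 10), 0.1))
        n = region_ion_count(conc, _full_mask(spec))
        assert n == pytest.approx(0.1 * N_A * 1e-24, rel=1e-12)
        assert n == pytest.approx(0.06022140760, rel=1e-9)

    def test_zero_map(self, small_gridspec):
        conc = _map(small_gridspec, np.zeros(small_gridspec.dims))
        assert region_ion_count(conc, _full_mask(small_gridspec)) == 0.0

    def test_matches_per_node_brute_force(self, rng):
        spec = GridSpec((0, 0, 0), (0.8, 1.0, 1.2), (5, 5, 5))
        vals = rng.uniform(0, 0.5, spec.dims)
        keep = rng.random(spec.dims) < 0.5
        conc = _map(spec, vals)
        mask = GridMap(spec, keep.astype(float), "mask")
        brute = 0.0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    if keep[i, j, k]:
                        brute += N_A * vals[i, j, k] * spec.voxel_volume * LITRE_PER_A3
        assert region_ion_count(conc, mask) == pytest.approx(brute, rel=1e-12)


class TestIonExcess:
    def test_bulk_concentration_gives_zero(self, small_gridspec):
        conc = _map(small_gridspec, np.full(small_gridspec.dims, 0.1))
        assert ion_excess(conc, _full_mask(small_gridspec), 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_empty_region_is_minus_bulk_count(self, small_gridspec):
        conc = _map(small_gridspec, np.zeros(small_gridspec.dims))
        mask = _full_mask(small_gridspec)
        v = float(np.prod(small_gridspec.dims)) * small_gridspec.voxel_volume
        expect = -N_A * 0.1 * v * LITRE_PER_A3
        assert ion_excess(conc, mask, 0.1) == pytest.approx(expect, rel=1e-12)

    def test_three_node_hand_sum(self):
        spec = GridSpec((0, 0, 0), (1, 1, 1), (3, 2, 2))
        vals = np.zeros((3, 2, 2))
        vals[0, 0, 0], vals[1, 0, 0], vals[2, 0, 0] = 0.0, 0.1, 0.3
        mask = np.zeros((3, 2, 2))
        mask[:, 0, 0] = 1.0
        # hand computation: counts (0 + 0.1 + 0.3)·N_A·1e-27 minus 3·0.1·N_A·1e-27
        expect = (0.4 - 0.3) * N_A * 1e-27
        got = ion_excess(_map(spec, vals), GridMap(spec, mask, "mask"), 0.1)
        assert got == pytest.approx(expect, rel=1e-12)


class TestIonAddition:
    def test_worked_example_Z12(self):
        """Z = 12 with I·N_A·V = 100 available pairs: N+ = 94, N- = 106."""
        V = 100.0 / (0.1 * N_A)
        sol = ion_addition(12.0, 0.1, V)
        assert sol.n_plus == pytest.approx(94.0)
        assert sol.n_minus == pytest.approx(106.0)
        assert sol.excess_plus == pytest.approx(-6.0)
        assert sol.excess_minus == pytest.approx(6.0)
        assert (sol.n_plus_int, sol.n_minus_int) == (94, 106)

    def test_neutral_protein_symmetric(self):
        V = 50.0 / (0.15 * N_A)
        sol = ion_addition(0.0, 0.15, V)
        assert sol.n_plus == sol.n_minus == pytest.approx(50.0)
        assert sol.excess_plus == sol.excess_minus == 0.0

    def test_excess_equals_half_count_difference(self):
        """The whole-box cation excess recomputed as (N+ − N−)/2 is −Z/2."""
        sol = ion_addition(7.3, 0.1, 1e-22)
        assert (sol.n_plus - sol.n_minus) / 2 == pytest.approx(-7.3 / 2, abs=1e-12)
        assert sol.excess_plus == pytest.approx(-7.3 / 2, rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        z=st.floats(-30, 30),
        ionic=st.floats(0.01, 1.0),
        v=st.floats(1e-24, 1e-20),
    )
    def test_neutrality_and_half_charge_identities(self, z, ionic, v):
        """Z + ΔN+ − ΔN− = 0 and ΔN± = ∓Z/2, exactly, pre-rounding."""
        try:
            sol = ion_addition(z, ionic, v)
        except InfeasibleError:
            assert abs(z) > 2 * ionic * N_A * v
            return
        assert z + sol.excess_plus - sol.excess_minus == pytest.approx(0.0, abs=1e-9)
        assert sol.excess_plus == pytest.approx(-z / 2, abs=1e-9)
        assert sol.excess_minus == pytest.approx(z / 2, abs=1e-9)
        # ionic-strength condition
        assert sol.n_plus + sol.n_minus == pytest.approx(2 * ionic * N_A * v, rel=1e-12)

    def test_rounding_half_away_from_zero(self):
        V = 10.5 / (0.1 * N_A)
        sol = ion_addition(0.0, 0.1, V)  # N± = 10.5
        assert sol.n_plus_int == 11

    def test_infeasible_charge(self):
        with pytest.raises(InfeasibleError):
            ion_addition(1000.0, 0.1, 1e-24)


class TestBoundIons:
    def _static_protein(self):
        return np.array([[10.0, 10.0, 10.0]])

    def test_single_ion_cutoff_window(self):
        frames = np.array([[[13.0, 10.0, 10.0]]])
        traj = IonTrajectory(frames, np.array(["CAT"], dtype=object), (20, 20, 20))
        assert bound_ion_count_md(traj, self._static_protein(), "CAT", 3.5) == 1.0
        assert bound_ion_count_md(traj, self._static_protein(), "CAT", 2.0) == 0.0

    def test_mean_over_frames(self):
        f1 = [[11.0, 10, 10], [12.0, 10, 10], [19.0, 10, 10]]
        f2 = [[11.0, 10, 10], [11.5, 10, 10], [12.5, 10, 10]]
        traj = IonTrajectory(np.array([f1, f2]), np.array(["ANI"] * 3, dtype=object),
                             (20, 20, 20))
        # frame counts within 3 Å: 2 and 3 -> mean 2.5... check: f1 has d=1,2,9 -> 2
        assert bound_ion_count_md(traj, self._static_protein(), "ANI", 3.0) == 2.5

    def test_matches_brute_force_random_fixture(self, rng):
        prot = rng.uniform(5, 15, (6, 3))
        frames = rng.uniform(0, 20, (10, 8, 3))
        traj = IonTrajectory(frames, np.array(["CAT"] * 8, dtype=object), (20, 20, 20))
        cutoff = 4.0
        brute = 0.0
        for f in range(10):
            for i in range(8):
                dmin = min(np.linalg.norm(frames[f, i] - prot[a]) for a in range(6))
                brute += dmin <= cutoff
        brute /= 10
        assert bound_ion_count_md(traj, prot, "CAT", cutoff) == pytest.approx(brute)


class TestProfiles:
    def _setup(self, rng):
        spec = GridSpec((0, 0, 0), (1, 1, 1), (9, 9, 9))
        s = StructureModel(np.array([[4.0, 4.0, 4.0]]), np.array([3.0]), np.ones(1))
        dmap = distance_map(spec, s)
        cp = _map(spec, rng.uniform(0, 0.3, spec.dims))
        cm = _map(spec, rng.uniform(0, 0.3, spec.dims))
        return spec, s, dmap, cp, cm

    def test_total_charge_profile_brute_force(self, rng):
        spec, s, dmap, cp, cm = self._setup(rng)
        cutoffs = [1.0, 2.5, 4.0]
        prof = total_charge_profile(3.0, cp, cm, dmap, cutoffs, 0.1)
        for _, row in prof.iterrows():
            sel = dmap.values <= row["cutoff"]
            npl = N_A * cp.values[sel].sum() * 1e-27
            nmi = N_A * cm.values[sel].sum() * 1e-27
            assert row["total_charge"] == pytest.approx(3.0 + npl - nmi, rel=1e-12)
            bulk_n = N_A * 0.1 * sel.sum() * 1e-27
            assert row["excess_plus"] == pytest.approx(npl - bulk_n, rel=1e-10)

    def test_ionic_strength_profile_uniform_and_zero(self, rng):
        spec, s, dmap, _, _ = self._setup(rng)
        uni = _map(spec, np.full(spec.dims, 0.1))
        prof = ionic_strength_profile(uni, uni, dmap, [2.0, 5.0])
        np.testing.assert_allclose(prof["ionic_strength"], 0.1, rtol=1e-12)
        zero = _map(spec, np.zeros(spec.dims))
        prof0 = ionic_strength_profile(zero, zero, dmap, [2.0])
        assert prof0["ionic_strength"].iloc[0] == 0.0

    def test_ionic_strength_hand_computed_toy(self):
        spec = GridSpec((0, 0, 0), (1, 1, 1), (2, 2, 2))
        s = StructureModel(np.zeros((1, 3)), np.zeros(1), np.ones(1))
        dmap = distance_map(spec, s)
        cp = _map(spec, np.full(spec.dims, 0.2))
        cm = _map(spec, np.full(spec.dims, 0.1))
        prof = ionic_strength_profile(cp, cm, dmap, [10.0])
        # I = (N+ + N-)/(2 N_A V): uniform maps -> (0.2 + 0.1)/2
        assert prof["ionic_strength"].iloc[0] == pytest.approx(0.15, rel=1e-12)


class TestMolalityRDF:
    def test_uniform_system_bulk_g_is_one(self, rng):
        """Uniform ions and water around a point: g = 1 within sampling error."""
        n_frames, n_ion, n_wat = 60, 40, 2000
        species = np.array(["CAT"] * n_ion + ["WAT"] * n_wat, dtype=object)
        frames = rng.uniform(0, 40, (n_frames, n_ion + n_wat, 3))
        traj = IonTrajectory(frames, species, (40, 40, 40))
        prot = np.array([[20.0, 20.0, 20.0]])
        curve = molality_rdf(traj, prot, "CAT", bin_width=2.0, r_max=18.0)
        sel = curve.r > 6.0  # bins with plenty of volume
        g = curve.g[sel]
        assert np.all(np.isfinite(g))
        assert np.abs(g - 1.0).max() < 0.4
        assert np.abs(np.mean(g) - 1.0) < 0.05

    def test_empty_ion_bin_gives_zero(self):
        # one ion far away, waters everywhere
        species = np.array(["CAT"] + ["WAT"] * 50, dtype=object)
        frames = np.zeros((1, 51, 3))
        frames[0, 0] = [15.0, 0, 0]
        frames[0, 1:] = np.linspace([1, 0, 0], [16, 0, 0], 50)
        traj = IonTrajectory(frames, species, (20, 20, 20))
        curve = molality_rdf(traj, np.zeros((1, 3)), "CAT", bin_width=1.0, r_max=16.0)
        assert curve.h[2] == 0.0 and curve.g[2] == 0.0

    def test_hand_placed_single_bin(self):
        """2 ions and 30 waters in one bin: m = 2/(30·M_water), g = m/m_bulk."""
        n_wat = 40
        species = np.array(["ANI"] * 2 + ["WAT"] * n_wat, dtype=object)
        frames = np.zeros((1, 2 + n_wat, 3))
        frames[0, 0] = [5.1, 0, 0]
        frames[0, 1] = [5.3, 0, 0]  # both ions in bin [5,6)
        frames[0, 2:32] = np.linspace([5.05, 0, 0], [5.95, 0, 0], 30)  # 30 waters
        frames[0, 32:] = np.linspace([8.05, 0, 0], [8.95, 0, 0], 10)  # rest elsewhere
        traj = IonTrajectory(frames, species, (20, 20, 20))
        curve = molality_rdf(traj, np.zeros((1, 3)), "ANI", bin_width=1.0, r_max=10.0)
        i = 5
        m = 2 / (30 * M_WATER)
        m_bulk = 2 / (n_wat * M_WATER)
        assert curve.molality[i] == pytest.approx(m, rel=1e-12)
        assert curve.g[i] == pytest.approx(m / m_bulk, rel=1e-12)
        assert curve.bulk_molality == pytest.approx(m_bulk, rel=1e-12)

    def test_water_free_bin_flagged_nan(self):
        species = np.array(["CAT", "WAT"], dtype=object)
        frames = np.zeros((1, 2, 3))
        frames[0, 0] = [2.5, 0, 0]
        frames[0, 1] = [7.5, 0, 0]
        traj = IonTrajectory(frames, species, (20, 20, 20))
        curve = molality_rdf(traj, np.zeros((1, 3)), "CAT", bin_width=1.0, r_max=10.0)
        assert np.isnan(curve.g[2])  # ion present, no water: undefined, not zero

    def test_atomistic_water_site_averaging(self, rng):
        """Three water sites per molecule average to the per-molecule histogram."""
        n_mol = 300
        centers = rng.uniform(5, 35, (1, n_mol, 3))
        sites = np.concatenate([centers + rng.normal(0, 0.05, centers.shape)
                                for _ in range(3)], axis=1)
        species1 = np.array(["CAT"] + ["WAT"] * n_mol, dtype=object)
        species3 = np.array(["CAT"] + ["WAT"] * (3 * n_mol), dtype=object)
        ion = np.full((1, 1, 3), 12.0)
        t1 = IonTrajectory(np.concatenate([ion, centers], axis=1), species1, (40,) * 3)
        t3 = IonTrajectory(np.concatenate([ion, sites], axis=1), species3, (40,) * 3)
        prot = np.array([[20.0, 20.0, 20.0]])
        c1 = molality_rdf(t1, prot, "CAT", bin_width=2.0, r_max=14.0)
        c3 = molality_rdf(t3, prot, "CAT", bin_width=2.0, r_max=14.0,
                          water_sites_per_molecule=3)
        assert c3.bulk_molality == pytest.approx(c1.bulk_molality, rel=1e-12)
        ok = c1.h_water > 0
        np.testing.assert_allclose(c3.h_water[ok], c1.h_water[ok], rtol=0.1)


class TestDispersion:
    def test_constant_map_degenerate(self, small_gridspec, random_structure):
        conc = _map(small_gridspec, np.full(small_gridspec.dims, 0.2))
        dmap = distance_map(small_gridspec, random_structure)
        s = dispersion_summary(conc, dmap, max_distance=50.0)
        assert s.median == s.q1 == s.q3 == s.whisker_low == s.whisker_high == 0.2
        assert len(s.outliers) == 0
        assert s.zero_fraction == 0.0

    def test_quantiles_match_reference_rule(self):
        spec = GridSpec((0, 0, 0), (1, 1, 1), (10, 10, 10))
        vals = np.arange(1.0, 1001.0).reshape(10, 10, 10)
        s_struct = StructureModel(np.array([[5.0, 5.0, 5.0]]), np.zeros(1), np.ones(1))
        dmap = distance_map(spec, s_struct)
        s = dispersion_summary(_map(spec, vals), dmap, max_distance=100.0)
        flat = vals.ravel()
        assert s.median == pytest.approx(np.quantile(flat, 0.5))
        assert s.q1 == pytest.approx(np.quantile(flat, 0.25))
        assert s.q3 == pytest.approx(np.quantile(flat, 0.75))
        assert s.whisker_low == pytest.approx(np.quantile(flat, 0.0005))
        # outliers lie strictly outside the whiskers
        assert np.all((s.outliers < s.whisker_low) | (s.outliers > s.whisker_high))

    def test_all_zero_map(self, small_gridspec, random_structure):
        conc = _map(small_gridspec, np.zeros(small_gridspec.dims))
        dmap = distance_map(small_gridspec, random_structure)
        assert dispersion_summary(conc, dmap, 50.0).zero_fraction == 1.0


class TestScatterAndIso:
    def test_scatter_rows_equal_retained_nodes(self, small_gridspec, random_structure, rng):
        conc = _map(small_gridspec, rng.uniform(0, 1, small_gridspec.dims))
        dmap = distance_map(small_gridspec, random_structure)
        t = scatter_table(conc, dmap, max_distance=3.0)
        assert len(t) == int((dmap.values <= 3.0).sum())
        # two-node toy
        spec2 = GridSpec((0, 0, 0), (1, 1, 1), (2, 2, 2))
        conc2 = _map(spec2, np.arange(8.0).reshape(2, 2, 2))
        d2 = distance_map(spec2, StructureModel(np.zeros((1, 3)), np.zeros(1), np.ones(1)))
        t2 = scatter_table(conc2, d2, max_distance=0.5)
        assert len(t2) == 1 and t2["concentration"].iloc[0] == 0.0

    def test_iso_mask_thresholds_and_nesting(self, small_gridspec, rng):
        vals = rng.uniform(0, 0.5, small_gridspec.dims)
        conc = _map(small_gridspec, vals)
        assert iso_concentration_mask(conc, 1.0).values.sum() == 0
        uniform = _map(small_gridspec, np.full(small_gridspec.dims, 0.2))
        assert np.all(iso_concentration_mask(uniform, 0.2).values == 1)
        m200 = iso_concentration_mask(conc, 0.2).values
        m400 = iso_concentration_mask(conc, 0.4).values
        assert np.all(m400 <= m200)
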