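"""RMSD coordinate, clustering, PMF construction, diffusion and the
resistivity integral."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lariatperm import permeability as pm
from lariatperm.ensemble_model import (
    KB_KCAL,
    KB_SI,
    OCTANOL_VISCOSITY_310K,
    WATER_VISCOSITY_310K,
)


class TestRMSD:
    def test_identical_frames_zero(self, water_ensemble):
        ref = water_ensemble.coordinates[0]
        r = pm.rmsd_to_reference(water_ensemble, ref)
        assert r[0] == pytest.approx(0.0, abs=1e-9)

    def test_rotated_translated_copy_zero(self, water_ensemble, rng):
        from scipy.spatial.transform import Rotation

        ref = water_ensemble.coordinates[0]
        R = Rotation.random(random_state=3).as_matrix()
        moved = ref @ R.T + rng.normal(size=3)
        import lariatperm.ensemble_model as em

        ens = em.ConformationalEnsemble(
            moved[None], water_ensemble.topology, water_ensemble.solvent
        )
        assert pm.rmsd_to_reference(ens, ref)[0] == pytest.approx(0.0, abs=1e-8)

    def test_subset_too_small_raises(self, water_ensemble):
        with pytest.raises(pm.GeometryError):
            pm.rmsd_to_reference(
                water_ensemble, water_ensemble.coordinates[0], subset=[0, 1]
            )


class TestClustering:
    def test_well_separated_populations(self):
        rng = np.random.default_rng(0)
        x = np.concatenate(
            [rng.normal(1.0, 0.05, 700), rng.normal(4.0, 0.05, 300)]
        )
        model = pm.fit_clusters(x, k=2, seed=0)
        assert model.centers[0] < model.centers[1]
        assert model.populations[0] == pytest.approx(0.7, abs=0.01)
        assert model.populations[1] == pytest.approx(0.3, abs=0.01)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        a = pm.fit_clusters(x, k=4, seed=9)
        b = pm.fit_clusters(x, k=4, seed=9)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.centers, b.centers)

    def test_frame_weights_shift_populations(self):
        x = np.array([0.0] * 5 + [10.0] * 5)
        w = np.array([4.0] * 5 + [1.0] * 5)
        model = pm.fit_clusters(x, k=2, seed=0, frame_weights=w)
        assert model.populations[0] == pytest.approx(0.8)

    def test_too_few_frames(self):
        with pytest.raises(pm.DegenerateInputError):
            pm.fit_clusters(np.arange(3.0), k=5)


def _model(pops, centers=None, F=1000):
    pops = np.asarray(pops, dtype=float)
    k = len(pops)
    centers = np.asarray(centers if centers is not None else np.arange(k), dtype=float)
    counts = np.round(pops * F).astype(int)
    assign = np.repeat(np.arange(k), counts)
    return pm.ClusterModel(k, centers, pops / pops.sum(), assign)


class TestPMF:
    def test_uniform_populations_give_flat_pmf(self):
        m = _model([0.25] * 4)
        pmf = pm.pmf_from_populations(m, m)
        assert np.allclose(pmf.W, 0.0, atol=1e-12)

    def test_population_ratio_closed_form(self):
        """W(0.2 cluster) - W(0.8 cluster) = -kB*310*ln(0.2/0.8)
        = 0.8540034 kcal/mol (about 0.854 kcal/mol)."""
        mw = _model([0.8, 0.2], centers=[1.0, 3.0])
        mo = _model([0.5, 0.5], centers=[1.0, 3.0])
        pmf = pm.pmf_from_populations(mw, mo, T=310.0)
        closed = -KB_KCAL * 310.0 * np.log(0.2 / 0.8)
        # water knots sit at the segment ends (z=0 and z=18 for the
        # default span/interface), on-grid for the 1001-point grid
        w0 = pmf.W[pmf.z == 0.0][0]
        w1 = pmf.W[pmf.z == 18.0][0]
        assert w1 - w0 == pytest.approx(closed, abs=1e-9)
        assert closed == pytest.approx(0.8540034, abs=1e-7)
        assert closed == pytest.approx(0.854, abs=2e-4)

    def test_empty_cluster_floored_not_infinite(self):
        m = _model([1.0, 0.0], centers=[1.0, 2.0], F=100)
        pmf = pm.pmf_from_populations(m, m)
        assert np.all(np.isfinite(pmf.W))
        assert pmf.floored_clusters == 2  # one per solvent copy
        kT = KB_KCAL * 310.0
        assert pmf.W.max() == pytest.approx(-kT * np.log(1e-3), abs=1e-9)

    def test_interface_bridge_is_continuous(self):
        mw = _model([0.9, 0.1], centers=[1.0, 3.0])
        mo = _model([0.1, 0.9], centers=[1.0, 3.0])
        pmf = pm.pmf_from_populations(mw, mo)
        assert np.max(np.abs(np.diff(pmf.W))) < 0.5  # no jump discontinuity
        assert (pmf.segment == "water").sum() + (pmf.segment == "octanol").sum() == len(pmf.z)

    def test_min_is_zero(self):
        mw = _model([0.6, 0.4])
        mo = _model([0.3, 0.7])
        pmf = pm.pmf_from_populations(mw, mo)
        assert pmf.W.min() == pytest.approx(0.0, abs=1e-12)


class TestMinEnclosingSphere:
    def test_two_points(self):
        c, r = pm.min_enclosing_sphere(np.array([[0, 0, 0], [2, 0, 0.0]]))
        assert r == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(c, [1, 0, 0], atol=1e-12)

    def test_regular_tetrahedron(self):
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        _c, r = pm.min_enclosing_sphere(pts)
        assert r == pytest.approx(np.sqrt(3.0), abs=1e-9)

    def test_interior_points_ignored(self, rng):
        shell = rng.normal(size=(30, 3))
        shell = 5.0 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
        cloud = np.vstack([shell, rng.uniform(-1, 1, size=(100, 3))])
        _c, r = pm.min_enclosing_sphere(cloud)
        assert r == pytest.approx(5.0, abs=1e-6)

    def test_matches_brute_force_support_search(self, rng):
        """Exactness oracle: enumerate all <=4-point supports of a small
        cloud and take the smallest sphere that encloses everything."""
        from itertools import combinations

        pts = rng.normal(size=(12, 3))
        best = np.inf
        for m in (1, 2, 3, 4):
            for idx in combinations(range(len(pts)), m):
                ball = pm._circumsphere([pts[i] for i in idx])
                if ball is None:
                    continue
                c, r = ball
                d = np.max(np.linalg.norm(pts - c, axis=1))
                if d <= r + 1e-9:
                    best = min(best, r)
        _c, r = pm.min_enclosing_sphere(pts)
        assert r == pytest.approx(best, abs=1e-9)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_encloses_all_points(self, seed):
        pts = np.random.default_rng(seed).normal(size=(40, 3))
        c, r = pm.min_enclosing_sphere(pts)
        assert np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-9)


class TestStokesEinstein:
    def test_independent_arithmetic(self):
        """D(310 K, water viscosity, 5 Å) recomputed digit by digit."""
        expected_m2s = (1.380649e-23 * 310.0) / (
            6.0 * np.pi * 6.913e-4 * 5.0e-10
        )
        assert pm.stokes_einstein(310.0, WATER_VISCOSITY_310K, 5.0) == pytest.approx(
            expected_m2s * 1e4, rel=1e-12
        )

    def test_inverse_proportionality_in_radius(self):
        d1 = pm.stokes_einstein(310.0, WATER_VISCOSITY_310K, 4.0)
        d2 = pm.stokes_einstein(310.0, WATER_VISCOSITY_310K, 8.0)
        assert d1 / d2 == pytest.approx(2.0, rel=1e-12)

    def test_octanol_slower_than_water(self):
        assert pm.stokes_einstein(310.0, OCTANOL_VISCOSITY_310K, 5.0) < pm.stokes_einstein(
            310.0, WATER_VISCOSITY_310K, 5.0
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pm.stokes_einstein(310.0, WATER_VISCOSITY_310K, -1.0)


class TestResistivityIntegral:
    def test_flat_pmf_is_series_resistor(self):
        """W = 0 everywhere: R = L_w/D_w + L_o/D_o exactly."""
        m = _model([0.5, 0.5])
        pmf = pm.pmf_from_populations(m, m, span=40.0)
        D_w, D_o = 6.6e-6, 9.1e-7
        res = pm.resistivity_integral(pmf, D_w, D_o)
        L = 20.0 * pm.ANGSTROM_TO_CM
        assert res.resistivity == pytest.approx(L / D_w + L / D_o, rel=1e-12)
        assert res.logP_calc == pytest.approx(np.log10(1.0 / res.resistivity))

    def test_grid_refinement_converges(self):
        mw = _model([0.6, 0.3, 0.1], centers=[1.0, 2.0, 4.0])
        mo = _model([0.2, 0.3, 0.5], centers=[1.0, 2.5, 4.0])
        coarse = pm.pmf_from_populations(mw, mo, n_grid=1001)
        fine = pm.pmf_from_populations(mw, mo, n_grid=8001)
        r1 = pm.resistivity_integral(coarse, 6.6e-6, 9.1e-7).resistivity
        r2 = pm.resistivity_integral(fine, 6.6e-6, 9.1e-7).resistivity
        assert abs(r1 - r2) / r2 < 1e-3

    def test_higher_barrier_lower_permeability(self):
        lo = pm.pmf_from_populations(_model([0.6, 0.4]), _model([0.6, 0.4]))
        hi = pm.pmf_from_populations(_model([0.99, 0.01]), _model([0.99, 0.01]))
        D = (6.6e-6, 9.1e-7)
        assert (
            pm.resistivity_integral(hi, *D).logP_calc
            < pm.resistivity_integral(lo, *D).logP_calc
        )

    def test_overflow_guard_finite(self):
        z = np.linspace(0.0, 40.0, 1001)
        W = np.full(1001, 400.0)  # beta*W ~ 650, overflows exp() naively
        W[0] = 0.0
        pmf = pm.PMFProfile(z, W, np.where(z < 20, "water", "octanol"), 40.0)
        res = pm.resistivity_integral(pmf, 6.6e-6, 9.1e-7)
        assert res.overflow_flag
        assert np.isfinite(res.resistivity) and res.resistivity > 0

    def test_explicit_diffusion_profile(self):
        m = _model([0.5, 0.5])
        pmf = pm.pmf_from_populations(m, m, span=40.0)
        D = np.full(len(pmf.z), 5.0e-6)
        res = pm.resistivity_integral(pmf, 6.6e-6, 9.1e-7, D_profile=D)
        L = 40.0 * pm.ANGSTROM_TO_CM
        assert res.resistivity == pytest.approx(L / 5.0e-6, rel=1e-12)


class TestEndToEnd:
    def test_pipeline_outputs_consistent(self, small_pair):
        water, octanol, record = small_pair
        result, pmf, mw, mo = pm.permeability_from_ensembles(
            water, octanol, k=record["k"], seed=0
        )
        assert result.permeability == pytest.approx(1.0 / result.resistivity)
        assert result.logP_calc == pytest.approx(np.log10(result.permeability))
        assert result.D_water > result.D_octanol  # viscosity ordering
        assert mw.populations.sum() == pytest.approx(1.0)
        assert mo.populations.sum() == pytest.approx(1.0)
        assert np.all(np.isfinite(pmf.W))

    def test_pipeline_deterministic(self, small_pair):
        water, octanol, record = small_pair
        a = pm.permeability_from_ensembles(water, octanol, k=record["k"], seed=0)
        b = pm.permeability_from_ensembles(water, octanol, k=record["k"], seed=0)
        assert a[0].logP_calc == b[0].logP_calc
        assert np.array_equal(a[1].W, b[1].W)


class TestAggregation:
    def test_outlier_rule_worked_example(self):
        """{1, 2, 3, 4, 100, -100}: the two farthest from the median are
        dropped, leaving mean 2.5."""
        results = {f"p{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 100.0, -100.0])}
        grouping = {k: 0 for k in results}
        df = pm.aggregate_by_group(results, grouping, drop_outliers=2)
        row = df.iloc[0]
        assert row["n_raw"] == 6 and row["n"] == 4
        assert row["mean"] == pytest.approx(2.5)
        assert row["min"] == 1.0 and row["max"] == 4.0

    def test_small_group_keeps_everything(self):
        results = {"a": 1.0, "b": 2.0, "c": 100.0}
        grouping = {k: 1 for k in results}
        df = pm.aggregate_by_group(results, grouping, drop_outliers=2)
        assert df.iloc[0]["n"] == 3  # n <= drop+2: no dropping
        assert df.iloc[0]["max"] == 100.0

    def test_groups_reported_separately(self):
        results = {"a": 1.0, "b": 2.0, "c": 5.0, "d": 6.0}
        grouping = {"a": 0, "b": 0, "c": 1, "d": 1}
        df = pm.aggregate_by_group(results, grouping)
        assert list(df["group"]) == [0, 1]
        assert df[df["group"] == 0].iloc[0]["mean"] == pytest.approx(1.5)


class TestExperimentCorrelation:
    def test_perfect_linear_relation(self):
        calc = {f"p{i}": float(i) for i in range(5)}
        app = {f"p{i}": 2.0 * i + 1.0 for i in range(5)}
        r, r2, table, unmatched = pm.correlate_with_experiment(calc, app)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert len(table) == 5 and unmatched == []

    def test_unmatched_ids_reported(self):
        calc = {"a": 1.0, "b": 2.0, "c": 3.0, "x": 9.0}
        app = {"a": 1.0, "b": 2.5, "c": 2.0, "y": 0.0}
        _r, _r2, table, unmatched = pm.correlate_with_experiment(calc, app)
        assert set(unmatched) == {"x", "y"}
        assert len(table) == 3

    def test_too_few_pairs(self):
        with pytest.raises(pm.InsufficientDataError):
            pm.correlate_with_experiment({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
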