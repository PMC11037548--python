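"""Dihedrals, cis/trans classification, H-bonds, SASA and PCA overlap."""

import numpy as np
import pytest

from lariatperm import descriptors as dsc
from lariatperm import ensemble_model as em
from lariatperm import synthetic_fixtures as sf


P0 = np.array([0.0, 1.0, 0.0])
P1 = np.array([0.0, 0.0, 0.0])
P2 = np.array([1.0, 0.0, 0.0])


class TestDihedrals:
    @pytest.mark.parametrize(
        "p3, expected",
        [
            ([1.0, 1.0, 0.0], 0.0),  # eclipsed -> cis
            ([1.0, -1.0, 0.0], 180.0),  # anti-periplanar -> trans
        ],
    )
    def test_closed_form_angles(self, p3, expected):
        ang = dsc.dihedral_angles(P0, P1, P2, np.asarray(p3))
        assert float(ang) == pytest.approx(expected, abs=1e-10)

    def test_perpendicular_magnitude_and_antisymmetry(self):
        up = float(dsc.dihedral_angles(P0, P1, P2, np.array([1.0, 0.0, 1.0])))
        dn = float(dsc.dihedral_angles(P0, P1, P2, np.array([1.0, 0.0, -1.0])))
        assert abs(up) == pytest.approx(90.0, abs=1e-10)
        assert dn == pytest.approx(-up, abs=1e-10)

    def test_rotation_translation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        p3 = np.array([1.0, 0.4, 0.7])
        base = float(dsc.dihedral_angles(P0, P1, P2, p3))
        R = Rotation.random(random_state=5).as_matrix()
        t = rng.normal(size=3)
        pts = [p @ R.T + t for p in (P0, P1, P2, p3)]
        assert float(dsc.dihedral_angles(*pts)) == pytest.approx(base, abs=1e-9)

    def test_wrap_convention(self):
        # exactly anti-periplanar must report +180, never -180
        ang = float(dsc.dihedral_angles(P0, P1, P2, np.array([1.0, -1.0, 0.0])))
        assert ang == pytest.approx(180.0)
        assert ang > 0

    def test_vectorized_over_frames(self, rng):
        pts = rng.normal(size=(20, 4, 3))
        batch = dsc.dihedral_angles(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        single = [
            float(dsc.dihedral_angles(pts[f, 0], pts[f, 1], pts[f, 2], pts[f, 3]))
            for f in range(20)
        ]
        assert np.allclose(batch, single, atol=1e-12)


class TestOmegaAndCisTrans:
    def test_omega_shape_and_closure_exclusion(self, water_ensemble):
        prof = dsc.compute_omega(water_ensemble)
        n_res = water_ensemble.topology.n_residues
        assert prof.excluded_positions == frozenset({n_res - 1})
        assert prof.omega.shape == (water_ensemble.n_frames, n_res - 1)

    def test_planted_cis_linkage_classified_cis(self):
        spec = sf.FixtureSpec(planted_cis={3: 1.0}, seed=2)
        ens = sf.generate_ensemble(spec, "water", 50)
        frac = dsc.classify_cis_trans(dsc.compute_omega(ens))
        assert frac[3] == pytest.approx(1.0)
        others = [i for i in range(len(frac)) if i != 3]
        assert np.all(frac[others] < 0.05)

    def test_cutoff_boundary(self):
        prof = dsc.OmegaProfile(
            omega=np.array([[89.9, 90.1, -89.9, 179.0]]),
            linkage_labels=["a", "b", "c", "d"],
            excluded_positions=frozenset(),
        )
        frac = dsc.classify_cis_trans(prof, cutoff_deg=90.0)
        assert list(frac) == [1.0, 0.0, 1.0, 0.0]


class TestHBonds:
    def test_planted_hbond_detected_at_planted_occupancy(self):
        spec = sf.FixtureSpec(planted_hbonds={(5, 2): 1.0}, seed=3)
        ens = sf.generate_ensemble(spec, "water", 40)
        hb = dsc.detect_hbonds(ens)
        di = [d[0] for d in hb.donors].index(5)
        ai = [a[0] for a in hb.acceptors].index(2)
        assert hb.occupancy[di, ai] == pytest.approx(1.0)

    def test_methylated_donor_never_reported(self):
        spec = sf.FixtureSpec(methylation=(5,), seed=3)
        ens = sf.generate_ensemble(spec, "water", 20)
        hb = dsc.detect_hbonds(ens)
        assert 5 not in {d[0] for d in hb.donors}

    def test_self_pairs_zero_and_tight_cutoff_kills_everything(self):
        spec = sf.FixtureSpec(planted_hbonds={(5, 2): 1.0}, seed=4)
        ens = sf.generate_ensemble(spec, "water", 10)
        hb = dsc.detect_hbonds(ens)
        for di, (rd, _) in enumerate(hb.donors):
            for ai, (ra, _) in enumerate(hb.acceptors):
                if rd == ra:
                    assert hb.occupancy[di, ai] == 0.0
        tight = dsc.detect_hbonds(ens, d_cut=0.1)
        assert np.all(tight.occupancy == 0.0)


class _StubEnsemble:
    """Minimal coordinates+topology carrier for SASA geometry checks."""

    def __init__(self, coords, radii):
        self.coordinates = np.asarray(coords, dtype=float)
        self.n_frames = self.coordinates.shape[0]
        r = np.asarray(radii, dtype=float)

        class _Top:
            n_atoms = len(r)

            def radii(self, indices=None):  # noqa: ARG002 - stub
                return r

        self.topology = _Top()


class TestSASA:
    def test_isolated_atom_is_full_sphere(self):
        """Single atom: SASA = 4 pi (r + probe)^2 within 1% at the default
        point count (the test points only discretize the exact sphere)."""
        ens = _StubEnsemble(np.zeros((1, 1, 3)), [1.52])
        prof = dsc.compute_sasa(ens, subset=[0])
        exact = 4.0 * np.pi * (1.52 + 1.4) ** 2
        assert prof.per_atom[0, 0] == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_additive(self):
        ens = _StubEnsemble([[[0.0, 0, 0], [50.0, 0, 0]]], [1.52, 1.70])
        prof = dsc.compute_sasa(ens, subset=[0, 1])
        exact = 4.0 * np.pi * ((1.52 + 1.4) ** 2 + (1.70 + 1.4) ** 2)
        assert prof.per_frame_total[0] == pytest.approx(exact, rel=0.01)

    def test_buried_atom_has_zero_area(self):
        ens = _StubEnsemble(np.zeros((1, 2, 3)), [3.0, 0.5])
        prof = dsc.compute_sasa(ens, subset=[0, 1])
        assert prof.per_atom[0, 1] == 0.0

    def test_cross_check_against_mdtraj(self, water_ensemble):
        """Shrake-Rupley on real peptide frames agrees with mdtraj's
        independent implementation within 3% of the total area."""
        mdtraj = pytest.importorskip("mdtraj")

        top = water_ensemble.topology
        mtop = mdtraj.Topology()
        chain = mtop.add_chain()
        res = mtop.add_residue("PEP", chain)
        for atom in top.atoms:
            elem = mdtraj.element.get_by_symbol(atom.element)
            mtop.add_atom(atom.name, elem, res)
        traj = mdtraj.Trajectory(water_ensemble.coordinates[:5] / 10.0, mtop)
        change = {
            el: em.DEFAULT_VDW_RADII[el] / 10.0
            for el in {a.element for a in top.atoms}
        }
        ref = mdtraj.shrake_rupley(
            traj, probe_radius=0.14, n_sphere_points=960, change_radii=change
        )
        sub = em.ConformationalEnsemble(
            water_ensemble.coordinates[:5], top, water_ensemble.solvent
        )
        mine = dsc.compute_sasa(sub)
        ref_total = ref.sum(axis=1) * 100.0  # nm^2 -> Å^2
        assert np.allclose(mine.per_frame_total, ref_total, rtol=0.03)


class TestPCAOverlap:
    def test_variance_fractions_sorted_and_sum_le_one(self, water_ensemble):
        res = dsc.pca(water_ensemble, mode="dihedral", n_components=3)
        vf = res.variance_fractions
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1.0 + 1e-9
        assert res.projections.shape == (water_ensemble.n_frames, 3)

    def test_deterministic_sign_convention(self, water_ensemble):
        a = dsc.pca(water_ensemble, mode="dihedral", n_components=2)
        b = dsc.pca(water_ensemble, mode="dihedral", n_components=2)
        assert np.array_equal(a.components, b.components)

    def test_cartesian_mode_translation_invariant(self, water_ensemble):
        shifted = em.ConformationalEnsemble(
            water_ensemble.coordinates + 37.0,
            water_ensemble.topology,
            water_ensemble.solvent,
        )
        a = dsc.pca(water_ensemble, mode="cartesian_heavy", n_components=2)
        b = dsc.pca(shifted, mode="cartesian_heavy", n_components=2)
        assert np.allclose(np.abs(a.projections), np.abs(b.projections), atol=1e-6)

    def test_too_few_frames_raises(self, topology):
        ens = em.ConformationalEnsemble(
            np.random.default_rng(0).normal(size=(2, topology.n_atoms, 3)),
            topology,
            em.water_spec(),
        )
        with pytest.raises(dsc.InsufficientSamplingError):
            dsc.pca(ens, mode="dihedral", n_components=2)

    def test_bhattacharyya_identical_is_one(self, rng):
        x = rng.normal(size=(500, 2))
        assert dsc.bhattacharyya_overlap(x, x) == pytest.approx(1.0)

    def test_bhattacharyya_disjoint_is_zero(self, rng):
        a = rng.normal(size=(500, 2))
        b = a + 100.0
        assert dsc.bhattacharyya_overlap(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_bhattacharyya_offset_gaussians_near_closed_form(self, rng):
        """First coordinate offset by 2 sigma (coefficient exp(-1/2)),
        second coordinate identically distributed."""
        a = np.column_stack([rng.normal(0.0, 1.0, 20_000), rng.normal(size=20_000)])
        b = np.column_stack([rng.normal(2.0, 1.0, 20_000), rng.normal(size=20_000)])
        assert dsc.bhattacharyya_overlap(a, b, bins=25) == pytest.approx(
            np.exp(-0.5), abs=0.05
        )

    def test_solvent_overlap_self_is_one(self, water_ensemble):
        assert dsc.solvent_overlap_score(
            water_ensemble, water_ensemble
        ) == pytest.approx(1.0)
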