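"""Discretization, entropy estimators, pucker, contacts and descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cispro import conformation, synthetic
from cispro.constants import R_KCAL, DEBYE_PER_E_ANGSTROM


class TestDiscretize:
    def test_examples(self):
        b = [0.0, 120.0, 240.0]
        assert conformation.discretize([10.0], b)[0] == 0
        assert conformation.discretize([359.9], b)[0] == 2

    def test_wrap_below_first_boundary(self):
        b = [30.0, 150.0, 270.0]
        assert conformation.discretize([10.0], b)[0] == 2  # wraps through 360

    def test_round_trip_of_representative_angles(self):
        b = [0.0, 120.0, 240.0]
        reps = [60.0, 180.0, 300.0]
        assert list(conformation.discretize(reps, b)) == [0, 1, 2]

    def test_empty_boundaries_rejected(self):
        with pytest.raises(ValueError):
            conformation.discretize([10.0], [])


class TestFirstOrderEntropy:
    def test_single_state_is_zero(self):
        assert conformation.first_order_entropy(np.zeros(100, dtype=int)) == 0.0

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_uniform_states_give_r_ln_m(self, m):
        states = np.tile(np.arange(m), 100)
        s = conformation.first_order_entropy(states)
        assert s == pytest.approx(R_KCAL * np.log(m), rel=1e-12)

    def test_half_quarter_quarter_distribution(self):
        states = np.array([0, 0, 1, 2] * 50)
        s = conformation.first_order_entropy(states)
        assert s == pytest.approx(R_KCAL * 1.5 * np.log(2.0), rel=1e-12)

    def test_sums_over_torsions(self):
        col = np.tile(np.arange(2), 50)
        both = np.stack([col, col], axis=1)
        assert conformation.first_order_entropy(both) == pytest.approx(
            2 * R_KCAL * np.log(2), rel=1e-12
        )

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            conformation.first_order_entropy(np.array([], dtype=int))


class TestCorrectedEntropy:
    def test_single_torsion_has_zero_correction(self):
        states = np.tile(np.arange(3), 100)
        est = conformation.mi_corrected_entropy(states, seed=0)
        assert est.correction == 0.0
        assert est.s == est.s1

    def test_independent_torsions_nearly_uncorrected(self):
        spec = synthetic.MarkovTorsionSpec(3, 3, 20_000, coupling=0.0, seed=5)
        traj = synthetic.sample_markov_torsions(spec)
        est = conformation.mi_corrected_entropy(traj.states, seed=6)
        assert est.s == pytest.approx(est.s1, rel=0.01)

    def test_identical_torsions_reduce_to_joint_entropy(self):
        col = np.tile(np.arange(4), 2500)
        rng = np.random.default_rng(7)
        col = rng.permutation(col)
        states = np.stack([col, col], axis=1)
        est = conformation.mi_corrected_entropy(states, seed=8)
        assert est.s == pytest.approx(R_KCAL * np.log(4), rel=0.02)

    def test_entropy_bounds_invariant(self):
        rng = np.random.default_rng(9)
        states = rng.integers(0, 3, size=(500, 4))
        est = conformation.mi_corrected_entropy(states, seed=10)
        assert 0.0 <= est.s <= est.s1 <= 4 * R_KCAL * np.log(3) + 1e-15
        assert est.correction <= est.mi_raw + 1e-15

    def test_shuffle_reps_required(self):
        states = np.zeros((10, 2), dtype=int)
        with pytest.raises(ValueError, match="shuffle"):
            conformation.mi_corrected_entropy(states, shuffle_reps=0)

    def test_minus_ts_convention(self):
        states = np.tile(np.arange(3), 100)
        est = conformation.mi_corrected_entropy(states, seed=0)
        assert est.minus_t_s(300.0) == pytest.approx(
            -300.0 * R_KCAL * np.log(3), rel=1e-12
        )


class TestConvergence:
    def test_constant_series_flat_zero(self):
        traj = conformation.DiscreteTorsionTrajectory(
            times=np.arange(100) * 2.5,
            states=np.zeros((100, 1), dtype=int),
            n_states=[1],
        )
        curve = conformation.entropy_convergence(traj, n_points=5)
        assert np.all(curve.entropy == 0.0)
        assert curve.uncertainty == 0.0

    def test_well_mixed_chain_plateaus(self):
        spec = synthetic.MarkovTorsionSpec(2, 3, 20_000, seed=11)
        traj = synthetic.sample_markov_torsions(spec)
        curve = conformation.entropy_convergence(traj, n_points=10)
        assert curve.uncertainty < 0.02 * curve.plateau_value()
        assert curve.plateau_value() == pytest.approx(
            2 * R_KCAL * np.log(3), rel=0.01
        )

    def test_longer_chain_never_loses_coverage(self):
        rng = np.random.default_rng(12)
        states = rng.integers(0, 4, size=(2000, 1))
        cover = [np.unique(states[:n]).size for n in (100, 500, 2000)]
        assert cover == sorted(cover)

    def test_needs_three_grid_points(self):
        traj = conformation.DiscreteTorsionTrajectory(
            times=np.arange(10.0), states=np.zeros((10, 1), dtype=int),
            n_states=[1],
        )
        with pytest.raises(ValueError):
            conformation.entropy_convergence(traj, n_points=2)


class TestPucker:
    def test_planar_ring_undefined_phase(self):
        res = conformation.pucker_phase([0.0] * 5)
        assert not res.defined
        assert res.amplitude == 0.0
        assert np.isnan(res.phase)

    def test_known_conformer_recovered(self):
        th = synthetic.make_ring_conformer(72.0, 40.0)
        res = conformation.pucker_phase(th)
        assert res.phase == pytest.approx(72.0, abs=1e-9)
        assert res.amplitude == pytest.approx(40.0, abs=1e-9)

    def test_negating_torsions_shifts_phase_by_180(self):
        th = synthetic.make_ring_conformer(30.0, 35.0)
        res = conformation.pucker_phase(-th)
        assert res.phase == pytest.approx(210.0, abs=1e-9)

    def test_wrong_torsion_count_rejected(self):
        with pytest.raises(ValueError):
            conformation.pucker_phase([0.0] * 4)

    @settings(max_examples=50, deadline=None)
    @given(
        phase=st.floats(0.0, 359.99),
        amplitude=st.floats(1e-3, 60.0),
    )
    def test_round_trip_property(self, phase, amplitude):
        th = synthetic.make_ring_conformer(phase, amplitude)
        res = conformation.pucker_phase(th)
        circ = (res.phase - phase + 180.0) % 360.0 - 180.0
        assert abs(circ) < 1e-6
        assert res.amplitude == pytest.approx(amplitude, rel=1e-9)


class TestPuckerPopulations:
    def test_single_class(self):
        pops = conformation.pucker_populations([100.0] * 10, np.arange(10) * 2.5)
        assert pops.f_endo == 1.0 and pops.f_exo == 0.0
        assert pops.flip_rate == 0.0

    def test_alternating_every_frame(self):
        phases = [100.0, 300.0] * 50
        t = np.arange(100) * 2.5
        pops = conformation.pucker_populations(phases, t)
        assert pops.flip_rate == pytest.approx(0.4, rel=1e-6)

    def test_markov_two_state_fractions_recovered(self):
        rng = np.random.default_rng(13)
        endo = rng.random(20_000) < 0.66
        phases = np.where(endo, 180.0, 0.0)
        pops = conformation.pucker_populations(phases, np.arange(20_000) * 2.5)
        assert pops.f_endo == pytest.approx(0.66, abs=0.01)


class TestContacts:
    def geometry(self, d_ho=1.9, angle=170.0):
        """Donor D(0)-H(1) ... O(2) with prescribed H...O distance/angle."""
        h = np.array([0.0, 0.0, 0.0])
        d = np.array([-1.0, 0.0, 0.0])  # D-H along -x
        theta = np.deg2rad(180.0 - angle)
        o = h + d_ho * np.array([np.cos(theta), np.sin(theta), 0.0])
        return np.stack([d, h, o])

    def criterion(self, cutoff=2.5, angle=120.0):
        return conformation.ContactCriterion(
            label="NH...O", donor=(0, 1), acceptor=2,
            distance_cutoff=cutoff, angle_cutoff=angle, kind="polar H-bond",
        )

    def test_contact_present(self):
        flags = conformation.detect_contacts(
            self.geometry(), bonds=[(0, 1)], criteria=[self.criterion()]
        )
        assert flags[0, 0]

    def test_tight_cutoff_excludes(self):
        flags = conformation.detect_contacts(
            self.geometry(), bonds=[(0, 1)], criteria=[self.criterion(cutoff=1.5)]
        )
        assert not flags[0, 0]

    def test_angle_cutoff_excludes_bent_geometry(self):
        flags = conformation.detect_contacts(
            self.geometry(angle=90.0), bonds=[(0, 1)],
            criteria=[self.criterion()],
        )
        assert not flags[0, 0]

    def test_one_three_pair_excluded_by_bond_distance(self):
        # H(1) and O(2) separated by two bonds through D(0)
        flags = conformation.detect_contacts(
            self.geometry(), bonds=[(0, 1), (0, 2)],
            criteria=[self.criterion()],
        )
        assert not flags[0, 0]

    def test_malformed_criterion_rejected(self):
        bad = conformation.ContactCriterion("x", donor=1, acceptor=1,
                                            distance_cutoff=2.0)
        with pytest.raises(ValueError):
            conformation.detect_contacts(self.geometry(), [(0, 1)], [bad])

    def test_statistics_invariant_under_snapshot_reorder(self, rng):
        flags = rng.random((50, 4)) < 0.3
        a = conformation.contact_statistics(flags)
        b = conformation.contact_statistics(flags[rng.permutation(50)])
        assert a.n_con == b.n_con and a.p_aver == b.p_aver


class TestContactStatistics:
    def test_always_present_contact(self):
        stats = conformation.contact_statistics(np.ones((20, 1), dtype=bool))
        assert stats == stats._replace(n_con=1, p_aver=1.0, p_max=1.0)

    def test_below_threshold_excluded(self):
        flags = np.zeros((100, 1), dtype=bool)
        flags[:4, 0] = True  # 4% population
        stats = conformation.contact_statistics(flags, 0.05)
        assert stats.n_con == 0

    def test_constructed_populations(self):
        flags = np.zeros((100, 3), dtype=bool)
        flags[:50, 0] = True
        flags[:20, 1] = True
        flags[:4, 2] = True
        stats = conformation.contact_statistics(flags, 0.05)
        assert stats.n_con == 2
        assert stats.p_aver == pytest.approx(0.35)
        assert stats.p_max == pytest.approx(0.5)


class TestDescriptors:
    def test_zero_charges_zero_dipole(self):
        assert conformation.dipole_moment(np.zeros((3, 3)), np.zeros(3)) == 0.0

    def test_unit_separation_dipole(self):
        mu = conformation.dipole_moment(
            np.array([[0, 0, 0], [0, 0, 1.0]]), np.array([-1.0, 1.0])
        )
        assert mu == pytest.approx(DEBYE_PER_E_ANGSTROM)

    def test_translation_invariance_for_neutral_system(self, rng):
        xyz = rng.normal(size=(6, 3))
        q = rng.normal(size=6)
        q -= q.mean()  # neutralize
        mu1 = conformation.dipole_moment(xyz, q)
        mu2 = conformation.dipole_moment(xyz + [5.0, -2.0, 9.0], q)
        assert mu1 == pytest.approx(mu2, rel=1e-9)

    def test_rg_single_atom_zero(self):
        assert conformation.radius_of_gyration(
            np.array([[1.0, 2.0, 3.0]]), np.array([12.0])
        ) == 0.0

    def test_rg_two_equal_masses(self):
        d = 3.0
        rg = conformation.radius_of_gyration(
            np.array([[0, 0, 0], [d, 0, 0]]), np.array([1.0, 1.0])
        )
        assert rg == pytest.approx(d / 2)

    def test_rg_tetrahedron_hand_calculation(self):
        # regular tetrahedron, vertices at distance sqrt(3) from center
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float)
        rg = conformation.radius_of_gyration(v, np.ones(4))
        assert rg == pytest.approx(np.sqrt(3.0), rel=1e-12)
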