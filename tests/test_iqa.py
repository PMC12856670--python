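"""IQA regrouping: energy conservation, filtering, fragments, range splits."""

import numpy as np
import pytest

from cispro import iqa, synthetic
from cispro.constants import COULOMB_K
from conftest import random_snapshot


def single_atom_snapshot(T=10.0, V_ne=-30.0, V_coul=5.0, V_xc=-1.0,
                         solv_elec=0.0, solv_cds=0.0):
    basin = iqa.BasinTerms(["C"], [T], [V_ne], [V_coul], [V_xc], [6.0])
    solv = iqa.SolvationTerms([solv_elec], [solv_cds])
    snap = iqa.IQASnapshot(basin, iqa.PairTerms.empty(), solv, e_ref=0.0)
    snap.e_ref = iqa.total_energy(snap)
    return snap


class TestNetEnergy:
    def test_zero_terms(self):
        s = single_atom_snapshot(0, 0, 0, 0)
        assert iqa.net_energy(s.basin, 0) == 0.0

    def test_arithmetic(self):
        s = single_atom_snapshot(10.0, -30.0, 5.0, -1.0)
        assert iqa.net_energy(s.basin, 0) == pytest.approx(-16.0)

    def test_missing_atom(self):
        s = single_atom_snapshot()
        with pytest.raises(IndexError):
            iqa.net_energy(s.basin, 3)

    def test_constructed_total_reproduces_reference(self, rng):
        snap = random_snapshot(rng, n_atoms=12)
        # independent full summation: atoms + all pair terms + solvation
        total = 0.0
        for i in range(12):
            total += iqa.net_energy(snap.basin, i)
        total += snap.solvation.total.sum()
        for i in range(snap.pairs.n_pairs):
            total += (
                snap.pairs.V_nn[i] + snap.pairs.V_ne_ab[i] + snap.pairs.V_ne_ba[i]
                + snap.pairs.V_ee_coul[i] + snap.pairs.V_ee_xc[i]
                + snap.pairs.E_d3[i]
            )
        assert total == pytest.approx(snap.e_ref, rel=1e-12)


class TestPairInteraction:
    def test_zero_pair(self):
        p = iqa.PairTerms([0], [1], [0.0], [0.0], [0.0], [0.0], [0.0], [0.0])
        assert iqa.pair_interaction(p, 0, 1) == (0.0, 0.0, 0.0)

    def test_arithmetic_and_symmetry(self):
        p = iqa.PairTerms([0], [1], [50.0], [-60.0], [-55.0], [40.0], [-8.0], [0.0])
        assert iqa.pair_interaction(p, 0, 1) == pytest.approx((-33.0, -25.0, -8.0))
        assert iqa.pair_interaction(p, 1, 0) == iqa.pair_interaction(p, 0, 1)

    def test_point_charge_pair_matches_coulomb_law(self):
        # two point charges: nn/ne/ee terms of q = Z - n reduce to k qA qB / r
        z_a, z_b, n_a, n_b, r = 8.0, 1.0, 8.4, 0.7, 2.5
        k = COULOMB_K / r
        p = iqa.PairTerms(
            [0], [1],
            V_nn=[k * z_a * z_b], V_ne_ab=[-k * z_a * n_b],
            V_ne_ba=[-k * z_b * n_a], V_ee_coul=[k * n_a * n_b],
            V_ee_xc=[0.0], E_d3=[0.0],
        )
        q_a, q_b = z_a - n_a, z_b - n_b
        _, elec, xc = iqa.pair_interaction(p, 0, 1)
        assert elec == pytest.approx(COULOMB_K * q_a * q_b / r, rel=1e-12)
        assert xc == 0.0

    def test_unrecorded_pair_zero_contract(self):
        p = iqa.PairTerms([0], [1], [1.0], [0.0], [0.0], [0.0], [0.0], [0.0])
        with pytest.warns(UserWarning, match="not recorded"):
            assert iqa.pair_interaction(p, 0, 2) == (0.0, 0.0, 0.0)

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            iqa.PairTerms([0, 1], [1, 0], [1.0, 2.0], [0, 0], [0, 0],
                          [0, 0], [0, 0], [0, 0])


class TestRegroup:
    def test_single_atom_no_pairs(self):
        s = single_atom_snapshot(10.0, -30.0, 5.0, -1.0, solv_elec=-2.0,
                                 solv_cds=0.5)
        c = iqa.regroup_atomic(s)
        assert c.e_t_xc[0] == pytest.approx(9.0)  # T + V_ee,xc
        assert c.e_elec[0] == pytest.approx(-25.0)  # V_ne + V_ee,Coul
        assert c.e_d3[0] == 0.0
        assert c.e_solv[0] == pytest.approx(-1.5)

    def test_two_identical_atoms_share_pair_terms_equally(self):
        basin = iqa.BasinTerms(
            ["C", "C"], [10.0, 10.0], [-30.0, -30.0], [5.0, 5.0],
            [-1.0, -1.0], [6.0, 6.0],
        )
        pairs = iqa.PairTerms([0], [1], [12.0], [-8.0], [-8.0], [6.0],
                              [-2.0], [-0.4])
        solv = iqa.SolvationTerms([0.0, 0.0], [0.0, 0.0])
        snap = iqa.IQASnapshot(basin, pairs, solv, e_ref=0.0)
        c = iqa.regroup_atomic(snap)
        assert c.e_t_xc[0] == c.e_t_xc[1] == pytest.approx(10.0 - 1.0 - 1.0)
        assert c.e_elec[0] == c.e_elec[1] == pytest.approx(-25.0 + 0.5 * 2.0)
        assert c.e_d3[0] == c.e_d3[1] == pytest.approx(-0.2)

    def test_random_snapshot_conserves_energy(self, rng):
        snap = random_snapshot(rng, n_atoms=20)
        c = iqa.regroup_atomic(snap)
        total = iqa.total_energy(snap)
        assert abs(c.total - total) / abs(total) < 1e-9

    def test_linearity_of_decomposition(self, rng):
        a = random_snapshot(rng, n_atoms=6)
        b = random_snapshot(rng, n_atoms=6)
        summed = iqa.IQASnapshot(
            basin=iqa.BasinTerms(
                a.basin.elements, a.basin.T + b.basin.T,
                a.basin.V_ne + b.basin.V_ne,
                a.basin.V_ee_coul + b.basin.V_ee_coul,
                a.basin.V_ee_xc + b.basin.V_ee_xc,
                a.basin.n_pop + b.basin.n_pop,
            ),
            pairs=iqa.PairTerms(
                a.pairs.a, a.pairs.b,
                a.pairs.V_nn + b.pairs.V_nn,
                a.pairs.V_ne_ab + b.pairs.V_ne_ab,
                a.pairs.V_ne_ba + b.pairs.V_ne_ba,
                a.pairs.V_ee_coul + b.pairs.V_ee_coul,
                a.pairs.V_ee_xc + b.pairs.V_ee_xc,
                a.pairs.E_d3 + b.pairs.E_d3,
            ),
            solvation=iqa.SolvationTerms(
                a.solvation.e_solv_elec + b.solvation.e_solv_elec,
                a.solvation.e_solv_cds + b.solvation.e_solv_cds,
            ),
            e_ref=a.e_ref + b.e_ref,
        )
        ca, cb, cs = (iqa.regroup_atomic(s) for s in (a, b, summed))
        assert np.allclose(cs.e_t_xc, ca.e_t_xc + cb.e_t_xc, atol=1e-10)
        assert np.allclose(cs.e_elec, ca.e_elec + cb.e_elec, atol=1e-10)


class TestReconstructionError:
    def test_consistent_snapshot_has_zero_error(self, rng):
        assert iqa.reconstruction_error(random_snapshot(rng)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_injected_discrepancy_recovered(self, rng):
        snap = random_snapshot(rng)
        snap.e_ref -= 0.5
        assert iqa.reconstruction_error(snap) == pytest.approx(0.5, abs=1e-9)


class TestQuantileFilter:
    def test_zero_quantile_retains_all(self, rng):
        snaps = [random_snapshot(rng, 4) for _ in range(10)]
        assert iqa.filter_by_error_quantile(snaps, 0.0) == snaps

    def test_constructed_outliers_removed_exactly(self, rng):
        snaps = [random_snapshot(rng, 4) for _ in range(100)]
        for i in (3, 17, 44, 78, 91):
            snaps[i].e_ref += 50.0
        kept = iqa.filter_by_error_quantile(snaps, 0.05)
        assert len(kept) == 95
        assert all(abs(iqa.reconstruction_error(s)) < 1.0 for s in kept)

    def test_all_equal_errors_all_retained(self, rng):
        snaps = [random_snapshot(rng, 4) for _ in range(10)]
        for s in snaps:
            s.e_ref += 2.0
        assert len(iqa.filter_by_error_quantile(snaps, 0.3)) == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            iqa.filter_by_error_quantile([], 0.05)


class TestEnsembleDecompose:
    def test_identical_ensembles_give_zero(self, rng):
        snaps = [random_snapshot(rng, 5) for _ in range(5)]
        dec = iqa.ensemble_decompose(snaps, snaps, quantile=0.0)
        for v in (dec.d_t_xc, dec.d_elec, dec.d_d3, dec.d_solv,
                  dec.d_net, dec.d_int, dec.d_iqa_full):
            assert v == 0.0

    def test_eq15_split_is_consistent(self):
        rng = np.random.default_rng(7)
        truth = synthetic.GroundTruthDecomposition(
            d_t_xc=rng.normal(size=5), d_elec=rng.normal(size=5),
            d_d3=0.1 * rng.normal(size=5), d_solv=rng.normal(size=5),
            noise_scale=0.3,
        )
        cis, trans = synthetic.make_iqa_ensembles(truth, n_snapshots=20, seed=8)
        dec = iqa.ensemble_decompose(cis, trans, quantile=0.0)
        # atomic regrouping vs monatomic/diatomic split of the same energy
        assert dec.d_iqa_full == pytest.approx(
            dec.d_net + dec.d_solv + 0.5 * dec.d_int + dec.d_d3, abs=1e-9
        )
        assert dec.d_iqa == pytest.approx(
            dec.d_t_xc + dec.d_elec + dec.d_solv, abs=1e-12
        )

    def test_published_component_column_reproduced(self):
        """Quantum 6.1, electrostatic -8.9, solvation 1.3 give the tabulated
        subtotal -2.8 and reconstructed isomerization energy -1.5."""
        subtotal, d_iqa = iqa.component_table_subtotals(6.1, -8.9, 1.3)
        assert subtotal == pytest.approx(-2.8, abs=0.05)
        assert d_iqa == pytest.approx(-1.5, abs=0.05)

    def test_too_few_snapshots_rejected(self, rng):
        s = [random_snapshot(rng, 3)]
        with pytest.raises(ValueError, match=">= 2"):
            iqa.ensemble_decompose(s, s, quantile=0.0)


class TestFragments:
    def test_whole_molecule_fragment_equals_total(self, rng):
        snap = random_snapshot(rng, 8)
        c = iqa.regroup_atomic(snap)
        rep = iqa.fragment_aggregate(
            {"t_xc": c.e_t_xc}, snap.pairs, {"all": range(8)}
        )
        assert rep.self_terms["all"]["t_xc"] == pytest.approx(c.e_t_xc.sum())
        assert rep.inter_fragment_total == 0.0

    def test_no_cross_pairs_no_interaction(self):
        pairs = iqa.PairTerms([0], [1], [5.0], [0], [0], [0], [0], [0])
        rep = iqa.fragment_aggregate(
            {"x": np.ones(4)}, pairs, {"left": [0, 1], "right": [2, 3]}
        )
        assert rep.inter_fragment_total == 0.0

    def test_random_partition_conserves_totals(self, rng):
        snap = random_snapshot(rng, 10)
        c = iqa.regroup_atomic(snap)
        frags = {"a": [0, 3, 5], "b": [1, 2, 9], "c": [4, 6, 7, 8]}
        rep = iqa.fragment_aggregate({"elec": c.e_elec}, snap.pairs, frags)
        assert rep.grand_total("elec") == pytest.approx(c.e_elec.sum(), rel=1e-12)
        cross = sum(rep.inter_fragment.values())
        assert cross == pytest.approx(rep.inter_fragment_total, rel=1e-12)

    def test_unassigned_atom_rejected(self):
        with pytest.raises(ValueError, match="no fragment"):
            iqa.fragment_aggregate({"x": np.ones(3)}, None, {"a": [0, 1]})


class TestRangeSplit:
    def chain_snapshot(self, rng, n=4):
        snap = random_snapshot(rng, n)
        topo = iqa.MolecularTopology(n, [(i, i + 1) for i in range(n - 1)])
        return snap, topo

    def test_linear_chain_classification(self, rng):
        snap, topo = self.chain_snapshot(rng, 4)
        split = iqa.range_split(snap, topo)
        # reconstruct by hand: (0,3) is the only 1-4 pair
        idx = {(int(a), int(b)): i for i, (a, b) in
               enumerate(zip(snap.pairs.a, snap.pairs.b))}
        medium_d3 = snap.pairs.E_d3[idx[(0, 3)]]
        assert split["d3"]["medium"] == pytest.approx(medium_d3)

    def test_diatomic_has_empty_medium_class(self, rng):
        snap, topo = self.chain_snapshot(rng, 2)
        split = iqa.range_split(snap, topo)
        assert all(v["medium"] == 0.0 for v in split.values())

    def test_classes_sum_to_component_totals(self, rng):
        snap, topo = self.chain_snapshot(rng, 8)
        split = iqa.range_split(snap, topo)
        c = iqa.regroup_atomic(snap)
        for key, col in (("t_xc", c.e_t_xc), ("elec", c.e_elec),
                         ("d3", c.e_d3), ("solv", c.e_solv)):
            assert split[key]["short"] + split[key]["medium"] == pytest.approx(
                col.sum(), rel=1e-10
            )

    def test_disconnected_pair_is_medium_with_warning(self, rng):
        snap = random_snapshot(rng, 3)
        topo = iqa.MolecularTopology(3, [(0, 1)])  # atom 2 disconnected
        with pytest.warns(UserWarning, match="disconnected"):
            split = iqa.range_split(snap, topo)
        assert split["d3"]["medium"] != 0.0


class TestXcDescriptor:
    def two_group_snaps(self, xc_cis, xc_trans):
        def snap(xc):
            basin = iqa.BasinTerms(
                ["O", "C"], [0.0, 0.0], [0, 0], [0, 0], [0, 0], [8.0, 6.0]
            )
            pairs = iqa.PairTerms([0], [1], [0.0], [0], [0], [0], [xc], [0])
            return iqa.IQASnapshot(
                basin, pairs, iqa.SolvationTerms([0, 0], [0, 0]), e_ref=xc
            )
        return [snap(xc_cis)] * 2, [snap(xc_trans)] * 2

    def test_zero_terms(self):
        cis, trans = self.two_group_snaps(0.0, 0.0)
        assert iqa.carbonyl_xc_descriptor(cis, trans, [0], [1]) == 0.0

    def test_single_cross_pair(self):
        cis, trans = self.two_group_snaps(0.0, -2.0)
        assert iqa.carbonyl_xc_descriptor(cis, trans, [0], [1]) == pytest.approx(-2.0)

    def test_overlapping_selections_rejected(self):
        cis, trans = self.two_group_snaps(0.0, 0.0)
        with pytest.raises(ValueError, match="disjoint"):
            iqa.carbonyl_xc_descriptor(cis, trans, [0], [0, 1])

    def test_nested_selection_monotonicity(self, rng):
        """Adding a pair whose xc change is negative can only lower the
        descriptor: descriptor(O, C) >= descriptor(O, {C, extra})."""
        def snap(xc01, xc02):
            basin = iqa.BasinTerms(
                ["O", "C", "O"], [0] * 3, [0] * 3, [0] * 3, [0] * 3, [8, 6, 8]
            )
            pairs = iqa.PairTerms(
                [0, 0], [1, 2], [0, 0], [0, 0], [0, 0], [0, 0],
                [xc01, xc02], [0, 0],
            )
            return iqa.IQASnapshot(
                basin, pairs, iqa.SolvationTerms([0] * 3, [0] * 3),
                e_ref=xc01 + xc02,
            )
        cis = [snap(0.0, 0.0)] * 2
        trans = [snap(-1.5, -0.7)] * 2  # extra pair's change is negative
        small = iqa.carbonyl_xc_descriptor(cis, trans, [0], [1])
        large = iqa.carbonyl_xc_descriptor(cis, trans, [0], [1, 2])
        assert small >= large
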