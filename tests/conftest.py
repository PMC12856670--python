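"""Shared fixtures: seeded generators and small reusable window/snapshot sets."""

import numpy as np
import pytest

from cispro import iqa, synthetic


def random_snapshot(rng: np.random.Generator, n_atoms: int = 20) -> iqa.IQASnapshot:
    """A fully random, internally consistent IQA snapshot (E_ref exact)."""
    elements = [("C", "N", "O", "H")[i % 4] for i in range(n_atoms)]
    basin = iqa.BasinTerms(
        elements=elements,
        T=rng.normal(50, 10, n_atoms),
        V_ne=rng.normal(-150, 20, n_atoms),
        V_ee_coul=rng.normal(30, 5, n_atoms),
        V_ee_xc=rng.normal(-8, 2, n_atoms),
        n_pop=np.clip(rng.normal(6, 1, n_atoms), 0.1, None),
    )
    iu, ju = np.triu_indices(n_atoms, k=1)
    pairs = iqa.PairTerms(
        a=iu, b=ju,
        V_nn=rng.normal(0, 20, iu.size),
        V_ne_ab=rng.normal(0, 20, iu.size),
        V_ne_ba=rng.normal(0, 20, iu.size),
        V_ee_coul=rng.normal(0, 20, iu.size),
        V_ee_xc=rng.normal(-1, 0.5, iu.size),
        E_d3=rng.normal(-0.05, 0.02, iu.size),
    )
    solv = iqa.SolvationTerms(
        e_solv_elec=rng.normal(-2, 1, n_atoms),
        e_solv_cds=rng.normal(0.1, 0.05, n_atoms),
    )
    snap = iqa.IQASnapshot(basin=basin, pairs=pairs, solvation=solv, e_ref=0.0)
    snap.e_ref = iqa.total_energy(snap)
    return snap


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def double_well():
    return synthetic.default_omega_potential()


@pytest.fixture(scope="session")
def small_window_set(double_well):
    """Moderate umbrella run reused by several WHAM tests (seeded)."""
    return synthetic.sample_biased_windows(
        double_well,
        centers=synthetic.STUDY_WINDOW_CENTERS,
        force_constant=synthetic.STUDY_FORCE_CONSTANT,
        n_per_window=5000,
        seed=7,
        k_unit=synthetic.STUDY_K_UNIT,
    )
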