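"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data the analysis consumes -- biased umbrella
window series on a periodic dihedral, two-isomer IQA snapshot ensembles
whose component-wise energy differences are fixed by construction, discrete
torsion-state sequences with known entropies, and five-membered-ring
conformers of known pucker phase -- so each downstream stage can be tested
for exact parameter recovery without any molecular-dynamics or
quantum-chemistry engine.

Window sampling draws from the exact biased Boltzmann density
exp(-[U(omega) + K d(omega, omega0)^2] / RT) by inverse-CDF on a dense 0.1
degree grid.  Compared with dynamical sampling this removes autocorrelation,
so WHAM bootstrap errors are clean i.i.d. estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import R_KCAL, DEFAULT_TEMPERATURE
from .conformation import DiscreteTorsionTrajectory
from .iqa import (
    ATOMIC_NUMBERS,
    BasinTerms,
    IQASnapshot,
    PairTerms,
    SolvationTerms,
    total_energy,
)
from .wham import K_PER_RAD2, UmbrellaWindow, bias_energy

__all__ = [
    "PeriodicPotentialSpec",
    "default_omega_potential",
    "STUDY_WINDOW_CENTERS",
    "STUDY_FORCE_CONSTANT",
    "STUDY_K_UNIT",
    "sample_biased_windows",
    "GroundTruthDecomposition",
    "make_iqa_ensembles",
    "MarkovTorsionSpec",
    "sample_markov_torsions",
    "make_ring_conformer",
]


# ---------------------------------------------------------------------------
# periodic potential and biased window sampling
# ---------------------------------------------------------------------------

@dataclass
class PeriodicPotentialSpec:
    """Fourier cosine series U(w) = sum_k c_k cos(k*w + p_k), 360-periodic.

    ``fourier_cos_coefficients`` are kcal/mol per harmonic order (k = 1, 2,
    ...); ``phase_offsets`` are degrees.  Analytic isomer populations are
    computed by dense quadrature.
    """

    fourier_cos_coefficients: Sequence[float]
    phase_offsets: Sequence[float] | None = None

    def __post_init__(self):
        self.fourier_cos_coefficients = np.asarray(
            self.fourier_cos_coefficients, dtype=float
        )
        if self.phase_offsets is None:
            self.phase_offsets = np.zeros_like(self.fourier_cos_coefficients)
        else:
            self.phase_offsets = np.asarray(self.phase_offsets, dtype=float)
        if self.phase_offsets.shape != self.fourier_cos_coefficients.shape:
            raise ValueError("one phase offset per harmonic required")

    def __call__(self, omega: np.ndarray | float) -> np.ndarray | float:
        w = np.deg2rad(np.asarray(omega, dtype=float))
        u = np.zeros_like(w)
        for k, (c, p) in enumerate(
            zip(self.fourier_cos_coefficients, np.deg2rad(self.phase_offsets)), 1
        ):
            u = u + c * np.cos(k * w + p)
        if np.ndim(omega) == 0:
            return float(u)
        return u

    def analytic_populations(
        self,
        temperature: float = DEFAULT_TEMPERATURE,
        trans_interval: tuple[float, float] = (90.0, 270.0),
        n_grid: int = 100_000,
    ) -> tuple[float, float]:
        """(P_trans, P_cis) by dense midpoint quadrature of the Boltzmann weight."""
        rt = R_KCAL * temperature
        grid = (np.arange(n_grid) + 0.5) * (360.0 / n_grid)
        w = np.exp(-(self(grid) - np.min(self(grid))) / rt)
        lo, hi = trans_interval
        mask = (grid >= lo) & (grid < hi)
        p_trans = w[mask].sum() / w.sum()
        return float(p_trans), float(1.0 - p_trans)

    def analytic_delta_g(
        self,
        temperature: float = DEFAULT_TEMPERATURE,
        trans_interval: tuple[float, float] = (90.0, 270.0),
    ) -> float:
        p_t, p_c = self.analytic_populations(temperature, trans_interval)
        return float(-R_KCAL * temperature * np.log(p_t / p_c))


def default_omega_potential() -> PeriodicPotentialSpec:
    """Double-well stand-in for the amide omega free-energy surface.

    Wells at omega = 0 (cis) and 180 (trans) separated by a ~12 kcal/mol
    rotation barrier, with the trans well 1.5 kcal/mol deeper -- the
    magnitude typical of capped dipeptides.  U = 0.75 cos(w) - 6.5 cos(2w)
    up to a constant.
    """
    return PeriodicPotentialSpec(fourier_cos_coefficients=[0.75, -6.5])


# Study conditions for the umbrella runs: 120 windows at 3-degree spacing,
# harmonic bias K = 300 kcal/mol/rad^2 (unit tag explicit; see package docs).
STUDY_WINDOW_CENTERS = np.arange(120) * 3.0
STUDY_FORCE_CONSTANT = 300.0
STUDY_K_UNIT = K_PER_RAD2


def sample_biased_windows(
    spec: PeriodicPotentialSpec,
    centers: Sequence[float],
    force_constant: float,
    n_per_window: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int | None = None,
    k_unit: str = K_PER_RAD2,
    grid_step: float = 0.1,
) -> list[UmbrellaWindow]:
    """Exact biased-Boltzmann draws for each umbrella window.

    Each window's samples are inverse-CDF draws on a ``grid_step``-degree
    grid of the biased density exp(-[U + K d^2]/RT); reproducible under a
    fixed seed.
    """
    if force_constant < 0 or temperature <= 0:
        raise ValueError("force constant must be >= 0 and temperature > 0")
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    centers = np.asarray(centers, dtype=float)
    if ((centers < 0) | (centers >= 360)).any():
        raise ValueError("window centers must lie in [0, 360)")
    rng = np.random.default_rng(seed)
    rt = R_KCAL * temperature
    n_grid = int(round(360.0 / grid_step))
    edges = np.linspace(0.0, 360.0, n_grid + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    u_grid = np.asarray(spec(mids))
    windows = []
    for c in centers:
        probe = UmbrellaWindow(
            center=float(c),
            force_constant=force_constant,
            samples=np.zeros(1),
            k_unit=k_unit,
        )
        e = u_grid + np.asarray(bias_energy(mids, probe))
        w = np.exp(-(e - e.min()) / rt)
        cdf = np.concatenate([[0.0], np.cumsum(w)])
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, edges)
        windows.append(
            UmbrellaWindow(
                center=float(c),
                force_constant=force_constant,
                samples=samples,
                k_unit=k_unit,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# IQA snapshot ensembles with known component differences
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthDecomposition:
    """Per-atom cis->trans component targets for parameter-recovery tests.

    Each target array holds the intended ensemble-mean change of one
    component on each atom (kcal/mol).  ``noise_scale`` is the per-snapshot
    Gaussian sd added to the underlying raw terms; ``outlier_fraction`` of
    snapshots carry a fixed large discrepancy between the stored reference
    energy and the reconstructable IQA sum, mimicking the numerical error of
    a basin integration gone bad.
    """

    d_t_xc: np.ndarray
    d_elec: np.ndarray
    d_d3: np.ndarray
    d_solv: np.ndarray
    noise_scale: float = 0.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 50.0  # kcal/mol
    d_pop: np.ndarray | None = None  # electron-population targets (optional)

    def __post_init__(self):
        arrs = []
        for name in ("d_t_xc", "d_elec", "d_d3", "d_solv"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
            arrs.append(arr)
        if len({a.size for a in arrs}) != 1:
            raise ValueError("component targets must share the atom count")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier fraction must be in [0, 0.5)")
        if self.d_pop is None:
            self.d_pop = np.zeros_like(self.d_t_xc)
        else:
            self.d_pop = np.atleast_1d(np.asarray(self.d_pop, dtype=float))

    @property
    def n_atoms(self) -> int:
        return int(self.d_t_xc.size)

    @property
    def total(self) -> float:
        """The specified total cis->trans energy change (component sum)."""
        return float(
            self.d_t_xc.sum() + self.d_elec.sum() + self.d_d3.sum() + self.d_solv.sum()
        )

    @classmethod
    def zeros(cls, n_atoms: int, **kw) -> "GroundTruthDecomposition":
        z = np.zeros(n_atoms)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), **kw)


def _pair_matrix_for_targets(targets: np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal matrix M with 1/2 row sums equal to targets.

    Solved as a least-squares problem over the upper-triangle entries; exact
    for n >= 3 (for n = 2 only symmetric targets are representable).
    """
    n = targets.size
    if n < 2:
        if abs(targets).max(initial=0.0) > 0:
            raise ValueError("pairwise targets need at least two atoms")
        return np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    design = np.zeros((n, iu.size))
    for col, (i, j) in enumerate(zip(iu, ju)):
        design[i, col] = 0.5
        design[j, col] = 0.5
    sol, *_ = np.linalg.lstsq(design, targets, rcond=None)
    if not np.allclose(design @ sol, targets, atol=1e-10):
        raise ValueError("pairwise targets not representable for this atom count")
    m = np.zeros((n, n))
    m[iu, ju] = sol
    m[ju, iu] = sol
    return m


ELEMENT_CYCLE = ("C", "N", "O", "H")


def make_iqa_ensembles(
    truth: GroundTruthDecomposition,
    n_atoms: int | None = None,
    n_snapshots: int = 100,
    seed: int | None = None,
) -> tuple[list[IQASnapshot], list[IQASnapshot]]:
    """Construct (cis, trans) snapshot ensembles realizing the ground truth.

    Raw basin/pair/solvation terms are built so the ensemble-averaged
    regrouped component differences equal the targets up to noise/sqrt(n):
    quantum targets enter the kinetic term, electrostatic targets the
    nucleus-electron term, solvation targets the electrostatic solvation
    term, and dispersion targets are spread over pairwise D3 terms whose
    half-shares reproduce the per-atom values exactly.  The reference energy
    of each snapshot is its own reconstructable total, except for the
    designated outlier fraction which carries a fixed +``outlier_magnitude``
    discrepancy.
    """
    if n_atoms is None:
        n_atoms = truth.n_atoms
    if n_atoms != truth.n_atoms:
        raise ValueError("atom count inconsistent with the ground truth")
    if n_snapshots < 10:
        raise ValueError("need at least 10 snapshots per ensemble")
    rng = np.random.default_rng(seed)
    elements = [ELEMENT_CYCLE[i % len(ELEMENT_CYCLE)] for i in range(n_atoms)]
    z = np.array([ATOMIC_NUMBERS[e] for e in elements], dtype=float)

    # fixed per-atom baseline, shared by the two isomers
    base_T = 50.0 + 10.0 * rng.random(n_atoms)
    base_Vne = -150.0 - 20.0 * rng.random(n_atoms)
    base_coul = 30.0 + 5.0 * rng.random(n_atoms)
    base_xc = -8.0 - 2.0 * rng.random(n_atoms)
    base_solv_elec = -3.0 * rng.random(n_atoms)
    base_solv_cds = 0.2 * rng.random(n_atoms)
    base_pop = z - 0.05 * rng.standard_normal(n_atoms)
    base_pop = np.clip(base_pop, 0.1, None)

    # baseline pairwise terms over all pairs
    iu, ju = np.triu_indices(n_atoms, k=1)
    n_pairs = iu.size
    base_pairs = {
        "V_nn": 40.0 * rng.random(n_pairs),
        "V_ne_ab": -45.0 * rng.random(n_pairs),
        "V_ne_ba": -45.0 * rng.random(n_pairs),
        "V_ee_coul": 42.0 * rng.random(n_pairs),
        "V_ee_xc": -1.0 * rng.random(n_pairs),
        "E_d3": -0.05 * rng.random(n_pairs),
    }
    d3_shift = _pair_matrix_for_targets(truth.d_d3)[iu, ju] if n_pairs else np.zeros(0)

    n_out = int(round(truth.outlier_fraction * n_snapshots))

    def build(is_trans: bool) -> list[IQASnapshot]:
        out_idx = set(rng.choice(n_snapshots, size=n_out, replace=False).tolist())
        snaps = []
        for s in range(n_snapshots):
            noise = truth.noise_scale
            t = base_T + (truth.d_t_xc if is_trans else 0.0)
            vne = base_Vne + (truth.d_elec if is_trans else 0.0)
            solv_e = base_solv_elec + (truth.d_solv if is_trans else 0.0)
            pop = base_pop + (truth.d_pop if is_trans else 0.0)
            if noise > 0:
                t = t + rng.normal(0.0, noise, n_atoms)
                vne = vne + rng.normal(0.0, noise, n_atoms)
                solv_e = solv_e + rng.normal(0.0, noise, n_atoms)
            basin = BasinTerms(
                elements=list(elements),
                T=t,
                V_ne=vne,
                V_ee_coul=base_coul.copy(),
                V_ee_xc=base_xc.copy(),
                n_pop=pop,
            )
            e_d3 = base_pairs["E_d3"] + (d3_shift if is_trans else 0.0)
            if noise > 0 and n_pairs:
                e_d3 = e_d3 + rng.normal(0.0, noise / max(n_pairs, 1), n_pairs)
            pairs = (
                PairTerms(
                    a=iu.copy(),
                    b=ju.copy(),
                    V_nn=base_pairs["V_nn"].copy(),
                    V_ne_ab=base_pairs["V_ne_ab"].copy(),
                    V_ne_ba=base_pairs["V_ne_ba"].copy(),
                    V_ee_coul=base_pairs["V_ee_coul"].copy(),
                    V_ee_xc=base_pairs["V_ee_xc"].copy(),
                    E_d3=e_d3,
                )
                if n_pairs
                else PairTerms.empty()
            )
            solv = SolvationTerms(e_solv_elec=solv_e, e_solv_cds=base_solv_cds.copy())
            snap = IQASnapshot(
                basin=basin,
                pairs=pairs,
                solvation=solv,
                e_ref=0.0,
                snapshot_id=f"{'trans' if is_trans else 'cis'}-{s:04d}",
            )
            snap.e_ref = total_energy(snap)
            if s in out_idx:
                snap.e_ref -= truth.outlier_magnitude
            snaps.append(snap)
        return snaps

    return build(False), build(True)


# ---------------------------------------------------------------------------
# Markov torsion-state sequences
# ---------------------------------------------------------------------------

@dataclass
class MarkovTorsionSpec:
    """Discrete torsion-state chains with known marginal/joint entropies.

    ``coupling`` in [0, 1] is the probability that a secondary torsion copies
    the state of torsion 0 (mod its own state count); 0 gives exactly
    independent columns, 1 makes the torsions deterministic copies.
    ``persistence`` adds first-order memory to torsion 0's chain via
    T = (1 - p) * pi + p * I, which preserves the stationary distribution.
    """

    n_torsions: int
    n_states: int | Sequence[int]
    chain_length: int
    stationary: Sequence[np.ndarray] | None = None
    coupling: float = 0.0
    persistence: float = 0.0
    seed: int | None = None
    time_step: float = 2.5  # ps between frames

    def __post_init__(self):
        if np.isscalar(self.n_states):
            self.n_states = [int(self.n_states)] * self.n_torsions
        else:
            self.n_states = [int(m) for m in self.n_states]
        if len(self.n_states) != self.n_torsions:
            raise ValueError("one state count per torsion required")
        if self.stationary is None:
            self.stationary = [np.full(m, 1.0 / m) for m in self.n_states]
        else:
            self.stationary = [np.asarray(p, dtype=float) for p in self.stationary]
        for p, m in zip(self.stationary, self.n_states):
            if p.size != m or (p < 0).any() or p.sum() <= 0:
                raise ValueError("unnormalizable stationary distribution")
        self.stationary = [p / p.sum() for p in self.stationary]
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")


def sample_markov_torsions(spec: MarkovTorsionSpec) -> DiscreteTorsionTrajectory:
    """Stationary ergodic sampling of the torsion-state model."""
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_torsions, spec.chain_length
    states = np.empty((length, n), dtype=int)
    # torsion 0: (possibly persistent) Markov chain at stationarity
    p0 = spec.stationary[0]
    m0 = spec.n_states[0]
    s = rng.choice(m0, p=p0)
    fresh = rng.random(length) >= spec.persistence
    draws = rng.choice(m0, size=length, p=p0)
    for t in range(length):
        if fresh[t]:
            s = draws[t]
        states[t, 0] = s
    # secondary torsions: copy torsion 0 with probability `coupling`
    for j in range(1, n):
        m = spec.n_states[j]
        own = rng.choice(m, size=length, p=spec.stationary[j])
        copy = rng.random(length) < spec.coupling
        states[:, j] = np.where(copy, states[:, 0] % m, own)
    times = np.arange(length) * spec.time_step
    return DiscreteTorsionTrajectory(
        times=times, states=states, n_states=list(spec.n_states)
    )


# ---------------------------------------------------------------------------
# ring conformers of known pucker phase
# ---------------------------------------------------------------------------

def make_ring_conformer(phase: float, amplitude: float) -> np.ndarray:
    """Five endocyclic torsions of a pseudorotating five-membered ring.

    theta_j = amplitude * cos(phase + 4*pi*j/5), all in degrees.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    j = np.arange(5)
    return amplitude * np.cos(np.deg2rad(phase) + 4.0 * np.pi * j / 5.0)
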