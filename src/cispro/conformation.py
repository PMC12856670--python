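"""Torsion discretization, conformational entropy, ring pucker and contacts.

Conformational entropy of a trajectory is estimated from discretized torsion
states: the first-order term sums -R sum_s p_s ln p_s over torsions, and
inter-torsion correlation is removed at pairwise order by subtracting mutual
information terms, each bias-corrected against a shuffled null (shuffling a
column destroys correlation but keeps the marginals, so the mean shuffled MI
estimates the finite-sampling bias).  Plotting the entropy against growing
trajectory prefixes gives a convergence curve whose final spread is the
limiting uncertainty.

Ring pucker of the five-membered prolyl ring is parameterized by the
pseudorotation relation theta_j = A cos(P + 4 pi j / 5) over the five
endocyclic torsions; the phase P classifies Cgamma-endo vs Cgamma-exo
conformers.  Noncovalent contacts are detected by geometric criteria
(distance and optional donor-H-acceptor angle), excluding 1-2 and 1-3
bonded pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import networkx as nx
import numpy as np

from .constants import R_KCAL, DEBYE_PER_E_ANGSTROM, DEFAULT_TEMPERATURE

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45,
}

__all__ = [
    "DiscreteTorsionTrajectory",
    "discretize",
    "first_order_entropy",
    "mutual_information",
    "EntropyEstimate",
    "mi_corrected_entropy",
    "entropy_convergence",
    "ConvergenceCurve",
    "PuckerResult",
    "pucker_phase",
    "PuckerPopulations",
    "pucker_populations",
    "ContactCriterion",
    "detect_contacts",
    "ContactStats",
    "contact_statistics",
    "dipole_moment",
    "radius_of_gyration",
]


@dataclass
class DiscreteTorsionTrajectory:
    """Integer state series per torsion with time stamps (ps)."""

    times: np.ndarray
    states: np.ndarray  # (n_frames, n_torsions)
    n_states: list[int]
    boundaries: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=int))
        if self.states.shape[0] != self.times.size:
            raise ValueError("one state row per time stamp required")
        for j, m in enumerate(self.n_states):
            col = self.states[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) >= m:
                raise ValueError(f"states of torsion {j} outside [0, {m})")

    @property
    def n_frames(self) -> int:
        return int(self.states.shape[0])

    @property
    def n_torsions(self) -> int:
        return int(self.states.shape[1])


def discretize(angles: np.ndarray, boundaries: Sequence[float]) -> np.ndarray:
    """Bin angles (degrees) into states by periodic boundaries.

    ``boundaries`` are sorted state-opening angles in [0, 360); state k spans
    [b_k, b_{k+1}) with the last state wrapping through 360 back to b_0.
    """
    b = np.asarray(sorted(boundaries), dtype=float)
    if b.size == 0:
        raise ValueError("at least one boundary required")
    a = np.asarray(angles, dtype=float) % 360.0
    idx = np.searchsorted(b, a, side="right") - 1
    idx = np.where(idx < 0, b.size - 1, idx)  # below b_0 wraps to the last state
    return idx.astype(int)


def _entropy_nats(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def first_order_entropy(states: np.ndarray, gas_constant: float = R_KCAL) -> float:
    """First-order conformational entropy: -R sum p ln p, summed over torsions.

    Units follow ``gas_constant`` (kcal/mol/K by default).
    """
    s2d = np.atleast_2d(np.asarray(states, dtype=int))
    if s2d.shape[0] == 1 and np.asarray(states).ndim == 1:
        s2d = s2d.T
    if s2d.size == 0:
        raise ValueError("empty state series")
    total = 0.0
    for j in range(s2d.shape[1]):
        _, counts = np.unique(s2d[:, j], return_counts=True)
        total += _entropy_nats(counts)
    return gas_constant * total


def mutual_information(
    x: np.ndarray, y: np.ndarray, gas_constant: float = R_KCAL
) -> float:
    """Empirical mutual information of two state series, in entropy units."""
    _, cx = np.unique(x, return_counts=True)
    _, cy = np.unique(y, return_counts=True)
    joint = np.unique(np.stack([x, y], axis=1), axis=0, return_counts=True)[1]
    mi = _entropy_nats(cx) + _entropy_nats(cy) - _entropy_nats(joint)
    return gas_constant * mi


@dataclass
class EntropyEstimate:
    """Conformational entropy with pairwise-correlation correction.

    All entropies in kcal/mol/K.  ``correction`` is the bias-corrected,
    non-negative sum of pairwise mutual informations removed from the
    first-order term.
    """

    s1: float
    mi_raw: float
    mi_bias: float
    correction: float
    s: float

    def minus_t_s(self, temperature: float = DEFAULT_TEMPERATURE) -> float:
        """-T*S in kcal/mol at the stated temperature."""
        return -temperature * self.s


def mi_corrected_entropy(
    states: np.ndarray,
    shuffle_reps: int = 20,
    seed: int | None = None,
    gas_constant: float = R_KCAL,
) -> EntropyEstimate:
    """Order-2 entropy: S = sum_j S1_j - sum_{j<k} max(0, MI_jk - null_jk).

    Each pairwise mutual information is reduced by the mean MI of
    ``shuffle_reps`` column-shuffled replicas (finite-sampling bias) and
    floored at zero, so the corrected entropy never exceeds the first-order
    value and never goes negative (floored with a warning).
    """
    s2d = np.atleast_2d(np.asarray(states, dtype=int))
    if s2d.shape[0] == 1 and np.asarray(states).ndim == 1:
        s2d = s2d.T
    n_torsions = s2d.shape[1]
    s1 = first_order_entropy(s2d, gas_constant)
    if n_torsions < 2:
        return EntropyEstimate(s1=s1, mi_raw=0.0, mi_bias=0.0, correction=0.0, s=s1)
    if shuffle_reps < 1:
        raise ValueError("shuffle_reps must be >= 1 when correction applies")
    rng = np.random.default_rng(seed)
    mi_raw = 0.0
    mi_bias = 0.0
    correction = 0.0
    for j in range(n_torsions):
        for k in range(j + 1, n_torsions):
            mi = mutual_information(s2d[:, j], s2d[:, k], gas_constant)
            null = np.mean(
                [
                    mutual_information(
                        rng.permutation(s2d[:, j]), s2d[:, k], gas_constant
                    )
                    for _ in range(shuffle_reps)
                ]
            )
            mi_raw += mi
            mi_bias += null
            correction += max(0.0, mi - null)
    s = s1 - correction
    if s < 0:
        warnings.warn("corrected entropy fell below zero; floored", stacklevel=2)
        s = 0.0
    return EntropyEstimate(
        s1=s1, mi_raw=mi_raw, mi_bias=mi_bias, correction=correction, s=s
    )


@dataclass
class ConvergenceCurve:
    """Entropy of growing trajectory prefixes and its limiting uncertainty."""

    times: np.ndarray  # ps, prefix end times
    entropy: np.ndarray  # kcal/mol/K
    uncertainty: float  # spread (max - min) over the final segment

    def plateau_value(self) -> float:
        return float(self.entropy[-1])


def entropy_convergence(
    traj: DiscreteTorsionTrajectory,
    n_points: int = 10,
    estimator: Callable[[np.ndarray], float] | None = None,
    final_fraction: float = 0.25,
) -> ConvergenceCurve:
    """Entropy as a function of simulation time, over prefix subsamples.

    ``estimator`` maps a state block to an entropy (default: first-order);
    the limiting uncertainty is the spread over the final ``final_fraction``
    of grid points.
    """
    if n_points < 3:
        raise ValueError("need at least 3 grid points")
    if estimator is None:
        estimator = first_order_entropy
    ends = np.unique(
        np.linspace(1, traj.n_frames, n_points).round().astype(int)
    )
    s_vals = np.array([estimator(traj.states[:e]) for e in ends])
    t_vals = traj.times[ends - 1]
    n_final = max(2, int(np.ceil(final_fraction * ends.size)))
    tail = s_vals[-n_final:]
    return ConvergenceCurve(
        times=t_vals, entropy=s_vals, uncertainty=float(tail.max() - tail.min())
    )


# ---------------------------------------------------------------------------
# ring pucker
# ---------------------------------------------------------------------------

class PuckerResult(NamedTuple):
    phase: float  # degrees in [0, 360); nan when undefined
    amplitude: float  # degrees, >= 0
    defined: bool


_PUCKER_J = 4.0 * np.pi * np.arange(5) / 5.0


def pucker_phase(
    torsions: Sequence[float], planar_threshold: float = 1e-9
) -> PuckerResult:
    """Least-squares pseudorotation fit theta_j = A cos(P + 4 pi j / 5).

    The cosine/sine basis over the five ring torsions is orthogonal, so the
    fit is closed-form.  Rings with amplitude below ``planar_threshold`` are
    planar and their phase is flagged undefined.
    """
    th = np.asarray(torsions, dtype=float)
    if th.shape != (5,):
        raise ValueError("exactly five endocyclic torsions required")
    a = (2.0 / 5.0) * float(np.sum(th * np.cos(_PUCKER_J)))
    b = (2.0 / 5.0) * float(np.sum(th * np.sin(_PUCKER_J)))
    amplitude = float(np.hypot(a, b))
    if amplitude < planar_threshold:
        return PuckerResult(phase=float("nan"), amplitude=amplitude, defined=False)
    phase = float(np.rad2deg(np.arctan2(-b, a)) % 360.0)
    return PuckerResult(phase=phase, amplitude=amplitude, defined=True)


class PuckerPopulations(NamedTuple):
    f_endo: float
    f_exo: float
    flip_rate: float  # ps^-1
    n_flips: int


def pucker_populations(
    phases: Sequence[float],
    times: Sequence[float],
    endo_interval: tuple[float, float] = (90.0, 270.0),
) -> PuckerPopulations:
    """Endo/exo fractions and flip rate of a pucker-phase time series.

    A frame is endo when its phase falls inside ``endo_interval`` (a
    configurable convention); flips are crossings between the two classes,
    and the rate is flips per unit simulation time.
    """
    p = np.asarray(phases, dtype=float) % 360.0
    t = np.asarray(times, dtype=float)
    if p.size != t.size:
        raise ValueError("one time stamp per phase required")
    lo, hi = endo_interval
    if lo <= hi:
        endo = (p >= lo) & (p < hi)
    else:
        endo = (p >= lo) | (p < hi)
    f_endo = float(endo.mean())
    flips = int(np.sum(endo[1:] != endo[:-1]))
    span = float(t[-1] - t[0]) if t.size > 1 else 0.0
    rate = flips / span if span > 0 else 0.0
    return PuckerPopulations(
        f_endo=f_endo, f_exo=1.0 - f_endo, flip_rate=rate, n_flips=flips
    )


# ---------------------------------------------------------------------------
# geometric contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactCriterion:
    """Geometric stand-in for a noncovalent-contact detector.

    ``donor`` is either the probe atom index or a (donor-heavy-atom,
    hydrogen) pair; the distance is measured from the hydrogen (or the probe
    atom) to the acceptor, and the optional angle cutoff applies to the
    donor-H...acceptor angle in degrees.
    """

    label: str
    donor: int | tuple[int, int]
    acceptor: int
    distance_cutoff: float  # Angstrom
    angle_cutoff: float | None = None  # degrees, minimum D-H...A angle
    kind: str = ""  # e.g. polar H-bond, CH...O, CH...HC, salt bridge

    def probe_atom(self) -> int:
        return self.donor[1] if isinstance(self.donor, tuple) else self.donor

    def validate(self):
        if self.distance_cutoff <= 0:
            raise ValueError(f"criterion {self.label!r}: non-positive cutoff")
        if self.angle_cutoff is not None and isinstance(self.donor, int):
            raise ValueError(
                f"criterion {self.label!r}: angle cutoff needs a (donor, H) pair"
            )
        if self.probe_atom() == self.acceptor:
            raise ValueError(f"criterion {self.label!r}: probe equals acceptor")


def detect_contacts(
    coordinates: np.ndarray,
    bonds: Sequence[tuple[int, int]],
    criteria: Sequence[ContactCriterion],
) -> np.ndarray:
    """Per-snapshot presence flags for each contact criterion.

    ``coordinates`` is (n_frames, n_atoms, 3) or (n_atoms, 3), in Angstrom.
    Pairs separated by fewer than 3 bonds on the covalent graph (1-2 and
    1-3) are never counted as contacts.
    """
    xyz = np.asarray(coordinates, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    n_atoms = xyz.shape[1]
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from(bonds)
    flags = np.zeros((xyz.shape[0], len(criteria)), dtype=bool)
    for c_idx, crit in enumerate(criteria):
        crit.validate()
        probe = crit.probe_atom()
        try:
            bond_dist = nx.shortest_path_length(g, probe, crit.acceptor)
        except nx.NetworkXNoPath:
            bond_dist = None
        if bond_dist is not None and bond_dist < 3:
            continue  # 1-2 / 1-3 exclusion
        vec = xyz[:, crit.acceptor] - xyz[:, probe]
        dist = np.linalg.norm(vec, axis=1)
        ok = dist <= crit.distance_cutoff
        if crit.angle_cutoff is not None:
            d_heavy = crit.donor[0]
            u = xyz[:, d_heavy] - xyz[:, probe]  # H -> D
            v = vec  # H -> A
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * dist
            )
            ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok &= ang >= crit.angle_cutoff
        flags[:, c_idx] = ok
    return flags


class ContactStats(NamedTuple):
    n_con: int
    p_aver: float
    p_max: float
    populations: np.ndarray  # per criterion, all of them


def contact_statistics(
    flags: np.ndarray, population_threshold: float = 0.05
) -> ContactStats:
    """Count contacts with population above the threshold; mean/max over them."""
    f = np.atleast_2d(np.asarray(flags, dtype=bool))
    if f.shape[0] < 1:
        raise ValueError("at least one snapshot required")
    pops = f.mean(axis=0)
    counted = pops > population_threshold
    n_con = int(counted.sum())
    p_aver = float(pops[counted].mean()) if n_con else 0.0
    p_max = float(pops.max()) if pops.size else 0.0
    return ContactStats(n_con=n_con, p_aver=p_aver, p_max=p_max, populations=pops)


# ---------------------------------------------------------------------------
# simple structural descriptors
# ---------------------------------------------------------------------------

def dipole_moment(
    coordinates: np.ndarray,
    charges: np.ndarray,
    masses: np.ndarray | None = None,
) -> float:
    """|sum q_i r_i| in Debye from point charges at Angstrom coordinates.

    Origin-independent only for neutral systems; charged systems are
    referred to the center of mass (or geometric center if no masses).
    """
    xyz = np.asarray(coordinates, dtype=float)
    q = np.asarray(charges, dtype=float)
    if abs(q.sum()) > 1e-9:
        if masses is not None:
            m = np.asarray(masses, dtype=float)
            origin = (m[:, None] * xyz).sum(axis=0) / m.sum()
        else:
            origin = xyz.mean(axis=0)
        xyz = xyz - origin
    mu = (q[:, None] * xyz).sum(axis=0)
    return float(np.linalg.norm(mu) * DEBYE_PER_E_ANGSTROM)


def radius_of_gyration(coordinates: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the center of mass, Angstrom."""
    xyz = np.asarray(coordinates, dtype=float)
    m = np.asarray(masses, dtype=float)
    if m.sum() <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    d2 = ((xyz - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))
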