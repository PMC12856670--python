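"""Interacting-quantum-atoms (IQA) data model and energy regrouping.

An IQA decomposition writes the total energy of a molecule as a sum of
atomic net energies and pairwise interaction energies over atomic basins,

    E = sum_A [ E_net^A + E_solv^A + 1/2 sum_{B!=A} (E_int^AB + E_D3^AB) ]

with E_net^A = T^A + V_ne^A + V_ee,Coul^A + V_ee,xc^A and
E_int^AB = V_nn^AB + V_ne^AB + V_ne^BA + V_ee,Coul^AB + V_ee,xc^AB.
Splitting the pair density into Coulomb and exchange-correlation parts
separates each pair term into a classical electrostatic piece and a quantum
(xc) piece, and the whole energy regroups exactly into four additive atomic
components -- quantum (kinetic + xc), electrostatic, dispersion, solvation:

    E_T,xc^A = T^A + V_ee,xc^A + 1/2 sum_B V_ee,xc^AB
    E_elec^A = V_ne^A + V_ee,Coul^A
               + 1/2 sum_B (V_nn + V_ne^AB + V_ne^BA + V_ee,Coul)^AB
    E_D3^A   = 1/2 sum_B E_D3^AB
    E_solv^A = E_solv,elec^A + E_solv,CDS^A

Every pairwise term is shared half-and-half between its two atoms, so the
four columns sum back to the total exactly (checked to 1e-9 relative).

Ensemble analysis of cis->trans isomerization averages these components over
snapshot ensembles of each isomer, after discarding the snapshots whose
IQA-reconstruction error falls in the worst 5% quantile, and reports
component-wise <trans> - <cis> differences with standard errors (sd/sqrt(n),
snapshots treated as independent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
}

__all__ = [
    "ATOMIC_NUMBERS",
    "BasinTerms",
    "PairTerms",
    "SolvationTerms",
    "IQASnapshot",
    "AtomicComponents",
    "EnsembleDecomposition",
    "MolecularTopology",
    "net_energy",
    "pair_interaction",
    "total_energy",
    "regroup_atomic",
    "reconstruction_error",
    "filter_by_error_quantile",
    "ensemble_decompose",
    "component_table_subtotals",
    "fragment_aggregate",
    "FragmentReport",
    "ensemble_fragment_aggregate",
    "range_split",
    "carbonyl_xc_descriptor",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class BasinTerms:
    """Per-atom basin energies and electron populations.

    All energies kcal/mol; ``n_pop`` in electrons.  The QTAIM charge is
    q_A = Z_A - n_A given the element.
    """

    elements: list[str]
    T: np.ndarray  # kinetic
    V_ne: np.ndarray  # nucleus-electron attraction within the basin
    V_ee_coul: np.ndarray  # intra-basin electron-electron Coulomb
    V_ee_xc: np.ndarray  # intra-basin exchange-correlation
    n_pop: np.ndarray  # electron population

    def __post_init__(self):
        n = len(self.elements)
        for name in ("T", "V_ne", "V_ee_coul", "V_ee_xc", "n_pop"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per atom")
            setattr(self, name, arr)
        if (self.n_pop < 0).any():
            raise ValueError("electron populations must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def charges(self) -> np.ndarray:
        z = np.array([ATOMIC_NUMBERS[e] for e in self.elements], dtype=float)
        return z - self.n_pop

    @property
    def net(self) -> np.ndarray:
        """E_net per atom."""
        return self.T + self.V_ne + self.V_ee_coul + self.V_ee_xc


PAIR_FIELDS = ("V_nn", "V_ne_ab", "V_ne_ba", "V_ee_coul", "V_ee_xc", "E_d3")


@dataclass
class PairTerms:
    """Pairwise interaction terms, stored once per unordered pair (a < b).

    Missing pairs are an exact zero interaction (sparse-storage contract).
    """

    a: np.ndarray  # atom indices
    b: np.ndarray
    V_nn: np.ndarray
    V_ne_ab: np.ndarray  # nucleus of a with electrons of b
    V_ne_ba: np.ndarray
    V_ee_coul: np.ndarray
    V_ee_xc: np.ndarray
    E_d3: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=int)
        self.b = np.asarray(self.b, dtype=int)
        m = self.a.size
        for name in PAIR_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have one entry per pair")
            setattr(self, name, arr)
        if (self.a == self.b).any():
            raise ValueError("self pairs are not allowed")
        # normalize to a < b, swapping the directed V_ne terms
        swap = self.a > self.b
        if swap.any():
            self.a[swap], self.b[swap] = self.b[swap], self.a[swap].copy()
            tmp = self.V_ne_ab[swap].copy()
            self.V_ne_ab[swap] = self.V_ne_ba[swap]
            self.V_ne_ba[swap] = tmp
        keys = set(zip(self.a.tolist(), self.b.tolist()))
        if len(keys) != m:
            raise ValueError("duplicate pair entries")
        self._index = {k: i for i, k in enumerate(zip(self.a, self.b))}

    @property
    def n_pairs(self) -> int:
        return int(self.a.size)

    @property
    def E_int(self) -> np.ndarray:
        return self.V_nn + self.V_ne_ab + self.V_ne_ba + self.V_ee_coul + self.V_ee_xc

    @property
    def E_int_elec(self) -> np.ndarray:
        return self.V_nn + self.V_ne_ab + self.V_ne_ba + self.V_ee_coul

    def half_sums(self, n_atoms: int, values: np.ndarray) -> np.ndarray:
        """Per-atom half shares: out[A] = 1/2 sum over pairs containing A."""
        out = np.zeros(n_atoms)
        np.add.at(out, self.a, 0.5 * values)
        np.add.at(out, self.b, 0.5 * values)
        return out

    @classmethod
    def empty(cls) -> "PairTerms":
        z = np.zeros(0)
        return cls(z.astype(int), z.astype(int), z, z, z, z, z, z)


@dataclass
class SolvationTerms:
    """Per-atom continuum-solvation terms (electrostatic + CDS), kcal/mol."""

    e_solv_elec: np.ndarray
    e_solv_cds: np.ndarray

    def __post_init__(self):
        self.e_solv_elec = np.asarray(self.e_solv_elec, dtype=float)
        self.e_solv_cds = np.asarray(self.e_solv_cds, dtype=float)
        if self.e_solv_elec.shape != self.e_solv_cds.shape:
            raise ValueError("solvation arrays must share a shape")
        if not (
            np.isfinite(self.e_solv_elec).all() and np.isfinite(self.e_solv_cds).all()
        ):
            raise ValueError("solvation terms must be finite")

    @property
    def total(self) -> np.ndarray:
        return self.e_solv_elec + self.e_solv_cds


@dataclass
class IQASnapshot:
    """All IQA terms for one structure, plus the reference total energy."""

    basin: BasinTerms
    pairs: PairTerms
    solvation: SolvationTerms
    e_ref: float
    snapshot_id: str = ""

    def __post_init__(self):
        n = self.basin.n_atoms
        if self.solvation.e_solv_elec.size != n:
            raise ValueError("solvation table does not match the atom set")
        if self.pairs.n_pairs and int(self.pairs.b.max()) >= n:
            raise ValueError("pair table references atoms outside the basin table")

    @property
    def n_atoms(self) -> int:
        return self.basin.n_atoms


@dataclass
class AtomicComponents:
    """Four-component additive atomic energies of one snapshot."""

    e_t_xc: np.ndarray
    e_elec: np.ndarray
    e_d3: np.ndarray
    e_solv: np.ndarray

    @property
    def total(self) -> float:
        return float(
            self.e_t_xc.sum() + self.e_elec.sum() + self.e_d3.sum() + self.e_solv.sum()
        )

    def per_atom_total(self) -> np.ndarray:
        return self.e_t_xc + self.e_elec + self.e_d3 + self.e_solv


@dataclass
class MolecularTopology:
    """Covalent bond graph plus an optional fragment partition of the atoms."""

    n_atoms: int
    bonds: list[tuple[int, int]]
    fragments: dict[str, list[int]] = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def validate_fragments(self):
        assigned = [i for atoms in self.fragments.values() for i in atoms]
        if sorted(assigned) != list(range(self.n_atoms)):
            raise ValueError("fragments must partition the atom set")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def net_energy(basin: BasinTerms, atom: int) -> float:
    """Net electronic energy of one atom: T + V_ne + V_ee,Coul + V_ee,xc."""
    if not 0 <= atom < basin.n_atoms:
        raise IndexError(f"atom {atom} not present")
    return float(basin.net[atom])


def pair_interaction(pairs: PairTerms, a: int, b: int) -> tuple[float, float, float]:
    """(E_int, E_int,elec, E_int,xc) for an unordered pair, symmetric in (a, b).

    Unrecorded pairs return (0, 0, 0) with a warning (sparse contract).
    """
    key = (min(a, b), max(a, b))
    idx = pairs._index.get(key)
    if idx is None:
        warnings.warn(f"pair {key} not recorded; treated as zero", stacklevel=2)
        return 0.0, 0.0, 0.0
    elec = float(pairs.E_int_elec[idx])
    xc = float(pairs.V_ee_xc[idx])
    return elec + xc, elec, xc


def total_energy(snapshot: IQASnapshot) -> float:
    """Full IQA total: sum_A E_net + E_solv + pairwise (E_int + E_D3)."""
    p = snapshot.pairs
    return float(
        snapshot.basin.net.sum()
        + snapshot.solvation.total.sum()
        + p.E_int.sum()
        + p.E_d3.sum()
    )


def regroup_atomic(snapshot: IQASnapshot) -> AtomicComponents:
    """Regroup basin/pair/solvation terms into the four atomic components."""
    basin = snapshot.basin
    p = snapshot.pairs
    n = basin.n_atoms
    e_t_xc = basin.T + basin.V_ee_xc + p.half_sums(n, p.V_ee_xc)
    e_elec = basin.V_ne + basin.V_ee_coul + p.half_sums(n, p.E_int_elec)
    e_d3 = p.half_sums(n, p.E_d3)
    e_solv = snapshot.solvation.total
    return AtomicComponents(e_t_xc=e_t_xc, e_elec=e_elec, e_d3=e_d3, e_solv=e_solv)


def reconstruction_error(snapshot: IQASnapshot) -> float:
    """Signed numerical error of the decomposition: E_IQA - E_ref."""
    return total_energy(snapshot) - snapshot.e_ref


def filter_by_error_quantile(
    snapshots: Sequence[IQASnapshot], quantile: float = 0.05
) -> list[IQASnapshot]:
    """Discard snapshots whose |reconstruction error| is in the worst quantile.

    Errors strictly above the empirical (1 - quantile) quantile of |error|
    are removed; ties are retained, and at least one snapshot survives.
    """
    if not snapshots:
        raise ValueError("no snapshots to filter")
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    if quantile == 0:
        return list(snapshots)
    errs = np.abs([reconstruction_error(s) for s in snapshots])
    cutoff = np.quantile(errs, 1.0 - quantile)
    kept = [s for s, e in zip(snapshots, errs) if e <= cutoff]
    return kept if kept else [snapshots[int(np.argmin(errs))]]


# ---------------------------------------------------------------------------
# ensemble averaging and the isomerization decomposition
# ---------------------------------------------------------------------------

def _component_scalars(snapshot: IQASnapshot) -> dict[str, float]:
    comp = regroup_atomic(snapshot)
    p = snapshot.pairs
    return {
        "t_xc": float(comp.e_t_xc.sum()),
        "elec": float(comp.e_elec.sum()),
        "d3": float(comp.e_d3.sum()),
        "solv": float(comp.e_solv.sum()),
        "net": float(snapshot.basin.net.sum()),
        # double-counted interaction sum, as in 1/2 sum_A sum_{B!=A}
        "int": float(2.0 * p.E_int.sum()),
        "ref": float(snapshot.e_ref),
    }


@dataclass
class EnsembleDecomposition:
    """Ensemble-averaged cis->trans component differences with uncertainties.

    ``d_iqa`` excludes dispersion (the quantum + electrostatic + solvation
    reconstruction, as tabulated); ``d_iqa_full`` adds dispersion.  ``d_int``
    is the double-counted interaction sum so the atomistic split reads
    d_iqa_full = d_net + d_solv + d_int/2 + d_d3.
    """

    d_t_xc: float
    d_elec: float
    d_d3: float
    d_solv: float
    d_net: float
    d_int: float
    d_ref: float
    se: dict[str, float]
    n_cis: int
    n_trans: int
    d_atomic: dict[str, np.ndarray]  # per-atom <trans> - <cis> by component
    d_net_atomic: np.ndarray
    d_pop_atomic: np.ndarray  # electron-population change per atom

    @property
    def d_subtotal(self) -> float:
        """Quantum + electrostatic subtotal (the steric/electronic balance)."""
        return self.d_t_xc + self.d_elec

    @property
    def d_iqa(self) -> float:
        """Reconstructed isomerization energy excluding dispersion."""
        return self.d_t_xc + self.d_elec + self.d_solv

    @property
    def d_iqa_full(self) -> float:
        return self.d_iqa + self.d_d3


def _ensemble_stats(snapshots: Sequence[IQASnapshot]):
    scalars = [_component_scalars(s) for s in snapshots]
    keys = scalars[0].keys()
    series = {k: np.array([s[k] for s in scalars]) for k in keys}
    comps = [regroup_atomic(s) for s in snapshots]
    atomic = {
        "t_xc": np.mean([c.e_t_xc for c in comps], axis=0),
        "elec": np.mean([c.e_elec for c in comps], axis=0),
        "d3": np.mean([c.e_d3 for c in comps], axis=0),
        "solv": np.mean([c.e_solv for c in comps], axis=0),
    }
    net = np.mean([s.basin.net for s in snapshots], axis=0)
    pop = np.mean([s.basin.n_pop for s in snapshots], axis=0)
    return series, atomic, net, pop


def ensemble_decompose(
    cis: Sequence[IQASnapshot],
    trans: Sequence[IQASnapshot],
    quantile: float = 0.05,
) -> EnsembleDecomposition:
    """Component-wise <trans> - <cis> decomposition of the isomerization energy.

    Each ensemble is error-filtered independently before differencing.
    Standard errors combine the two ensembles as sqrt(se_cis^2 + se_trans^2)
    with se = sd/sqrt(n) per ensemble.
    """
    cis_f = filter_by_error_quantile(cis, quantile)
    trans_f = filter_by_error_quantile(trans, quantile)
    if len(cis_f) < 2 or len(trans_f) < 2:
        raise ValueError("need >= 2 snapshots per ensemble after filtering")
    if cis_f[0].n_atoms != trans_f[0].n_atoms:
        raise ValueError("cis and trans ensembles have mismatched atom sets")
    s_cis, a_cis, net_cis, pop_cis = _ensemble_stats(cis_f)
    s_trans, a_trans, net_trans, pop_trans = _ensemble_stats(trans_f)
    se = {}
    d = {}
    for k in s_cis:
        d[k] = float(s_trans[k].mean() - s_cis[k].mean())
        se[k] = float(
            np.sqrt(
                np.var(s_cis[k], ddof=1) / len(cis_f)
                + np.var(s_trans[k], ddof=1) / len(trans_f)
            )
        )
    return EnsembleDecomposition(
        d_t_xc=d["t_xc"],
        d_elec=d["elec"],
        d_d3=d["d3"],
        d_solv=d["solv"],
        d_net=d["net"],
        d_int=d["int"],
        d_ref=d["ref"],
        se=se,
        n_cis=len(cis_f),
        n_trans=len(trans_f),
        d_atomic={k: a_trans[k] - a_cis[k] for k in a_cis},
        d_net_atomic=net_trans - net_cis,
        d_pop_atomic=pop_trans - pop_cis,
    )


def component_table_subtotals(
    d_t_xc: float, d_elec: float, d_solv: float
) -> tuple[float, float]:
    """Aggregate printed component rows into the tabulated subtotals.

    Returns (quantum+electrostatic subtotal, reconstructed isomerization
    energy excluding dispersion) -- the two derived rows of a component
    table.
    """
    subtotal = d_t_xc + d_elec
    return subtotal, subtotal + d_solv


# ---------------------------------------------------------------------------
# fragment aggregation and range splitting
# ---------------------------------------------------------------------------

@dataclass
class FragmentReport:
    """Fragment-resolved sums of atomic values plus inter-fragment terms."""

    self_terms: dict[str, dict[str, float]]  # fragment -> value name -> sum
    inter_fragment: dict[tuple[str, str], float]  # (frag_i, frag_j) -> elec+xc
    inter_fragment_total: float

    def grand_total(self, name: str) -> float:
        return sum(v[name] for v in self.self_terms.values())


def fragment_aggregate(
    atomic_values: Mapping[str, np.ndarray],
    pairs: PairTerms | None,
    fragments: Mapping[str, Iterable[int]],
) -> FragmentReport:
    """Group atomic values into fragment sums; sum cross-fragment interactions.

    ``atomic_values`` maps a value name to a per-atom array (e.g. the four
    components, or their trans-minus-cis differences).  The inter-fragment
    term sums the pairwise elec+xc interaction energies across fragment
    boundaries; grand totals are conserved by construction.
    """
    frag_of = {}
    for name, atoms in fragments.items():
        for i in atoms:
            if i in frag_of:
                raise ValueError(f"atom {i} assigned to more than one fragment")
            frag_of[int(i)] = name
    n_atoms = next(iter(atomic_values.values())).size
    missing = [i for i in range(n_atoms) if i not in frag_of]
    if missing:
        raise ValueError(f"atoms {missing} belong to no fragment")
    self_terms = {
        name: {k: float(v[list(atoms)].sum()) for k, v in atomic_values.items()}
        for name, atoms in fragments.items()
    }
    inter: dict[tuple[str, str], float] = {}
    total_cross = 0.0
    if pairs is not None and pairs.n_pairs:
        e_pair = pairs.E_int  # elec + xc
        for i in range(pairs.n_pairs):
            fa = frag_of[int(pairs.a[i])]
            fb = frag_of[int(pairs.b[i])]
            if fa == fb:
                continue
            key = tuple(sorted((fa, fb)))
            inter[key] = inter.get(key, 0.0) + float(e_pair[i])
            total_cross += float(e_pair[i])
    return FragmentReport(
        self_terms=self_terms,
        inter_fragment=inter,
        inter_fragment_total=total_cross,
    )


def ensemble_fragment_aggregate(
    cis: Sequence[IQASnapshot],
    trans: Sequence[IQASnapshot],
    fragments: Mapping[str, Iterable[int]],
    quantile: float = 0.05,
    values: tuple[str, ...] = ("t_xc", "elec"),
) -> FragmentReport:
    """Trans-minus-cis fragment table of ensemble-averaged component energies.

    Self terms are fragment sums of the requested atomic components (default
    quantum + electrostatic); the inter-fragment entry is the change of the
    cross-fragment elec+xc interaction sums.
    """
    cis_f = filter_by_error_quantile(cis, quantile)
    trans_f = filter_by_error_quantile(trans, quantile)
    _, a_cis, _, _ = _ensemble_stats(cis_f)
    _, a_trans, _, _ = _ensemble_stats(trans_f)
    d_atomic = {k: a_trans[k] - a_cis[k] for k in values}
    d_atomic["sum"] = sum(d_atomic.values())

    def cross_means(snaps):
        reports = [
            fragment_aggregate(
                {"z": np.zeros(s.n_atoms)}, s.pairs, fragments
            )
            for s in snaps
        ]
        keys = set().union(*(r.inter_fragment.keys() for r in reports))
        means = {
            k: float(np.mean([r.inter_fragment.get(k, 0.0) for r in reports]))
            for k in keys
        }
        total = float(np.mean([r.inter_fragment_total for r in reports]))
        return means, total

    m_cis, t_cis = cross_means(cis_f)
    m_trans, t_trans = cross_means(trans_f)
    rep = fragment_aggregate(d_atomic, None, fragments)
    keys = set(m_cis) | set(m_trans)
    rep.inter_fragment = {
        k: m_trans.get(k, 0.0) - m_cis.get(k, 0.0) for k in keys
    }
    rep.inter_fragment_total = t_trans - t_cis
    return rep


def range_split(
    snapshot: IQASnapshot, topology: MolecularTopology
) -> dict[str, dict[str, float]]:
    """Split each component into short-range (atomic, 1-2, 1-3) and medium.

    Pair terms are classified by bond-path distance on the covalent graph:
    distance 1 or 2 is short, 3 and beyond is medium.  Pairs between
    disconnected atoms are classified as medium with a warning.  Atomic-only
    terms (including solvation) are short-range by definition, and
    short + medium reproduces every component total.
    """
    g = topology.graph()
    p = snapshot.pairs
    basin = snapshot.basin
    out = {
        "t_xc": {"short": float((basin.T + basin.V_ee_xc).sum()), "medium": 0.0},
        "elec": {"short": float((basin.V_ne + basin.V_ee_coul).sum()), "medium": 0.0},
        "d3": {"short": 0.0, "medium": 0.0},
        "solv": {"short": float(snapshot.solvation.total.sum()), "medium": 0.0},
    }
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    warned = False
    for i in range(p.n_pairs):
        a, b = int(p.a[i]), int(p.b[i])
        dist = lengths.get(a, {}).get(b)
        if dist is None and not nx.has_path(g, a, b):
            if not warned:
                warnings.warn(
                    "disconnected atom pair(s) classified as medium range",
                    stacklevel=2,
                )
                warned = True
        cls = "short" if dist is not None and dist <= 2 else "medium"
        out["t_xc"][cls] += float(p.V_ee_xc[i])
        out["elec"][cls] += float(p.E_int_elec[i])
        out["d3"][cls] += float(p.E_d3[i])
    return out


def carbonyl_xc_descriptor(
    cis: Sequence[IQASnapshot],
    trans: Sequence[IQASnapshot],
    group_a: Iterable[int],
    group_b: Iterable[int],
    quantile: float = 0.0,
) -> float:
    """Trans-minus-cis change of the cross-group pairwise xc energy sum.

    Used to quantify hyperconjugative (n -> pi*) stabilization between e.g.
    a donor carbonyl oxygen and the acceptor C=O group: the xc interaction
    sum over all pairs with one atom in each (disjoint) selection, ensemble
    averaged per isomer.
    """
    set_a = set(int(i) for i in group_a)
    set_b = set(int(i) for i in group_b)
    if set_a & set_b:
        raise ValueError("selections must be disjoint")

    def mean_xc(snaps):
        snaps = filter_by_error_quantile(snaps, quantile)
        vals = []
        for s in snaps:
            p = s.pairs
            mask = np.array(
                [
                    (int(a) in set_a and int(b) in set_b)
                    or (int(a) in set_b and int(b) in set_a)
                    for a, b in zip(p.a, p.b)
                ],
                dtype=bool,
            )
            vals.append(float(p.V_ee_xc[mask].sum()) if mask.any() else 0.0)
        return float(np.mean(vals))

    return mean_xc(trans) - mean_xc(cis)
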