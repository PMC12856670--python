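"""Charge-transfer-corrected steric descriptor E_ST = E_def - E_CT.

The atomic deformation energy E_def^A = <E_net^A>_trans - <E_net^A>_cis has
been proposed as a steric-strain measure, but small electron-count changes
between isomers shift net energies strongly.  The correction subtracts a
charge-transfer energy E_CT^A = E(n_trans^A) - E(n_cis^A) evaluated on a
piecewise-linear conceptual-DFT atomic energy E(n): E(N) = 0 for the
neutral atom, E(N-1) = +IP, E(N+1) = -EA, linear between, with IP/EA from a
tabulated reference (config data, editable).  What remains, E_ST = E_def -
E_CT, is insensitive to pure charge transfer and positive under genuine
steric compression.

E_CT defaults to ensemble-mean electron populations; evaluating E(n) per
snapshot and averaging is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .constants import EV_TO_KCAL
from .iqa import IQASnapshot, filter_by_error_quantile

__all__ = [
    "AtomReference",
    "load_atom_references",
    "piecewise_energy",
    "charge_transfer_energy",
    "StericResult",
    "steric_descriptor",
]


@dataclass(frozen=True)
class AtomReference:
    """Neutral electron count and IP/EA (kcal/mol) of one element."""

    element: str
    n_neutral: int
    ip: float  # kcal/mol
    ea: float  # kcal/mol

    def __post_init__(self):
        if not self.ip > self.ea >= 0:
            raise ValueError(
                f"{self.element}: require IP > EA >= 0 "
                f"(got IP={self.ip}, EA={self.ea})"
            )


def load_atom_references() -> dict[str, AtomReference]:
    """Load the shipped IP/EA config table (stored in eV, converted here)."""
    text = resources.files("cispro.data").joinpath("atom_reference.yaml").read_text()
    cfg = yaml.safe_load(text)
    scale = EV_TO_KCAL if cfg.get("units", "eV") == "eV" else 1.0
    return {
        el: AtomReference(
            element=el,
            n_neutral=int(row["n_neutral"]),
            ip=float(row["ip"]) * scale,
            ea=float(row["ea"]) * scale,
        )
        for el, row in cfg["elements"].items()
    }


def piecewise_energy(ref: AtomReference, n: float) -> float:
    """Atomic energy E(n) relative to the neutral atom, kcal/mol.

    E(N) = 0, E(N-1) = +IP, E(N+1) = -EA, linear between; outside
    [N-1, N+1] the nearest segment is extended linearly with a warning.
    """
    big_n = ref.n_neutral
    if n < big_n - 1 or n > big_n + 1:
        warnings.warn(
            f"population {n} outside [{big_n - 1}, {big_n + 1}] for "
            f"{ref.element}; extending linearly",
            stacklevel=2,
        )
    if n <= big_n:
        return (big_n - n) * ref.ip
    return -(n - big_n) * ref.ea


def charge_transfer_energy(
    ref: AtomReference, n_cis: float, n_trans: float
) -> float:
    """E_CT = E(n_trans) - E(n_cis); antisymmetric under isomer swap."""
    return piecewise_energy(ref, n_trans) - piecewise_energy(ref, n_cis)


@dataclass
class StericResult:
    """Per-atom deformation, charge-transfer and steric energies (kcal/mol)."""

    elements: list[str]
    e_def: np.ndarray  # <E_net>_trans - <E_net>_cis
    e_ct: np.ndarray
    e_st: np.ndarray  # e_def - e_ct, exactly

    @property
    def global_e_st(self) -> float:
        return float(self.e_st.sum())

    @property
    def global_e_def(self) -> float:
        return float(self.e_def.sum())

    def fragment_sums(
        self, fragments: Mapping[str, Sequence[int]]
    ) -> dict[str, dict[str, float]]:
        return {
            name: {
                "e_def": float(self.e_def[list(atoms)].sum()),
                "e_ct": float(self.e_ct[list(atoms)].sum()),
                "e_st": float(self.e_st[list(atoms)].sum()),
            }
            for name, atoms in fragments.items()
        }


def steric_descriptor(
    cis: Sequence[IQASnapshot],
    trans: Sequence[IQASnapshot],
    references: Mapping[str, AtomReference] | None = None,
    quantile: float = 0.05,
    per_snapshot_ct: bool = False,
) -> StericResult:
    """Atomwise E_def, E_CT and E_ST from two isomer ensembles.

    Both ensembles are error-filtered with the same quantile before
    averaging.  ``per_snapshot_ct`` switches E_CT from the default
    mean-population evaluation to averaging E(n) over snapshots.
    """
    if references is None:
        references = load_atom_references()
    cis_f = filter_by_error_quantile(cis, quantile)
    trans_f = filter_by_error_quantile(trans, quantile)
    elements = cis_f[0].basin.elements
    if trans_f[0].basin.elements != elements:
        raise ValueError("cis and trans ensembles must share the atom set")
    refs = []
    for e in elements:
        if e not in references:
            raise KeyError(f"no IP/EA reference for element {e!r}")
        refs.append(references[e])

    net_cis = np.mean([s.basin.net for s in cis_f], axis=0)
    net_trans = np.mean([s.basin.net for s in trans_f], axis=0)
    e_def = net_trans - net_cis

    if per_snapshot_ct:
        e_n_cis = np.mean(
            [
                [piecewise_energy(r, p) for r, p in zip(refs, s.basin.n_pop)]
                for s in cis_f
            ],
            axis=0,
        )
        e_n_trans = np.mean(
            [
                [piecewise_energy(r, p) for r, p in zip(refs, s.basin.n_pop)]
                for s in trans_f
            ],
            axis=0,
        )
        e_ct = e_n_trans - e_n_cis
    else:
        pop_cis = np.mean([s.basin.n_pop for s in cis_f], axis=0)
        pop_trans = np.mean([s.basin.n_pop for s in trans_f], axis=0)
        e_ct = np.array(
            [
                charge_transfer_energy(r, pc, pt)
                for r, pc, pt in zip(refs, pop_cis, pop_trans)
            ]
        )
    return StericResult(
        elements=list(elements), e_def=e_def, e_ct=e_ct, e_st=e_def - e_ct
    )
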