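"""Atomic partitioning of continuum-solvation energy on toy solutes.

A polarizable-continuum electrostatic solvation energy is a sum over
surface-charge tesserae, E_solv,elec = 1/2 sum_k q_k Phi(s_k).  Because the
solute potential Phi is a sum of atomic-basin potentials Phi^A, the energy
partitions exactly into per-atom terms E_solv,elec^A = 1/2 sum_k q_k
Phi^A(s_k) -- an identity that holds for any charge model, which is what
this module verifies on point-charge (optionally point-dipole) toys where
everything is computable in closed form.  The nonpolar
cavity-dispersion-structure (CDS) term is a surface-tension model,
E_solv,CDS = sum_A (gamma_A + gamma^M) sigma_A, over per-atom
solvent-accessible surface areas sigma_A from a deterministic
Shrake-Rupley construction.

Surface charges use a conductor-like scaling f(eps) = (eps - 1)/eps with
eps = 78.4 for water; this is a transparent stand-in for a full
boundary-element solution, adequate because the partition identity being
tested does not depend on how the tessera charges were obtained.  The
Coulomb constant is 332.0637 kcal A mol^-1 e^-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .constants import COULOMB_K, WATER_EPSILON

__all__ = [
    "Tessera",
    "AtomicChargeModel",
    "SurfaceTensionParams",
    "default_surface_tension_params",
    "atomic_potential",
    "molecular_potential",
    "solv_elec_atomic",
    "solv_elec_total",
    "sphere_points",
    "shrake_rupley_sasa",
    "cds_atomic",
    "fibonacci_tessellate",
    "conductor_scale",
]


@dataclass
class Tessera:
    """A surface segment carrying an apparent polarization charge."""

    position: np.ndarray  # Angstrom, 3-vector
    charge: float  # e-
    area: float  # Angstrom^2

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class AtomicChargeModel:
    """Point charges (optionally + point dipoles) standing in for basin densities."""

    positions: np.ndarray  # (n, 3) Angstrom
    charges: np.ndarray  # (n,) e-
    dipoles: np.ndarray | None = None  # (n, 3) e-.Angstrom
    molecular_charge: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.size != self.positions.shape[0]:
            raise ValueError("one charge per atom required")
        if self.dipoles is not None:
            self.dipoles = np.asarray(self.dipoles, dtype=float).reshape(-1, 3)
            if self.dipoles.shape[0] != self.charges.size:
                raise ValueError("one dipole per atom required")
        if self.molecular_charge is not None and not np.isclose(
            self.charges.sum(), self.molecular_charge, atol=1e-9
        ):
            raise ValueError("atomic charges do not sum to the molecular charge")

    @property
    def n_atoms(self) -> int:
        return int(self.charges.size)


def atomic_potential(
    model: AtomicChargeModel, atom: int, point: np.ndarray
) -> float:
    """Electrostatic potential of one atom's charge (+ dipole) at a point.

    Units: kcal mol^-1 e^-1 (the Coulomb constant 332.0637 kcal.A/mol/e^2 is
    folded in, so multiplying by a charge in e- gives kcal/mol).
    """
    r_vec = np.asarray(point, dtype=float) - model.positions[atom]
    r = float(np.linalg.norm(r_vec))
    if r < 1e-12:
        raise ValueError("evaluation point coincides with the atom position")
    phi = COULOMB_K * model.charges[atom] / r
    if model.dipoles is not None:
        phi += COULOMB_K * float(model.dipoles[atom] @ r_vec) / r**3
    return float(phi)


def molecular_potential(model: AtomicChargeModel, point: np.ndarray) -> float:
    """Total solute potential at a point: sum of the atomic potentials."""
    return sum(atomic_potential(model, a, point) for a in range(model.n_atoms))


def _potential_matrix(
    tesserae: Sequence[Tessera], model: AtomicChargeModel
) -> np.ndarray:
    """Phi^A(s_k) for every atom A (rows) and tessera k (columns)."""
    s = np.array([t.position for t in tesserae])  # (K, 3)
    d = s[None, :, :] - model.positions[:, None, :]  # (n, K, 3)
    r = np.linalg.norm(d, axis=2)
    phi = COULOMB_K * model.charges[:, None] / r
    if model.dipoles is not None:
        phi = phi + COULOMB_K * np.einsum("nd,nkd->nk", model.dipoles, d) / r**3
    return phi


def solv_elec_atomic(
    tesserae: Sequence[Tessera],
    model: AtomicChargeModel,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom electrostatic solvation: E^A = 1/2 sum_k q_k Phi^A(s_k).

    The atomic values sum to the molecular 1/2 sum_k q_k Phi(s_k) exactly
    (additivity of the potential).  If ``radii`` are given, tesserae found
    inside an atomic sphere trigger a warning.
    """
    if not tesserae:
        raise ValueError("at least one tessera required")
    q = np.array([t.charge for t in tesserae])
    if radii is not None:
        s = np.array([t.position for t in tesserae])
        d = np.linalg.norm(
            s[None, :, :] - model.positions[:, None, :], axis=2
        )
        inside = (d < np.asarray(radii, dtype=float)[:, None]).any(axis=0)
        if inside.any():
            warnings.warn(
                f"{int(inside.sum())} tesserae lie inside an atomic sphere",
                stacklevel=2,
            )
    phi = _potential_matrix(tesserae, model)
    return 0.5 * phi @ q


def solv_elec_total(
    tesserae: Sequence[Tessera], model: AtomicChargeModel
) -> float:
    """Molecular electrostatic solvation energy, 1/2 sum_k q_k Phi(s_k)."""
    q = np.array([t.charge for t in tesserae])
    phi = _potential_matrix(tesserae, model).sum(axis=0)
    return float(0.5 * q @ phi)


# ---------------------------------------------------------------------------
# solvent-accessible surface (Shrake-Rupley)
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


def shrake_rupley_sasa(
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Test points on each atom's probe-expanded sphere are counted accessible
    when outside every other atom's expanded sphere; sigma_A is the
    accessible fraction of 4 pi (r_A + probe)^2.  Fully buried atoms get 0.
    """
    xyz = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    r = np.asarray(radii, dtype=float)
    if (r <= 0).any():
        raise ValueError("radii must be positive")
    if n_points < 32:
        raise ValueError("need at least 32 sphere points")
    n = xyz.shape[0]
    unit = sphere_points(n_points)
    expanded = r + probe
    sasa = np.empty(n)
    for a in range(n):
        pts = xyz[a] + expanded[a] * unit
        accessible = np.ones(n_points, dtype=bool)
        for b in range(n):
            if b == a:
                continue
            d2 = ((pts - xyz[b]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[b] ** 2
        sasa[a] = 4.0 * np.pi * expanded[a] ** 2 * accessible.mean()
    return sasa


# ---------------------------------------------------------------------------
# CDS surface-tension term
# ---------------------------------------------------------------------------

@dataclass
class SurfaceTensionParams:
    """Per-element tensions gamma_A, molecular tension gamma^M, radii, probe.

    Tensions in kcal mol^-1 A^-2, radii in Angstrom.
    """

    gamma: dict[str, float]
    gamma_molecular: float
    probe_radius: float
    radii: dict[str, float]
    n_points: int = 960
    note: str = ""

    def radius_of(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(f"no radius parameter for element {element!r}") from None


def default_surface_tension_params() -> SurfaceTensionParams:
    """Load the shipped config table (Bondi radii; placeholder tensions)."""
    text = resources.files("cispro.data").joinpath("solvation_params.yaml").read_text()
    cfg = yaml.safe_load(text)
    return SurfaceTensionParams(
        gamma={k: float(v) for k, v in cfg["gamma"].items()},
        gamma_molecular=float(cfg["gamma_molecular"]),
        probe_radius=float(cfg["probe_radius"]),
        radii={k: float(v) for k, v in cfg["radii"].items()},
        n_points=int(cfg.get("n_points", 960)),
        note=str(cfg.get("note", "")),
    )


def cds_atomic(
    sasa: np.ndarray, elements: Sequence[str], params: SurfaceTensionParams
) -> np.ndarray:
    """Per-atom CDS term (gamma_A + gamma^M) * sigma_A; linear in sigma."""
    sasa = np.asarray(sasa, dtype=float)
    if sasa.size != len(elements):
        raise ValueError("one SASA value per atom required")
    out = np.empty(sasa.size)
    for i, e in enumerate(elements):
        if e not in params.gamma:
            raise KeyError(f"no surface-tension parameter for element {e!r}")
        out[i] = (params.gamma[e] + params.gamma_molecular) * sasa[i]
    return out


# ---------------------------------------------------------------------------
# toy tessellation
# ---------------------------------------------------------------------------

def conductor_scale(epsilon: float = WATER_EPSILON) -> float:
    """Conductor-like dielectric scaling f(eps) = (eps - 1)/eps."""
    return (epsilon - 1.0) / epsilon


def fibonacci_tessellate(
    center: np.ndarray,
    radius: float,
    n: int,
    enclosed_charge: float = 0.0,
    epsilon: float = WATER_EPSILON,
) -> list[Tessera]:
    """Quasi-uniform spherical tessellation with conductor-like charges.

    For a single spherical cavity each tessera carries
    q_k = -f(eps) * Q / n where Q is the enclosed solute charge, so the
    charges sum to -f(eps) Q exactly; an empty cavity gives zero charges.
    """
    if n < 8:
        raise ValueError("need at least 8 tesserae")
    center = np.asarray(center, dtype=float).reshape(3)
    pts = center + radius * sphere_points(n)
    q = -conductor_scale(epsilon) * enclosed_charge / n
    area = 4.0 * np.pi * radius**2 / n
    return [Tessera(position=p, charge=q, area=area) for p in pts]
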