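"""Versioned plain-text readers/writers, config, and the demo pipeline.

All on-disk formats are inspectable, diff-able text: per-window time series
plus a metadata file (path, center, force constant, unit tag per line, '#'
comments) for umbrella runs; comma-separated snapshot tables with a
mandatory schema-version header line for IQA terms; YAML for topology,
fragments and pipeline configuration.  ``run_pipeline`` ties the stages into
one seeded, reproducible report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformation, iqa, steric, synthetic, wham
from .constants import DEFAULT_TEMPERATURE

SCHEMA_ATOMS = "# cispro-schema: atoms v1"
SCHEMA_PAIRS = "# cispro-schema: pairs v1"
SCHEMA_MANIFEST = "# cispro-schema: manifest v1"

ATOM_COLUMNS = [
    "id", "element", "n_pop", "T", "V_ne", "V_ee_coul", "V_ee_xc",
    "E_solv_elec", "E_solv_cds",
]
PAIR_COLUMNS = ["a", "b", "V_nn", "V_ne_ab", "V_ne_ba", "V_ee_coul", "V_ee_xc", "E_d3"]

FLOAT_FMT = "%.17g"

__all__ = [
    "write_windows",
    "read_windows",
    "write_pmf",
    "read_pmf",
    "write_snapshots",
    "read_snapshots",
    "read_topology",
    "write_topology",
    "validate_tables",
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# umbrella windows
# ---------------------------------------------------------------------------

def write_windows(
    windows: list[wham.UmbrellaWindow],
    directory: str | Path,
    time_step: float = 2.5,
    meta_name: str = "windows.meta",
) -> Path:
    """Write per-window (time, omega) series plus the metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["# path center force_constant k_unit"]
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        t = np.arange(w.n_samples) * time_step
        np.savetxt(
            directory / fname,
            np.column_stack([t, w.samples]),
            fmt=FLOAT_FMT,
            header="time_ps omega_deg",
        )
        lines.append(f"{fname} {w.center:.17g} {w.force_constant:.17g} {w.k_unit}")
    meta = directory / meta_name
    meta.write_text("\n".join(lines) + "\n")
    return meta


def read_windows(meta_path: str | Path) -> list[wham.UmbrellaWindow]:
    """Read an umbrella-window set from its metadata file."""
    meta_path = Path(meta_path)
    windows = []
    for raw in meta_path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"malformed metadata line: {raw!r}")
        path, center, k = parts[0], float(parts[1]), float(parts[2])
        k_unit = parts[3] if len(parts) > 3 else wham.K_PER_DEG2
        data = np.loadtxt(meta_path.parent / path, ndmin=2)
        windows.append(
            wham.UmbrellaWindow(
                center=center, force_constant=k, samples=data[:, 1], k_unit=k_unit
            )
        )
    if not windows:
        raise ValueError(f"no windows listed in {meta_path}")
    return windows


def write_pmf(profile: wham.PMFProfile, path: str | Path) -> Path:
    path = Path(path)
    cols = [profile.bin_centers, profile.free_energy]
    header = "omega_deg G_kcal_mol"
    if profile.errors is not None:
        cols.append(profile.errors)
        header += " err_kcal_mol"
    np.savetxt(path, np.column_stack(cols), fmt=FLOAT_FMT, header=header)
    return path


def read_pmf(path: str | Path, temperature: float = DEFAULT_TEMPERATURE) -> wham.PMFProfile:
    data = np.loadtxt(path, ndmin=2)
    errors = data[:, 2] if data.shape[1] > 2 else None
    return wham.PMFProfile(
        bin_centers=data[:, 0],
        free_energy=data[:, 1],
        window_free_energies=np.array([]),
        temperature=temperature,
        errors=errors,
    )


# ---------------------------------------------------------------------------
# IQA snapshot tables
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, schema: str):
    with open(path, "w") as fh:
        fh.write(schema + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _read_csv(path: Path, schema: str) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().strip()
        if first != schema:
            raise ValueError(
                f"{path.name}: expected schema header {schema!r}, got {first!r}"
            )
        return pd.read_csv(fh)


def write_snapshots(snapshots: list[iqa.IQASnapshot], directory: str | Path) -> Path:
    """Write one atoms/pairs CSV pair per snapshot plus the E_ref manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(snapshots):
        sid = s.snapshot_id or f"snap-{i:04d}"
        b = s.basin
        atoms = pd.DataFrame(
            {
                "id": np.arange(b.n_atoms),
                "element": b.elements,
                "n_pop": b.n_pop,
                "T": b.T,
                "V_ne": b.V_ne,
                "V_ee_coul": b.V_ee_coul,
                "V_ee_xc": b.V_ee_xc,
                "E_solv_elec": s.solvation.e_solv_elec,
                "E_solv_cds": s.solvation.e_solv_cds,
            }
        )
        p = s.pairs
        pairs = pd.DataFrame(
            {
                "a": p.a, "b": p.b, "V_nn": p.V_nn, "V_ne_ab": p.V_ne_ab,
                "V_ne_ba": p.V_ne_ba, "V_ee_coul": p.V_ee_coul,
                "V_ee_xc": p.V_ee_xc, "E_d3": p.E_d3,
            }
        )
        _write_csv(atoms, directory / f"{sid}.atoms.csv", SCHEMA_ATOMS)
        _write_csv(pairs, directory / f"{sid}.pairs.csv", SCHEMA_PAIRS)
        manifest.append({"snapshot": sid, "e_ref": s.e_ref})
    _write_csv(pd.DataFrame(manifest), directory / "manifest.csv", SCHEMA_MANIFEST)
    return directory


def read_snapshots(directory: str | Path) -> list[iqa.IQASnapshot]:
    directory = Path(directory)
    manifest = _read_csv(directory / "manifest.csv", SCHEMA_MANIFEST)
    snaps = []
    for _, row in manifest.iterrows():
        sid = row["snapshot"]
        atoms = _read_csv(directory / f"{sid}.atoms.csv", SCHEMA_ATOMS)
        pairs = _read_csv(directory / f"{sid}.pairs.csv", SCHEMA_PAIRS)
        basin = iqa.BasinTerms(
            elements=list(atoms["element"]),
            T=atoms["T"].to_numpy(),
            V_ne=atoms["V_ne"].to_numpy(),
            V_ee_coul=atoms["V_ee_coul"].to_numpy(),
            V_ee_xc=atoms["V_ee_xc"].to_numpy(),
            n_pop=atoms["n_pop"].to_numpy(),
        )
        solv = iqa.SolvationTerms(
            e_solv_elec=atoms["E_solv_elec"].to_numpy(),
            e_solv_cds=atoms["E_solv_cds"].to_numpy(),
        )
        if len(pairs):
            pt = iqa.PairTerms(
                a=pairs["a"].to_numpy(), b=pairs["b"].to_numpy(),
                V_nn=pairs["V_nn"].to_numpy(), V_ne_ab=pairs["V_ne_ab"].to_numpy(),
                V_ne_ba=pairs["V_ne_ba"].to_numpy(),
                V_ee_coul=pairs["V_ee_coul"].to_numpy(),
                V_ee_xc=pairs["V_ee_xc"].to_numpy(), E_d3=pairs["E_d3"].to_numpy(),
            )
        else:
            pt = iqa.PairTerms.empty()
        snaps.append(
            iqa.IQASnapshot(
                basin=basin, pairs=pt, solvation=solv,
                e_ref=float(row["e_ref"]), snapshot_id=str(sid),
            )
        )
    return snaps


def write_topology(topology: iqa.MolecularTopology, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            {
                "n_atoms": topology.n_atoms,
                "bonds": [list(b) for b in topology.bonds],
                "fragments": {k: list(map(int, v)) for k, v in topology.fragments.items()},
            }
        )
    )
    return path


def read_topology(path: str | Path) -> iqa.MolecularTopology:
    cfg = yaml.safe_load(Path(path).read_text())
    return iqa.MolecularTopology(
        n_atoms=int(cfg["n_atoms"]),
        bonds=[tuple(b) for b in cfg.get("bonds", [])],
        fragments={k: list(v) for k, v in cfg.get("fragments", {}).items()},
    )


# ---------------------------------------------------------------------------
# validation diagnostics
# ---------------------------------------------------------------------------

def validate_tables(directory: str | Path) -> list[str]:
    """Schema and consistency diagnostics for a snapshot directory.

    Returns a list of human-readable problems (empty when valid): schema
    headers, column sets, duplicate / self pairs, atom-set consistency and
    manifest completeness are checked.
    """
    directory = Path(directory)
    diags: list[str] = []
    try:
        manifest = _read_csv(directory / "manifest.csv", SCHEMA_MANIFEST)
    except (FileNotFoundError, ValueError) as exc:
        return [f"manifest.csv: {exc}"]
    if "e_ref" not in manifest.columns or "snapshot" not in manifest.columns:
        diags.append("manifest.csv: missing 'snapshot'/'e_ref' column")
        return diags
    if manifest["e_ref"].isna().any():
        diags.append("manifest.csv: snapshot(s) missing E_ref")
    for sid in manifest["snapshot"]:
        for suffix, schema, cols in (
            ("atoms", SCHEMA_ATOMS, ATOM_COLUMNS),
            ("pairs", SCHEMA_PAIRS, PAIR_COLUMNS),
        ):
            path = directory / f"{sid}.{suffix}.csv"
            try:
                df = _read_csv(path, schema)
            except (FileNotFoundError, ValueError) as exc:
                diags.append(f"{path.name}: {exc}")
                continue
            missing = [c for c in cols if c not in df.columns]
            if missing:
                diags.append(f"{path.name}: missing column(s) {missing}")
                continue
            if suffix == "pairs" and len(df):
                if (df["a"] == df["b"]).any():
                    diags.append(f"{path.name}: self pair present")
                key = df[["a", "b"]].apply(
                    lambda r: (min(r["a"], r["b"]), max(r["a"], r["b"])), axis=1
                )
                if key.duplicated().any():
                    diags.append(f"{path.name}: duplicate pair (a,b)/(b,a) present")
                atoms_path = directory / f"{sid}.atoms.csv"
                try:
                    n_atoms = len(_read_csv(atoms_path, SCHEMA_ATOMS))
                    if df[["a", "b"]].to_numpy().max() >= n_atoms:
                        diags.append(
                            f"{path.name}: pair references atom outside the atoms table"
                        )
                except (FileNotFoundError, ValueError):
                    pass
    return diags


# ---------------------------------------------------------------------------
# pipeline configuration and report
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings for the seeded end-to-end demo pipeline.

    All physical settings carry explicit units in their names; a serialized
    copy is embedded in every report.
    """

    temperature_K: float = DEFAULT_TEMPERATURE
    seed: int = 0
    # umbrella / WHAM stage
    n_windows: int = 120
    n_per_window: int = 500
    force_constant: float = synthetic.STUDY_FORCE_CONSTANT
    k_unit: str = synthetic.STUDY_K_UNIT
    n_bins: int = 120
    wham_tolerance_kcal: float = 1e-5
    n_bootstrap: int = 8
    trans_interval_deg: tuple[float, float] = (90.0, 270.0)
    # decomposition stage
    n_atoms: int = 8
    n_snapshots: int = 100
    noise_kcal: float = 0.5
    outlier_fraction: float = 0.05
    quantile: float = 0.05
    # entropy / pucker stage
    n_torsions: int = 3
    torsion_states: int = 3
    chain_length: int = 20000
    shuffle_reps: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "trans_interval_deg" in cfg:
            cfg["trans_interval_deg"] = tuple(cfg["trans_interval_deg"])
        return cls(**cfg)


@dataclass
class ReportBundle:
    """Stage tables plus a provenance block (config + input hashes)."""

    tables: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def report_hash(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.provenance, sort_keys=True).encode())
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False).encode())
        return h.hexdigest()

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(directory / f"{name}.csv", index=False)
        prov = dict(self.provenance)
        prov["report_hash"] = self.report_hash()
        (directory / "provenance.json").write_text(json.dumps(prov, indent=2))
        return directory


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage on seeded synthetic inputs and assemble the report.

    Deterministic given the config seed; the report embeds the serialized
    config so identical inputs give identical report hashes.
    """
    rng_seed = int(config.seed)
    t = config.temperature_K
    pot = synthetic.default_omega_potential()
    centers = np.arange(config.n_windows) * (360.0 / config.n_windows)

    # --- free-energy stage: forward and reverse umbrella runs -------------
    dg_dir = {}
    for direction, seed_off in (("forward", 0), ("reverse", 1)):
        windows = synthetic.sample_biased_windows(
            pot, centers, config.force_constant, config.n_per_window,
            temperature=t, seed=rng_seed + seed_off, k_unit=config.k_unit,
        )
        boot = wham.bootstrap_pmf(
            windows, n_bins=config.n_bins, temperature=t,
            n_bootstrap=config.n_bootstrap, seed=rng_seed + seed_off,
            tolerance=config.wham_tolerance_kcal,
            trans_interval=config.trans_interval_deg,
        )
        dg_dir[direction] = boot
    avg = wham.average_directions(
        dg_dir["forward"].delta_g, dg_dir["reverse"].delta_g
    )
    dg_table = pd.DataFrame(
        [
            {
                "quantity": "delta_G_cis_trans_kcal",
                "forward": dg_dir["forward"].delta_g,
                "reverse": dg_dir["reverse"].delta_g,
                "average": avg.delta_g,
                "hysteresis": avg.hysteresis,
                "bootstrap_err_fwd": dg_dir["forward"].delta_g_error,
                "analytic": pot.analytic_delta_g(t, config.trans_interval_deg),
            }
        ]
    )

    # --- decomposition stage ---------------------------------------------
    rng = np.random.default_rng(rng_seed + 100)
    truth = synthetic.GroundTruthDecomposition(
        d_t_xc=rng.normal(0.0, 1.0, config.n_atoms),
        d_elec=rng.normal(0.0, 1.0, config.n_atoms),
        d_d3=rng.normal(0.0, 0.3, config.n_atoms),
        d_solv=rng.normal(0.0, 0.5, config.n_atoms),
        noise_scale=config.noise_kcal,
        outlier_fraction=config.outlier_fraction,
    )
    cis, trans = synthetic.make_iqa_ensembles(
        truth, n_snapshots=config.n_snapshots, seed=rng_seed + 101
    )
    dec = iqa.ensemble_decompose(cis, trans, quantile=config.quantile)
    comp_table = pd.DataFrame(
        [
            {
                "d_T_xc": dec.d_t_xc, "d_elec": dec.d_elec,
                "d_subtotal": dec.d_subtotal, "d_D3": dec.d_d3,
                "d_solv": dec.d_solv, "d_iqa_excl_disp": dec.d_iqa,
                "d_iqa_full": dec.d_iqa_full, "d_ref": dec.d_ref,
                "n_cis_used": dec.n_cis, "n_trans_used": dec.n_trans,
                "truth_total": truth.total,
            }
        ]
    )

    # --- steric stage ------------------------------------------------------
    st = steric.steric_descriptor(cis, trans, quantile=config.quantile)
    steric_table = pd.DataFrame(
        {
            "atom": np.arange(config.n_atoms),
            "element": st.elements,
            "e_def": st.e_def,
            "e_ct": st.e_ct,
            "e_st": st.e_st,
        }
    )

    # --- conformational stage ----------------------------------------------
    spec = synthetic.MarkovTorsionSpec(
        n_torsions=config.n_torsions, n_states=config.torsion_states,
        chain_length=config.chain_length, coupling=0.5, seed=rng_seed + 200,
    )
    traj = synthetic.sample_markov_torsions(spec)
    est = conformation.mi_corrected_entropy(
        traj.states, shuffle_reps=config.shuffle_reps, seed=rng_seed + 201
    )
    phases = (
        180.0
        + 90.0 * np.sign(np.random.default_rng(rng_seed + 202).standard_normal(500))
    ) % 360.0
    pops = conformation.pucker_populations(
        phases, np.arange(phases.size) * 2.5
    )
    conform_table = pd.DataFrame(
        [
            {
                "S1_kcal_mol_K": est.s1,
                "S_corrected_kcal_mol_K": est.s,
                "minus_TS_kcal_mol": est.minus_t_s(t),
                "pucker_f_endo": pops.f_endo,
                "pucker_flip_rate_ps": pops.flip_rate,
            }
        ]
    )

    cfg_json = json.dumps(asdict(config), sort_keys=True, default=list)
    provenance = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": ["wham", "decompose", "steric", "conform"],
    }
    return ReportBundle(
        tables={
            "delta_g": dg_table,
            "components": comp_table,
            "steric": steric_table,
            "conformation": conform_table,
        },
        provenance=provenance,
    )
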