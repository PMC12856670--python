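# cispro

Energetics of peptide-bond *cis*–*trans* isomerization: periodic
umbrella-sampling/WHAM free energies and an interacting-quantum-atoms (IQA)
style decomposition of conformationally averaged isomerization energies,
with a synthetic-data module that generates every input with known ground
truth.

## Who this is for

The *cis* and *trans* configurations of a peptide amide bond (ω ≈ 0° vs
ω ≈ 180°) are separated by a large rotation barrier but only ~0.5–3 kcal/mol
in free energy, and proline is unusual in stabilizing the *cis* form (the
"Pro *cis* effect").  Disentangling the steric, electrostatic,
hyperconjugative, dispersion and solvation contributions behind such a small
difference requires (a) unbiasing umbrella-sampling simulations on the
periodic ω coordinate and (b) averaging and decomposing per-snapshot atomic
energy tables.  This package implements the analysis layer of that workflow
— everything downstream of the MD and quantum-chemistry engines — for
computational chemists who have (or want to emulate) per-window ω time
series and per-snapshot IQA term tables.

## What it computes

**Free energies.**  Biased windows `K·(ω − ω₀)²` (force-constant units carry
an explicit per-deg² / per-rad² tag) are unbiased with self-consistent WHAM
on the periodic coordinate (convergence: max |Δf_i| ≤ 10⁻⁵ kcal/mol), and

&nbsp;&nbsp;&nbsp;&nbsp;ΔG(*cis*→*trans*) = −RT ln(P_trans / P_cis),&nbsp;&nbsp;P_trans = P(ω ∈ [90°, 270°)),

with Monte-Carlo bootstrap errors and forward/reverse averaging
(hysteresis reported).

**Energy decomposition.**  Per-snapshot IQA tables (atomic basin energies
T^A, V_ne^A, V_ee^A split into Coulomb/xc; pairwise V_nn, V_ne, V_ee terms;
D3 dispersion pairs; continuum-solvation terms per atom) are regrouped into
four additive atomic components — quantum E_T,xc^A, electrostatic E_elec^A,
dispersion E_D3^A, solvation E_solv^A — whose sum reproduces the total
energy exactly.  Ensembles of the two isomers are averaged after discarding
the worst 5% of |IQA reconstruction error|, giving component-wise
⟨trans⟩ − ⟨cis⟩ differences with standard errors, fragment aggregates,
short/medium-range splits and pairwise-xc hyperconjugation descriptors.

**Steric descriptor.**  E_ST = E_def − E_CT, where E_def is the
trans-minus-cis change of atomic net energies and E_CT a charge-transfer
energy from a piecewise-linear conceptual-DFT atomic E(n) built from
tabulated IP/EA values.

**Solvation partition.**  E_solv,elec = ½ Σ_k q_k Φ(s_k) over
surface-charge tesserae partitions exactly into per-atom terms via the
atomic potentials Φ^A; the nonpolar CDS term is (γ_A + γ^M)·σ_A over
deterministic Shrake–Rupley accessible surfaces.

**Conformational analysis.**  Torsion discretization; conformational
entropy with a pairwise mutual-information correction (shuffle-null bias
subtracted) and convergence curves; five-membered-ring pseudorotation
phase/amplitude and endo/exo populations; geometric noncovalent-contact
statistics; point-charge dipole moments and radii of gyration.

## Worked example

```python
import numpy as np
from cispro import synthetic, wham, iqa

# 120 umbrella windows at 3-degree spacing on a double-well omega surface
pot = synthetic.default_omega_potential()
windows = synthetic.sample_biased_windows(
    pot, synthetic.STUDY_WINDOW_CENTERS, synthetic.STUDY_FORCE_CONSTANT,
    n_per_window=5000, seed=1, k_unit=synthetic.STUDY_K_UNIT)
boot = wham.bootstrap_pmf(windows, n_bins=360, n_bootstrap=15, seed=1)
print(f"dG(cis->trans) = {boot.delta_g:.2f} +/- {boot.delta_g_error:.2f} kcal/mol")
print(f"analytic value = {pot.analytic_delta_g():.2f} kcal/mol")

# two-isomer IQA ensembles with injected component differences
truth = synthetic.GroundTruthDecomposition(
    d_t_xc=np.array([6.1, 0, 0, 0]), d_elec=np.array([0, -8.9, 0, 0]),
    d_d3=np.array([0.0, 0, 0.6, 0]), d_solv=np.array([0, 0, 0, 1.3]),
    noise_scale=0.5, outlier_fraction=0.05)
cis, trans = synthetic.make_iqa_ensembles(truth, n_snapshots=100, seed=1)
dec = iqa.ensemble_decompose(cis, trans, quantile=0.05)
print(f"d_T,xc = {dec.d_t_xc:+.2f}  d_elec = {dec.d_elec:+.2f}  "
      f"d_D3 = {dec.d_d3:+.2f}  d_solv = {dec.d_solv:+.2f}")
print(f"subtotal = {dec.d_subtotal:+.2f}   d_IQA(excl. D3) = {dec.d_iqa:+.2f}")
print(f"snapshots used after 5% error filter: {dec.n_cis}/{dec.n_trans}")
```

prints

```
dG(cis->trans) = -1.41 +/- 0.08 kcal/mol
analytic value = -1.48 kcal/mol
d_T,xc = +6.12  d_elec = -8.85  d_D3 = +0.60  d_solv = +1.53
subtotal = -2.73   d_IQA(excl. D3) = -1.20
snapshots used after 5% error filter: 95/95
```

The WHAM estimate recovers the analytic free-energy difference of the
generating double-well within its bootstrap error; the injected component
differences (+6.1 quantum, −8.9 electrostatic, +0.6 dispersion, +1.3
solvation, 0.5 kcal/mol snapshot noise) are recovered within sampling
error, and the 5 deliberately corrupted snapshots per ensemble are removed
by the error-quantile filter.

A command-line interface mirrors the library
(`cispro simulate | wham | decompose | steric | conform | validate | report`).

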