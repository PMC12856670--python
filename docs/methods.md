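# Methods

This note documents the models implemented in `cispro`, the conventions and
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.  It
states no empirical result that the test suite and `scripts/acceptance.py`
do not themselves compute.

## Coordinate, constants and units

The reaction coordinate is the amide torsion ω on the periodic interval
[0°, 360°), with the *trans* isomer defined as ω ∈ [90°, 270°) and *cis* as
the complement.  Energies are kcal/mol, distances Å, angles degrees.
Throughout: R = 1.9872159×10⁻³ kcal mol⁻¹ K⁻¹, T defaults to 300 K, the
Coulomb constant is 332.0637 kcal Å mol⁻¹ e⁻², 1 e·Å = 4.8032 D, and
1 eV = 23.0605 kcal/mol (used only at the IP/EA config boundary).

## Umbrella sampling and WHAM

Windows carry a harmonic bias K·d(ω, ω₀)² with d the minimum-image angular
difference in (−180°, 180°].  **Force-constant units are an explicit tag**
(`kcal/mol/deg^2` or `kcal/mol/rad^2`) carried by every window and never
converted silently: the two conventions differ by (π/180)² ≈ 3×10⁻⁴ and a
mistagged K silently destroys window overlap.  The packaged study
conditions use 120 windows at 3° spacing with K = 300 kcal mol⁻¹ rad⁻²
(≈ 0.0914 kcal mol⁻¹ deg⁻²), which gives biased distributions of width
σ = √(RT/2K) ≈ 1.8° — neighbouring windows overlap well.  The same
magnitude interpreted per-deg² would give σ ≈ 0.03° and no overlap at any
practical spacing, which is why the unit tag exists.

WHAM is solved by the standard self-consistent iteration on binned counts
(default 360 bins of 1°; the bin width is a package choice), with bias
energies evaluated at bin centers.  Convergence is declared when the
maximum absolute change of the window free-energy constants f_i between
iterations falls below the tolerance (default 10⁻⁵ kcal/mol); exceeding
`max_iterations` raises an error carrying the last residual.  Bins with no
counts in any window get +∞ free energy, are excluded from population sums,
and trigger a warning.  The profile is gauge-fixed to min G = 0.

Populations are accumulated two equivalent ways: bin sums of exp(−G/RT)
over each interval (default), and a binless route that sums per-sample
WHAM/MBAR weights — exposed because the two differ only by binning and the
agreement is itself a useful diagnostic.  ΔG(*cis*→*trans*) =
−RT ln(P_trans/P_cis); negative values mean *trans* is more stable.

Bootstrap errors resample each window independently with replacement.  In
synthetic mode the samples are i.i.d. by construction, so resampling acts
on individual samples; this is implemented as a multinomial redraw of each
window's histogram, which is exactly equivalent after binning and much
faster.  A `block_length` option resamples contiguous blocks of the raw
series for autocorrelated inputs.  Forward and reverse umbrella runs are
combined by arithmetic averaging with |forward − reverse| reported as the
hysteresis.

The test suite cross-checks the fixed-point solver against an independent
route: direct quasi-Newton minimization of the convex WHAM log-likelihood
F(f) = Σ_j h_j ln Σ_i N_i e^{(f_i − c_ij)/RT} − Σ_i N_i f_i/RT, requiring
per-bin agreement below 0.01 kcal/mol.

## IQA data model and regrouping

A snapshot stores per-atom basin terms (kinetic T^A, nucleus–electron
V_ne^A, intra-basin Coulomb V_ee,Coul^A and exchange–correlation V_ee,xc^A,
electron population n_A), per-pair terms (V_nn, the two directed V_ne
terms, V_ee,Coul, V_ee,xc, and the pairwise D3 dispersion energy), per-atom
solvation terms (electrostatic + CDS), and a reference total energy E_ref.
Pairs are stored once per unordered pair; **missing pairs are exactly zero
interaction** (sparse contract, with a warning on explicit lookup).

The four-component regrouping assigns every pairwise term half to each
partner atom — symmetric halving, no asymmetric sharing:

- E_T,xc^A = T^A + V_ee,xc^A + ½ Σ_B V_ee,xc^AB  (quantum)
- E_elec^A = V_ne^A + V_ee,Coul^A + ½ Σ_B (V_nn + V_ne^AB + V_ne^BA + V_ee,Coul)^AB
- E_D3^A = ½ Σ_B E_D3^AB
- E_solv^A = E_solv,elec^A + E_solv,CDS^A

This is an exact rearrangement: the column sums reproduce the directly
accumulated total on every snapshot (tested at 10⁻⁹ relative), and the
decomposition is linear in the raw terms.

**Error filtering.**  The signed reconstruction error is E_IQA − E_ref.
Ensemble averaging discards snapshots whose |error| lies strictly above the
empirical (1 − q) quantile of |error| (default q = 0.05, i.e. the worst 5%
are dropped); ties are retained and at least one snapshot always survives.
Filtering is applied to each isomer ensemble independently, before
differencing.  The default q and the "worst 5%" reading reflect the
purpose of the filter: removing the tail of numerically failed
decompositions so that error cancellation in the average can act.

**Ensemble decomposition.**  Component-wise ⟨trans⟩ − ⟨cis⟩ differences are
reported with standard errors sd/√n per ensemble, combined in quadrature;
snapshots are treated as statistically independent (they are widely spaced
MD frames in the intended application and i.i.d. in synthetic mode — block
averaging is not implemented).  Two reconstructions are reported: the
tabulated ΔE_IQA excluding dispersion (ΔE_T,xc + ΔE_elec + ΔE_solv) and the
full sum including ΔE_D3, which also equals the monatomic/diatomic split
ΔE_net + ΔE_solv + ½ΔE_int + ½ΔE_D3.

Fragment aggregation sums atomic values over a user partition and sums
pairwise (elec + xc) interactions across fragment boundaries; grand totals
are conserved by construction.  The short/medium range split classifies
pair terms by bond-path distance on the covalent graph: atomic terms plus
1–2 and 1–3 pairs are short range, 1–4 and beyond (and disconnected pairs,
with a warning) are medium.  The hyperconjugation descriptor sums pairwise
xc energies over the cross pairs of two disjoint atom selections (e.g. a
donor carbonyl oxygen against an acceptor C=O), ensemble-averaged,
trans-minus-cis.

## Steric descriptor

E(n) for each element is piecewise linear through the charge states:
E(N) = 0, E(N−1) = +IP, E(N+1) = −EA; outside [N−1, N+1] the nearest
segment is extended linearly with a warning.  IP/EA are config data
(`data/atom_reference.yaml`, stored in eV with the source noted), not code
constants; nitrogen's EA is clamped to 0 because the neutral atom has no
stable anion and the descriptor requires a monotone anionic segment.
E_CT^A = E(n̄_trans) − E(n̄_cis) is evaluated on **ensemble-mean
populations** by default; averaging E(n) per snapshot is available as an
option and agrees exactly whenever both populations stay on one linear
segment.  E_ST = E_def − E_CT holds exactly atom-by-atom and in every
fragment aggregate.

## Solvation partition

The electrostatic solvation energy ½ Σ_k q_k Φ(s_k) partitions into atomic
terms through the additivity of the solute potential, Φ = Σ_A Φ^A — an
identity that holds for any charge model.  The toy solutes therefore use
point charges (optionally point dipoles) in place of basin-confined
densities; this is the honest scope of the module: it verifies the
partition identities and the surface-term plumbing, not a
boundary-element continuum solver.  Tessera charges use the conductor-like
scaling f(ε) = (ε − 1)/ε with ε = 78.4 for water on a deterministic
golden-spiral tessellation; for a charge-centred spherical cavity this
reproduces the Born closed form.

SASA is a deterministic Shrake–Rupley construction (golden-spiral test
points, default 960; probe 1.4 Å; Bondi radii shipped as config).  Totals
are exactly invariant under atom reordering and rigid translation; rigid
*rotation* changes per-atom values only at the point-grid discretisation
level (sub-percent at the default density), as in any fixed-grid SASA
implementation.  The CDS term (γ_A + γ^M)·σ_A is linear in the surfaces;
the shipped γ values are placeholders of plausible magnitude and are
flagged as such in the config file, since published continuum
parameterizations do not expose per-element tensions in a reusable form.

## Conformational analysis

Torsions are discretized by periodic state boundaries (defaults: 3 states
at {0°, 120°, 240°} for sp³-like torsions, 2 states for amide ω; both
config).  The first-order entropy is −R Σ_s p_s ln p_s summed over
torsions.  Inter-torsion correlation is removed at pairwise order:
S = Σ S1_j − Σ_{j<k} max(0, MI_jk − null_jk), where null_jk is the mean
mutual information of shuffle-randomized replicas (shuffling one column
destroys correlation while preserving marginals, so the null estimates the
finite-sampling MI bias).  The corrected entropy never exceeds the
first-order value and is floored at zero with a warning.  Truncating the
correlation expansion at order 2 is a deliberate scope decision: it
preserves the estimator structure that matters (bias-corrected MI
subtraction, convergence monitoring) while higher-order multibody schemes
require choices that are not testable against closed forms.  Convergence
curves evaluate the estimator on growing trajectory prefixes; the limiting
uncertainty is the spread over the final quarter of the grid.  −T·S is
reported at an explicit temperature.

Ring pucker uses the pseudorotation relation θ_j = A cos(P + 4πj/5) over
the five endocyclic torsions; the cos/sin basis is orthogonal, so the
least-squares fit is closed-form and the round trip with the generator is
exact to numerical precision.  Planar rings (A below threshold) have an
undefined phase, flagged rather than guessed.  Endo/exo classification is
an interval test on P with a configurable boundary (default endo =
[90°, 270°)); the interval is a convention choice and is reported with the
results.  Flip rates count class crossings per unit simulation time.

Noncovalent contacts are geometric stand-ins for density-topology
detection: distance (and optionally donor–H···acceptor angle) criteria,
with 1–2 and 1–3 bonded pairs excluded.  Default cutoffs (config): polar
H-bond 2.5 Å / 120°; CH···O 2.8 Å; CH···HC 2.4 Å; C(π)···HC 2.9 Å.
Contact statistics count contacts with population above 5% and report
their mean and maximum populations.

## Synthetic data: what it emulates and what it does not

The generator supplies every input with known ground truth:

- **Window series** are exact inverse-CDF draws on a 0.1° grid from the
  biased Boltzmann density of a known Fourier potential.  The packaged
  double-well (U = 0.75 cos ω − 6.5 cos 2ω, wells at 0°/180°, ~12 kcal/mol
  barrier, trans deeper by ~1.5 kcal/mol) has the magnitude typical of
  capped dipeptides.  Sampling is i.i.d. — there is no autocorrelation, no
  hysteresis between forward/reverse runs beyond sampling noise, and no
  slow orthogonal degrees of freedom.  Passing WHAM tests therefore
  demonstrates correct unbiasing and error propagation, not robustness to
  correlated or quasi-nonergodic MD data.
- **IQA ensembles** realize prescribed per-atom component differences by
  construction (quantum targets through T^A, electrostatic through V_ne^A,
  solvation through E_solv,elec^A, dispersion through a least-squares
  allocation over pairwise D3 terms whose half-shares reproduce the
  per-atom targets exactly), plus Gaussian snapshot noise and a designated
  fraction of outlier snapshots carrying a fixed 50 kcal/mol discrepancy
  between E_ref and the reconstructable sum — mimicking a failed basin
  integration.  Real IQA errors are smaller, correlated across terms, and
  not bimodal; the construction is designed to make filter behaviour
  exactly checkable, not realistic.
- **Torsion chains** are stationary ergodic state sequences with tunable
  inter-torsion coupling (probability of copying a reference torsion) and
  optional first-order memory that preserves the stationary distribution.
  Coupling 0 gives exactly independent columns; coupling 1 gives
  deterministic copies with known joint entropy.
- **Ring conformers** follow the pseudorotation relation exactly.

Defaults throughout are the study conditions: 300 K; 120 windows, 3°
spacing, K = 300 kcal mol⁻¹ rad⁻², 5000 samples per window; 100 snapshots
per isomer ensemble, noise 0.5 kcal/mol, 5% outliers, 5% filter quantile;
2.5 ps frame spacing.

## Numerical choices and degenerate inputs

- Minimum-image convention maps differences to (−180°, 180°], with −180°
  mapped to +180°.
- The quantile filter uses NumPy's default (linear-interpolation)
  empirical quantile; ties at the cutoff are retained.
- Zero-variance windows bootstrap to exactly zero error; empty windows and
  empty ensembles are rejected with explicit messages.
- Dipole moments of charged systems are referred to the center of mass
  (geometric center without masses) and flagged as origin-dependent;
  neutral systems are origin-independent to round-off.
- All generators and the bootstrap accept explicit seeds; identical seeds
  give bit-identical outputs, and the pipeline report embeds a hash of its
  serialized configuration.

## Problem sizes used by the checks

The test suite and acceptance script run at the study conditions above;
the heaviest check (free-energy recovery across 20 generator seeds with
15 bootstrap replicates each) completes in about two minutes on one CPU,
and the remaining stages in seconds.  These sizes were chosen as the
smallest at which the statistical claims being tested (bootstrap coverage,
recovery within stated standard errors) are meaningful.

## Known limitations

- No MBAR generalization, 2-D profiles, or adaptive biasing; WHAM bias
  energies are evaluated at bin centers.
- Standard errors assume independent snapshots; block averaging is not
  implemented.
- The entropy correction stops at pairwise order and can under-remove
  higher-order correlation; it never goes below zero but that floor is a
  clamp, not an estimate.
- The solvation module does not construct solvent-excluded surfaces with
  reentrant patches and does not solve the continuum boundary-element
  equations self-consistently; its CDS tensions are placeholders.
- Contact detection is purely geometric and will disagree with
  density-topology methods near criterion boundaries.
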