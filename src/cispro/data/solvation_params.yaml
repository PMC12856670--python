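# Solvation-partition config: Bondi van der Waals radii (Angstrom) and
# surface-tension parameters (kcal/mol/A^2) for the CDS term.
#
# The gamma values below are PLACEHOLDERS of a plausible magnitude: the
# published continuum-solvation parameterizations do not expose per-element
# tensions in a reusable form, and the partition identities this package
# checks are linear in gamma, so any values exercise them.  Override for
# production use.
note: "gamma values are placeholders; Bondi radii; probe 1.4 A"
probe_radius: 1.4
n_points: 960
gamma_molecular: 0.005
gamma:
  H: 0.010
  C: 0.012
  N: 0.008
  O: 0.009
  S: 0.011
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
  Cl: 1.75
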