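# Conceptual-DFT atomic reference states for the charge-transfer energy.
#
# n_neutral: electron count of the neutral atom; ip / ea: first ionization
# potential and electron affinity in eV (converted to kcal/mol at load time,
# 1 eV = 23.0605 kcal/mol).  Values are standard gas-phase atomic data
# (NIST ASD / CRC Handbook).  Nitrogen has no stable anion (its measured
# electron affinity is slightly negative), so ea(N) is clamped to 0.0 to
# keep the piecewise E(n) monotone on the anionic segment.
units: eV
elements:
  H:  {n_neutral: 1,  ip: 13.598, ea: 0.754}
  C:  {n_neutral: 6,  ip: 11.260, ea: 1.262}
  N:  {n_neutral: 7,  ip: 14.534, ea: 0.000}
  O:  {n_neutral: 8,  ip: 13.618, ea: 1.461}
  S:  {n_neutral: 16, ip: 10.360, ea: 2.077}
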