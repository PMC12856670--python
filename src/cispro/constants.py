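"""Physical constants and unit conversions used across the package.

All energies are kcal/mol, distances Angstrom, angles degrees unless a
function states otherwise.
"""

# Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872159e-3

# Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0

# Coulomb constant for point charges: E[kcal/mol] = COULOMB_K * q1*q2 / r[A]
COULOMB_K = 332.0637

# Dipole conversion: 1 e.Angstrom = 4.8032 Debye
DEBYE_PER_E_ANGSTROM = 4.8032

# Electronvolt to kcal/mol (used only at the config boundary for IP/EA tables)
EV_TO_KCAL = 23.0605

# Water relative permittivity for the conductor-like surface-charge scaling
WATER_EPSILON = 78.4
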