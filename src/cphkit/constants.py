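"""Physical constants and unit conventions.

Internal units throughout the package: energies in kJ/mol, time in ps,
masses in amu (g/mol), temperatures in K, angles in radians.  With these
units 1 kJ/mol = 1 amu (unit-lambda/ps)^2, so kinetic energy is simply
``0.5 * m * v**2``.  Degrees are accepted and emitted only at the I/O
boundary (config files, CSV columns).
"""

#: Boltzmann constant in kJ mol^-1 K^-1
KB = 0.0083144621

#: natural log of 10, for pH free-energy terms ln(10)*kB*T*(pKa - pH)
import math

LN10 = math.log(10.0)


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
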