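"""Physical constants and unit conventions.

Units are fixed package-wide: energies in kJ/mol, lengths in nm, times in ps,
temperatures in K, charges in units of the elementary charge e.
"""

import math

#: Gas constant in J mol^-1 K^-1 (value used throughout the titration algebra).
GAS_CONSTANT_J = 8.314

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = GAS_CONSTANT_J * 1e-3

LN10 = math.log(10.0)


def rt_kj(temperature: float) -> float:
    """Thermal energy R*T in kJ/mol."""
    return GAS_CONSTANT_KJ * temperature


def rt_ln10(temperature: float) -> float:
    """R*T*ln(10) in kJ/mol: the free energy of one pH (or pKa) unit."""
    return GAS_CONSTANT_KJ * temperature * LN10
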