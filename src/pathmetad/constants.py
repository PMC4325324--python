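"""Physical constants and unit conventions.

Units used throughout the package: length nm, time ps, energy kJ/mol,
temperature K, mass amu.  MSD-based quantities are nm**2 and the path-metric
constant lambda is nm**-2.
"""

#: Boltzmann constant in kJ/(mol*K)
KB = 0.0083144621


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
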