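"""Physical constants in the unit system used throughout the package.

Energies are kcal/mol, temperatures Kelvin, distances Angstrom, times ps
(trajectory/pulling modules). Rates are in "reduced rate units": the
transition-state-theory prefactor k_B*T/h times the dimensionless frequency
factor is absorbed into a single user-settable scale constant, because every
network-level conclusion the solver produces is a rate ratio.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 310.0


def rt(temperature: float) -> float:
    """R*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
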