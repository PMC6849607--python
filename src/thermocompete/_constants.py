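"""Physical constants shared across the package."""

#: Boltzmann constant in electronvolts per Kelvin.
BOLTZMANN_EV_K: float = 8.617333e-5

#: Additive offset converting degrees Celsius to Kelvin.
CELSIUS_OFFSET: float = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from Celsius to Kelvin."""
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    """Convert a temperature from Kelvin to Celsius."""
    return t_kelvin - CELSIUS_OFFSET
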