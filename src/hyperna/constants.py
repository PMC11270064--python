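"""Physical constants, in the unit convention of the ventricular cell models
(time ms, voltage mV, concentration mmol/L, current A/F)."""

#: Gas constant, J / (kmol K)  -> R*T/F comes out in mV
R = 8314.0
#: Faraday constant, C / mol
F = 96485.0
#: Physiological temperature used by both cell models, K
T_BODY = 310.0


def rt_over_f(temperature: float = T_BODY) -> float:
    """R*T/F in mV."""
    return R * temperature / F
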