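"""Analytic toy excitable cell for fast protocol/biomarker testing.

Three variables (Vm, Na-channel inactivation h, K-channel activation n)
with a K+ leak, a Na+ leak, an optional constant outward pump and a fast
regenerative inward current.  At rest the regenerative current is shut
(m_inf(V_rest) ~ 0), so the resting potential has the chord-conductance
closed form

    V_rest = (gK*EK + gNa_leak*ENa - I_pump) / (gK + gNa_leak)

and the firing threshold is monotone in the regenerative conductance.

Hypernatremia hooks: EK and ENa are computed from the condition milieu
and fixed intracellular concentrations; osmotic shrinkage concentrates
the intracellular ions by the active-volume factor implied by the
relative volume; the pump leak scales with f_INaK.  The toy is fully
deterministic and integrates in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import rt_over_f
from ..osmotic import ExtracellularMilieu
from .base import (
    P_FNAK,
    P_ISTIM,
    P_KO,
    P_MASK,
    P_NAO,
    P_VFRAC,
    ModelDef,
)

STATE_NAMES = ("vm", "h", "n")

_INACTIVE_FRACTION = 0.32  # matches the osmotic volume model default


@dataclass(frozen=True)
class ToyParams:
    g_k: float = 0.09          # K+ leak conductance, mS/uF
    g_na_leak: float = 0.01    # Na+ leak conductance, mS/uF
    g_na_fast: float = 8.0     # regenerative inward conductance, mS/uF
    g_k_rep: float = 0.5       # delayed repolarizing conductance, mS/uF
    g_pump: float = 0.0        # constant outward pump current, A/F
    k_i: float = 145.6         # fixed intracellular K+, mmol/L
    na_i: float = 10.0         # fixed intracellular Na+, mmol/L
    ek: float | None = None    # explicit Nernst potentials override the
    ena: float | None = None   # milieu-based ones when set
    temperature: float = 310.0

    def __post_init__(self) -> None:
        for name in ("g_k", "g_na_leak", "g_na_fast", "g_k_rep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def resting_potential(params: ToyParams, ek: float, ena: float) -> float:
    """Chord-conductance resting potential (regenerative current shut)."""
    return (params.g_k * ek + params.g_na_leak * ena - params.g_pump) / (
        params.g_k + params.g_na_leak
    )


def toy_model(params: ToyParams = ToyParams()) -> ModelDef:
    """Build a registered-interface model from toy parameters."""
    rtf = rt_over_f(params.temperature)

    def _potentials(p):
        if params.ek is not None and params.ena is not None:
            return params.ek, params.ena
        # shrinkage concentrates the fixed intracellular ions
        vfrac = p[P_VFRAC]
        gain = (1.0 - _INACTIVE_FRACTION) / (vfrac - _INACTIVE_FRACTION)
        ek = rtf * np.log(p[P_KO] / (params.k_i * gain))
        ena = rtf * np.log(p[P_NAO] / (params.na_i * gain))
        return ek, ena

    def rhs(t, y, p):
        v, h, n = y
        ek, ena = _potentials(p)
        minf = 1.0 / (1.0 + np.exp(-(v + 38.0) / 4.0))
        hinf = 1.0 / (1.0 + np.exp((v + 60.0) / 6.0))
        ninf = 1.0 / (1.0 + np.exp(-(v + 30.0) / 5.0))
        mask = p[P_MASK]
        i_k = params.g_k * (v - ek) * mask
        i_na_leak = params.g_na_leak * (v - ena) * mask
        i_na_fast = params.g_na_fast * minf ** 3 * h * (v - ena) * mask
        i_k_rep = params.g_k_rep * n * (v - ek) * mask
        i_pump = params.g_pump * p[P_FNAK] * mask
        dv = -(i_k + i_na_leak + i_na_fast + i_k_rep + i_pump + p[P_ISTIM])
        return np.array([dv, (hinf - h) / 2.0, (ninf - n) / 15.0])

    def currents(y, p):
        v, h, n = y
        ek, ena = _potentials(p)
        minf = 1.0 / (1.0 + np.exp(-(v + 38.0) / 4.0))
        cur = np.zeros(18)
        cur[0] = params.g_na_fast * minf ** 3 * h * (v - ena)  # i_na
        cur[6] = params.g_k_rep * n * (v - ek)                 # i_kr-like
        cur[8] = params.g_k * (v - ek)                         # i_k1-like
        cur[9] = params.g_pump * p[P_FNAK]                     # i_nak-like
        cur[12] = params.g_na_leak * (v - ena)                 # i_nab-like
        return cur

    p0 = np.zeros(13)
    p0[P_NAO] = 140.0
    p0[P_KO] = 5.0
    p0[P_VFRAC] = 1.0
    p0[P_FNAK] = 1.0
    p0[P_MASK] = 1.0
    if params.ek is not None and params.ena is not None:
        ek0, ena0 = params.ek, params.ena
    else:
        ek0 = rtf * np.log(p0[P_KO] / params.k_i)
        ena0 = rtf * np.log(p0[P_NAO] / params.na_i)
    v0 = resting_potential(params, ek0, ena0)
    y0 = np.array(
        [
            v0,
            1.0 / (1.0 + np.exp((v0 + 60.0) / 6.0)),
            1.0 / (1.0 + np.exp(-(v0 + 30.0) / 5.0)),
        ]
    )

    return ModelDef(
        model_id="toy",
        name="analytic toy excitable cell",
        baseline_milieu=ExtracellularMilieu(na_e=140.0, k_e=5.0, ca_e=1.8, cl_e=150.0),
        temperature=params.temperature,
        state_names=STATE_NAMES,
        y0=y0,
        rhs=rhs,
        currents=currents,
        conc_indices={},
        notes="closed-form test fixture; not a physiological model",
    )
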