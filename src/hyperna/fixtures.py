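"""Deterministic synthetic inputs with closed-form ground truth.

These stand in for full-model runs so the protocol and biomarker code is
testable in milliseconds.  The trace fixture is piecewise linear, so every
biomarker has an exact closed form; the toy sweep exercises the whole
condition -> threshold -> biomarker pipeline on the analytic cell.
No randomness is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models.base import N_CURRENTS
from .models.toy import ToyParams, toy_model
from .osmotic import build_condition
from .protocols import PacedTrace, PacingProtocol, find_threshold, pace

__all__ = ["SyntheticTruth", "synthetic_ap_trace", "toy_condition_sweep"]


@dataclass(frozen=True)
class SyntheticTruth:
    rmp: float
    apa: float
    apd50: float
    apd90: float
    dvdt_max: float


def synthetic_ap_trace(
    rest: float = -85.0,
    peak: float = 35.0,
    apd90_true: float = 300.0,
    rate: float = 60.0,
    n_beats: int = 5,
    rise: float = 2.0,
    pulse_width: float = 1.0,
    dt: float = 0.05,
    t_offset: float = 0.0,
) -> tuple[PacedTrace, SyntheticTruth]:
    """Piecewise-linear AP train with attached closed-form biomarkers.

    Geometry per beat: Vm sits at ``rest`` during the stimulus pulse, rises
    linearly to ``peak`` over ``rise`` ms, then decays linearly back to
    ``rest`` over a span chosen so that the 90 %-repolarization duration,
    measured from the (dVm/dt)max instant at pulse offset, is exactly
    ``apd90_true``.  ``t_offset`` shifts the whole time axis (biomarkers
    must be invariant to it).
    """
    if rest >= peak:
        raise ValueError("rest must lie below peak")
    cl = 60000.0 / rate
    decay = (apd90_true - rise) / 0.9
    if decay <= 0 or pulse_width + rise + decay >= cl:
        raise ValueError("infeasible AP geometry for this cycle length")
    apa = peak - rest

    def vm_of(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Waveform and right-derivative on intra-beat time tau."""
        v = np.full_like(tau, rest)
        dv = np.zeros_like(tau)
        up = (tau >= pulse_width) & (tau < pulse_width + rise)
        v[up] = rest + apa * (tau[up] - pulse_width) / rise
        dv[up] = apa / rise
        down = (tau >= pulse_width + rise) & (tau < pulse_width + rise + decay)
        v[down] = peak - apa * (tau[down] - pulse_width - rise) / decay
        dv[down] = -apa / decay
        return v, dv

    tau = np.arange(0.0, cl, dt)
    v_beat, dv_beat = vm_of(tau)
    t = np.concatenate([tau + k * cl for k in range(n_beats)]) + t_offset
    vm = np.tile(v_beat, n_beats)
    dvm = np.tile(dv_beat, n_beats)
    # closing sample so the final beat is a complete cycle
    t = np.append(t, n_beats * cl + t_offset)
    vm = np.append(vm, rest)
    dvm = np.append(dvm, 0.0)
    stim_times = np.arange(n_beats) * cl + t_offset

    protocol = PacingProtocol(
        rate=rate,
        pulse_width=pulse_width,
        total_duration_min=n_beats / rate,
        analysis_window_s=n_beats * cl / 1000.0,
        fine_dt=dt,
        coarse_dt=dt,
    )
    trace = PacedTrace(
        model_id="synthetic",
        condition=None,
        protocol=protocol,
        stim_amplitude=0.0,
        t=t,
        states=vm[:, None],
        dvm=dvm,
        currents=np.zeros((len(t), N_CURRENTS)),
        stim_times=stim_times,
        state_names=("vm",),
        final_state=np.array([rest]),
    )
    truth = SyntheticTruth(
        rmp=rest,
        apa=apa,
        apd50=rise + 0.5 * decay,
        apd90=apd90_true,
        dvdt_max=apa / rise,
    )
    return trace, truth


def toy_condition_sweep(
    levels=(0.0, 0.10, 0.20, 0.50),
    params: ToyParams = ToyParams(g_pump=0.05),
    rate: float = 60.0,
) -> pd.DataFrame:
    """Resting potential and threshold current of the toy cell across
    hypernatremia levels (milieu, scaling and shrinkage all applied)."""
    model = toy_model(params)
    protocol = PacingProtocol(rate=rate, total_duration_min=0.05,
                              analysis_window_s=3.0 / rate)
    rows = []
    for level in levels:
        cond = build_condition(level, "toy", baseline=model.baseline_milieu)
        # settle to the condition's rest with a brief quiescent run
        trace = pace(model, cond, protocol, stim_amplitude=0.0)
        y_rest = trace.final_state
        thr = find_threshold(model, y_rest, cond, protocol, bracket=(0.1, 50.0))
        rows.append(
            {
                "level": level,
                "rmp": float(y_rest[0]),
                "ith": thr.i_threshold,
            }
        )
    return pd.DataFrame(rows)
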