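"""Pacing to quasi-steady state, threshold-current search, trace capture.

The protocol mirrors the study design: a cell is paced with 1-ms current
pulses at 50, 75 or 100 stimuli per minute for 10 simulated minutes — long
enough for quasi-steady behaviour — and the final five seconds are captured
at high resolution for biomarker extraction.  Stimulus amplitudes are
expressed as positive magnitudes in A/F; the pulse is applied as an inward
(negative) current and is assigned to the K+ balance, following the source
models' convention.

Integration uses the adaptive stiff LSODA method (relative tolerance 1e-7,
per-variable absolute tolerances) restarted at every stimulus edge, so the
discontinuous pulse never crosses an integrator step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.integrate import odeint

from .models.base import ModelDef, N_CURRENTS
from .osmotic import PerturbedCondition

__all__ = [
    "PacingProtocol",
    "PacedTrace",
    "ThresholdResult",
    "BracketingError",
    "SolverError",
    "pace",
    "find_threshold",
    "quasi_steady_check",
]


class BracketingError(RuntimeError):
    """Both or neither end of the initial bracket elicits an AP."""


class SolverError(RuntimeError):
    """Stiff integration failed; message carries the last valid time."""


@dataclass(frozen=True)
class PacingProtocol:
    rate: float = 50.0              # stimuli per minute
    pulse_width: float = 1.0        # ms
    total_duration_min: float = 10.0
    analysis_window_s: float = 5.0
    rtol: float = 1e-7
    fine_dt: float = 0.05           # ms, output step around the upstroke
    coarse_dt: float = 1.0          # ms, output step elsewhere
    fine_span: float = 60.0         # ms of fine output after stimulus onset

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.pulse_width <= 0:
            raise ValueError("rate and pulse_width must be positive")
        if self.analysis_window_s * 1000.0 > self.total_duration_min * 60000.0:
            raise ValueError("analysis window longer than total duration")

    @property
    def cycle_length(self) -> float:
        """ms between stimuli."""
        return 60000.0 / self.rate

    @property
    def n_beats(self) -> int:
        return int(round(self.rate * self.total_duration_min))


@dataclass
class PacedTrace:
    """High-resolution capture of the analysis window of a paced run."""

    model_id: str
    condition: PerturbedCondition | None
    protocol: PacingProtocol
    stim_amplitude: float           # magnitude, A/F
    t: np.ndarray                   # ms, global simulation time
    states: np.ndarray              # (n_t, n_states)
    dvm: np.ndarray                 # mV/ms at the samples
    currents: np.ndarray            # (n_t, N_CURRENTS), A/F
    stim_times: np.ndarray          # onsets of captured stimuli, ms
    state_names: tuple[str, ...]
    final_state: np.ndarray
    missed_beats: list[int] = field(default_factory=list)

    @property
    def vm(self) -> np.ndarray:
        return self.states[:, 0]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def current(self, name: str) -> np.ndarray:
        from .models.base import CURRENT_NAMES

        if name == "i_naca":
            return self.current("i_naca_i") + self.current("i_naca_ss")
        if name == "i_cl":
            return self.current("i_clca") + self.current("i_clb")
        return self.currents[:, CURRENT_NAMES.index(name)]


@dataclass(frozen=True)
class ThresholdResult:
    i_threshold: float              # magnitude, A/F
    bracket: tuple[float, float]
    iterations: int


def _atol_vector(model: ModelDef) -> np.ndarray:
    atol = np.full(model.n_states, 1e-7)
    for i, name in enumerate(model.state_names):
        if name in ("cai", "cass"):
            atol[i] = 1e-9
        elif name in ("cansr", "cajsr"):
            atol[i] = 1e-8
        elif name == "vm":
            atol[i] = 1e-5
    return atol


def _segment(model, y, p, t0, t1, rtol, atol, t_eval=None):
    """Integrate one constant-stimulus segment; return (samples, y_end)."""
    if t_eval is None:
        ts = np.array([t0, t1])
    else:
        ts = t_eval
    sol, info = odeint(
        model.rhs,
        y,
        ts,
        args=(p,),
        tfirst=True,
        rtol=rtol,
        atol=atol,
        mxstep=200000,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise SolverError(
            f"{model.model_id}: LSODA failed near t={info['tcur'][-1]:.3f} ms "
            f"({info['message']})"
        )
    y_end = sol[-1]
    model.validate_state(y_end)
    return sol, y_end


def _beat_grid(t0: float, cl: float, pw: float, proto: PacingProtocol):
    """Output grids for the stimulus-on and stimulus-off segments of a beat."""
    fine_end = min(proto.fine_span, cl)
    g_on = np.arange(0.0, pw + 1e-9, proto.fine_dt)
    if g_on[-1] < pw:
        g_on = np.append(g_on, pw)
    g_off = np.arange(pw, fine_end + 1e-9, proto.fine_dt)
    if fine_end < cl:
        coarse = np.arange(fine_end + proto.coarse_dt, cl + 1e-9, proto.coarse_dt)
        g_off = np.concatenate([g_off, coarse])
    if g_off[-1] < cl:
        g_off = np.append(g_off, cl)
    return t0 + g_on, t0 + g_off


def pace(
    model: ModelDef,
    condition: PerturbedCondition | None,
    protocol: PacingProtocol,
    stim_amplitude: float,
    y0: np.ndarray | None = None,
    step_concentrations: bool = True,
) -> PacedTrace:
    """Pace for the protocol duration and capture the analysis window.

    ``step_concentrations`` (the default, matching the acute water-loss
    physics) applies the mole-conservation step at shrinkage onset: every
    intracellular concentration state is multiplied by the active-volume
    concentration factor before integration starts, because the exiting
    water leaves the dissolved ions behind.
    """
    if stim_amplitude < 0:
        raise ValueError("stim_amplitude is a magnitude; must be >= 0")
    y = model.initial_state() if y0 is None else np.array(y0, dtype=float)
    if step_concentrations and condition is not None and condition.apply_shrinkage:
        q = condition.volume_model.inactive_fraction
        gain = (1.0 - q) / (condition.volume_fraction - q)
        for idx in model.conc_indices.values():
            y[idx] *= gain

    p_on = model.pack_params(condition, istim=-stim_amplitude)
    p_off = model.pack_params(condition, istim=0.0)
    atol = _atol_vector(model)
    rtol = protocol.rtol
    cl = protocol.cycle_length
    pw = protocol.pulse_width
    n_beats = protocol.n_beats

    n_capture = min(n_beats, math.ceil(protocol.analysis_window_s * 1000.0 / cl))
    first_captured = n_beats - n_capture

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    stim_times: list[float] = []
    missed: list[int] = []

    for beat in range(n_beats):
        t0 = beat * cl
        if beat < first_captured:
            _, y = _segment(model, y, p_on, t0, t0 + pw, rtol, atol)
            _, y = _segment(model, y, p_off, t0 + pw, t0 + cl, rtol, atol)
            continue
        g_on, g_off = _beat_grid(t0, cl, pw, protocol)
        sol_on, y = _segment(model, y, p_on, t0, t0 + pw, rtol, atol, t_eval=g_on)
        sol_off, y = _segment(
            model, y, p_off, t0 + pw, t0 + cl, rtol, atol, t_eval=g_off
        )
        # the beat-start sample duplicates the previous beat's closing one
        drop = 1 if ts else 0
        ts.append(g_on[drop:])
        ys.append(sol_on[drop:])
        ts.append(g_off[1:])
        ys.append(sol_off[1:])
        stim_times.append(t0)
        beat_vm = max(sol_on[:, 0].max(), sol_off[:, 0].max())
        if beat_vm < 0.0:
            missed.append(beat)

    t = np.concatenate(ts)
    states = np.vstack(ys)

    dvm = np.empty(len(t))
    currents = np.empty((len(t), N_CURRENTS))
    stim_set = np.asarray(stim_times)
    for i in range(len(t)):
        in_pulse = np.any((t[i] >= stim_set) & (t[i] < stim_set + pw))
        p = p_on if in_pulse else p_off
        dvm[i] = model.rhs(t[i], states[i], p)[0]
        currents[i] = model.currents(states[i], p)

    return PacedTrace(
        model_id=model.model_id,
        condition=condition,
        protocol=protocol,
        stim_amplitude=stim_amplitude,
        t=t,
        states=states,
        dvm=dvm,
        currents=currents,
        stim_times=stim_set,
        state_names=model.state_names,
        final_state=y,
        missed_beats=missed,
    )


def _elicits_ap(
    model: ModelDef,
    y_diastolic: np.ndarray,
    condition: PerturbedCondition | None,
    protocol: PacingProtocol,
    amplitude: float,
    window: float,
) -> bool:
    """True if a 1-ms pulse of this magnitude drives Vm above 0 mV within
    ``window`` ms of pulse onset."""
    if amplitude == 0.0:
        return False
    p_on = model.pack_params(condition, istim=-amplitude)
    p_off = model.pack_params(condition, istim=0.0)
    atol = _atol_vector(model)
    pw = protocol.pulse_width
    grid_on = np.linspace(0.0, pw, 6)
    sol_on, y = _segment(model, y_diastolic, p_on, 0.0, pw, protocol.rtol, atol,
                         t_eval=grid_on)
    if sol_on[:, 0].max() > 0.0:
        return True
    grid_off = np.arange(pw, window + 1e-9, 0.5)
    sol_off, _ = _segment(model, y, p_off, pw, window, protocol.rtol, atol,
                          t_eval=grid_off)
    return sol_off[:, 0].max() > 0.0


def find_threshold(
    model: ModelDef,
    y_diastolic: np.ndarray,
    condition: PerturbedCondition | None,
    protocol: PacingProtocol,
    bracket: tuple[float, float] = (0.5, 200.0),
    rel_tol: float = 0.005,
    window: float = 50.0,
) -> ThresholdResult:
    """Bisection for the minimal 1-ms pulse magnitude that elicits an AP.

    The search starts from the condition's quasi-steady diastolic state.
    An amplitude elicits an AP iff Vm exceeds 0 mV within 50 ms of pulse
    onset.  Converges to a relative bracket width of 0.5 %.
    """
    lo, hi = bracket
    if not (0.0 <= lo < hi):
        raise ValueError("bracket must satisfy 0 <= lo < hi")
    fires_lo = _elicits_ap(model, y_diastolic, condition, protocol, lo, window)
    fires_hi = _elicits_ap(model, y_diastolic, condition, protocol, hi, window)
    if fires_lo and fires_hi:
        raise BracketingError(
            f"both bracket ends fire (lo={lo}, hi={hi}); lower the bracket"
        )
    if not fires_lo and not fires_hi:
        raise BracketingError(
            f"neither bracket end fires (lo={lo}, hi={hi}); raise the bracket"
        )
    iterations = 0
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if _elicits_ap(model, y_diastolic, condition, protocol, mid, window):
            hi = mid
        else:
            lo = mid
        iterations += 1
    return ThresholdResult(i_threshold=hi, bracket=(lo, hi), iterations=iterations)


def quasi_steady_check(trace: PacedTrace) -> tuple[bool, dict[str, float]]:
    """Beat-to-beat stability of APD90 and diastolic [Na+]i.

    Returns (flag, deltas); flag is True when the maximum relative
    beat-to-beat change of both quantities over the analysis window is
    below 0.5 %.
    """
    from .biomarkers import beats, _apd

    beat_list = beats(trace)
    if len(beat_list) < 2:
        raise ValueError("quasi-steady check needs at least 2 complete beats")
    apd90s = []
    na_dia = []
    has_na = "nai" in trace.state_names
    for b in beat_list:
        apd90s.append(_apd(trace, b, 0.9))
        if has_na:
            na_dia.append(trace.state("nai")[b.pre_stim_index])
    apd90s = np.asarray(apd90s)
    d_apd = float(np.max(np.abs(np.diff(apd90s)) / apd90s[:-1]))
    if has_na:
        na_dia = np.asarray(na_dia)
        d_na = float(np.max(np.abs(np.diff(na_dia)) / na_dia[:-1]))
    else:
        d_na = 0.0
    flag = (d_apd < 0.005) and (d_na < 0.005)
    return flag, {"apd90": d_apd, "na_i_diastolic": d_na}
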