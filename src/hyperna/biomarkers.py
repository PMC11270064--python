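"""AP and ionic-concentration biomarkers from a paced trace.

Conventions:

* RMP is the pre-stimulus diastolic Vm (the paced "resting" potential).
* (dVm/dt)max is the maximum of the stimulus-corrected derivative: the
  1-ms pulse adds its amplitude to dVm/dt additively, so subtracting it
  over the pulse window removes the artifact exactly even when the
  upstroke completes within the pulse (it does, at 2x threshold).
* APD50/APD90 run from the instant of (dVm/dt)max to the repolarizing
  crossing of RMP + 0.5*APA / RMP + 0.1*APA (linear interpolation
  between samples); the amplitude-based levels implement "APD at x %
  repolarization".
* All reported values come from the last complete beat of the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import F, R, T_BODY
from .protocols import PacedTrace

__all__ = [
    "BiomarkerSet",
    "Beat",
    "beats",
    "ap_biomarkers",
    "calcium_biomarkers",
    "nernst",
    "extract",
    "NoActionPotentialError",
]


class NoActionPotentialError(ValueError):
    """The trace contains no action potential (or never repolarizes)."""


@dataclass(frozen=True)
class BiomarkerSet:
    rmp: float                  # mV
    apa: float                  # mV
    apd50: float                # ms
    apd90: float                # ms
    dvdt_max: float             # V/s
    ith: float | None           # A/F (magnitude), if a threshold was run
    ek: float | None            # mV
    ena: float | None           # mV
    ca_peak: float | None       # umol/L
    ca_diastolic: float | None  # umol/L
    na_i_diastolic: float | None  # mmol/L
    k_i_diastolic: float | None   # mmol/L

    def __post_init__(self) -> None:
        if self.apa <= 0:
            raise ValueError("APA must be positive")
        if self.apd50 >= self.apd90:
            raise ValueError("APD50 must be shorter than APD90")

    def as_dict(self) -> dict[str, float | None]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class Beat:
    onset: float            # stimulus onset, ms
    start: int              # first sample index of the beat
    stop: int               # one-past-last sample index
    pre_stim_index: int     # sample at (or just before) stimulus onset
    pulse_off_time: float   # ms


def beats(trace: PacedTrace) -> list[Beat]:
    """Complete beats (full cycle inside the trace), in order."""
    cl = trace.protocol.cycle_length
    pw = trace.protocol.pulse_width
    out: list[Beat] = []
    t = trace.t
    for onset in trace.stim_times:
        if onset + cl > t[-1] + 1e-6:
            continue
        start = int(np.searchsorted(t, onset - 1e-9))
        stop = int(np.searchsorted(t, onset + cl - 1e-9))
        out.append(
            Beat(
                onset=float(onset),
                start=start,
                stop=stop,
                pre_stim_index=start,
                pulse_off_time=float(onset + pw),
            )
        )
    return out


def _corrected_dvm(trace: PacedTrace, beat: Beat) -> np.ndarray:
    """dVm/dt over the beat with the additive stimulus contribution
    subtracted during the pulse window."""
    t = trace.t[beat.start:beat.stop]
    dvm = trace.dvm[beat.start:beat.stop].copy()
    in_pulse = (t >= beat.onset) & (t < beat.pulse_off_time)
    dvm[in_pulse] -= trace.stim_amplitude
    return dvm


def _crossing_time(t: np.ndarray, vm: np.ndarray, level: float, i_from: int) -> float:
    """First downward crossing of ``level`` at or after sample ``i_from``."""
    below = vm[i_from:] <= level
    if not below.any():
        raise NoActionPotentialError(
            f"repolarization never reaches {level:.2f} mV within the cycle"
        )
    k = i_from + int(np.argmax(below))
    if k == i_from or vm[k - 1] <= level:
        return float(t[k])
    # linear interpolation between the bracketing samples
    f = (vm[k - 1] - level) / (vm[k - 1] - vm[k])
    return float(t[k - 1] + f * (t[k] - t[k - 1]))


def _apd(trace: PacedTrace, beat: Beat, fraction: float) -> float:
    """APD at ``fraction`` repolarization for one beat."""
    t = trace.t[beat.start:beat.stop]
    vm = trace.vm[beat.start:beat.stop]
    dvm = _corrected_dvm(trace, beat)
    rmp = vm[beat.pre_stim_index - beat.start]
    i_dvdt = int(np.argmax(dvm))
    peak = float(vm.max())
    apa = peak - rmp
    if peak < 0.0 or apa < 20.0:
        raise NoActionPotentialError("no AP in trace (Vm never overshoots)")
    level = rmp + (1.0 - fraction) * apa
    i_peak = int(np.argmax(vm))
    t_cross = _crossing_time(t, vm, level, max(i_peak, i_dvdt))
    return t_cross - float(t[i_dvdt])


def ap_biomarkers(trace: PacedTrace, ith: float | None = None) -> BiomarkerSet:
    """AP biomarkers of the last complete beat."""
    beat_list = beats(trace)
    if not beat_list:
        raise NoActionPotentialError("trace holds no complete beat")
    b = beat_list[-1]
    vm = trace.vm[b.start:b.stop]
    rmp = float(vm[b.pre_stim_index - b.start])
    peak = float(vm.max())
    apa = peak - rmp
    if peak < 0.0 or apa < 20.0:
        raise NoActionPotentialError("no AP in trace (Vm never overshoots)")
    dvdt_max = float(_corrected_dvm(trace, b).max())
    apd50 = _apd(trace, b, 0.5)
    apd90 = _apd(trace, b, 0.9)

    ek = ena = None
    na_dia = k_dia = None
    if trace.condition is not None and "nai" in trace.state_names:
        milieu = trace.condition.milieu
        nai = float(trace.state("nai")[b.pre_stim_index])
        ki = float(trace.state("ki")[b.pre_stim_index])
        ek = nernst(1, milieu.k_e, ki)
        ena = nernst(1, milieu.na_e, nai)
        na_dia, k_dia = nai, ki
    ca_peak = ca_dia = None
    if "cai" in trace.state_names:
        ca_peak, ca_dia = calcium_biomarkers(trace)

    return BiomarkerSet(
        rmp=rmp,
        apa=apa,
        apd50=apd50,
        apd90=apd90,
        dvdt_max=dvdt_max,
        ith=ith,
        ek=ek,
        ena=ena,
        ca_peak=ca_peak,
        ca_diastolic=ca_dia,
        na_i_diastolic=na_dia,
        k_i_diastolic=k_dia,
    )


def calcium_biomarkers(trace: PacedTrace) -> tuple[float, float]:
    """(peak, diastolic) myoplasmic [Ca2+]i of the last complete beat, umol/L."""
    if "cai" not in trace.state_names:
        raise ValueError("trace lacks a myoplasmic Ca2+ series")
    beat_list = beats(trace)
    if not beat_list:
        raise ValueError("trace holds no complete beat")
    b = beat_list[-1]
    cai = trace.state("cai")
    peak = float(cai[b.start:b.stop].max()) * 1000.0
    dia = float(cai[b.pre_stim_index]) * 1000.0
    return peak, dia


def nernst(z: int, conc_out: float, conc_in: float, temperature: float = T_BODY) -> float:
    """Nernst equilibrium potential in mV."""
    if z == 0:
        raise ValueError("valence must be non-zero")
    if conc_out <= 0 or conc_in <= 0:
        raise ValueError("concentrations must be strictly positive")
    return (R * temperature) / (z * F) * math.log(conc_out / conc_in)


def extract(trace: PacedTrace, ith: float | None = None) -> BiomarkerSet:
    """Full biomarker set of a paced trace (alias kept for discoverability)."""
    return ap_biomarkers(trace, ith=ith)
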