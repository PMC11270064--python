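"""Experiment orchestration: condition grids, scenario studies, tables.

``run_condition`` performs the full per-condition procedure: the
threshold current and the pacing amplitude are solved self-consistently
(pace at a provisional 2x-threshold amplitude, re-measure the threshold
at the resulting quasi-steady diastolic state, pace once more at twice
the re-measured threshold), then biomarkers are extracted from the last
complete beat.  ``run_grid`` sweeps models x rates x levels x scenarios
and emits a flat table with percent/absolute changes against the
same-rate baseline.  Everything is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerSet, ap_biomarkers
from .models import get_model
from .osmotic import PerturbedCondition, build_condition
from .protocols import (
    PacedTrace,
    PacingProtocol,
    ThresholdResult,
    find_threshold,
    pace,
    quasi_steady_check,
)

__all__ = [
    "ExperimentGrid",
    "ConditionResult",
    "run_condition",
    "run_grid",
    "compare_models",
    "SCENARIOS",
]

#: named scenarios of the study: the default condition, the two
#: alternative ICaL scalings at 50 % hypernatremia, and the two ablations
#: (which keep the milieu change, removing only shrinkage or only scaling)
SCENARIOS: dict[str, dict] = {
    "default": {},
    "ical-0.72": {"ical_scenario": 0.72},
    "ical-1.45": {"ical_scenario": 1.45},
    "no-shrinkage": {"apply_shrinkage": False},
    "no-scaling": {"apply_current_scaling": False},
}


@dataclass(frozen=True)
class ExperimentGrid:
    models: Sequence[str] = ("bps2020", "torord")
    rates: Sequence[float] = (50.0, 75.0, 100.0)
    levels: Sequence[float] = (0.0, 0.10, 0.20, 0.50)
    scenarios: Sequence[str] = ("default",)

    def __post_init__(self) -> None:
        if 0.0 not in self.levels:
            raise ValueError("the baseline level 0 must be part of the grid")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")


@dataclass
class ConditionResult:
    model_id: str
    level: float
    rate: float
    scenario: str
    condition: PerturbedCondition
    threshold: ThresholdResult
    biomarkers: BiomarkerSet
    trace: PacedTrace
    quasi_steady: bool
    qs_deltas: dict = field(default_factory=dict)

    def row(self) -> dict:
        r = {
            "model": self.model_id,
            "rate": self.rate,
            "level": self.level,
            "scenario": self.scenario,
            "quasi_steady": self.quasi_steady,
        }
        r.update(self.biomarkers.as_dict())
        r["ith"] = self.threshold.i_threshold
        return r


def run_condition(
    model_id: str,
    level: float,
    rate: float,
    scenario: str = "default",
    protocol: PacingProtocol | None = None,
    provisional_amplitude: float | None = None,
    step_concentrations: bool = True,
    iterate: bool = True,
) -> ConditionResult:
    """Threshold search, 10-min pacing at 2x threshold, biomarkers.

    With ``iterate`` (the default) the amplitude is solved
    self-consistently: pace at a provisional 2x-threshold amplitude,
    re-measure the threshold at the quasi-steady diastolic state, and
    pace once more at twice the re-measured threshold.  ``iterate=False``
    keeps the provisional pacing run (used for trend scans, where the
    sub-percent amplitude effect on biomarkers is immaterial)."""
    model = get_model(model_id)
    condition = build_condition(level, model_id, **SCENARIOS[scenario])
    proto = protocol or PacingProtocol(rate=rate)

    if provisional_amplitude is None:
        thr0 = find_threshold(model, model.initial_state(), condition, proto)
        provisional_amplitude = 2.0 * thr0.i_threshold
    trace1 = pace(model, condition, proto, provisional_amplitude,
                  step_concentrations=step_concentrations)
    guess = 0.5 * provisional_amplitude
    try:
        thr = find_threshold(model, trace1.final_state, condition, proto,
                             bracket=(0.5 * guess, 3.0 * guess))
    except Exception:
        thr = find_threshold(model, trace1.final_state, condition, proto)
    if iterate:
        trace2 = pace(model, condition, proto, 2.0 * thr.i_threshold,
                      step_concentrations=step_concentrations)
    else:
        trace2 = trace1
    bm = ap_biomarkers(trace2, ith=thr.i_threshold)
    qs_flag, qs_deltas = quasi_steady_check(trace2)
    return ConditionResult(
        model_id=model_id,
        level=level,
        rate=rate,
        scenario=scenario,
        condition=condition,
        threshold=thr,
        biomarkers=bm,
        trace=trace2,
        quasi_steady=qs_flag,
        qs_deltas=qs_deltas,
    )


_PERCENT_FIELDS = ("apd50", "apd90", "dvdt_max", "ith", "apa")
_ABSOLUTE_FIELDS = ("rmp", "ek", "ena", "ca_peak", "ca_diastolic",
                    "na_i_diastolic", "k_i_diastolic")


def _add_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Percent/absolute changes vs the same-model, same-rate default baseline."""
    out = table.copy()
    for f in _PERCENT_FIELDS:
        out[f"d_{f}_pct"] = np.nan
    for f in _ABSOLUTE_FIELDS:
        out[f"d_{f}"] = np.nan
    for (model, rate), group in table.groupby(["model", "rate"]):
        base = group[(group["level"] == 0.0) & (group["scenario"] == "default")]
        if base.empty:
            continue
        b = base.iloc[0]
        idx = group.index
        for f in _PERCENT_FIELDS:
            out.loc[idx, f"d_{f}_pct"] = 100.0 * (group[f] - b[f]) / b[f]
        for f in _ABSOLUTE_FIELDS:
            out.loc[idx, f"d_{f}"] = group[f] - b[f]
    return out


def run_grid(
    grid: ExperimentGrid,
    output_dir: str | Path | None = None,
    protocol_kwargs: dict | None = None,
    save_traces: bool = False,
) -> pd.DataFrame:
    """Run every grid cell; failures are recorded and remaining cells run."""
    rows: list[dict] = []
    failures: list[dict] = []
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for model_id in grid.models:
        for rate in grid.rates:
            for level in grid.levels:
                for scenario in grid.scenarios:
                    if scenario != "default" and level == 0.0:
                        continue  # scenarios modify the perturbation only
                    proto = PacingProtocol(rate=rate, **(protocol_kwargs or {}))
                    try:
                        res = run_condition(model_id, level, rate, scenario,
                                            protocol=proto)
                    except Exception as exc:  # keep the sweep alive
                        failures.append(
                            {"model": model_id, "rate": rate, "level": level,
                             "scenario": scenario, "error": str(exc)}
                        )
                        continue
                    rows.append(res.row())
                    if out is not None and save_traces:
                        stem = f"{model_id}_r{rate:g}_l{level:g}_{scenario}"
                        save_trace(res.trace, out / f"{stem}.csv")
    table = _add_changes(pd.DataFrame(rows))
    if out is not None:
        table.to_csv(out / "biomarkers.csv", index=False)
        if failures:
            (out / "failures.json").write_text(json.dumps(failures, indent=2))
    return table


def compare_models(table: pd.DataFrame) -> pd.DataFrame:
    """Pair the two models' biomarkers at identical grid cells."""
    keys = ["rate", "level", "scenario"]
    models = sorted(table["model"].unique())
    if len(models) != 2:
        raise ValueError("model comparison needs exactly two models in the table")
    a = table[table["model"] == models[0]].set_index(keys)
    b = table[table["model"] == models[1]].set_index(keys)
    common = a.index.intersection(b.index)
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(f"grid cells present for only one model: {list(missing)}")
    joined = a.loc[common].add_suffix(f"_{models[0]}").join(
        b.loc[common].add_suffix(f"_{models[1]}")
    )
    for f in ("rmp", "apd90", "na_i_diastolic", "ca_peak"):
        joined[f"delta_{f}"] = (
            joined[f"{f}_{models[1]}"] - joined[f"{f}_{models[0]}"]
        )
    return joined.reset_index()


def save_trace(trace: PacedTrace, path: str | Path) -> None:
    """Delimited trace table plus a JSON sidecar with run metadata."""
    path = Path(path)
    cols = {"time_ms": trace.t, "vm_mV": trace.vm, "dvm_mV_per_ms": trace.dvm}
    for name in trace.state_names:
        if name in ("nai", "ki", "cai", "cass", "cansr", "cajsr"):
            cols[f"{name}_mM"] = trace.state(name)
    from .models.base import CURRENT_NAMES

    for i, name in enumerate(CURRENT_NAMES):
        cols[f"{name}_A_per_F"] = trace.currents[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "model": trace.model_id,
        "stim_amplitude_A_per_F": trace.stim_amplitude,
        "rate_per_min": trace.protocol.rate,
        "pulse_width_ms": trace.protocol.pulse_width,
        "rtol": trace.protocol.rtol,
        "missed_beats": trace.missed_beats,
    }
    if trace.condition is not None:
        c = trace.condition
        meta["condition"] = {
            "level": c.level,
            "volume_fraction": c.volume_fraction,
            "factors": c.factors.as_dict(),
            "milieu": {"na_e": c.milieu.na_e, "k_e": c.milieu.k_e,
                       "ca_e": c.milieu.ca_e, "cl_e": c.milieu.cl_e},
            "apply_shrinkage": c.apply_shrinkage,
            "apply_current_scaling": c.apply_current_scaling,
            "ical_scenario": c.ical_scenario,
        }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
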