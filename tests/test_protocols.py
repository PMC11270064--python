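"""Pacing and threshold-search protocol behaviour on the analytic toy cell."""

import numpy as np
import pytest

from hyperna.fixtures import synthetic_ap_trace
from hyperna.models import ToyParams, toy_model
from hyperna.protocols import (
    BracketingError,
    PacingProtocol,
    find_threshold,
    pace,
    quasi_steady_check,
)


def grid_search_threshold(model, y, condition, protocol, amps):
    """Independent oracle: exhaustive scan over stimulus amplitudes."""
    from hyperna.protocols import _elicits_ap

    for amp in amps:
        if _elicits_ap(model, y, condition, protocol, amp, 50.0):
            return amp
    raise AssertionError("grid search found no firing amplitude")


class TestThresholdSearch:
    def test_bisection_agrees_with_grid_search(self, toy, toy_protocol):
        y = toy.initial_state()
        thr = find_threshold(toy, y, None, toy_protocol, bracket=(0.1, 50.0))
        amps = np.arange(0.1, 50.0, 0.05)
        oracle = grid_search_threshold(toy, y, None, toy_protocol, amps)
        assert abs(thr.i_threshold - oracle) <= 0.05 + 0.005 * oracle

    def test_result_independent_of_bracket(self, toy, toy_protocol):
        y = toy.initial_state()
        a = find_threshold(toy, y, None, toy_protocol, bracket=(0.1, 50.0))
        b = find_threshold(toy, y, None, toy_protocol, bracket=(0.01, 173.0))
        assert a.i_threshold == pytest.approx(b.i_threshold, rel=0.01)

    def test_zero_amplitude_never_fires(self, toy, toy_protocol):
        from hyperna.protocols import _elicits_ap

        assert not _elicits_ap(toy, toy.initial_state(), None, toy_protocol,
                               0.0, 50.0)

    def test_halved_regenerative_conductance_raises_threshold(self, toy_protocol):
        """Less inward regenerative current means a harder-to-excite cell;
        verified against the grid-search oracle for both variants."""
        lo = toy_model(ToyParams(g_na_fast=4.0))
        hi = toy_model(ToyParams(g_na_fast=8.0))
        t_lo = find_threshold(lo, lo.initial_state(), None, toy_protocol,
                              bracket=(0.1, 50.0)).i_threshold
        t_hi = find_threshold(hi, hi.initial_state(), None, toy_protocol,
                              bracket=(0.1, 50.0)).i_threshold
        assert t_lo > t_hi
        amps = np.arange(0.1, 50.0, 0.1)
        assert grid_search_threshold(lo, lo.initial_state(), None,
                                     toy_protocol, amps) > grid_search_threshold(
            hi, hi.initial_state(), None, toy_protocol, amps
        )

    def test_bracketing_errors(self, toy, toy_protocol):
        y = toy.initial_state()
        with pytest.raises(BracketingError, match="neither"):
            find_threshold(toy, y, None, toy_protocol, bracket=(0.0, 1e-4))
        with pytest.raises(BracketingError, match="both"):
            find_threshold(toy, y, None, toy_protocol, bracket=(40.0, 50.0))


class TestPacing:
    def test_stimulus_count_matches_rate_times_window(self, toy):
        proto = PacingProtocol(rate=60.0, total_duration_min=0.2,
                               analysis_window_s=5.0)
        tr = pace(toy, None, proto, 10.0)
        window_start = proto.total_duration_min * 60000.0 - 5000.0
        in_window = np.sum(tr.stim_times >= window_start)
        assert in_window == int(proto.rate * 5.0 / 60.0)

    def test_one_to_one_capture_on_toy(self, toy):
        proto = PacingProtocol(rate=60.0, total_duration_min=0.1,
                               analysis_window_s=4.0)
        thr = find_threshold(toy, toy.initial_state(), None, proto,
                             bracket=(0.1, 50.0))
        tr = pace(toy, None, proto, 2.0 * thr.i_threshold)
        assert tr.missed_beats == []
        # every captured beat overshoots 0 mV
        from hyperna.biomarkers import beats

        for b in beats(tr):
            assert tr.vm[b.start:b.stop].max() > 0.0

    def test_strictly_increasing_time_grid(self, toy, toy_protocol):
        tr = pace(toy, None, toy_protocol, 10.0)
        assert np.all(np.diff(tr.t) > 0.0)

    def test_output_resolution_independence(self, toy):
        """Doubling output resolution leaves biomarkers unchanged (well
        within 0.1 %): the adaptive solver, not the output grid, sets
        accuracy."""
        from hyperna.biomarkers import ap_biomarkers

        base = PacingProtocol(rate=60.0, total_duration_min=0.05,
                              analysis_window_s=2.0)
        fine = PacingProtocol(rate=60.0, total_duration_min=0.05,
                              analysis_window_s=2.0, fine_dt=0.025,
                              coarse_dt=0.5)
        b1 = ap_biomarkers(pace(toy, None, base, 40.0))
        b2 = ap_biomarkers(pace(toy, None, fine, 40.0))
        # the (dVm/dt)max instant is located to within one output sample,
        # so APD agreement is sample-step-limited
        assert b2.apd90 == pytest.approx(b1.apd90, abs=2 * base.fine_dt)
        assert b2.rmp == pytest.approx(b1.rmp, rel=1e-3)


class TestQuasiSteadyCheck:
    def test_perfectly_repeating_beat_is_flagged_steady(self):
        trace, _ = synthetic_ap_trace(n_beats=4)
        # attach a constant Na+ series
        trace.states = np.column_stack(
            [trace.states[:, 0], np.full(len(trace.t), 8.0)]
        )
        trace.state_names = ("vm", "nai")
        flag, deltas = quasi_steady_check(trace)
        assert flag
        assert deltas["apd90"] == pytest.approx(0.0, abs=1e-12)
        assert deltas["na_i_diastolic"] == 0.0

    def test_drifting_sodium_fails_the_check(self):
        trace, _ = synthetic_ap_trace(n_beats=4)
        na = 8.0 * (1.0 + 0.01 * trace.t / trace.protocol.cycle_length)
        trace.states = np.column_stack([trace.states[:, 0], na])
        trace.state_names = ("vm", "nai")
        flag, deltas = quasi_steady_check(trace)
        assert not flag
        assert deltas["na_i_diastolic"] > 0.005

    def test_requires_two_beats(self):
        trace, _ = synthetic_ap_trace(n_beats=1)
        with pytest.raises(ValueError, match="2 complete beats"):
            quasi_steady_check(trace)
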