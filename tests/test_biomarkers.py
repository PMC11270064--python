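"""Biomarker extraction against closed-form synthetic waveforms."""

import numpy as np
import pytest

from hyperna.biomarkers import (
    NoActionPotentialError,
    ap_biomarkers,
    beats,
    calcium_biomarkers,
    nernst,
)
from hyperna.fixtures import synthetic_ap_trace


class TestSyntheticTrapezoid:
    def test_biomarkers_match_closed_form(self):
        trace, truth = synthetic_ap_trace(rest=-85.0, peak=35.0,
                                          apd90_true=300.0)
        b = ap_biomarkers(trace)
        assert b.rmp == pytest.approx(truth.rmp)
        assert b.apa == pytest.approx(truth.apa)
        assert b.dvdt_max == pytest.approx(truth.dvdt_max)
        # crossings are linear-in-linear: exact up to one sample step
        assert b.apd90 == pytest.approx(truth.apd90, abs=0.06)
        assert b.apd50 == pytest.approx(truth.apd50, abs=0.06)

    def test_last_beat_rule_single_vs_many(self):
        t5, _ = synthetic_ap_trace(n_beats=5)
        t1, _ = synthetic_ap_trace(n_beats=1)
        b5, b1 = ap_biomarkers(t5), ap_biomarkers(t1)
        assert b5.apd90 == pytest.approx(b1.apd90, abs=1e-9)
        assert b5.apa == pytest.approx(b1.apa, abs=1e-9)

    def test_time_shift_invariance(self):
        a, _ = synthetic_ap_trace()
        s, _ = synthetic_ap_trace(t_offset=12345.0)
        ba, bs = ap_biomarkers(a), ap_biomarkers(s)
        for f in ("rmp", "apa", "apd50", "apd90", "dvdt_max"):
            assert getattr(ba, f) == pytest.approx(getattr(bs, f), abs=1e-9)

    def test_supersampling_invariance(self):
        coarse, _ = synthetic_ap_trace(dt=0.05)
        fine, _ = synthetic_ap_trace(dt=0.025)
        bc, bf = ap_biomarkers(coarse), ap_biomarkers(fine)
        for f in ("apd50", "apd90"):
            assert getattr(bf, f) == pytest.approx(getattr(bc, f), rel=1e-3)

    def test_constant_trace_raises_no_ap(self):
        trace, _ = synthetic_ap_trace()
        trace.states[:, 0] = -85.0
        trace.dvm[:] = 0.0
        with pytest.raises(NoActionPotentialError, match="no AP"):
            ap_biomarkers(trace)

    def test_beat_count_matches_stimulus_count(self):
        trace, _ = synthetic_ap_trace(n_beats=5)
        assert len(beats(trace)) == 5
        assert len(trace.stim_times) == 5


def test_calcium_biomarkers_on_constructed_transient():
    """A raised-cosine Ca2+ transient on a diastolic floor reports the
    constructed peak and the pre-stimulus value, in umol/L."""
    trace, _ = synthetic_ap_trace(n_beats=2)
    cl = trace.protocol.cycle_length
    dia, amp = 1.0e-4, 5.0e-4  # mmol/L
    tau = np.mod(trace.t, cl)
    ca = dia + amp * np.where(
        tau < 200.0, 0.5 * (1.0 - np.cos(2 * np.pi * tau / 200.0)), 0.0
    )
    trace.states = np.column_stack([trace.states[:, 0], ca])
    trace.state_names = ("vm", "cai")
    peak, diastolic = calcium_biomarkers(trace)
    assert peak == pytest.approx((dia + amp) * 1000.0, rel=1e-6)
    assert diastolic == pytest.approx(dia * 1000.0, rel=1e-6)


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst(1, 5.4, 5.4) == 0.0

    def test_tenfold_gradient_monovalent(self):
        assert nernst(1, 10.0, 1.0, 310.0) == pytest.approx(61.5, abs=0.1)

    def test_potassium_like_gradient(self):
        assert nernst(1, 5.4, 144.0, 310.0) == pytest.approx(-87.7, abs=0.1)

    def test_valence_and_positivity_checks(self):
        with pytest.raises(ValueError):
            nernst(0, 5.4, 144.0)
        with pytest.raises(ValueError):
            nernst(1, -5.4, 144.0)
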