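"""Model-layer checks: identity condition, current-scaling hooks,
reversal potentials, conservation with silenced membrane currents,
and the analytic toy cell."""

import numpy as np
import pytest

from hyperna.constants import rt_over_f
from hyperna.models import ToyParams, get_model, resting_potential, toy_model
from hyperna.models.base import (
    CURRENT_NAMES,
    P_FCAL,
    P_FK1,
    P_FKR,
    P_FKS,
    P_FNAK,
    P_FNCX,
    P_MASK,
)
from hyperna.osmotic import build_condition
from hyperna.protocols import PacingProtocol, pace


def _cur(model, y, p):
    return dict(zip(CURRENT_NAMES, model.currents(y, p)))


class TestConditionHooks:
    def test_identity_condition_is_bitwise_unperturbed(self, ionic_model):
        """Level 0 with default toggles changes nothing in the RHS."""
        m = ionic_model
        cond = build_condition(0.0, m.model_id)
        y = m.initial_state()
        p0 = m.pack_params(None)
        p1 = m.pack_params(cond)
        np.testing.assert_array_equal(m.rhs(0.0, y, p0), m.rhs(0.0, y, p1))

    @pytest.mark.parametrize(
        "pidx,current",
        [(P_FKR, "i_kr"), (P_FKS, "i_ks"), (P_FK1, "i_k1")],
    )
    def test_zeroed_conductance_removes_current_from_dvdt(
        self, ionic_model, probe_state, pidx, current
    ):
        m = ionic_model
        y = probe_state(m)
        p = m.pack_params(None)
        base = _cur(m, y, p)[current]
        dv0 = m.rhs(0.0, y, p)[0]
        p2 = p.copy()
        p2[pidx] = 0.0
        assert _cur(m, y, p2)[current] == 0.0
        dv1 = m.rhs(0.0, y, p2)[0]
        assert dv1 - dv0 == pytest.approx(base, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "pidx,currents,factor",
        [
            (P_FNAK, ("i_nak",), 0.5),
            (P_FNCX, ("i_naca_i", "i_naca_ss"), 0.5),
            (P_FCAL, ("i_cal", "i_cana", "i_cak"), 0.72),
        ],
    )
    def test_scaling_factor_scales_current_exactly(
        self, ionic_model, probe_state, pidx, currents, factor
    ):
        """Scaling acts on the maximal amplitude: at a pinned state the
        current scales exactly by the factor (both NCX components share
        the single INaCa factor)."""
        m = ionic_model
        y = probe_state(m)
        p = m.pack_params(None)
        base = _cur(m, y, p)
        p2 = p.copy()
        p2[pidx] = factor
        scaled = _cur(m, y, p2)
        for name in currents:
            assert scaled[name] == pytest.approx(factor * base[name], rel=1e-12)

    def test_volume_scaling_speeds_concentration_change(self, ionic_model):
        """Halving the intracellular volume doubles d[Na+]i/dt from the
        membrane flux at a pinned state (area unchanged)."""
        m = ionic_model
        y = m.initial_state()
        y[0] = -20.0  # active currents
        y[m.state_index("nass")] = y[m.state_index("nai")]  # no diffusion term
        p = m.pack_params(None)
        p2 = p.copy()
        from hyperna.models.base import P_VFRAC

        p2[P_VFRAC] = 0.5
        i_na = m.state_index("nai")
        d1 = m.rhs(0.0, y, p)[i_na]
        d2 = m.rhs(0.0, y, p2)[i_na]
        assert d2 == pytest.approx(2.0 * d1, rel=1e-9)

    def test_background_na_current_vanishes_at_reversal(self, ionic_model):
        """With Vm pinned to ENa the Na+ background driving force is zero."""
        m = ionic_model
        y = m.initial_state()
        p = m.pack_params(None)
        rtf = rt_over_f(m.temperature)
        nai = y[m.state_index("nai")]
        y[0] = rtf * np.log(p[0] / nai)  # ENa
        assert _cur(m, y, p)["i_nab"] == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_state_is_named(self, ionic_model):
        m = ionic_model
        y = m.initial_state()
        y[m.state_index("cai")] = np.nan
        with pytest.raises(FloatingPointError, match="cai"):
            m.validate_state(y)


class TestConservation:
    def test_total_ion_amounts_conserved_without_membrane_currents(
        self, ionic_model
    ):
        """With every transmembrane current silenced, total intracellular
        Na, K and Ca amounts (free + buffered + SR) are conserved over 10 s
        even though internal diffusion and SR fluxes keep running."""
        m = ionic_model
        from hyperna.protocols import _atol_vector, _segment

        p = m.pack_params(None)
        p[P_MASK] = 0.0
        y = m.initial_state()
        before = m.ion_amounts(y, p)
        _, y_end = _segment(m, y, p, 0.0, 10000.0, 1e-8, _atol_vector(m))
        after = m.ion_amounts(y_end, p)
        for ion in ("na", "k", "ca"):
            assert after[ion] == pytest.approx(before[ion], rel=1e-5), ion

    def test_charge_bookkeeping_over_one_beat(self, ionic_model):
        """Cumulative ion-specific current integrals match the change in
        total intracellular ion amounts to 0.5 % of the transferred charge
        over a paced beat."""
        from hyperna.constants import F
        from hyperna.models.torord import ACAP

        m = ionic_model
        cond = build_condition(0.0, m.model_id)
        proto = PacingProtocol(rate=50.0, total_duration_min=0.1,
                               analysis_window_s=1.2, fine_dt=0.05,
                               coarse_dt=0.5)
        tr = pace(m, cond, proto, 40.0)
        t = tr.t
        c = {name: tr.current(name) for name in CURRENT_NAMES}
        stim = np.zeros_like(t)
        for s in tr.stim_times:
            stim[(t >= s) & (t < s + proto.pulse_width)] = -40.0
        i_na = (c["i_na"] + c["i_nal"] + 3 * (c["i_naca_i"] + c["i_naca_ss"])
                + c["i_cana"] + 3 * c["i_nak"] + c["i_nab"])
        i_k = (c["i_to"] + c["i_kr"] + c["i_ks"] + c["i_k1"] + c["i_kb"]
               + c["i_cak"] + stim - 2 * c["i_nak"])
        i_ca = (c["i_cal"] + c["i_cab"] + c["i_pca"]
                - 2 * (c["i_naca_i"] + c["i_naca_ss"]))
        p = m.pack_params(cond)
        amounts0 = m.ion_amounts(tr.states[0], p)
        amounts1 = m.ion_amounts(tr.states[-1], p)
        for ion, i_ion, z in (("na", i_na, 1.0), ("k", i_k, 1.0),
                              ("ca", i_ca, 2.0)):
            transferred = -np.trapezoid(i_ion, t) * ACAP / (z * F)
            measured = amounts1[ion] - amounts0[ion]
            # 0.5 % of the gross turnover (the net change can be ~0 at
            # quasi-steady state, so it cannot serve as the scale)
            gross = np.trapezoid(np.abs(i_ion), t) * ACAP / (z * F)
            assert measured == pytest.approx(transferred, abs=0.005 * gross), ion


class TestToyModel:
    def test_resting_potential_chord_conductance(self):
        """gK:gNa = 9:1 with EK=-90, ENa=+60 rests at exactly -75 mV."""
        params = ToyParams(g_k=0.9, g_na_leak=0.1, ek=-90.0, ena=60.0)
        assert resting_potential(params, -90.0, 60.0) == pytest.approx(-75.0)
        model = toy_model(params)
        proto = PacingProtocol(rate=60, total_duration_min=0.02,
                               analysis_window_s=1.0)
        tr = pace(model, None, proto, 0.0)
        assert tr.final_state[0] == pytest.approx(-75.0, abs=0.5)

    def test_pure_k_cell_rests_at_ek(self):
        """With a vanishing Na+ leak the rest sits at EK."""
        params = ToyParams(g_k=1.0, g_na_leak=1e-12, ek=-90.0, ena=60.0)
        assert resting_potential(params, -90.0, 60.0) == pytest.approx(
            -90.0, abs=1e-6
        )

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(ValueError):
            ToyParams(g_k=0.0)
        with pytest.raises(ValueError):
            ToyParams(g_na_fast=-1.0)
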