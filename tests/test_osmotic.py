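"""The osmotic perturbation layer: ion-current scaling factors, perturbed
milieu, and osmotic cell shrinkage with a 32 % inactive volume fraction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperna.osmotic import (
    DEFAULT_ANCHORS,
    ExtracellularMilieu,
    OsmoticVolumeModel,
    PerturbedCondition,
    ScalingFactors,
    build_condition,
    perturbed_milieu,
    scaling_factors,
    shrinkage_concentration_gain,
    volume_fraction,
)

BPS = ExtracellularMilieu.with_charge_balance_cl(144.0, 5.4, 2.7)
TOR = ExtracellularMilieu(140.0, 5.0, 1.8, 150.0)
VM = OsmoticVolumeModel()

# (level, f_ICaL, f_IKr, f_IKs, f_IK1, f_INaCa, f_INaK): printed table cells
FACTOR_TABLE = [
    (0.00, 1.0, 1.000, 1.000, 1.0, 1.000, 1.000),
    (0.10, 1.0, 0.920, 0.900, 1.0, 1.077, 0.867),
    (0.20, 1.0, 0.840, 0.800, 1.0, 1.153, 0.733),
    (0.50, 1.0, 0.600, 0.500, 1.0, 1.383, 0.333),
]

# printed relative cell volumes, percent
VCELL_TABLE = {
    ("bps", 0.00): 100.00, ("bps", 0.10): 94.17,
    ("bps", 0.20): 89.25, ("bps", 0.50): 78.28,
    ("tor", 0.00): 100.00, ("tor", 0.10): 94.14,
    ("tor", 0.20): 89.21, ("tor", 0.50): 78.21,
}


@pytest.mark.parametrize("level,ical,ikr,iks,ik1,incx,inak", FACTOR_TABLE)
def test_scaling_factor_table(level, ical, ikr, iks, ik1, incx, inak):
    f = scaling_factors(level)
    assert round(f.f_ICaL, 3) == ical
    assert round(f.f_IKr, 3) == ikr
    assert round(f.f_IKs, 3) == iks
    assert round(f.f_IK1, 3) == ik1
    assert round(f.f_INaCa, 3) == incx
    assert round(f.f_INaK, 3) == inak


def test_scaling_factors_at_anchor_level():
    # the 30 % anchors themselves, plus the interpolated IKr/IKs values
    # on the line through (0,1) and the 50 % anchors
    f = scaling_factors(0.30)
    assert round(f.f_INaCa, 2) == 1.23
    assert round(f.f_INaK, 2) == 0.60
    assert round(f.f_IKr, 2) == 0.76
    assert round(f.f_IKs, 2) == 0.70


def test_scaling_factor_errors():
    with pytest.raises(ValueError):
        scaling_factors(-0.1)
    # INaK hits zero at level 0.75; beyond that the line is non-physical
    with pytest.raises(ValueError, match="non-positive"):
        scaling_factors(0.80)


@pytest.mark.parametrize(
    "milieu,level,expect",
    [
        (BPS, 0.50, (216.0, 5.4, 2.7, 226.8)),
        (BPS, 0.00, (144.0, 5.4, 2.7, 154.8)),
        (TOR, 0.20, (168.0, 5.0, 1.8, 178.0)),
        (TOR, 0.10, (154.0, 5.0, 1.8, 164.0)),
    ],
)
def test_perturbed_milieu_table(milieu, level, expect):
    m = perturbed_milieu(level, milieu)
    assert (m.na_e, m.k_e, m.ca_e, m.cl_e) == pytest.approx(expect)


def test_charge_balance_chloride():
    assert BPS.cl_e == pytest.approx(BPS.na_e + BPS.k_e + 2 * BPS.ca_e)
    # the balance is preserved under equimolar NaCl addition
    m = perturbed_milieu(0.5, BPS)
    assert m.cl_e == pytest.approx(m.na_e + m.k_e + 2 * m.ca_e)


@pytest.mark.parametrize("key,pct", sorted(VCELL_TABLE.items()))
def test_relative_volume_table(key, pct):
    tag, level = key
    milieu = BPS if tag == "bps" else TOR
    assert round(100.0 * volume_fraction(level, VM, milieu), 2) == pct


def test_concentration_gain_examples():
    assert round(100.0 * shrinkage_concentration_gain(VM, 0.50, TOR)) == 47
    assert shrinkage_concentration_gain(VM, 0.0, TOR) == 0.0
    # 2 * 0.10 * 144 / 306.9, by hand
    assert shrinkage_concentration_gain(VM, 0.10, BPS) == pytest.approx(
        2 * 0.10 * 144 / 306.9
    )


@given(
    level=st.floats(0.0, 0.7),
    na=st.floats(100.0, 160.0),
    k=st.floats(3.0, 8.0),
    ca=st.floats(1.0, 3.5),
)
@settings(max_examples=200, deadline=None)
def test_volume_gain_solute_conservation(level, na, k, ca):
    """(v - q) * osm(level) == (1 - q) * osm0: the shrunken active volume
    holds the same solute amount at the elevated osmolarity."""
    milieu = ExtracellularMilieu.with_charge_balance_cl(na, k, ca)
    q = VM.inactive_fraction
    v = volume_fraction(level, VM, milieu)
    gain = shrinkage_concentration_gain(VM, level, milieu)
    assert v <= 1.0 + 1e-12
    assert (v - q) * (1.0 + gain) == pytest.approx(1.0 - q, rel=1e-12)


@given(st.floats(0.0, 0.69), st.floats(0.001, 0.7))
@settings(max_examples=100, deadline=None)
def test_volume_decreases_gain_increases(level, dlevel):
    v0 = volume_fraction(level, VM, TOR)
    v1 = volume_fraction(level + dlevel, VM, TOR)
    assert v1 < v0
    g0 = shrinkage_concentration_gain(VM, level, TOR)
    g1 = shrinkage_concentration_gain(VM, level + dlevel, TOR)
    assert g1 > g0


def test_identity_at_level_zero():
    assert volume_fraction(0.0, VM, BPS) == 1.0
    assert shrinkage_concentration_gain(VM, 0.0, BPS) == 0.0
    assert perturbed_milieu(0.0, BPS) == BPS
    assert all(v == 1.0 for v in scaling_factors(0.0).as_dict().values())


class TestBuildCondition:
    def test_default_bundle(self):
        c = build_condition(0.50, "bps2020")
        f = c.factors
        assert (round(f.f_IKr, 3), round(f.f_IKs, 3)) == (0.600, 0.500)
        assert (round(f.f_INaCa, 3), round(f.f_INaK, 3)) == (1.383, 0.333)
        assert f.f_ICaL == 1.0 and f.f_IK1 == 1.0
        assert round(100 * c.volume_fraction, 2) == 78.28
        assert c.milieu.na_e == pytest.approx(216.0)

    def test_scaling_ablation(self):
        c = build_condition(0.50, "bps2020", apply_current_scaling=False)
        assert all(v == 1.0 for v in c.factors.as_dict().values())
        assert round(100 * c.volume_fraction, 2) == 78.28
        assert c.milieu.na_e == pytest.approx(216.0)  # milieu change kept

    def test_shrinkage_ablation(self):
        c = build_condition(0.50, "torord", apply_shrinkage=False)
        assert c.volume_fraction == 1.0
        assert c.factors.f_IKs == pytest.approx(0.5)

    def test_ical_scenario(self):
        c = build_condition(0.50, "torord", ical_scenario=1.45)
        assert c.factors.f_ICaL == pytest.approx(1.45)
        assert c.factors.f_IKr == pytest.approx(0.60)
        with pytest.raises(ValueError, match="scenario"):
            build_condition(0.50, "torord", ical_scenario=-1.0)

    def test_unknown_model(self):
        with pytest.raises(KeyError, match="unknown model"):
            build_condition(0.0, "nonexistent")


def test_invalid_types_rejected():
    with pytest.raises(ValueError):
        ExtracellularMilieu(-1.0, 5.0, 1.8, 150.0)
    with pytest.raises(ValueError):
        ScalingFactors(f_IKr=0.0)
    with pytest.raises(ValueError):
        OsmoticVolumeModel(inactive_fraction=1.0)
    with pytest.raises(ValueError, match="volume_fraction"):
        PerturbedCondition(
            model_id="torord", level=0.0, milieu=TOR,
            factors=ScalingFactors(), volume_fraction=0.9,
            apply_shrinkage=False,
        )
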