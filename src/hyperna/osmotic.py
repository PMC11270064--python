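"""Osmotic hypernatremia perturbation layer.

Acute hypernatremia is modelled as an equimolar addition of NaCl to the
extracellular solution, expressed as a fractional ``level`` (0.10, 0.20,
0.50 for mild, severe, extreme).  Three things follow from a level:

* a perturbed extracellular milieu (Na and Cl raised, K and Ca untouched);
* a set of dimensionless scaling factors on ion-current amplitudes,
  interpolated/extrapolated linearly from experimental hyperosmosis data
  anchored per current (IKr 0.6 and IKs 0.5 at 50 %; INaCa 1.23 and INaK
  0.6 at 30 %; ICaL and IK1 unchanged);
* a relative cell volume: only the osmotically active fraction of the
  cell (68 %; 32 % is osmotically inactive) shrinks in inverse proportion
  to extracellular osmolarity, taken as the plain sum of the four
  extracellular ion concentrations.

Membrane capacitance and capacitive area are never altered by shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "ExtracellularMilieu",
    "ScalingFactors",
    "OsmoticVolumeModel",
    "PerturbedCondition",
    "DEFAULT_ANCHORS",
    "scaling_factors",
    "perturbed_milieu",
    "volume_fraction",
    "shrinkage_concentration_gain",
    "build_condition",
]


@dataclass(frozen=True)
class ExtracellularMilieu:
    """Extracellular ion concentrations in mmol/L."""

    na_e: float
    k_e: float
    ca_e: float
    cl_e: float

    def __post_init__(self) -> None:
        for name in ("na_e", "k_e", "ca_e", "cl_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def osmolarity(self) -> float:
        """Plain-sum osmolarity (each ionic species counted once), mmol/L."""
        return self.na_e + self.k_e + self.ca_e + self.cl_e

    @classmethod
    def with_charge_balance_cl(cls, na_e: float, k_e: float, ca_e: float) -> "ExtracellularMilieu":
        """Cl⁻ computed from the extracellular charge of Ca²⁺, K⁺ and Na⁺."""
        return cls(na_e=na_e, k_e=k_e, ca_e=ca_e, cl_e=na_e + k_e + 2.0 * ca_e)


@dataclass(frozen=True)
class ScalingFactors:
    """Dimensionless multipliers on maximal current amplitudes."""

    f_ICaL: float = 1.0
    f_IKr: float = 1.0
    f_IKs: float = 1.0
    f_IK1: float = 1.0
    f_INaCa: float = 1.0
    f_INaK: float = 1.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (0.0 < value <= 2.0):
                raise ValueError(f"{name}={value} outside (0, 2]")

    def as_dict(self) -> dict[str, float]:
        return {
            "f_ICaL": self.f_ICaL,
            "f_IKr": self.f_IKr,
            "f_IKs": self.f_IKs,
            "f_IK1": self.f_IK1,
            "f_INaCa": self.f_INaCa,
            "f_INaK": self.f_INaK,
        }


#: Per-current (level, factor) anchor pairs from the hyperosmosis data;
#: the pair (0, 1) is implicit in every line.
DEFAULT_ANCHORS: Mapping[str, tuple[float, float]] = {
    "f_IKr": (0.50, 0.60),
    "f_IKs": (0.50, 0.50),
    "f_INaCa": (0.30, 1.23),
    "f_INaK": (0.30, 0.60),
}


@dataclass(frozen=True)
class OsmoticVolumeModel:
    """Step osmotic shrinkage with an osmotically inactive volume fraction."""

    inactive_fraction: float = 0.32

    def __post_init__(self) -> None:
        if not (0.0 <= self.inactive_fraction < 1.0):
            raise ValueError("inactive_fraction must lie in [0, 1)")


def scaling_factors(
    level: float,
    anchors: Mapping[str, tuple[float, float]] = DEFAULT_ANCHORS,
) -> ScalingFactors:
    """Linear interpolation/extrapolation of current scaling factors.

    Each factor lies on the straight line through (0, 1) and its anchor
    (level*, factor*).  Currents without an anchor (ICaL, IK1) stay at 1.
    """
    if level < 0:
        raise ValueError("hypernatremia level must be non-negative")
    values: dict[str, float] = {}
    for name, (lvl_a, f_a) in anchors.items():
        slope = (f_a - 1.0) / lvl_a
        f = 1.0 + slope * level
        if f <= 0:
            raise ValueError(
                f"{name} extrapolates to a non-positive factor ({f:.4g}) at level {level}"
            )
        values[name] = f
    return ScalingFactors(**values)


def perturbed_milieu(level: float, baseline: ExtracellularMilieu) -> ExtracellularMilieu:
    """Raise extracellular NaCl equimolarly by ``level``; K and Ca unchanged."""
    if level < 0:
        raise ValueError("hypernatremia level must be non-negative")
    added = level * baseline.na_e
    return replace(baseline, na_e=baseline.na_e + added, cl_e=baseline.cl_e + added)


def _osmolarity_ratio(level: float, baseline: ExtracellularMilieu) -> float:
    """osm(level)/osm(0) for an equimolar NaCl addition."""
    osm0 = baseline.osmolarity
    return (osm0 + 2.0 * level * baseline.na_e) / osm0


def volume_fraction(
    level: float,
    vm: OsmoticVolumeModel,
    baseline: ExtracellularMilieu,
) -> float:
    """Relative cell volume after the osmotic step (1.0 at level 0).

    The inactive fraction does not exchange water; the active fraction
    scales inversely with extracellular osmolarity.
    """
    if level < 0:
        raise ValueError("hypernatremia level must be non-negative")
    q = vm.inactive_fraction
    return q + (1.0 - q) / _osmolarity_ratio(level, baseline)


def shrinkage_concentration_gain(
    vm: OsmoticVolumeModel,
    level: float,
    baseline: ExtracellularMilieu,
) -> float:
    """Fractional rise in concentration of a conserved solute confined to
    the osmotically active volume; equals osm(level)/osm(0) − 1."""
    if level < 0:
        raise ValueError("hypernatremia level must be non-negative")
    return _osmolarity_ratio(level, baseline) - 1.0


@dataclass(frozen=True)
class PerturbedCondition:
    """Everything that defines one simulated condition."""

    model_id: str
    level: float
    milieu: ExtracellularMilieu
    factors: ScalingFactors
    volume_fraction: float
    apply_shrinkage: bool = True
    apply_current_scaling: bool = True
    ical_scenario: float = 1.0
    volume_model: OsmoticVolumeModel = field(default=OsmoticVolumeModel())

    def __post_init__(self) -> None:
        if not (self.volume_model.inactive_fraction < self.volume_fraction <= 1.0 + 1e-12):
            raise ValueError("volume_fraction outside (inactive_fraction, 1]")
        if not self.apply_shrinkage and self.volume_fraction != 1.0:
            raise ValueError("volume_fraction must be 1 when shrinkage is off")
        if not self.apply_current_scaling and any(
            f != 1.0 for f in self.factors.as_dict().values()
        ):
            raise ValueError("all factors must be 1 when current scaling is off")


def build_condition(
    level: float,
    model_id: str,
    *,
    baseline: ExtracellularMilieu | None = None,
    apply_shrinkage: bool = True,
    apply_current_scaling: bool = True,
    ical_scenario: float = 1.0,
    volume_model: OsmoticVolumeModel = OsmoticVolumeModel(),
    anchors: Mapping[str, tuple[float, float]] = DEFAULT_ANCHORS,
) -> PerturbedCondition:
    """Bundle milieu, scaling factors and shrinkage into one condition.

    ``ical_scenario`` overrides the ICaL scaling factor (0.72 and 1.45 are
    the experimentally motivated alternatives at 50 % hypernatremia); it is
    honoured only while current scaling is on.
    """
    if baseline is None:
        from .models import get_model  # local import to avoid a cycle

        baseline = get_model(model_id).baseline_milieu
    if ical_scenario <= 0 or ical_scenario > 2.0:
        raise ValueError(f"invalid ICaL scenario factor {ical_scenario}")

    milieu = perturbed_milieu(level, baseline)
    if apply_current_scaling:
        factors = scaling_factors(level, anchors)
        if ical_scenario != 1.0:
            factors = replace(factors, f_ICaL=ical_scenario)
    else:
        factors = ScalingFactors()
    vfrac = volume_fraction(level, volume_model, baseline) if apply_shrinkage else 1.0
    return PerturbedCondition(
        model_id=model_id,
        level=level,
        milieu=milieu,
        factors=factors,
        volume_fraction=vfrac,
        apply_shrinkage=apply_shrinkage,
        apply_current_scaling=apply_current_scaling,
        ical_scenario=ical_scenario if apply_current_scaling else 1.0,
        volume_model=volume_model,
    )
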