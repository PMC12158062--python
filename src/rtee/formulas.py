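"""Closed-form energy-expenditure equations and unit conversions.

Every estimator in this package ultimately funnels through the functions
here: indirect calorimetry from oxygen uptake, the MET product formula,
the Keytel heart-rate regression, the Mifflin-St Jeor resting metabolic
rate, and the modified-MET predictor ``rmr_sec * (1 + a)``.

All functions are pure and deterministic.  The canonical internal unit
for comparing estimators is kcal/s; converters are provided for the
kJ/min and kcal/min scales the individual formulas natively produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "ParticipantProfile",
    "EnergyRate",
    "KCAL_PER_KJ",
    "ee_from_vo2",
    "gt_ee_per_second",
    "ee_met",
    "met_from_ee",
    "ee_keytel",
    "rmr_day_mifflin",
    "rmr_per_second",
    "pred_ee",
    "convert",
]

#: Thermochemical calorie: 1 kcal = 4.184 kJ.
KCAL_PER_KJ = 1.0 / 4.184

_UNITS = frozenset({"kcal/min", "kJ/min", "kcal/s", "kcal/day"})

#: Seconds per unit time, keyed by the time part of a unit string.
_SECONDS = {"s": 1.0, "min": 60.0, "day": 86400.0}


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics consumed by the Mifflin/Keytel formulas and the RL state.

    Parameters
    ----------
    weight : float
        Body mass in kg, > 0.
    height : float
        Stature in cm, > 0.
    age : float
        Age in years, > 0.
    gender_flag : int
        1 for male, 0 for female.
    """

    weight: float
    height: float
    age: float
    gender_flag: int

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.gender_flag not in (0, 1):
            raise ValueError(f"gender_flag must be 0 or 1, got {self.gender_flag}")


@dataclass(frozen=True)
class EnergyRate:
    """An energy-per-time quantity tagged with its unit.

    ``value`` may be negative only for the Keytel formula output, which
    is returned unclamped by contract; clamping is an evaluation-stage
    decision.
    """

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(_UNITS)}")

    def to(self, target_unit: str) -> "EnergyRate":
        return convert(self, target_unit)


def _energy_time(unit: str) -> tuple[str, str]:
    energy, _, time = unit.partition("/")
    return energy, time


def convert(rate: EnergyRate, target_unit: str) -> EnergyRate:
    """Convert an :class:`EnergyRate` between the supported units.

    kJ -> kcal divides by 4.184 (thermochemical); per-min -> per-s
    divides by 60; per-day -> per-s divides by 86,400.  Conversions
    compose and round-trip to within 1e-12 relative error.
    """
    if target_unit not in _UNITS:
        raise ValueError(f"unknown target unit {target_unit!r}")
    e_from, t_from = _energy_time(rate.unit)
    e_to, t_to = _energy_time(target_unit)
    value = rate.value
    if e_from != e_to:
        if (e_from, e_to) == ("kJ", "kcal"):
            value *= KCAL_PER_KJ
        elif (e_from, e_to) == ("kcal", "kJ"):
            value /= KCAL_PER_KJ
        else:  # pragma: no cover - _UNITS only spans kcal/kJ
            raise ValueError(f"cannot convert energy {e_from} -> {e_to}")
    value *= _SECONDS[t_to] / _SECONDS[t_from]
    return EnergyRate(value, target_unit)


def _as_value(rate: Union[EnergyRate, float], unit: str) -> float:
    """Accept a bare float (assumed in ``unit``) or a tagged EnergyRate."""
    if isinstance(rate, EnergyRate):
        if rate.unit != unit:
            raise ValueError(f"expected unit {unit!r}, got {rate.unit!r}")
        return rate.value
    return float(rate)


def ee_from_vo2(vo2: float, weight: float) -> EnergyRate:
    """Indirect-calorimetry EE in kcal/min: ``vo2 * weight * 5 / 1000``.

    ``vo2`` is oxygen uptake in mL/kg/min, ``weight`` in kg.
    """
    if not weight > 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    if vo2 < 0:
        raise ValueError(f"vo2 must be >= 0, got {vo2}")
    return EnergyRate(vo2 * weight * 5.0 / 1000.0, "kcal/min")


def gt_ee_per_second(vo2: float, weight: float) -> EnergyRate:
    """Ground-truth EE per second: the indirect-calorimetry rate / 60."""
    return EnergyRate(ee_from_vo2(vo2, weight).value / 60.0, "kcal/s")


def ee_met(met: float, weight: float) -> EnergyRate:
    """MET-based EE in kcal/min: ``met * weight * 3.5 / 200``."""
    if not weight > 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    if met < 0:
        raise ValueError(f"met must be >= 0, got {met}")
    return EnergyRate(met * weight * 3.5 / 200.0, "kcal/min")


def met_from_ee(ee: Union[EnergyRate, float], rmr: Union[EnergyRate, float]) -> float:
    """MET value as the ratio EE / RMR (same units required)."""
    if isinstance(ee, EnergyRate) != isinstance(rmr, EnergyRate):
        raise ValueError("ee and rmr must both be EnergyRate or both be floats")
    if isinstance(ee, EnergyRate):
        if ee.unit != rmr.unit:
            raise ValueError(f"unit mismatch: {ee.unit!r} vs {rmr.unit!r}")
        ee, rmr = ee.value, rmr.value
    if not rmr > 0:
        raise ValueError(f"rmr must be > 0, got {rmr}")
    return ee / rmr


# Heart-rate regression coefficients: (intercept, hr, weight, age).
_KEYTEL_MALE = (-55.0969, 0.6309, 0.1988, 0.2017)
_KEYTEL_FEMALE = (-20.4022, 0.4472, -0.1263, 0.074)


def ee_keytel(profile: ParticipantProfile, hr: float) -> EnergyRate:
    """Keytel heart-rate EE estimate in kJ/min, unclamped.

    The gender flag selects exactly one linear branch; the inactive
    branch never contributes.  Output may be negative at very low heart
    rates — downstream consumers decide whether to clamp.
    """
    if not hr > 0:
        raise ValueError(f"hr must be > 0, got {hr}")
    c0, c_hr, c_w, c_a = _KEYTEL_MALE if profile.gender_flag == 1 else _KEYTEL_FEMALE
    value = c0 + c_hr * hr + c_w * profile.weight + c_a * profile.age
    return EnergyRate(value, "kJ/min")


def rmr_day_mifflin(profile: ParticipantProfile) -> EnergyRate:
    """Mifflin-St Jeor resting metabolic rate in kcal/day.

    Male: ``10 W + 6.25 H - 5 A + 5``; female: ``10 W + 6.25 H - 5 A - 161``.
    """
    base = 10.0 * profile.weight + 6.25 * profile.height - 5.0 * profile.age
    offset = 5.0 if profile.gender_flag == 1 else -161.0
    return EnergyRate(base + offset, "kcal/day")


def rmr_per_second(profile: ParticipantProfile) -> EnergyRate:
    """Resting metabolic rate in kcal/s: the daily value / 86,400."""
    return EnergyRate(rmr_day_mifflin(profile).value / 86400.0, "kcal/s")


def pred_ee(rmr_sec: Union[EnergyRate, float], a: float) -> EnergyRate:
    """Modified-MET predictor: ``rmr_sec * (1 + a)`` in kcal/s.

    ``a`` is the activity-intensity coefficient in [0, 20]; ``a = 0``
    reproduces the resting rate exactly.
    """
    rmr_value = _as_value(rmr_sec, "kcal/s")
    if not rmr_value > 0:
        raise ValueError(f"rmr_sec must be > 0, got {rmr_value}")
    if not 0.0 <= a <= 20.0:
        raise ValueError(f"activity coefficient a must lie in [0, 20], got {a}")
    return EnergyRate(rmr_value * (1.0 + a), "kcal/s")
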