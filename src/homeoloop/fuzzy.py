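"""Generic two-input, five-class fuzzy controller.

Each control loop is defined by three user-set points on the controlled
variable's axis — a critical lower bound, the desired target, and an upper
limit — from which five symmetric membership classes are constructed
("critically low", "low", "normal", "high", "critically high").  The
controller takes the measured value and its slope, fires a 5x5 rule table,
and defuzzifies to a single proportional factor in [-1, +1] describing the
required relative change of the actuator (pump rate or respiratory rate).

Design choices (the construction is deliberately the simplest one consistent
with a symmetric five-class partition):

* membership functions are triangular with shouldered extremes; class
  centers sit at the three set points and the two midpoints between them,
  so adjacent grades always sum to 1 (a Ruspini partition);
* the slope axis uses the same construction on ``[-2*s, +2*s]`` about zero,
  where ``s`` is the loop's slope scale in variable-units per minute;
* rules combine antecedents with the product t-norm and duplicate
  consequents additively (probabilistic/Larsen inference), and the
  consequent class index is the clipped negated sum of the two antecedent
  offsets — the minimal monotone, antisymmetric table.  With min/max
  inference the normalized output is not monotone in the measured value;
  the product/sum pair makes "more of the variable never asks for more
  infusion" an exact property;
* defuzzification is the firing-strength-weighted mean of the five output
  centers ``{-1, -0.5, 0, +0.5, +1}``, which coincides with the Mamdani
  centroid whenever a single consequent fires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "ConfigurationError",
    "MeasurementError",
    "FuzzySetSpec",
    "TriangularPartition",
    "MembershipModel",
    "FiredRule",
    "ControlDecision",
    "build_membership",
    "inference",
    "evaluate",
    "update_actuator",
    "VALUE_LABELS",
    "SLOPE_LABELS",
    "OUTPUT_LABELS",
    "OUTPUT_CENTERS",
]

VALUE_LABELS = ("critically low", "low", "normal", "high", "critically high")
SLOPE_LABELS = ("falling fast", "falling", "steady", "rising", "rising fast")
#: consequent classes, indexed by offset -2..+2
OUTPUT_LABELS = ("strong decrease", "decrease", "hold", "increase", "strong increase")
#: defuzzification centers of the output classes, same order as OUTPUT_LABELS
OUTPUT_CENTERS = (-1.0, -0.5, 0.0, 0.5, 1.0)


class ConfigurationError(ValueError):
    """A controller or experiment configuration violates its invariants."""


class MeasurementError(ValueError):
    """A measurement is unusable (non-finite value, empty trace/window)."""


@dataclass(frozen=True)
class FuzzySetSpec:
    """The three-point definition of one fuzzy control loop.

    Parameters
    ----------
    lower_bound, target, upper_bound
        Critical lower bound, desired target and upper limit, in the
        physical units of the controlled variable.  Must be strictly
        increasing.
    slope_scale
        Normalization of the slope input, in variable-units per minute:
        a slope of ``+slope_scale`` grades fully as "rising", and
        ``+2*slope_scale`` as "rising fast".
    """

    lower_bound: float
    target: float
    upper_bound: float
    slope_scale: float

    def __post_init__(self) -> None:
        if not (self.lower_bound < self.target < self.upper_bound):
            raise ConfigurationError(
                "fuzzy set points must satisfy lower_bound < target < upper_bound, "
                f"got ({self.lower_bound}, {self.target}, {self.upper_bound})"
            )
        if not (self.slope_scale > 0):
            raise ConfigurationError(f"slope_scale must be > 0, got {self.slope_scale}")


@dataclass(frozen=True)
class TriangularPartition:
    """Five triangular membership functions with shouldered extremes.

    Interior classes are triangles whose feet are the adjacent centers;
    the outermost classes keep grade 1 beyond their center.  For any x the
    grades of the five classes sum to exactly 1 and at most two are nonzero.
    """

    centers: tuple[float, float, float, float, float]
    labels: tuple[str, str, str, str, str]

    def grades(self, x: float) -> tuple[float, ...]:
        """Membership grade of each class at ``x``, in label order."""
        c = self.centers
        if x <= c[0]:
            return (1.0, 0.0, 0.0, 0.0, 0.0)
        if x >= c[4]:
            return (0.0, 0.0, 0.0, 0.0, 1.0)
        g = [0.0] * 5
        for i in range(4):
            if c[i] <= x <= c[i + 1]:
                u = (x - c[i]) / (c[i + 1] - c[i])
                g[i] = 1.0 - u
                g[i + 1] = u
                break
        return tuple(g)

    def grade(self, label: str, x: float) -> float:
        """Membership grade of the class named ``label`` at ``x``."""
        return self.grades(x)[self.labels.index(label)]


@dataclass(frozen=True)
class MembershipModel:
    """The compiled fuzzy sets of one control loop."""

    value_classes: TriangularPartition
    slope_classes: TriangularPartition
    output_centers: tuple[float, ...] = field(default=OUTPUT_CENTERS)


class FiredRule(NamedTuple):
    """One fired rule, kept for auditability of every control decision."""

    value_class: str
    slope_class: str
    output_class: str
    strength: float


@dataclass(frozen=True)
class ControlDecision:
    """Defuzzified factor plus the resulting actuator command."""

    factor: float
    commanded_rate: float
    fired_rules: tuple[FiredRule, ...] = ()
    held: bool = False  # True when the controller kept its last command


def build_membership(spec: FuzzySetSpec) -> MembershipModel:
    """Compile a three-point spec into the five-class membership model.

    Value-axis class centers are ``{L, (L+T)/2, T, (T+U)/2, U}``; slope-axis
    centers are ``{-2s, -s, 0, +s, +2s}``.
    """
    lo, t, up = spec.lower_bound, spec.target, spec.upper_bound
    value_centers = (lo, (lo + t) / 2.0, t, (t + up) / 2.0, up)
    s = spec.slope_scale
    slope_centers = (-2.0 * s, -s, 0.0, s, 2.0 * s)
    return MembershipModel(
        value_classes=TriangularPartition(value_centers, VALUE_LABELS),
        slope_classes=TriangularPartition(slope_centers, SLOPE_LABELS),
    )


def inference(
    model: MembershipModel, value: float, slope: float
) -> tuple[float, tuple[FiredRule, ...]]:
    """Fire the 5x5 rule table and defuzzify, before polarity.

    The consequent of rule (i, j) — with antecedent offsets
    ``i, j in {-2..+2}`` relative to "normal"/"steady" — is the output class
    at offset ``clip(-(i + j), -2, +2)``: a low and falling variable asks for
    a strong increase, a high and rising one for a strong decrease.  Rule
    strength is the product of the antecedent grades; duplicate consequents
    add; the factor is the strength-weighted mean of the output centers.
    Because the grades on each axis sum to 1, the total firing strength is
    exactly 1 and the factor is monotone in each input.
    """
    if not (math.isfinite(value) and math.isfinite(slope)):
        raise MeasurementError(f"non-finite controller input: value={value}, slope={slope}")
    vg = model.value_classes.grades(value)
    sg = model.slope_classes.grades(slope)
    consequent_strength = [0.0] * 5  # indexed by output offset + 2
    fired: list[FiredRule] = []
    for i in range(5):
        if vg[i] == 0.0:
            continue
        for j in range(5):
            if sg[j] == 0.0:
                continue
            strength = vg[i] * sg[j]
            out = -((i - 2) + (j - 2))
            out = max(-2, min(2, out))
            k = out + 2
            consequent_strength[k] += strength
            fired.append(
                FiredRule(VALUE_LABELS[i], SLOPE_LABELS[j], OUTPUT_LABELS[k], strength)
            )
    total = sum(consequent_strength)
    factor = (
        sum(w * c for w, c in zip(consequent_strength, model.output_centers)) / total
    )
    return factor, tuple(fired)


def evaluate(model: MembershipModel, value: float, slope: float, polarity: int = +1) -> float:
    """Proportional change factor in [-1, +1] for one measurement.

    ``polarity`` is +1 for actuators that raise the controlled variable
    (infusion pumps) and -1 for actuators that lower it (respiratory rate
    versus etCO2): with polarity -1 a high measurement yields a positive
    factor, i.e. an increase of the actuator.
    """
    if polarity not in (+1, -1):
        raise ConfigurationError(f"polarity must be +1 or -1, got {polarity}")
    factor, _ = inference(model, value, slope)
    return polarity * factor


def update_actuator(
    current_rate: float,
    factor: float,
    gain: float,
    limits: tuple[float, float],
    restart_floor: float = 0.0,
) -> float:
    """Map a proportional factor to the new actuator rate.

    ``new = clip(current * (1 + gain * factor), min, max)``.  Because the
    update is multiplicative, zero is absorbing: a pump at 0 ml/h could never
    restart.  When ``current < restart_floor`` and the factor asks for an
    increase, the new rate is raised to ``restart_floor``.
    """
    lo, hi = limits
    if not (lo <= hi):
        raise ConfigurationError(f"actuator limits inverted: {limits}")
    if not (gain > 0):
        raise ConfigurationError(f"gain must be > 0, got {gain}")
    new = current_rate * (1.0 + gain * factor)
    if current_rate < restart_floor and factor > 0:
        new = max(new, restart_floor)
    return min(hi, max(lo, new))
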