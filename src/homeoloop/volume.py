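"""Volume-need analysis (VNA): the rule-based fluid-management subsystem.

Intravascular volume is managed with a recruitment-style ventilation
maneuver: PEEP is transiently raised to the peak inspiratory pressure
(PIP) for a short hold, and systolic arterial pressure is monitored during
the hold and a subsequent observation phase.  The pressure excursion
("VNA delta" = max - min of the systolic trace) grows with intravascular
volume deficit, so a simple threshold rule decides fluid therapy: below
the threshold no volume is needed and the next maneuver runs after a long
interval; at or above the threshold a weight-scaled crystalloid bolus is
given via the second balanced electrolyte solution (BES2) pump and the
maneuver is repeated after a short interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .fuzzy import ConfigurationError, MeasurementError

__all__ = [
    "VnaConfig",
    "VnaResult",
    "VentilatorCommand",
    "ManeuverTimeline",
    "maneuver_timeline",
    "compute_vna_delta",
    "decide_volume",
]


@dataclass(frozen=True)
class VnaConfig:
    """Maneuver geometry and decision rule parameters.

    ``threshold`` (mmHg) separates "no volume need" from "bolus"; the
    breakpoint is inclusive (delta equal to the threshold triggers the
    bolus).  ``hold_duration`` is the PEEP-at-PIP hold (s),
    ``observe_duration`` the post-hold monitoring phase (s).
    ``interval_no_need`` / ``interval_after_bolus`` (min) schedule the next
    maneuver; re-checking is deliberately faster after an intervention.
    """

    threshold: float = 8.0
    bolus_per_kg: float = 2.0
    hold_duration: float = 20.0
    observe_duration: float = 60.0
    interval_no_need: float = 60.0
    interval_after_bolus: float = 15.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError(f"vna threshold must be > 0, got {self.threshold}")
        for name in (
            "bolus_per_kg",
            "hold_duration",
            "observe_duration",
            "interval_no_need",
            "interval_after_bolus",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"vna {name} must be > 0")


class VnaResult(NamedTuple):
    """Outcome of one maneuver: measured delta, decision, next interval."""

    time: float  # min since experiment start
    delta: float  # mmHg
    bolus_ml: float  # 0.0 when no volume is needed
    next_interval: float  # min until the next maneuver


class VentilatorCommand(NamedTuple):
    """A timed remote PEEP command within the maneuver, times in seconds."""

    time_s: float
    peep: float  # cmH2O


@dataclass(frozen=True)
class ManeuverTimeline:
    """Ordered ventilator commands plus the monitoring window of one maneuver."""

    commands: tuple[VentilatorCommand, VentilatorCommand]
    window: tuple[float, float]  # (start_s, end_s) of pressure monitoring


def maneuver_timeline(
    config: VnaConfig, pip: float, baseline_peep: float
) -> ManeuverTimeline:
    """Build the maneuver: raise PEEP to PIP, hold, restore, keep watching.

    PEEP is set to the PIP level at t=0 and restored to baseline after
    ``hold_duration`` seconds; systolic pressure is monitored over the hold
    plus the following ``observe_duration`` seconds.
    """
    if not (pip > baseline_peep):
        raise ConfigurationError(
            f"maneuver needs PIP > baseline PEEP, got PIP={pip}, PEEP={baseline_peep}"
        )
    commands = (
        VentilatorCommand(0.0, pip),
        VentilatorCommand(config.hold_duration, baseline_peep),
    )
    window = (0.0, config.hold_duration + config.observe_duration)
    return ManeuverTimeline(commands=commands, window=window)


def compute_vna_delta(systolic_trace: Sequence[tuple[float, float]]) -> float:
    """Delta = max - min systolic pressure over the monitoring window, mmHg."""
    if len(systolic_trace) == 0:
        raise MeasurementError("empty systolic trace: maneuver invalid")
    pressures = [p for _, p in systolic_trace]
    return max(pressures) - min(pressures)


def decide_volume(delta: float, config: VnaConfig, weight: float) -> VnaResult:
    """Apply the if/then/else volume rule to one measured delta.

    delta < threshold: no volume needed, re-check after
    ``interval_no_need`` minutes.  delta >= threshold (inclusive): command
    a bolus of ``bolus_per_kg`` ml per kg body weight and re-check after
    ``interval_after_bolus`` minutes.
    """
    if delta < 0:
        raise MeasurementError(f"VNA delta cannot be negative, got {delta}")
    if weight <= 0:
        raise ConfigurationError(f"weight must be > 0, got {weight}")
    if delta >= config.threshold:
        return VnaResult(0.0, delta, config.bolus_per_kg * weight, config.interval_after_bolus)
    return VnaResult(0.0, delta, 0.0, config.interval_no_need)
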