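"""The four parameter-specific control loops.

Three loops are driven by the intermittent arterial blood-gas analysis
(BGA, every 2 h): glucose via the 20% glucose pump (G20), ionized calcium
via the calcium chloride pump, and arterial base excess (ABE) via the
sodium bicarbonate pump.  The fourth loop adapts the ventilator's
respiratory rate from the 5-min average of the continuously measured
end-tidal CO2.

Each loop is one configured instance of the generic fuzzy controller in
:mod:`homeoloop.fuzzy`; this module adds slope estimation, cadence and
polarity, and the per-actuator limits and gains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fuzzy import (
    ConfigurationError,
    ControlDecision,
    FuzzySetSpec,
    MeasurementError,
    build_membership,
    inference,
    update_actuator,
)

__all__ = [
    "ControllerConfig",
    "BgaSample",
    "BGA_CONTROLLERS",
    "default_controller_configs",
    "estimate_slope",
    "step_bga_controllers",
    "step_etco2_controller",
]

#: names of the three BGA-driven loops, in their (commuting) processing order
BGA_CONTROLLERS = ("glucose", "calcium", "abe")

#: BgaSample attribute holding each controlled analyte
_SAMPLE_FIELD = {"glucose": "glucose", "calcium": "ionized_calcium", "abe": "abe"}


@dataclass(frozen=True)
class ControllerConfig:
    """Configuration of one control loop.

    ``polarity`` is +1 for infusion loops (the infusate raises the variable)
    and -1 for the etCO2 loop (a faster respiratory rate lowers etCO2).
    ``update_interval`` is the loop cadence in minutes: 120 (the BGA
    interval) for the three pump loops, 5 for the respiratory loop.
    ``averaging_window`` (minutes) applies to the etCO2 loop only.
    """

    name: str
    spec: FuzzySetSpec
    polarity: int
    gain: float
    actuator_limits: tuple[float, float]
    update_interval: float
    averaging_window: float | None = None
    restart_floor: float = 0.0
    initial_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ConfigurationError(f"{self.name}: polarity must be +1 or -1")
        if self.gain <= 0:
            raise ConfigurationError(f"{self.name}: gain must be > 0")
        lo, hi = self.actuator_limits
        if not (lo <= hi):
            raise ConfigurationError(f"{self.name}: actuator limits inverted")
        if self.update_interval <= 0:
            raise ConfigurationError(f"{self.name}: update_interval must be > 0")


@dataclass(frozen=True)
class BgaSample:
    """One arterial blood-gas measurement vector.

    Concentrations in mmol/L; ``abe`` (arterial base excess) may be
    negative.  ``time`` is minutes since the start of the observation
    period.  Missing analytes are ``None`` and make the corresponding
    controller hold its last command.
    """

    time: float
    glucose: float | None
    ionized_calcium: float | None
    abe: float | None
    lactate: float | None = None
    hemoglobin: float | None = None


def default_controller_configs(etco2_target: float = 40.0) -> dict[str, ControllerConfig]:
    """The four loops with their default set points and actuator envelopes.

    Set points are symmetric about physiologically normal targets for an
    anesthetized pig; pump envelopes 0-100 ml/h with a 2 ml/h restart
    floor, respiratory rate 6-40 breaths/min.  The pump gain (0.5) is
    larger than the respiratory gain (0.1) because the respiratory loop
    runs 24x more often; small per-step moves keep it free of overshoot.
    ``etco2_target`` defaults to 40 mmHg; the fuzzy set spans +-10 mmHg
    around it.
    """
    pump_limits = (0.0, 100.0)
    return {
        "glucose": ControllerConfig(
            name="glucose",
            spec=FuzzySetSpec(3.5, 5.5, 7.5, slope_scale=0.01),
            polarity=+1,
            gain=0.5,
            actuator_limits=pump_limits,
            update_interval=120.0,
            restart_floor=2.0,
            initial_rate=7.0,
        ),
        "calcium": ControllerConfig(
            name="calcium",
            spec=FuzzySetSpec(1.05, 1.25, 1.45, slope_scale=0.001),
            polarity=+1,
            gain=0.5,
            actuator_limits=pump_limits,
            update_interval=120.0,
            restart_floor=2.0,
            initial_rate=2.0,
        ),
        "abe": ControllerConfig(
            name="abe",
            spec=FuzzySetSpec(-6.0, 0.0, 6.0, slope_scale=0.005),
            polarity=+1,
            gain=0.5,
            actuator_limits=pump_limits,
            update_interval=120.0,
            restart_floor=2.0,
            initial_rate=0.0,
        ),
        "etco2": ControllerConfig(
            name="etco2",
            spec=FuzzySetSpec(
                # slope scale sits above the noise floor of the 5-min-mean
                # finite difference, so only sustained trends grade as rising
                etco2_target - 10.0, etco2_target, etco2_target + 10.0, slope_scale=0.5
            ),
            polarity=-1,
            gain=0.1,
            actuator_limits=(6.0, 40.0),
            update_interval=5.0,
            averaging_window=5.0,
            initial_rate=12.0,
        ),
    }


def estimate_slope(
    history: Sequence, variable: str | None = None
) -> float:
    """Backward two-point slope, in variable-units per minute.

    ``history`` is an ordered sequence of either ``(time_min, value)``
    pairs or :class:`BgaSample` objects (then ``variable`` selects the
    analyte).  With a single usable point the slope is 0.  Entries whose
    value is ``None``/non-finite are skipped.
    """
    if len(history) == 0:
        raise MeasurementError("cannot estimate a slope from an empty history")
    points: list[tuple[float, float]] = []
    for item in history:
        if isinstance(item, BgaSample):
            if variable is None:
                raise ConfigurationError("variable name required for BgaSample history")
            value = getattr(item, _SAMPLE_FIELD.get(variable, variable))
            t = item.time
        else:
            t, value = item
        if value is not None and math.isfinite(value):
            points.append((t, value))
    if len(points) < 2:
        return 0.0
    (t0, v0), (t1, v1) = points[-2], points[-1]
    if t1 == t0:
        return 0.0
    return (v1 - v0) / (t1 - t0)


def _decide(
    config: ControllerConfig, value: float, slope: float, current_rate: float
) -> ControlDecision:
    model = build_membership(config.spec)
    raw_factor, fired = inference(model, value, slope)
    factor = config.polarity * raw_factor
    new_rate = update_actuator(
        current_rate, factor, config.gain, config.actuator_limits, config.restart_floor
    )
    return ControlDecision(factor=factor, commanded_rate=new_rate, fired_rules=fired)


def _hold(current_rate: float) -> ControlDecision:
    return ControlDecision(factor=0.0, commanded_rate=current_rate, held=True)


def step_bga_controllers(
    sample: BgaSample,
    history: Sequence[BgaSample],
    configs: Mapping[str, ControllerConfig],
    current_rates: Mapping[str, float],
) -> dict[str, ControlDecision]:
    """Process one BGA: one decision per pump (G20, CaCl, bicarbonate).

    ``history`` holds the previous samples (the new ``sample`` is appended
    internally for slope estimation).  A missing analyte makes that loop
    hold its current rate with a warning; the three loops are independent,
    so their processing order does not matter.
    """
    full = list(history) + [sample]
    decisions: dict[str, ControlDecision] = {}
    for name in BGA_CONTROLLERS:
        config = configs[name]
        value = getattr(sample, _SAMPLE_FIELD[name])
        current = current_rates[name]
        if value is None or not math.isfinite(value):
            warnings.warn(
                f"BGA sample at t={sample.time} min missing {name}; holding pump rate",
                stacklevel=2,
            )
            decisions[name] = _hold(current)
            continue
        slope = estimate_slope(full, name)
        decisions[name] = _decide(config, value, slope, current)
    return decisions


def step_etco2_controller(
    readings: Sequence[float],
    config: ControllerConfig,
    current_rr: float,
    previous_mean: float | None = None,
) -> ControlDecision:
    """Adapt the respiratory rate from a window of etCO2 readings.

    The controlled value is the arithmetic mean of the readings over the
    averaging window (5 min by default); the slope is the backward
    difference between this mean and the previous window's mean over one
    update interval.  An empty window holds the current rate.
    """
    finite = [r for r in readings if math.isfinite(r)]
    if not finite:
        warnings.warn("empty etCO2 averaging window; holding respiratory rate", stacklevel=2)
        return _hold(current_rr)
    mean = sum(finite) / len(finite)
    if previous_mean is None:
        slope = 0.0
    else:
        slope = (mean - previous_mean) / config.update_interval
    return _decide(config, mean, slope, current_rr)
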