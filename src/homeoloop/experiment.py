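"""Closed-loop experiment engine: the 72-h automated life-support protocol.

The orchestrator advances a virtual pig on a 1-min grid and wires the
controllers to it exactly on the protocol's cadences: an arterial
blood-gas analysis (BGA) every 2 h drives the glucose, calcium and
base-excess pumps; the etCO2 loop adapts the respiratory rate every 5 min
from the 5-min average reading; volume-need maneuvers run on their own
rule-driven schedule (60 min after "no need", 15 min after a bolus); and
the pig is repositioned left / back / right / back on an 8/4/8/4-h cycle.
Within one tick, simultaneous events execute in a fixed order —
measure, BGA controllers, etCO2 controller, VNA, position change,
physiology step — so identical configuration and seed replay
bit-identically.

No channel other than the controllers and the VNA rule ever mutates an
actuator: the log carries an audit trail (every command row's event tag
names its trigger) that :func:`audit_commands` checks mechanically.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .controllers import (
    BGA_CONTROLLERS,
    BgaSample,
    ControllerConfig,
    default_controller_configs,
    step_bga_controllers,
    step_etco2_controller,
)
from .fuzzy import ConfigurationError
from .pig import (
    POSITIONS,
    PigParams,
    VentilatorSettings,
    concentration,
    etco2_reading,
    initial_state,
    sample_bga,
    simulate_vna_trace,
    step_physiology,
)
from .record import TimeSeriesLog
from .volume import VnaConfig, compute_vna_delta, decide_volume, maneuver_timeline

__all__ = [
    "ExperimentConfig",
    "InRangeReport",
    "default_ranges",
    "run_experiment",
    "in_range_report",
    "audit_commands",
    "position_at",
]

#: infusion channel actuated by each BGA loop
_PUMP_CHANNEL = {"glucose": "g20", "calcium": "cacl", "abe": "bicarb"}
_PUMP_VARIABLE = {"glucose": "g20_rate", "calcium": "cacl_rate", "abe": "bicarb_rate"}

DEFAULT_POSITION_CYCLE: tuple[tuple[str, float], ...] = (
    ("left", 8.0),
    ("back", 4.0),
    ("right", 8.0),
    ("back", 4.0),
)


def default_ranges(etco2_target: float = 40.0) -> dict[str, tuple[float, float]]:
    """Physiological acceptance ranges per controlled variable.

    Laboratory-normal bands for an anesthetized pig; etCO2 uses its
    configured target +- 5 mmHg.
    """
    return {
        "glucose": (3.9, 8.3),
        "calcium": (1.10, 1.40),
        "abe": (-3.0, 3.0),
        "etco2": (etco2_target - 5.0, etco2_target + 5.0),
    }


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one closed-loop run depends on, seed included."""

    duration_h: float = 72.0
    bga_interval: int = 120  # min
    etco2_interval: int = 5  # min
    position_cycle: tuple[tuple[str, float], ...] = DEFAULT_POSITION_CYCLE
    controllers: Mapping[str, ControllerConfig] = field(
        default_factory=default_controller_configs
    )
    vna: VnaConfig = field(default_factory=VnaConfig)
    pig: PigParams = field(default_factory=PigParams)
    ventilator: VentilatorSettings = field(default_factory=VentilatorSettings)
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=default_ranges)
    bes_rate: float = 52.0 * 10.0 / 24.0  # ml/h, 10 ml/kg/day baseline crystalloid
    bes2_max_rate: float = 600.0  # ml/h, bolus delivery rate
    controllers_enabled: bool = True
    vna_enabled: bool = True
    seed: int = 1

    @property
    def duration_min(self) -> int:
        return int(round(self.duration_h * 60.0))

    def validate(self) -> None:
        if self.duration_h <= 0:
            raise ConfigurationError("experiment.duration_h must be > 0")
        for key in ("bga_interval", "etco2_interval"):
            value = getattr(self, key)
            if not (isinstance(value, int) and value >= 1):
                raise ConfigurationError(f"experiment.{key} must be a whole number of minutes")
            if self.duration_min % value != 0:
                raise ConfigurationError(
                    f"experiment.{key}={value} does not divide the {self.duration_min}-min grid"
                )
        for pos, hours in self.position_cycle:
            if pos not in POSITIONS:
                raise ConfigurationError(f"position_cycle: unknown position {pos!r}")
            if hours <= 0:
                raise ConfigurationError("position_cycle: segment durations must be > 0")
        targets = {
            "glucose": self.controllers["glucose"].spec.target,
            "calcium": self.controllers["calcium"].spec.target,
            "abe": self.controllers["abe"].spec.target,
            "etco2": self.controllers["etco2"].spec.target,
        }
        for name, (lo, hi) in self.ranges.items():
            if not (lo < hi):
                raise ConfigurationError(f"ranges.{name}: lower limit must be below upper")
            if name in targets and not (lo <= targets[name] <= hi):
                raise ConfigurationError(
                    f"ranges.{name} does not contain the controller target {targets[name]}"
                )
        if self.bes_rate < 0 or self.bes2_max_rate <= 0:
            raise ConfigurationError("infusion rates must be non-negative (bes2 max > 0)")


def position_at(cycle: Sequence[tuple[str, float]], t_min: float) -> str:
    """Position prescribed by the rotation schedule at minute ``t_min``."""
    period = sum(h for _, h in cycle) * 60.0
    t = t_min % period
    elapsed = 0.0
    for pos, hours in cycle:
        elapsed += hours * 60.0
        if t < elapsed:
            return pos
    return cycle[-1][0]


def run_experiment(config: ExperimentConfig) -> TimeSeriesLog:
    """Run the full closed-loop protocol and return the complete log.

    The event loop walks the 1-min grid from t=0 to the configured
    duration inclusive, so a 72-h run performs 37 BGAs (t = 0, 120, ...,
    4320 min) and 864 etCO2 adaptations (t = 5, ..., 4320; the first
    5-min average needs 5 min of readings).  With ``controllers_enabled``
    or ``vna_enabled`` off, the corresponding actuators stay frozen at
    their initial values — the open-loop reference the drift checks use.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = config.pig
    log = TimeSeriesLog()

    state = initial_state(params, position_at(config.position_cycle, 0.0), config.ventilator)
    ventilator = config.ventilator
    rates = {name: config.controllers[name].initial_rate for name in BGA_CONTROLLERS}
    rr = config.controllers["etco2"].initial_rate
    ventilator = VentilatorSettings(
        tidal_volume=config.ventilator.tidal_volume,
        peep=config.ventilator.peep,
        pip=config.ventilator.pip,
        fio2=config.ventilator.fio2,
        respiratory_rate=rr,
    )

    bga_history: list[BgaSample] = []
    window: deque[float] = deque(maxlen=config.etco2_interval)
    previous_mean: float | None = None
    bolus_remaining = 0.0
    next_vna = 0 if config.vna_enabled else None
    duration = config.duration_min

    log.append(0.0, "positions", "position", POSITIONS.index(state.position), "", state.position)

    for t in range(duration + 1):
        ft = float(t)
        # -- measure ------------------------------------------------------
        window.append(etco2_reading(state, params, rng))

        # -- BGA tick: sample + the three pump loops -----------------------
        if t % config.bga_interval == 0:
            sample = sample_bga(state, params, rng)
            for name in BGA_CONTROLLERS:
                value = getattr(sample, {"calcium": "ionized_calcium"}.get(name, name))
                log.append(ft, "measurements", name, value, "mmol/L", "bga")
            if config.controllers_enabled:
                decisions = step_bga_controllers(
                    sample, bga_history, config.controllers, rates
                )
                for name in BGA_CONTROLLERS:
                    rates[name] = decisions[name].commanded_rate
                    log.append(
                        ft, "commands", _PUMP_VARIABLE[name], rates[name], "ml/h", "bga"
                    )
            bga_history.append(sample)

        # -- etCO2 tick: 5-min average + respiratory loop ------------------
        if t > 0 and t % config.etco2_interval == 0:
            mean = sum(window) / len(window)
            log.append(ft, "measurements", "etco2", mean, "mmHg", "etco2")
            if config.controllers_enabled:
                decision = step_etco2_controller(
                    list(window), config.controllers["etco2"], rr, previous_mean
                )
                rr = decision.commanded_rate
                ventilator = VentilatorSettings(
                    tidal_volume=ventilator.tidal_volume,
                    peep=ventilator.peep,
                    pip=ventilator.pip,
                    fio2=ventilator.fio2,
                    respiratory_rate=rr,
                )
                log.append(ft, "commands", "respiratory_rate", rr, "/min", "etco2")
            previous_mean = mean

        # -- VNA maneuver on its rule-driven schedule ----------------------
        if next_vna is not None and t == next_vna:
            timeline = maneuver_timeline(config.vna, ventilator.pip, ventilator.peep)
            trace = simulate_vna_trace(state, params, timeline, rng)
            delta = compute_vna_delta(trace)
            result = decide_volume(delta, config.vna, params.weight)
            log.append(ft, "maneuvers", "vna_delta", delta, "mmHg", "vna")
            if result.bolus_ml > 0:
                bolus_remaining += result.bolus_ml
                log.append(ft, "commands", "bes2_bolus", result.bolus_ml, "ml", "vna")
            next_vna = t + int(round(result.next_interval))

        # -- position rotation --------------------------------------------
        if t > 0 and t < duration:
            new_pos = position_at(config.position_cycle, ft)
            if new_pos != state.position:
                state = _with_position(state, new_pos)
                log.append(
                    ft, "positions", "position", POSITIONS.index(new_pos), "", new_pos
                )
                # airway suctioning after repositioning: protocol event, no
                # physiological effect modeled
                log.append(ft, "events", "suction", 0.0, "", "position-change")

        # -- physiology advances to the next tick --------------------------
        if t < duration:
            bes2_rate = min(config.bes2_max_rate, bolus_remaining * 60.0)
            bolus_remaining = max(0.0, bolus_remaining - bes2_rate / 60.0)
            infusions = {
                "g20": rates["glucose"],
                "cacl": rates["calcium"],
                "bicarb": rates["abe"],
                "bes": config.bes_rate,
                "bes2": bes2_rate,
            }
            state = step_physiology(state, params, infusions, ventilator, dt=1.0)

    return log


def _with_position(state, position):
    from dataclasses import replace

    return replace(state, position=position)


@dataclass(frozen=True)
class InRangeReport:
    """Per-variable in-range percentages plus the volume-need summary."""

    percentages: dict[str, float]  # variable -> % of measurements in range
    counts: dict[str, tuple[int, int]]  # variable -> (in-range, total)
    vna_by_position: dict[str, tuple[float, int]]  # position -> (mean delta, n)
    total_bolus_ml: float
    n_boluses: int

    def to_frame(self) -> "object":
        import pandas as pd

        return pd.DataFrame(
            {
                "variable": list(self.percentages),
                "percent_in_range": [self.percentages[v] for v in self.percentages],
                "n_in_range": [self.counts[v][0] for v in self.percentages],
                "n_total": [self.counts[v][1] for v in self.percentages],
            }
        )


def in_range_report(
    log: TimeSeriesLog, ranges: Mapping[str, tuple[float, float]]
) -> InRangeReport:
    """Fraction of measurements inside the physiological range, per variable.

    Glucose, calcium and base excess are scored on their BGA samples;
    etCO2 on its 5-min averages.  The report also summarizes the measured
    VNA deltas by the position the pig was in at maneuver time, and the
    total bolus volume — the volume-need-vs-position picture.
    """
    percentages: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for name, (lo, hi) in ranges.items():
        if not (lo < hi):
            raise ConfigurationError(f"ranges.{name}: lower limit must be below upper")
        values = [r.value for r in log.select("measurements", name)]
        if not values:
            warnings.warn(f"no measurements for {name!r}; omitted from report", stacklevel=2)
            continue
        n_in = sum(1 for v in values if lo <= v <= hi)
        counts[name] = (n_in, len(values))
        percentages[name] = 100.0 * n_in / len(values)

    position_rows = log.select("positions", "position")
    deltas_by_pos: dict[str, list[float]] = {}
    for row in log.select("maneuvers", "vna_delta"):
        pos = "unknown"
        for p in position_rows:
            if p.time_min <= row.time_min:
                pos = p.event
            else:
                break
        deltas_by_pos.setdefault(pos, []).append(row.value)
    vna_by_position = {
        pos: (sum(d) / len(d), len(d)) for pos, d in sorted(deltas_by_pos.items())
    }
    boluses = [r.value for r in log.select("commands", "bes2_bolus")]
    return InRangeReport(
        percentages=percentages,
        counts=counts,
        vna_by_position=vna_by_position,
        total_bolus_ml=sum(boluses),
        n_boluses=len(boluses),
    )


def audit_commands(config: ExperimentConfig, log: TimeSeriesLog) -> list[str]:
    """Check the no-manual-interaction contract; return violations (empty = clean).

    Every actuator-command row must be attributable to its trigger: pump
    commands only on the BGA grid, respiratory-rate commands only on the
    etCO2 grid, boluses only at logged maneuver times.
    """
    violations: list[str] = []
    maneuver_times = {r.time_min for r in log.select("maneuvers", "vna_delta")}
    for row in log.select("commands"):
        t = row.time_min
        if row.variable in _PUMP_VARIABLE.values():
            if row.event != "bga" or (t % config.bga_interval) != 0:
                violations.append(f"pump command off the BGA schedule at t={t}")
        elif row.variable == "respiratory_rate":
            if row.event != "etco2" or t == 0 or (t % config.etco2_interval) != 0:
                violations.append(f"respiratory command off the etCO2 schedule at t={t}")
        elif row.variable == "bes2_bolus":
            if row.event != "vna" or t not in maneuver_times:
                violations.append(f"bolus without a maneuver at t={t}")
        else:
            violations.append(f"unknown actuator command {row.variable!r} at t={t}")
    return violations
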