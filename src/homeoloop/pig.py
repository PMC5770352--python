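"""Seeded virtual-pig physiology: the plant the closed loops act on.

A deliberately small discrete-time compartment model of a 52-kg
anesthetized pig, built to exhibit — with realistic magnitudes — exactly
the behaviors the control system has to cope with:

* **solute mass balance with dilution.**  Glucose, ionized calcium and the
  buffer base behind arterial base excess (ABE) each live in a single
  well-mixed distribution volume with zero-order endogenous production and
  first-order elimination.  Distribution volumes scale with relative blood
  volume, so an infusion of solute-free crystalloid (BES/BES2) dilutes
  every concentration — the cross-subsystem interaction in which a fluid
  bolus transiently lowers measured calcium, and a fluid-rate reduction
  concentrates the co-infused glucose.
* **ventilation.**  etCO2 follows the alveolar-ventilation relation
  ``etCO2 = 0.863 * VCO2 / VA`` with ``VA = RR * (VT - dead space)`` in
  L/min; CO2 production is modulated by a slow oscillation so the
  respiratory loop has something to track.
* **volume need.**  Fluid losses (urine + insensible) exceed the baseline
  infusions, so a deficit accrues; the recruitment-maneuver pressure
  excursion grows linearly with the deficit relative to a
  position-dependent volume target (highest supine/dorsal, where preload
  is most sensitive to hypovolemia).
* **measurement noise.**  BGA analytes and per-minute etCO2 readings carry
  independent Gaussian noise with configurable SDs; all randomness flows
  through one seeded generator, so runs replay bit-identically.

The model makes no claim to porcine pharmacokinetic fidelity; kinetic
constants are plausibility-scaled for a 52-kg pig and fully exposed in
:class:`PigParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .controllers import BgaSample
from .volume import ManeuverTimeline

__all__ = [
    "SimulationFault",
    "PigParams",
    "PigState",
    "VentilatorSettings",
    "SOLUTES",
    "POSITIONS",
    "initial_state",
    "concentration",
    "step_physiology",
    "simulate_vna_trace",
    "sample_bga",
    "etco2_reading",
]

SOLUTES = ("glucose", "calcium", "buffer_base")
POSITIONS = ("left", "back", "right")

#: solute carried by each infusion channel, as (solute, mmol per ml infusate);
#: balanced electrolyte solutions are treated as solute-neutral volume.
CHANNEL_SOLUTE: dict[str, tuple[str, float] | None] = {
    "g20": ("glucose", 1.111),  # 20% glucose = 200 g/L / 180 g/mol
    "cacl": ("calcium", 0.68),  # 10% CaCl2 dihydrate
    "bicarb": ("buffer_base", 1.0),  # 8.4% NaHCO3 = 1 mmol/ml
    "bes": None,
    "bes2": None,
}


class SimulationFault(RuntimeError):
    """The physiology reached an impossible state (e.g. non-positive volume)."""


@dataclass(frozen=True)
class VentilatorSettings:
    """Volume-controlled ventilation baseline; pressures in cmH2O."""

    tidal_volume: float = 520.0  # ml (10 ml/kg for 52 kg)
    peep: float = 5.0
    pip: float = 20.0
    fio2: float = 0.40  # recorded but physiologically inert here
    respiratory_rate: float = 12.0  # breaths/min (actuated by the etCO2 loop)


@dataclass(frozen=True)
class PigParams:
    """All physiological constants, kinetics and noise levels.

    Volumes of distribution in L; production in mmol/min (negative for
    buffer base: net metabolic acid production consumes buffer);
    elimination as first-order rate constants in 1/min.  ``loss_rate``
    (ml/min) is combined urinary + insensible fluid loss.
    ``position_volume_stress`` (ml) is the extra volume the circulation
    needs per position; supine ("back") is highest, which makes the
    maneuver deltas largest there.  ``vna_baseline``/``vna_volume_gain``
    shape the maneuver response delta = d0 + k_v * deficit.
    """

    weight: float = 52.0  # kg
    blood_volume: float = 3380.0  # ml (65 ml/kg)
    volume_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"glucose": 12.0, "calcium": 14.0, "buffer_base": 15.0}
    )
    production: Mapping[str, float] = field(
        default_factory=lambda: {"glucose": 0.20, "calcium": 0.010, "buffer_base": -0.05}
    )
    elimination: Mapping[str, float] = field(
        default_factory=lambda: {"glucose": 0.005, "calcium": 0.002, "buffer_base": 0.0}
    )
    target_concentration: Mapping[str, float] = field(
        default_factory=lambda: {"glucose": 5.5, "calcium": 1.25, "buffer_base": 0.0}
    )
    vco2: float = 200.0  # ml/min CO2 production
    vco2_osc_amplitude: float = 0.08  # relative slow modulation of VCO2
    vco2_osc_period: float = 360.0  # min
    dead_space: float = 150.0  # ml
    loss_rate: float = 1.0  # ml/min urine + insensible
    position_volume_stress: Mapping[str, float] = field(
        default_factory=lambda: {"left": 0.0, "back": 200.0, "right": 0.0}
    )
    vna_baseline: float = 5.0  # mmHg, maneuver delta at zero deficit
    vna_volume_gain: float = 0.02  # mmHg per ml of deficit
    vna_noise_sd: float = 0.5  # mmHg, amplitude noise of the maneuver
    systolic_baseline: float = 110.0  # mmHg
    bp_volume_slope: float = 0.02  # mmHg systolic drop per ml deficit
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "glucose": 0.15,
            "calcium": 0.02,
            "abe": 0.30,
            "etco2": 1.0,
            "lactate": 0.1,
            "hemoglobin": 0.2,
        }
    )
    lactate: float = 1.2  # mmol/L, reported but uncontrolled
    hemoglobin: float = 9.0  # g/dL, reported but uncontrolled
    seed: int = 0


@dataclass(frozen=True)
class PigState:
    """Full physiological state at one instant."""

    weight: float
    blood_volume: float  # ml
    amounts: Mapping[str, float]  # mmol per solute in its distribution volume
    etco2: float  # mmHg, noise-free
    systolic_bp: float  # mmHg
    position: str
    time: float  # min since start


def initial_state(
    params: PigParams,
    position: str = "left",
    ventilator: VentilatorSettings | None = None,
) -> PigState:
    """State with every solute at its target concentration."""
    amounts = {
        s: params.target_concentration[s] * params.volume_distribution[s] for s in SOLUTES
    }
    return PigState(
        weight=params.weight,
        blood_volume=params.blood_volume,
        amounts=amounts,
        etco2=_alveolar_etco2(params, ventilator or VentilatorSettings(), 0.0),
        systolic_bp=params.systolic_baseline,
        position=position,
        time=0.0,
    )


def concentration(state: PigState, params: PigParams, solute: str) -> float:
    """mmol/L, with the distribution volume scaled by relative blood volume.

    Scaling the distribution volume by ``blood_volume / baseline`` is what
    makes solute-free infusions dilute every solute: only amounts are
    conserved, concentrations are emergent.
    """
    vd_eff = params.volume_distribution[solute] * (state.blood_volume / params.blood_volume)
    return state.amounts[solute] / vd_eff


def _alveolar_etco2(params: PigParams, ventilator: VentilatorSettings, time: float) -> float:
    """etCO2 (mmHg) from the alveolar ventilation equation, noise-free."""
    vco2 = params.vco2
    if params.vco2_osc_amplitude > 0:
        vco2 *= 1.0 + params.vco2_osc_amplitude * math.sin(
            2.0 * math.pi * time / params.vco2_osc_period
        )
    alveolar = ventilator.respiratory_rate * (ventilator.tidal_volume - params.dead_space)
    if alveolar <= 0:
        raise SimulationFault("alveolar ventilation is non-positive")
    return 0.863 * vco2 / (alveolar / 1000.0)


def _volume_deficit(state: PigState, params: PigParams) -> float:
    """ml of missing volume relative to the position-dependent target."""
    target = params.blood_volume + params.position_volume_stress[state.position]
    return max(0.0, target - state.blood_volume)


def step_physiology(
    state: PigState,
    params: PigParams,
    infusions: Mapping[str, float],
    ventilator: VentilatorSettings,
    dt: float = 1.0,
) -> PigState:
    """Advance the pig by ``dt`` minutes under the given infusion rates.

    ``infusions`` maps channel name ('g20', 'cacl', 'bicarb', 'bes',
    'bes2') to rate in ml/h.  Solute amounts integrate infusion input plus
    endogenous production minus first-order elimination; blood volume
    integrates total infused volume minus losses.  Explicit Euler on a
    1-min grid is exact for the pure-accumulation ablations used in the
    conservation checks.
    """
    if dt <= 0:
        raise SimulationFault(f"dt must be > 0, got {dt}")
    inflow_ml_min = 0.0
    infused_mmol_min = dict.fromkeys(SOLUTES, 0.0)
    for channel, rate_ml_h in infusions.items():
        if channel not in CHANNEL_SOLUTE:
            raise SimulationFault(f"unknown infusion channel {channel!r}")
        if rate_ml_h < 0:
            raise SimulationFault(f"negative infusion rate on {channel!r}")
        ml_min = rate_ml_h / 60.0
        inflow_ml_min += ml_min
        carried = CHANNEL_SOLUTE[channel]
        if carried is not None:
            solute, mmol_per_ml = carried
            infused_mmol_min[solute] += ml_min * mmol_per_ml

    amounts = {}
    for s in SOLUTES:
        rate = (
            infused_mmol_min[s]
            + params.production[s]
            - params.elimination[s] * state.amounts[s]
        )
        amounts[s] = state.amounts[s] + rate * dt

    volume = state.blood_volume + (inflow_ml_min - params.loss_rate) * dt
    if volume <= 0:
        raise SimulationFault(
            f"blood volume non-positive ({volume:.1f} ml) at t={state.time + dt} min"
        )

    time = state.time + dt
    new = replace(
        state,
        blood_volume=volume,
        amounts=amounts,
        time=time,
        etco2=_alveolar_etco2(params, ventilator, time),
    )
    deficit = _volume_deficit(new, params)
    return replace(new, systolic_bp=params.systolic_baseline - params.bp_volume_slope * deficit)


def simulate_vna_trace(
    state: PigState,
    params: PigParams,
    timeline: ManeuverTimeline,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Systolic pressure trace (1-s resolution) over the monitoring window.

    The trace dips during the high-PEEP hold (raised intrathoracic
    pressure impedes venous return) and recovers afterwards; its
    excursion max - min equals ``d0 + k_v * deficit`` plus Gaussian
    amplitude noise, so hypovolemia — and the supine position's higher
    volume target — directly enlarges the measured delta.
    """
    hold = timeline.commands[1].time_s
    start, end = timeline.window
    amplitude = params.vna_baseline + params.vna_volume_gain * _volume_deficit(state, params)
    if rng is not None and params.vna_noise_sd > 0:
        amplitude += rng.normal(0.0, params.vna_noise_sd)
    amplitude = max(0.0, amplitude)
    recovery = max(1.0, (end - hold) / 2.0)  # recovered halfway through observation
    trace = []
    t = start
    while t <= end + 1e-9:
        if t <= hold:
            shape = t / hold if hold > 0 else 1.0
        else:
            shape = max(0.0, 1.0 - (t - hold) / recovery)
        trace.append((t, state.systolic_bp - amplitude * shape))
        t += 1.0
    return trace


def sample_bga(
    state: PigState, params: PigParams, rng: np.random.Generator | None = None
) -> BgaSample:
    """Draw one arterial blood-gas sample (true concentrations + noise)."""

    def noisy(value: float, key: str) -> float:
        if rng is None or params.noise_sd[key] == 0:
            return value
        return value + rng.normal(0.0, params.noise_sd[key])

    return BgaSample(
        time=state.time,
        glucose=noisy(concentration(state, params, "glucose"), "glucose"),
        ionized_calcium=noisy(concentration(state, params, "calcium"), "calcium"),
        abe=noisy(concentration(state, params, "buffer_base"), "abe"),
        lactate=noisy(params.lactate, "lactate"),
        hemoglobin=noisy(params.hemoglobin, "hemoglobin"),
    )


def etco2_reading(
    state: PigState, params: PigParams, rng: np.random.Generator | None = None
) -> float:
    """One per-minute etCO2 reading from the ventilator's capnometer."""
    if rng is None or params.noise_sd["etco2"] == 0:
        return state.etco2
    return state.etco2 + rng.normal(0.0, params.noise_sd["etco2"])
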