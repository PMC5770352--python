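"""TOML experiment configuration: parsing, validation, template generation.

The configuration file mirrors :class:`~homeoloop.experiment.ExperimentConfig`
field for field, with one ``[subsystems.<name>]`` table per control loop and
``[pig]``, ``[vna]``, ``[ventilator]``, ``[ranges]`` and ``[experiment]``
tables.  Every key is optional — an empty file yields the default 72-h,
52-kg experiment — but unknown keys are rejected by name, so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .controllers import ControllerConfig, default_controller_configs
from .experiment import DEFAULT_POSITION_CYCLE, ExperimentConfig, default_ranges
from .fuzzy import ConfigurationError, FuzzySetSpec
from .pig import PigParams, VentilatorSettings
from .volume import VnaConfig

__all__ = ["load_config", "config_template", "CONFIG_TEMPLATE"]

_EXPERIMENT_KEYS = {
    "duration_h",
    "bga_interval_min",
    "etco2_interval_min",
    "seed",
    "bes_rate_ml_h",
    "bes2_max_rate_ml_h",
    "position_cycle",
    "controllers_enabled",
    "vna_enabled",
}

#: config key -> PigParams field (flat scalar keys only)
_PIG_KEYS = {
    "weight_kg": "weight",
    "blood_volume_ml": "blood_volume",
    "vco2_ml_min": "vco2",
    "vco2_osc_amplitude": "vco2_osc_amplitude",
    "vco2_osc_period_min": "vco2_osc_period",
    "dead_space_ml": "dead_space",
    "loss_rate_ml_min": "loss_rate",
    "vna_baseline_mmhg": "vna_baseline",
    "vna_volume_gain_mmhg_per_ml": "vna_volume_gain",
    "vna_noise_sd_mmhg": "vna_noise_sd",
    "systolic_baseline_mmhg": "systolic_baseline",
    "bp_volume_slope": "bp_volume_slope",
}

_PIG_TABLE_KEYS = {
    "volume_distribution_l": "volume_distribution",
    "production_mmol_min": "production",
    "elimination_per_min": "elimination",
    "target_concentration": "target_concentration",
    "position_volume_stress_ml": "position_volume_stress",
    "noise_sd": "noise_sd",
}

_VNA_KEYS = {
    "threshold_mmhg": "threshold",
    "bolus_ml_per_kg": "bolus_per_kg",
    "hold_s": "hold_duration",
    "observe_s": "observe_duration",
    "interval_no_need_min": "interval_no_need",
    "interval_after_bolus_min": "interval_after_bolus",
}

_VENTILATOR_KEYS = {"tidal_volume_ml_per_kg", "peep_cmh2o", "pip_cmh2o", "fio2"}

_SUBSYSTEM_KEYS = {
    "lower_bound",
    "target",
    "upper_bound",
    "slope_scale",
    "gain",
    "limits",
    "initial_rate",
    "restart_floor",
}

_RANGE_KEYS = {"glucose", "calcium", "abe", "etco2"}


def _reject_unknown(table: dict, allowed, where: str) -> None:
    unknown = set(table) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in [{where}]: {', '.join(sorted(unknown))}"
        )


def _merge_mapping(defaults, overrides: dict, where: str) -> dict:
    merged = dict(defaults)
    _reject_unknown(overrides, merged, where)
    merged.update(overrides)
    return merged


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a TOML config file into an ExperimentConfig.

    Raises ``FileNotFoundError`` for a missing file, ``tomllib.TOMLDecodeError``
    for malformed TOML and :class:`ConfigurationError` (naming the offending
    key) for invariant violations.
    """
    path = Path(path)
    raw = tomllib.loads(path.read_text(encoding="utf-8"))
    _reject_unknown(
        raw, {"experiment", "pig", "vna", "ventilator", "ranges", "subsystems"}, "top level"
    )

    exp = raw.get("experiment", {})
    _reject_unknown(exp, _EXPERIMENT_KEYS, "experiment")

    pig_raw = dict(raw.get("pig", {}))
    _reject_unknown(pig_raw, set(_PIG_KEYS) | set(_PIG_TABLE_KEYS), "pig")
    pig_kwargs = {_PIG_KEYS[k]: v for k, v in pig_raw.items() if k in _PIG_KEYS}
    defaults_pig = PigParams()
    for key, attr in _PIG_TABLE_KEYS.items():
        if key in pig_raw:
            pig_kwargs[attr] = _merge_mapping(
                getattr(defaults_pig, attr), pig_raw[key], f"pig.{key}"
            )
    if "weight" in pig_kwargs and "blood_volume" not in pig_kwargs:
        pig_kwargs["blood_volume"] = 65.0 * pig_kwargs["weight"]  # 65 ml/kg
    pig = PigParams(**pig_kwargs)

    vna_raw = raw.get("vna", {})
    _reject_unknown(vna_raw, _VNA_KEYS, "vna")
    vna = VnaConfig(**{_VNA_KEYS[k]: v for k, v in vna_raw.items()})

    vent_raw = raw.get("ventilator", {})
    _reject_unknown(vent_raw, _VENTILATOR_KEYS, "ventilator")
    ventilator = VentilatorSettings(
        tidal_volume=vent_raw.get("tidal_volume_ml_per_kg", 10.0) * pig.weight,
        peep=vent_raw.get("peep_cmh2o", 5.0),
        pip=vent_raw.get("pip_cmh2o", 20.0),
        fio2=vent_raw.get("fio2", 0.40),
    )

    subsystems_raw = raw.get("subsystems", {})
    _reject_unknown(subsystems_raw, {"glucose", "calcium", "abe", "etco2"}, "subsystems")
    etco2_target = subsystems_raw.get("etco2", {}).get("target", 40.0)
    controllers = dict(default_controller_configs(etco2_target=etco2_target))
    for name, table in subsystems_raw.items():
        _reject_unknown(table, _SUBSYSTEM_KEYS, f"subsystems.{name}")
        base = controllers[name]
        try:
            spec = FuzzySetSpec(
                lower_bound=table.get("lower_bound", base.spec.lower_bound),
                target=table.get("target", base.spec.target),
                upper_bound=table.get("upper_bound", base.spec.upper_bound),
                slope_scale=table.get("slope_scale", base.spec.slope_scale),
            )
        except ConfigurationError as err:
            raise ConfigurationError(f"[subsystems.{name}]: {err}") from err
        limits = table.get("limits", list(base.actuator_limits))
        controllers[name] = ControllerConfig(
            name=name,
            spec=spec,
            polarity=base.polarity,
            gain=table.get("gain", base.gain),
            actuator_limits=(float(limits[0]), float(limits[1])),
            update_interval=base.update_interval,
            averaging_window=base.averaging_window,
            restart_floor=table.get("restart_floor", base.restart_floor),
            initial_rate=table.get("initial_rate", base.initial_rate),
        )

    ranges_raw = raw.get("ranges", {})
    _reject_unknown(ranges_raw, _RANGE_KEYS, "ranges")
    ranges = default_ranges(etco2_target=etco2_target)
    for name, pair in ranges_raw.items():
        ranges[name] = (float(pair[0]), float(pair[1]))

    cycle = exp.get("position_cycle")
    if cycle is not None:
        cycle = tuple((str(p), float(h)) for p, h in cycle)
    else:
        cycle = DEFAULT_POSITION_CYCLE

    config = ExperimentConfig(
        duration_h=exp.get("duration_h", 72.0),
        bga_interval=int(exp.get("bga_interval_min", 120)),
        etco2_interval=int(exp.get("etco2_interval_min", 5)),
        position_cycle=cycle,
        controllers=controllers,
        vna=vna,
        pig=pig,
        ventilator=ventilator,
        ranges=ranges,
        bes_rate=exp.get("bes_rate_ml_h", pig.weight * 10.0 / 24.0),
        bes2_max_rate=exp.get("bes2_max_rate_ml_h", 600.0),
        controllers_enabled=exp.get("controllers_enabled", True),
        vna_enabled=exp.get("vna_enabled", True),
        seed=int(exp.get("seed", 1)),
    )
    config.validate()
    return config


CONFIG_TEMPLATE = """\
# homeoloop experiment configuration.
# Every key is optional; the values below are the defaults (a 52-kg virtual
# pig under the 72-h automated life-support protocol).  Unknown keys are
# rejected.

[experiment]
duration_h = 72.0
bga_interval_min = 120          # arterial blood-gas cadence
etco2_interval_min = 5          # respiratory-loop cadence and averaging window
seed = 1
bes2_max_rate_ml_h = 600.0      # bolus delivery rate of the BES2 pump
controllers_enabled = true
vna_enabled = true
position_cycle = [["left", 8.0], ["back", 4.0], ["right", 8.0], ["back", 4.0]]

[pig]
weight_kg = 52.0
blood_volume_ml = 3380.0        # 65 ml/kg
vco2_ml_min = 200.0
vco2_osc_amplitude = 0.08
vco2_osc_period_min = 360.0
dead_space_ml = 150.0
loss_rate_ml_min = 1.0          # urine + insensible losses
vna_baseline_mmhg = 5.0
vna_volume_gain_mmhg_per_ml = 0.02
vna_noise_sd_mmhg = 0.5
systolic_baseline_mmhg = 110.0

[pig.volume_distribution_l]
glucose = 12.0
calcium = 14.0
buffer_base = 15.0

[pig.production_mmol_min]       # negative buffer production = net acid load
glucose = 0.20
calcium = 0.010
buffer_base = -0.05

[pig.elimination_per_min]
glucose = 0.005
calcium = 0.002
buffer_base = 0.0

[pig.position_volume_stress_ml]
left = 0.0
back = 200.0                    # supine needs the most volume
right = 0.0

[pig.noise_sd]
glucose = 0.15
calcium = 0.02
abe = 0.30
etco2 = 1.0

[vna]
threshold_mmhg = 8.0
bolus_ml_per_kg = 2.0
hold_s = 20.0
observe_s = 60.0
interval_no_need_min = 60.0
interval_after_bolus_min = 15.0

[ventilator]
tidal_volume_ml_per_kg = 10.0
peep_cmh2o = 5.0
pip_cmh2o = 20.0
fio2 = 0.40

[ranges]
glucose = [3.9, 8.3]
calcium = [1.10, 1.40]
abe = [-3.0, 3.0]
etco2 = [35.0, 45.0]

[subsystems.glucose]
lower_bound = 3.5
target = 5.5
upper_bound = 7.5
slope_scale = 0.01              # mmol/L/min that grades fully as "rising"
gain = 0.5
limits = [0.0, 100.0]
initial_rate = 7.0
restart_floor = 2.0

[subsystems.calcium]
lower_bound = 1.05
target = 1.25
upper_bound = 1.45
slope_scale = 0.001
gain = 0.5
limits = [0.0, 100.0]
initial_rate = 2.0
restart_floor = 2.0

[subsystems.abe]
lower_bound = -6.0
target = 0.0
upper_bound = 6.0
slope_scale = 0.005
gain = 0.5
limits = [0.0, 100.0]
initial_rate = 0.0
restart_floor = 2.0

[subsystems.etco2]
target = 40.0                   # set 45.0 to reproduce the first subject's target
slope_scale = 0.5
gain = 0.1
limits = [6.0, 40.0]
initial_rate = 12.0
"""


def config_template() -> str:
    """The annotated default configuration, reloadable as-is."""
    return CONFIG_TEMPLATE
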