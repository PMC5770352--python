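"""A complete 72-h automated life-support run on the default virtual pig.

Runs the full closed loop (BGA-driven pumps every 2 h, respiratory rate
every 5 min, rule-scheduled volume maneuvers, 8/4/8/4-h repositioning) and
prints the in-range report — the system's homeostasis scorecard — plus the
volume-need-by-position summary.
"""

from homeoloop import ExperimentConfig, audit_commands, in_range_report, run_experiment

config = ExperimentConfig(seed=1)  # 72 h, 52-kg pig, etCO2 target 40 mmHg
log = run_experiment(config)
report = in_range_report(log, config.ranges)

print(f"log rows: {len(log)}   (measurements, commands, maneuvers, positions)")
print("\npercent of measurements inside the physiological range:")
for name, pct in report.percentages.items():
    n_in, n = report.counts[name]
    lo, hi = config.ranges[name]
    print(f"  {name:<8} {pct:6.1f} %  ({n_in}/{n} samples, range {lo}..{hi})")

print("\nmean VNA delta by position (higher = more volume need):")
for pos, (mean, n) in report.vna_by_position.items():
    print(f"  {pos:<6} {mean:6.2f} mmHg  over {n} maneuvers")
print(f"boluses given: {report.n_boluses} totalling {report.total_bolus_ml:.0f} ml")

violations = audit_commands(config, log)
print(f"\nunattributable actuator commands: {len(violations)} (closed-loop contract)")
print("Supine ('back') deltas exceed the lateral ones: the position itself")
print("creates volume need, which the maneuver detects and the rule treats.")
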