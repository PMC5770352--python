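"""The volume-need-analysis maneuver and decision rule, step by step.

Builds the default maneuver (PEEP to PIP for 20 s, watch systolic pressure
for 20 + 60 s), computes a delta from a small synthetic pressure trace,
and applies the threshold rule for a 52-kg subject.
"""

from homeoloop import VnaConfig, compute_vna_delta, decide_volume, maneuver_timeline

cfg = VnaConfig()  # threshold 8 mmHg, bolus 2 ml/kg, intervals 60 / 15 min
timeline = maneuver_timeline(cfg, pip=20.0, baseline_peep=5.0)
for cmd in timeline.commands:
    print(f"t={cmd.time_s:5.1f} s  PEEP := {cmd.peep:.0f} cmH2O")
print(f"systolic pressure monitored over t = {timeline.window[0]:.0f}..{timeline.window[1]:.0f} s")

trace = [(0.0, 110.0), (10.0, 104.0), (20.0, 95.0), (40.0, 103.0), (80.0, 110.0)]
delta = compute_vna_delta(trace)
print(f"\nmeasured VNA delta = max - min = {delta:.0f} mmHg")

for d in (delta, cfg.threshold - 1.0):
    result = decide_volume(d, cfg, weight=52.0)
    verdict = f"bolus {result.bolus_ml:.0f} ml" if result.bolus_ml else "no volume needed"
    print(f"delta {d:5.1f} mmHg -> {verdict}, next maneuver in {result.next_interval:.0f} min")

print("\nA large excursion means preload is sensitive to intrathoracic")
print("pressure, i.e. the circulation is underfilled: give 2 ml/kg, re-check soon.")
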