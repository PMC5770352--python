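"""One fuzzy control loop in isolation: from set points to pump commands.

Builds the glucose loop (critical lower bound 3.5, target 5.5, upper limit
7.5 mmol/L), then shows the proportional change factor and the resulting
G20 pump rate for a few measured states.
"""

from homeoloop import FuzzySetSpec, build_membership, evaluate, update_actuator

spec = FuzzySetSpec(lower_bound=3.5, target=5.5, upper_bound=7.5, slope_scale=0.01)
model = build_membership(spec)

print("glucose loop, current G20 rate 10 ml/h, gain 0.5, limits 0-100 ml/h")
print(f"{'glucose':>8} {'slope':>8} {'factor':>8} {'new rate':>9}")
for value, slope in [
    (5.5, 0.0),   # on target, steady
    (4.5, 0.0),   # low
    (3.5, 0.0),   # critically low
    (5.5, -0.02), # on target but falling fast
    (6.5, 0.0),   # high
    (7.5, 0.0),   # critically high
]:
    factor = evaluate(model, value, slope, polarity=+1)
    rate = update_actuator(10.0, factor, gain=0.5, limits=(0.0, 100.0), restart_floor=2.0)
    print(f"{value:8.1f} {slope:8.3f} {factor:8.3f} {rate:9.2f}")

print()
print("factor 0 leaves the pump alone; +1/-1 scale the rate by 1 +- gain.")
print("A falling slope raises the rate pre-emptively even at target glucose.")
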