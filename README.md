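# homeoloop

Fully automated, fuzzy-logic life support in silico: four physiological
closed loops plus rule-based fluid management, run against a seeded
virtual-pig simulator over a 72-hour intensive-care protocol.

## The problem

Keeping an anesthetized subject in homeostasis — every monitored variable
inside its physiological range — normally requires a caregiver to read
intermittent blood-gas analyses (BGA) and continuously adjust infusion
pumps and the ventilator. `homeoloop` implements a complete automated
replacement for that regulatory work and a virtual patient to exercise it
against, for people studying physiological closed-loop control: control
engineers prototyping ICU automation, and educators demonstrating
multi-loop interaction effects (e.g. fluid boluses diluting electrolytes).

## The controllers

Each of the four loops is a two-input fuzzy controller defined by three
user-set points on the controlled variable's axis — critical lower bound
*L*, target *T*, upper limit *U*. Five symmetric triangular membership
classes ("critically low" … "critically high") are centered at
*{L, (L+T)/2, T, (T+U)/2, U}*, with the same construction for the slope
axis on *[−2s, +2s]*. The 5×5 rule table maps antecedent offsets
*(i, j) ∈ {−2..+2}²* to the consequent at offset `clip(−(i+j), −2, +2)`;
product-t-norm inference with additive aggregation and weighted-mean
defuzzification over output centers *{−1, −½, 0, +½, +1}* yields a
proportional factor *f ∈ [−1, +1]*, applied multiplicatively to the
actuator: `rate ← clip(rate · (1 + g·f), min, max)`.

| loop | measured | actuator | cadence | polarity |
|---|---|---|---|---|
| glucose | BGA, mmol/L | 20% glucose pump (G20) | 2 h | +1 |
| ionized calcium | BGA, mmol/L | CaCl₂ pump | 2 h | +1 |
| base excess (ABE) | BGA, mmol/L | NaHCO₃ pump | 2 h | +1 |
| etCO₂ | 5-min mean, mmHg | respiratory rate | 5 min | −1 |

The fifth subsystem manages intravascular volume without fuzzy logic: a
**volume-need analysis (VNA)** maneuver raises PEEP to the peak
inspiratory pressure for 20 s and monitors systolic pressure for 20 + 60 s.
If the excursion Δ = max − min is below a threshold, no volume is needed
and the next maneuver runs in 60 min; if Δ ≥ threshold, a 2 ml/kg
crystalloid bolus is given and the maneuver repeats in 15 min.

The virtual pig closes the loop: one well-mixed distribution volume per
solute with zero-order production and first-order elimination,
distribution volumes that scale with blood volume (so solute-free fluid
dilutes every concentration), the alveolar-ventilation relation
etCO₂ = 0.863·V̇CO₂/V̇A for the respiratory loop, and a maneuver response
Δ = d₀ + k_v · (volume deficit) with a position-dependent volume target
(highest supine). See `docs/methods.md` for the model and all defaults.

## Worked example

```bash
python examples/closed_loop_run.py
```

```
percent of measurements inside the physiological range:
  glucose   100.0 %  (37/37 samples, range 3.9..8.3)
  calcium   100.0 %  (37/37 samples, range 1.1..1.4)
  abe       100.0 %  (37/37 samples, range -3.0..3.0)
  etco2     100.0 %  (864/864 samples, range 35.0..45.0)

mean VNA delta by position (higher = more volume need):
  back     8.07 mmHg  over 38 maneuvers
  left     6.28 mmHg  over 25 maneuvers
  right    5.95 mmHg  over 24 maneuvers
boluses given: 19 totalling 1976 ml

unattributable actuator commands: 0 (closed-loop contract)
```

The 72-h run performs 37 BGAs and 864 respiratory-rate adaptations; every
controlled variable stays inside its range, the supine ("back") position
shows systematically higher volume need than the lateral ones, and the
audit confirms no actuator was ever touched outside the control loops.
Other examples: `fuzzy_controller.py` (one loop's factor algebra),
`vna_rule.py` (the maneuver and threshold rule), `dilution_interaction.py`
(a fluid bolus transiently diluting calcium and glucose).

## Command line

```bash
homeoloop init                          # write an annotated default config
homeoloop run --config homeoloop.toml --seed 1 --out results/
homeoloop report --log results/log.csv  # recompute the report offline
```

Runs are fully deterministic: identical config and seed reproduce the log
CSV byte for byte.

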