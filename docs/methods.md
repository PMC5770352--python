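# Methods

## Scope and architecture

`homeoloop` couples five automated subsystems to a virtual-pig plant
through a discrete-event engine on a 1-minute grid:

1. three BGA-driven fuzzy loops (glucose → G20 pump, ionized calcium →
   CaCl₂ pump, arterial base excess → NaHCO₃ pump), stepped every 120 min;
2. one continuous fuzzy loop (etCO₂ → respiratory rate), stepped every
   5 min on the 5-min mean of per-minute capnometer readings;
3. the volume-need-analysis (VNA) maneuver plus threshold rule driving the
   BES2 crystalloid pump on its own rule-driven schedule.

Within a tick, simultaneous events execute in a fixed order — measure,
BGA controllers, etCO₂ controller, VNA, position change, physiology step —
which, with a single seeded generator for all noise, makes every run
replay bit-identically.

## The fuzzy controller

Membership construction. A loop is specified by the critical lower bound
*L*, target *T* and upper limit *U*. Value classes are triangular with
centers at *{L, (L+T)/2, T, (T+U)/2, U}*, feet at the adjacent centers,
and shouldered extremes (grade 1 beyond the outer centers): a Ruspini
partition, so grades always sum to 1 with at most two classes active.
Slope classes use the same construction on *[−2s, +2s]* about zero; the
scale *s* (units/min) is the slope magnitude that grades fully as
"rising"/"falling".

Inference. Antecedent offsets *(i, j) ∈ {−2..+2}²* map to the consequent
at offset `clip(−(i+j), −2, +2)`. Rule strength is the **product** of the
antecedent grades and duplicate consequents **add** (probabilistic /
Larsen inference); the factor is the strength-weighted mean of the output
centers {−1, −½, 0, +½, +1}, times the loop polarity. Because each axis's
grades sum to 1, total strength is exactly 1 and the factor is exactly 0
at (target, zero slope), saturates at ±1 at the critical bounds, is
antisymmetric for symmetric set points, and is monotone in each input.
Min/max (Mamdani) inference was rejected: normalizing max-aggregated min
strengths is *not* monotone in the measured value near class boundaries
when the slope grades are fractional, so a slightly higher glucose could
have commanded slightly more glucose infusion. For singleton consequents
the weighted mean coincides with the integrated Mamdani centroid of
clipped output triangles, which the test suite checks against an
independent 41-point numerical oracle at 1e−9.

Actuator mapping. The factor acts multiplicatively,
`rate ← clip(rate·(1 + g·f), min, max)`, reflecting its meaning as a
*relative* required change. Zero would be absorbing, so a restart floor
(2 ml/h for pumps) revives a stopped pump when the factor turns positive.
Defaults: pump gain 0.5 with limits 0–100 ml/h; respiratory gain 0.1 with
limits 6–40 breaths/min — the respiratory loop runs 24× more often, so
smaller per-step moves keep it overshoot-free.

Slope estimation is the two-point backward difference over the last two
samples (0 with a single sample). Slope scales per loop: glucose
0.01 mmol/L/min, calcium 0.001, ABE 0.005 — of the order of the largest
drifts the plant produces between BGAs, and above the noise floor of the
2-h finite difference. For etCO₂ the scale is 0.5 mmHg/min: consecutive
5-min means carry a noise-induced apparent slope of ≈0.13 mmHg/min SD,
and a scale below that lets noise saturate the slope axis and destabilize
the respiratory rate; 0.5 reserves the slope channel for sustained trends.

## The VNA subsystem

The maneuver sets PEEP to the PIP level for 20 s and monitors systolic
pressure for the hold plus 60 s. Δ = max − min of the trace. The rule is
a step function with one inclusive breakpoint: Δ < threshold → no volume,
next maneuver in 60 min; Δ ≥ threshold → bolus of 2 ml/kg, next maneuver
in 15 min. Defaults: threshold 8 mmHg (any positive value preserves the
rule's structure; 8 places the default pig's supine deltas above and its
replete lateral deltas below the breakpoint). Boluses are delivered by
the BES2 pump at its maximum configured rate (600 ml/h, i.e. ~10 min for
a 104-ml bolus), then the pump returns to zero. Only the two stated
re-check intervals are implemented.

## The virtual pig

State: blood volume *V* (ml), solute amounts (mmol) for glucose, calcium
and buffer base, etCO₂, systolic pressure, position, time.

Solutes. Each solute occupies one well-mixed distribution volume *V_d*
with zero-order production *P* and first-order elimination *k·A*:
`dA/dt = infused + P − k·A`. Concentration is `A / (V_d · V/V₀)`: the
distribution volume scales with relative blood volume, so solute-free
crystalloid (BES/BES2) dilutes every concentration. This single mechanism
produces both reported cross-subsystem interactions — a volume bolus
transiently lowers measured calcium, and a BES2 rate reduction
concentrates the co-infused glucose.

Defaults (52 kg, V₀ = 65 ml/kg = 3380 ml): glucose V_d 12 L, target
5.5 mmol/L, k = 0.005/min, endogenous production 0.20 mmol/min (an
anesthetized, fasted animal produces less than it consumes, so ~7 ml/h of
G20 is needed at steady state); calcium V_d 14 L at 1.25 mmol/L,
k = 0.002/min, production 0.01 mmol/min (≈2 ml/h CaCl₂ needed); buffer
base V_d 15 L with net metabolic acid production 0.05 mmol/min and no
first-order elimination, so ABE ≈ buffer-base concentration drifts acidotic
at ~0.2 mmol/L/h unless bicarbonate (1 mmol/ml) replaces it. The
bicarbonate pump starts at 0 ml/h: uncontrolled, ABE leaves the ±3 mmol/L
range in ≈15 h, which is what makes the open-loop-drift check meaningful —
the plant genuinely needs its controllers. Infusate solute contents:
G20 1.111 mmol/ml glucose, CaCl₂ 0.68 mmol/ml calcium, NaHCO₃ 1 mmol/ml.

Ventilation. `etCO₂ = 0.863 · V̇CO₂ / V̇A` with
`V̇A = RR · (VT − V_D)` in L/min; VT = 10 ml/kg = 520 ml, dead space
150 ml, V̇CO₂ = 200 ml/min modulated by a slow ±8% sinusoid (period 6 h)
so the respiratory loop has a disturbance to track. Ventilator pressures
are stored in cmH₂O (baseline PEEP 5, PIP 20).

Volume and the maneuver response. Losses (urine + insensible) are
1 ml/min against ~0.55 ml/min of steady infusions (baseline BES
10 ml/kg/day plus the controlled pumps), so a deficit accrues and the VNA
loop must intervene roughly every 3–4 h. The maneuver trace dips linearly
during the hold and recovers over the first half of the observation
phase; its amplitude is `Δ = d₀ + k_v · max(0, V_target(position) − V)`
plus Gaussian amplitude noise (SD 0.5 mmHg), with d₀ = 5 mmHg and
k_v = 0.02 mmHg/ml. The position-dependent target is V₀ laterally and
V₀ + 200 ml supine — supine preload is most sensitive to hypovolemia —
which reproduces the position pattern: supine deltas sit above the 8-mmHg
threshold and trigger bolus trains, lateral deltas mostly below.

Measurement noise (SD): glucose 0.15 mmol/L, calcium 0.02 mmol/L, ABE
0.3 mmol/L per BGA; etCO₂ 1.0 mmHg per per-minute reading (≈0.45 on the
5-min mean). Noise-free mode (SD 0) returns exact state values.

Integration is explicit Euler at 1-min steps — the dynamics' time
constants (hours) make the scheme's error negligible, and it is exact for
the pure-accumulation ablations used in the conservation tests (mass and
volume track infusion integrals to machine precision when production,
elimination and losses are zeroed).

## What the simulator does and does not show

The plant reproduces the *structure* of the control problem: intermittent
sparse measurements, noise, inter-loop dilution coupling,
position-dependent volume need and an etCO₂ disturbance. It omits
regulation the live animal performs itself (endocrine glucose control,
respiratory compensation of acid-base status), stress responses,
pharmacology, temperature and oxygenation. Passing the in-range targets
therefore demonstrates that the control laws are stable and correctly
wired under realistic cadences and noise — not that they would achieve
the same percentages in vivo, where unmodeled disturbances caused the
live experiments' occasional outliers. The in-vivo percentages are used
as lower bounds for exactly this reason.

## Problem sizes and numerical conventions

The canonical experiment is 72 h at 1-min resolution (4321 ticks, 37
BGAs, 864 respiratory decisions, 3 position cycles); calibration
quantities average 10 seeded runs, which completes in seconds. Degenerate
inputs: a single-point or constant pressure trace gives Δ = 0; an empty
trace, empty etCO₂ window or missing BGA analyte makes the affected
controller hold its last command (and marks the maneuver invalid rather
than guessing); non-finite measurements raise rather than propagate. Log
CSVs serialize numbers with 9 significant digits; serialization is
idempotent (write∘read∘write is byte-identical), which is the practical
round-trip guarantee double-precision values admit at fixed printed
precision. The etCO₂ target defaults to 40 mmHg; 45 mmHg (used for one
subject in the live experiments) is a one-line config change.
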