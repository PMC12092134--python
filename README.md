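# jumpsim

Forward-dynamics simulation of maximum-effort vertical jumping in planar
biped models, with the muscle-reconstruction schemes used for fossil
taxa and the performance metrics used to compare simulations against
force-plate experiments.

The package is aimed at comparative biomechanists who want a desk-scale,
fully scripted version of the classic predictive-simulation workflow:
build a sagittal-plane musculoskeletal model (rigid segments, hinge
joints with soft limits, unilateral spring-damper foot contacts,
Hill-type aggregated muscle-tendon actuators, midshaft bone-stress
constraints), search for the activation pattern that maximizes
centre-of-mass height with a genetic algorithm, and analyse the result
exactly as one would analyse a force-plate trial.

## The model in brief

Each aggregated actuator represents the pooled muscles performing one
action about a joint (e.g. "hip extensor"). Its maximum isometric force
is `F_max = sigma_max * PCSA` with `sigma_max = 0.3 N/mm^2`, where the
physiological cross-sectional area comes from one of three
reconstruction routes:

1. **measured** — PCSA = muscle volume / fibre length, with volume from
   dissection or imaging masses at muscle density 1056 kg/m^3;
2. **schematic** — a whole-limb budget (35% of body mass across both
   limbs) split 40/30/20/10% across hip/knee/ankle/TMTP and 65:35
   between extensors and flexors, shared equally within each pool;
3. **regression** — allometric prediction from bone or attachment areas,
   `10^(a + b log10 A)`.

Fibre length follows the range-of-motion convention `FL = max - min
path length` over the admissible joint range, and tendon slack length is
the reference-pose path length minus FL. The contractile element obeys
`F = a(t) F_max f_L(L) f_V(v)` with a quadratic force-length curve and
the Hill hyperbola `(1 - v/vmax) / (1 + v/(0.25 vmax))`, in series with
a linear tendon and parallel with a linear passive element.

Jump analysis uses the standard force/positional criteria: the jump
starts when vertical force departs from body weight by 5%, take-off is
the first instant force reaches zero, and a jump is a countermovement
(CMJ) rather than a squat jump (SJ) if the CoM first drops below its
starting height. Reported parameters: jump height (CoM apex),
concentric distance, take-off velocity, contact time, and the relative
net vertical impulse `RNVI = (integral of Fz over the concentric phase)/m
- g dt`, which equals the take-off velocity by impulse-momentum. The
ballistic prediction `z_apex = z_to + v_to^2 / (2 g)` ties the two views
together.

## Worked example

```python
import numpy as np
from jumpsim import (make_toy_jumper, simulate, analyze_trace,
                     ballistic_height)
from jumpsim.optimizer import GAConfig, run_ga

# predicted jump height from a published take-off state
print(round(ballistic_height(0.25, 3.3, 9.81), 2))   # 0.81

# optimize the toy jumper's activations from a deep crouch
toy = make_toy_jumper("deep_crouch")
cfg = GAConfig(population=50, generations=200, time_limit=0.55, sim_dt=1e-3)
res = run_ga(toy, cfg, seed=1, return_trajectory=True)
phases, metrics = analyze_trace(res.best_trajectory.to_frame(), toy.body_mass)
print(round(res.best_fitness, 3), metrics.strategy)  # 0.662 SJ
```

The toy starts with its centre of mass 0.295 m above the ground; the
optimized squat jump raises it to about 0.66 m, and the strategy label
confirms a monotone extension (no countermovement) from the deep crouch.
Starting the same model from full extension instead makes the optimizer
discover a countermovement: it has no extension stroke left, so it must
dip first.

Reference models with the published actuator tables are available as
`make_reference_human(variant, posture)` (9 actuators, 68.33 kg, Vmax
8.4 L/s) and `make_reference_guineafowl(variant)` (11 actuators incl. a
TMTP joint, 1.38 kg, Vmax 14 L/s), where `variant` selects the
reconstruction route (`model1`/`model2`/`model3`) or one of the
sensitivity variants (`fl_x2`, `fl_half`, `optimized_tendons`, ...).

A thin CLI mirrors the library: `jumpsim build`, `jumpsim fixtures`,
`jumpsim metrics`, `jumpsim optimize`.

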