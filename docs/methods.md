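# Methods

## Scope and model

jumpsim integrates planar (sagittal) musculoskeletal models forward in
time. A model is a tree of rigid segments joined by frictionless hinges;
the root segment carries a free planar base (x, z, pitch), so the
generalized coordinates are `q = [x, z, phi, theta_1..theta_n]` with one
anatomical angle per joint. All hinges permit flexion-extension only —
the planar restriction is justified for jumping, where the task is
essentially sagittal, and it collapses bilateral symmetry: each
left/right muscle pair becomes one actuator carrying the two-limb PCSA,
and the foot contacts are pooled per foot.

Equations of motion are assembled each step from point Jacobians
(`dP/dtheta_j = s_j * perp(P - hinge_j)` for every joint between the
root and the point's segment) and solved with a dense Cholesky
factorisation; the inner loop is numba-compiled. Angle conventions
follow the printed posture conventions of the experimental literature:
hip positive = flexion (0 = fully extended), knee flexion negative
(0 = straight), ankle positive = dorsiflexion.

## Muscle model

Each actuator is a Hill-type muscle-tendon unit:

* active CE force `a(t) * F_max * f_L(L_ce) * f_V(v_ce)`, with
  `F_max = sigma_max * PCSA`;
* `f_L` quadratic around the optimal length (equal to the reconstructed
  fibre length), reaching zero at `+/- fl_width * L_opt`
  (default width 0.5);
* `f_V` the Hill hyperbola with shape `a/F0 = 0.25`, zero at the maximum
  shortening velocity, and a plateau at 1 for lengthening (no eccentric
  force enhancement);
* a linear series element (tendon) reaching `F_max` at 4% strain;
* a linear parallel element engaging at 20% CE strain with stiffness
  `2 F_max` per unit strain (≈ half `F_max` of passive force at 45%
  stretch).

Activation is instantaneous — there is no excitation-activation ODE —
which deliberately reproduces the simplification of the workflow this
package models; its known consequence is that simulated jumps need no
force-development time and tend to use shorter contact phases than real
jumpers.

The CE length is a state variable: each step the series-elastic force is
computed from `L_se = L_mt - L_ce`, and the CE velocity is found by
inverting the force-velocity relation so CE+PE force balances the
tendon. Two numerical guards keep this well-posed: when the demanded
force ratio exceeds the eccentric plateau the CE yields at up to twice
the maximum shortening speed (a steep eccentric branch in place of the
non-invertible flat plateau), and the tendon stiffness is floored on 5%
of the optimal fibre length so near-zero slack lengths cannot produce an
unintegrable spring. Work bookkeeping defines the CE force as
`F_se - F_pe`, which makes CE + SE + PE work sum to the muscle-tendon
work identically.

Muscle paths are polylines of via points with at most one circular wrap
per actuator, placed on a joint hinge where a constant-sign moment arm
must be guaranteed across a large range. The wrap is a frictionless
pulley with tangent-arc-tangent geometry; its length gradient uses the
envelope property (the arc contributes no first-order term). A cable
whose tangent construction sweeps more than pi radians is treated as
lifted off: legitimate hinge wraps in these models stay below ~2.7 rad
at the deepest flexion, while a cable forced onto the wrong side of its
cylinder would sweep >4 rad. Wrap sides are chosen automatically so that
extensors lengthen with flexion and flexors with extension.

## Contacts, joint limits, bone stress

Ground contact points are unilateral spring-dampers
(`Fz = max(0, k*pen - c*v_z)`, no adhesion) with smoothed Coulomb
friction bounded by `mu * Fz` (`tanh` of slip speed, mu = 1). The
published workflow's contact constants are not public, so stiffness and
damping are per-model configuration: reference human 1.2e5 N/m and
1.2e3 N s/m per point, guineafowl 8e3 and 60, toy 2e4 and 150 — chosen
to give millimetre-scale static penetration and ~0.2-0.3 damping ratio.

Joint limits are soft: inside the admissible range they are inactive;
outside, a spring-damper torque pulls back. The damping coefficient is
capped each step at the explicit-integration stability bound for that
coordinate's instantaneous inertia, which keeps light distal segments
stable at coarse step sizes.

Midshaft bone stress is recovered by a backward Newton-Euler pass
(joint reactions transported to the section) and evaluated as
`|F_axial|/A + |M| c / I`; the transported proximal reaction ignores the
mass of the segment sliver between joint and midshaft, an approximation
consistent with the constraint's role as a safety cut-off. Solutions
exceeding the 300 MPa failure stress abort with a flag and are discarded
by the optimizer with a `-inf` sentinel. Besides its anatomical
motivation, this constraint is what prevents the optimizer from
exploiting violently unphysical limb-whipping solutions.

## Integration

Fixed-step semi-implicit (symplectic) Euler, default `dt = 1e-4 s`;
classical RK4 is available where high accuracy is wanted (conservative
energy drift < 1e-6, exact ballistic flight). Stiff contacts are why
steps are fixed and small. Trajectories record CoM position/velocity,
ground reaction forces, per-actuator forces and work components, bone
stresses and energies at a configurable output rate. Simulations also
stop early (optionally) once the model is airborne, past its apex and
above its starting height — nothing after that can change the maximum
CoM height used as fitness.

## Reconstruction schemes

* `pcsa_from_mass`: PCSA = (mass/density in mm^3) / FL, density
  1056 kg/m^3; exact inverse of `mass_from_pcsa`.
* `fibre_length_rom`: FL is the actuator's path-length excursion over
  the admissible range of its action joints, scanned on a 1-degree grid
  (all combinations for multi-joint actuators).
* `tendon_length_from_reference`: TL = reference-pose path length - FL,
  clamped at zero.
* `apply_fibre_tuning`: FL scales by the factor, PCSA inversely (volume
  conserved), and the tendon absorbs the length change.
* `partition_masses_schematic`: the whole-limb budget (35% body mass,
  both limbs) splits 40/30/20/10 across hip/knee/ankle/TMTP, 65:35
  extensor:flexor, equally within each (joint, action) pool. A
  biarticular actuator takes its share from every pool it belongs to
  (`sum-of-joint-shares`, which conserves the budget exactly); the
  alternative `equal-within-action` policy down-weights each pooled take
  by the actuator's number of actions. Models lacking a joint either
  drop that share (default) or renormalize.
* `joint_extensor_totals`: per-joint extensor sums count a biarticular
  extensor at every joint it extends; the grand extensor total counts
  each actuator once. Percentages are rounded half away from zero to
  integers, matching the reference table formatting.

## Optimization

The controller genome holds, per actuator, six piecewise-constant
activation phases (durations normalized to the time limit, levels in
[0, 1]); left/right activations are implicitly symmetrized and in phase.
Optional tendon genes scale designated actuators' slack lengths within
+/-10%. The GA is generational: tournament selection (size 2), uniform
crossover (rate 0.7), Gaussian mutation (rate 0.15, sd 0.15 of the gene
range) clipped to bounds, elitism 1 — so the best-of-generation history
is monotone. Fitness is the maximum CoM height within the time limit;
discarded (bone-stress or divergent) solutions rank below every finite
fitness, with ties broken deterministically by population index. All
randomness flows from one integer seed; replicate and sweep seeds are
spawned from `SeedSequence([base, stream, replicate])`.

The time limit matters: given more time than a jump needs, the search
happily fills the surplus (e.g. with bounce sequences), which can reduce
single-jump quality — hence `time_limit_sweep` runs replicated GAs
across a grid of limits and flags the first limit whose best comes
within tolerance of the overall maximum.

## The synthetic-data module

`synth_trace` builds force/CoM traces from piecewise-sinusoidal force
profiles whose double integral (and hence every jump metric) is known in
closed form: quiet standing, an optional unweighting dip (countermovement
only, 30% of body weight), a push hump scaled to the target take-off
velocity, a smooth release, ballistic flight. Because take-off is
operationally "force first reaches epsilon" (default 0.5 N — float GRF
never reaches exact zero), the take-off-state ground truths are
evaluated at the analytic epsilon-crossing; sampling is 20 kHz so the
sub-sample residual stays well below the 1e-3 recovery target. Gaussian
force noise is seeded and optional. What these traces do **not** emulate:
marker-based kinematics, force-plate drift and filtering artefacts,
multi-axis forces, or inter-trial variability of real subjects — so
metric-recovery tests validate the analysis code, not its field
robustness.

The reference human (68.33 kg, 9 actuators, Vmax 8.4 L/s) and
guineafowl (1.38 kg, 11 actuators incl. TMTP, Vmax 14 L/s) models carry
the published architecture tables (shipped as
`data/actuator_tables.tsv`) on a primitive-geometry skeleton. Segment
proportions, joint limits, muscle via points and contact parameters are
documented package estimates: the published models derive them from
MRI/CT scans that are out of scope here, so simulated jump heights of
these fixtures are structurally comparable but not quantitatively
matched to the published performance values. Postures use the printed
joint angles; the base (trunk) pitch is set so the distal foot segment
starts flat, which for this angle convention equals the summed joint
angles. The guineafowl's unpublished starting pose is a documented
estimate under the hip-horizontal convention (crouched: hip 75, knee
-80, ankle 40, TMTP -35 degrees; deeper crouch: 95/-100/55/-30).

## The toy jumper

The optimization experiments use a deliberately small 4-segment,
3-joint, 6-actuator jumper (10 kg, ~1 m): three uniarticular extensors
strong enough to jump, three weaker antagonist flexors that give the
optimizer authority over a countermovement, wide feet, and femur/tibia
stress sections. Its design encodes the postural contrast of interest:

* the deep-crouch pose sits at the flexion limits — there is no room to
  descend, so optimal solutions extend monotonically (squat jumps);
* the full-extension pose sits at the extension limits (including a
  plantarflexion range that ends at the neutral foot) — there is no
  extension stroke left, so any jump must transiently flex first
  (countermovement).

Toy-specific parameters: compliant tendons (12% strain at `F_max`) and
wide force-length curves (width 0.85) keep the toy integrable and
force-productive across its whole crouch at the coarse `dt = 1e-3 s`
used for optimization studies; tendons are referenced at a mid-range
pose so fibres pass through optimum mid-extension from either posture.
The replicated study in the test suite runs GA populations of 50 for
200 generations, 10 seeds per condition, with time limits 0.9 s
(full extension) and 0.55 s (deep crouch) — sizes chosen so the full
study runs at desk scale.

## Numerical choices and degenerate inputs

* `sigma_max` 0.3 N/mm^2 (the conventional vertebrate value),
  configurable per actuator.
* Divergence guard: non-finite state, |q| > 50 (m or rad) or
  |qdot| > 500 aborts with a flag.
* CE length clamped at 0.01 mm; zero-excursion actuators in the RoM
  method warn and receive a configurable floor fibre length.
* Percent rounding: half away from zero.
* Take-off epsilon 0.5 N; CMJ depth threshold 5 mm (separates
  countermovement from numerical jitter); take-off velocity by central
  finite difference one sample around take-off. On traces whose force
  reaches zero transiently mid-dip (possible in vigorous simulated
  countermovements), the take-off used is the start of the zero-force
  interval leading to the CoM apex, judged on a 5 ms moving average so
  isolated noisy flight samples cannot pose as ground contact; on
  experimental-shaped traces this is identical to "first zero".

## Known limitations

* No eccentric force enhancement and no activation dynamics: jumps
  underuse stretch-shortening mechanisms and develop force unrealistically
  fast.
* The bone-stress recovery is a beam-theory screen, not a stress
  analysis.
* Reference-model geometry is schematic; their absolute simulated
  performance should not be compared quantitatively against published
  subject data.
* The wrap model handles one cylinder per actuator and releases beyond a
  pi sweep; extreme postures outside the fitted joint ranges may produce
  discontinuous moment arms.
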