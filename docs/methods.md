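# Methods

`exoassist` simulates one gait cycle of an adult wearing a powered knee
exoskeleton and asks how four assistance strategies redistribute load
between the user's knee muscles, the tibiofemoral joint, and the straps
that couple the device to the leg. This note documents the model, its
assumptions, the numerical choices, and what the synthetic data can and
cannot show.

## The human-device model

The body is a planar (sagittal) linked-segment chain: a lumped HAT
(head-arms-trunk) segment over two thigh-shank-foot legs. Segment masses,
lengths, centres of mass and radii of gyration are scaled from body mass
and stature with standard cadaver-based fraction tables
(`config.SEGMENT_TABLE`); the reference subject is 66 kg and 1.75 m. The
hip translates at the trial's mean walking speed at constant height; all
joint motion comes from the prescribed hip/knee/ankle angle trajectories,
with the left leg running the same channels half a cycle out of phase.

The exoskeleton consists of a thigh shell (default 1.2 kg) and a shank
shell (0.8 kg) joined by an actuated hinge at the knee with reflected rotor
inertia 0.005 kg m^2 and passive viscous damping 0.1 N m s/rad. For rigid
-body dynamics the shell masses are merged into their host segments
(parallel-axis composition); for interaction-force analysis the shells are
isolated as free bodies coupled to the leg through sixteen strap contact
nodes. Device hardware masses are not published for the physical prototype
the model emulates, so these are plausible configurable defaults.

Only the ten knee-crossing muscles are modelled: flexors SAR, BFL, ST, SM,
GRA, GAS and extensors VL, VM, VI, RF. Moment arms are low-order
polynomials in the joint angle (extensors ~+0.04 m, hamstrings ~-0.03 m,
gastrocnemius ~-0.02 m at the knee), with hip arms for the biarticular
hamstrings/RF/SAR/GRA and an ankle arm for GAS. Maximum isometric forces
are order-of-magnitude physiological values (vasti 2000-3000 N, GAS
1500 N, GRA 100 N). Because the published source model's geometry is not
printed anywhere reusable, only *orderings* of muscle outcomes across
assistance modes are meaningful, never absolute magnitudes.

## Synthetic gait

Joint-angle trajectories are fixed truncated Fourier series (6 harmonics)
fit once to normative sagittal way-points: knee flexion stays non-negative,
with a small stance flexion wave and a ~60 deg swing peak near 70% of the
cycle; hip flexion runs +30 deg at contact to -10 deg in late stance;
ankle dorsiflexion peaks ~+10 deg in terminal stance with a ~-20 deg
push-off excursion. Two presets: normal walking at 1.22 m/s (cycle 1.10 s)
and fast walking at 1.49 m/s (cycle 1.00 s, amplitudes scaled by 1.10).
Stance occupies the first 60% of the cycle.

The frontal-plane knee abduction moment, which the planar model cannot
produce itself, is an exogenous template: a smooth positive double hump
spanning stance (peak 20 N m, zero value and slope at both stance
boundaries, zero in swing). The default peak keeps both tibiofemoral
compartments compressive with a mild medial bias.

The generator is deterministic; the seed only feeds an optional smooth
perturbation (`noise`, default 0) for robustness experiments. Channels are
evaluated at frame phases, so refining the time grid never changes values
at shared phases.

What the synthetic data does *not* emulate: measured marker kinematics,
vertical pelvis excursion, double-support force-plate transitions,
inter-subject variability, and any 3D motion. Passing tests therefore
demonstrate internal mechanical consistency and the direction of
controller effects, not agreement with any particular experimental gait
dataset.

## Ground-reaction prediction

Ground reactions are predicted, not measured, using 25 contact nodes under
each foot (a 5 x 5 grid along the sole), each carrying a vertical
artificial actuator and an antagonistic antero-posterior pair under a
Coulomb cone (mu = 0.8). At each frame, nodes of stance-phase feet within
4 cm of the lowest foot point (and below a 3 m/s speed gate) are active.
The weakly penalized node activations must reproduce the whole-body Newton
equation exactly and the sagittal angular-momentum balance up to a heavily
penalized slack; swing feet carry zero force. In the sagittal plane the
five medio-laterally stacked nodes of a column are co-located, so the
quadratic objective splits a column's load equally among them; the
implementation solves per column and divides, which is exact and cheaper.

## Inverse dynamics and torque bookkeeping

Net joint torques come from a distal-up Newton-Euler recursion
(foot -> shank -> thigh) per leg, with the HAT closing the chain; the
whole-body force residual is reported per frame. Velocities and
accelerations are periodic central differences (the same operator
everywhere, O(dt^2)); at the default 101 frames/cycle the knee-torque
discretization error against closed forms is ~1e-3 N m.

Sign conventions: knee extension, hip flexion and ankle dorsiflexion
positive. The net knee torque is the *total* the muscle+device system must
produce. The device's share is the controller torque plus the passive
hinge damping `c * theta_k_dot` (charged to the device by default;
configurable), and the user's required physiological torque is
`tau_physio = tau_net - tau_device`. This identity is exact by
construction and asserted in the tests.

## Assistive controllers

* **NA** - no assistance; the device is dead weight (its mass, rotor
  inertia and passive damping stay in the model).
* **RA** - rotational actuator, `u_r = -K (theta - theta_ref)` with
  pseudo-stiffness K (reference value 4 N m/rad) about the fully extended
  knee; active in both phases.
* **SPM** - simple pendulum: during swing the shank-foot-lower-device is a
  pendulum about the knee, `u_s = I_c1 theta_k'' + m_c1 g l_c1
  sin(theta_k)`; during stance the shank-device is an inverted pendulum
  about the ankle, `u_s = I_s theta_a'' - T_a + m_c2 g l_s sin(theta_a)`,
  with T_a the same-leg ankle torque from inverse dynamics at the current
  frame. The emitted torque is `a_phase * u_s`; reference assistance
  levels a = 0.23 (stance) / 0.78 (swing).
* **DPM** - damped pendulum: adds `+b_phase * theta_dot` inside the
  pendulum torque (knee rate in swing, shank-inclination rate in stance);
  reference values a = 0.33, b = 12.6 (normal) / 18.4 (fast) in stance and
  a = 0.78, b = 0.34 (normal) / 0.1 (fast) in swing.

The stance pendulum coordinate `theta_a` is operationalized as the shank
inclination from vertical (the inverted-pendulum angle); the composite
constants I_c1, m_c1, l_c1, I_s, m_c2, l_s come from parallel-axis
composition with the ankle in the neutral position. Controller equations
are written in their pendulum (flexion-positive) coordinates; the single
documented mapping to the package convention is `tau_device = -u`. Phase
switching happens at the stance boundary with no smoothing; the
discontinuity magnitude is computed and reported
(`AssistiveTorqueSeries.stance_swing_discontinuity`), and an optional
cosine blending flag exists but defaults to off.

## Muscle recruitment and interaction forces

Per frame, a strictly convex quadratic program allocates forces by
minimizing the weighted sum of squared activations: muscles at weight 1,
foot/strap artificial actuators at 1e-3 (they are load paths, not
physiological effort), the knee reserve at 1e3 (it only exposes demand the
muscles cannot meet and stays < 1 N m in all default runs), and the
hip/ankle reserves at weight 1 - these two act as ideal torque sources
standing in for the hip/ankle musculature that is outside this model's
muscle set, so that biarticular coupling does not distort the knee
recruitment. Equality rows balance the hip/knee/ankle torques of the
instrumented leg, with the knee row driven by `tau_physio`.

The strap interaction is resolved as the free-body balance of the two
shells: 2 rings x 4 nodes per shell (anterior/posterior nodes carry
sagittal load; medial/lateral nodes exist but are unloaded in the planar
model), each node a conditional contact element transmitting compression
plus Coulomb-bounded tangential force (mu = 0.5, strength 2000 N) only
while inside its activation window. The hinge pin force is eliminated
algebraically, leaving the combined force balance and one moment balance
per shell; commanded torque with no active nodes raises an explicit
"assistance cannot be transmitted" error.

The QP engine solves the closed-form equality KKT system with a primal
active-set loop (exact for these small diagonal-Hessian problems) and
falls back to SLSQP/trust-constr; equality residuals are accepted at 1e-6
relative, and solver-tolerance dust on the friction cone is projected back
onto it. Solutions are checked against a brute-force activation-grid
oracle in the tests.

## Knee contact loads

Total tibiofemoral compression is the axial (along-shank) intersegmental
reaction plus each knee-crossing muscle's force times its axial fraction
(a documented per-muscle cosine-like factor, ~1 for vasti and
hamstrings). The medial/lateral split solves the frontal-plane moment and
force balance with condyle moment arms `r = 0.25 * knee width` (0.10 m) on
each side; a tensile compartment is clamped to zero (lift-off flag) with
the sum preserved. Loads are reported in N and % body weight
(body mass x g, device excluded).

## Sensitivity search

Controller parameters are tuned by exhaustive grid search minimizing the
summed flexor+extensor muscle impulse (optionally restricted to stance or
swing), with ties broken toward smaller parameter values. Default grids:
K in {0..10} N m/rad, a in {0, 0.05, ..., 1}, b in {0, 0.1, 0.34, 1, 5,
12.6, 18.4, 25} N m s/rad. The controller-independent pipeline stages are
computed once per trial and shared across grid points. On the default
synthetic trials the search returns interior optima (K = 7 N m/rad,
a_swing = 0.6 at normal speed), of the same order as the reference values
for this class of device; exact agreement is not expected because the
underlying musculoskeletal model and motion data differ.

## Numerical choices and problem sizes

Default trials use 101 frames/cycle; all pipeline results in the tests and
the acceptance script use this size, with toy-chain oracles at 121-801
frames and discretization-convergence checks up to 6401. Tolerances:
equality residuals 1e-6 relative; the statics and contact-split checks
hold to 1e-6-1e-9 absolute; finite-difference-vs-closed-form torque
agreement is O(dt^2) and bottoms out near 4e-8 N m (second-difference
round-off), which is why exact 1e-8-level oracle comparisons are run with
analytically supplied kinematics or equilibrium trajectories.

## Known limitations

* Planar model: no 3D joint moments (the knee abduction moment is an
  exogenous template), no medio-lateral ground reaction, no patellar
  mechanism or ligaments.
* The hip rides at constant height, so vertical whole-body dynamics are
  milder than in measured gait; predicted GRFs lack the characteristic
  double-hump shape.
* Contralateral muscles are not recruited (no output depends on them);
  hip/ankle demands of the instrumented leg are partly carried by ideal
  reserve actuators.
* Strap modelling ignores strap tension, soft tissue and surface
  compliance; interaction-force *trends* across modes are meaningful, not
  magnitudes.
* Single synthetic subject; no statistical comparison across subjects.
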