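# Methods

## Scope and model

`liftsim` analyses two-handed, bilaterally symmetric lifting and lowering
in the sagittal plane. The skeleton is a planar tree rooted at the pelvis
with nine generalized coordinates — the planar pelvis pose plus six
revolute joints (lumbar/L5S1, shoulder, elbow, hip, knee, ankle) — in which
left and right limbs are merged into single chains with doubled inertial
properties. For a symmetric two-handed task all out-of-plane components
vanish by construction, so the reduction loses no information about the
quantities of interest; it is *not* a model of asymmetric lifting (see
Limitations). Segment masses, lengths, centres of mass and gyration radii
come from standard proportional anthropometric tables parameterized by body
mass and stature (defaults 75.16 kg, 1.74 m); the mass fractions sum to
one, so total model mass equals body mass exactly. All table values are
serialized with the model (`PlanarModel.to_json`) for reproducibility.

The pelvis is a free base: inverse dynamics reports, besides the six joint
torques, the residual force (2 components) and moment left over at the
ground–pelvis interface. These residuals are the package's measure of
dynamic consistency; the compliance check compares their vertical
component's peak and RMS against 5% of the net external vertical force
(|GRF_y + ΣEHF_y|), the conventional recommendation for trustworthy
simulations.

### Muscles and actuators

Each muscle-driven joint (lumbar, hip, knee) carries an extensor/flexor
pair of lumped Hill-type actuators; the arm joints and ankle are driven by
ideal reserve torque actuators (there is no muscle wrapping worth modeling
there for this task). Muscles are rigid-tendon with straight-line
origin–insertion paths; the hip extensor carries one fixed via point on the
pelvis (an ischial deflection) because a straight line loses its extension
moment arm in deep hip flexion. Moment arms are tendon-excursion arms,
`r = -dL/dq`, evaluated by central differencing of the path length; this
guarantees virtual-work consistency between the torque constraint in static
optimization and the line-of-action forces used in joint reaction analysis.

Force–length is a Gaussian in normalized fiber length with width 0.45;
force–velocity is a rectangular-hyperbola Hill relation (shape 0.25, capped
at 1.4 eccentric); `v_max = 10 l_opt / s`. `l_opt` is the path length in
the neutral upright posture times a per-muscle factor chosen so the
operating range over the study's postures stays centred on the
force–length curve (the factors, attachment offsets and maximum isometric
forces are declared defaults in `default_muscles`, sized so that the study
conditions — boxes up to ~25 kg — remain inside activation bounds).

### Pipeline stages

* **Inverse kinematics** — per-frame weighted least squares of model marker
  positions against observations, solved by batched damped Gauss–Newton
  with a finite-difference Jacobian, seeded in closed form from marker-pair
  directions (exact for noise-free joint-centre markers). Frames with RMS
  marker error above 5 cm are flagged.
* **Inverse dynamics** — leaf-to-root Newton–Euler over the planar tree.
  Segment kinematics (COM accelerations, angular accelerations) come from
  second-order central differences of forward-kinematics quantities;
  endpoint frames use one-sided second-order stencils. Coordinates fit to
  already low-pass-filtered markers are *not* filtered again: double
  filtering of the kinematics against singly filtered force records is
  itself a dynamic-inconsistency source worth ~10 N of spurious residual.
* **Static optimization** — per frame, minimize `Σ a_m² + w_res Σ
  (τ_k/τ_opt,k)²` subject to torque equilibrium at each joint and `0 ≤ a_m
  ≤ 1`. Under the rigid-tendon assumption the muscle torque capacity is a
  frame constant, so each frame is a tiny convex QP solved by a direct KKT
  factorization with an active-set loop on the bounds (visited-set guard
  against cycling). Infeasibility (torque beyond saturated capacity, or an
  equality system that forces an activation out of bounds) raises an error
  naming the frame and joint. `w_res = 1` with torque-optimal
  normalization, configurable.
* **Joint reaction analysis** — the L5S1 reaction is reported as the force
  on the superior body: the superior stack (torso, arms, hands, plus any
  attached load mass) is balanced under gravity, inertia, external hand
  loads and the pulls of the muscles crossing the joint. A bottom-up
  variant through the legs (including the ground reaction but excluding the
  residual actuators) differs from the top-down computation by exactly the
  trial's residual wrench, which the tests use as a two-sided oracle.

### Hand-load approaches

* **APP 1** applies the preprocessed handle load-cell wrench at its centre
  of pressure, and runs over the whole cycle.
* **APP 2** adds half the box mass to each hand (the merged hand body
  receives the full box mass as a point mass at the third metacarpal,
  composed by the parallel-axis theorem) and reconstructs the per-hand
  force as `-(m_box/2)(a_hand - g)` with hand acceleration from
  second-order ("quadratic") finite differences of the metacarpal
  displacement. No hand moment is reconstructed — an added point mass has
  no independent moment channel; this is a documented error source in the
  boundary quartiles.
* **APP 3** welds a half-box rigid body (half mass, half-box planar
  inertia) to each hand at the metacarpal. The attachment offset of the
  half-box COM in the hand frame is calibrated once per trial against the
  corner-marker box pose at the midpoint of the first handling phase,
  mirroring a CAD-matched weld. The per-hand estimate is the weld reaction
  from Newton–Euler on the half-box (force and moment). In the planar
  symmetric reduction the two half-boxes move identically, so the
  inter-half constraint is satisfied implicitly.

APP 2/3 are defined only while the load is gripped, so their muscle-level
stages run per detected handling phase; outputs hold NaN elsewhere.

## Synthetic data generator

The generator emulates the instrumented-box experiment the analysis is
designed for: a paced transfer of a 15 kg box (0.40 × 0.30 × 0.30 m,
handles 0.15 m above the centre) between a 0.33 m shelf and a 0.78 m table
at 10 cycles/min, 20-repetition capable, with markers at 100 Hz and force
records at 1000 Hz.

Construction order:

1. **Box trajectory** — minimum-jerk point-to-point moves (C²-continuous,
   zero end velocity/acceleration) between dwells on the two surfaces, the
   box held level. Each half-cycle is one move (default one third of the
   cycle, i.e. 2 s) plus a dwell; 1 s quiet lead-in/lead-out brackets the
   trial.
2. **Posture** — the whole-body chain (ankle-rooted; foot flat) tracks the
   handle point exactly (≤ 1e-9 m) via nullspace-regularized inverse
   kinematics: the task-space Newton step is complemented by a weighted
   pull toward a crouch-to-upright reference scheduled on handle height.
   The forearm's pull toward vertical is weighted ~6× the proximal chain:
   a loaded forearm hangs plumb in real lifting, and this keeps the hand
   frame nearly rotation-free so the APP 3 weld rides realistically. Warm
   starting makes the solution continuous (no branch flips); unreachable
   targets raise an error with the frame index.
3. **Hand loads** — during each move the hands carry a fraction `s(t)` of
   the box's inertial-plus-gravity wrench, with `s` ramping 0→1 over
   `grip_ramp_duration` (default 0.3 s) after the move starts and 1→0
   before it ends (cubic smoothstep); the support surface carries the rest
   at the box bottom. Load transfer therefore overlaps the start and end of
   the box's motion — the physical picture of a lift-off that begins while
   the box still touches the shelf — which places the ramps *inside* the
   detected handling phase, where real grip transitions live. True grip
   on/off times are the move start/end. The hand couple balances the box's
   rotational equation, and the handle records are re-expressed in the
   box-fixed frame exactly as a handle-mounted transducer would report
   them.
4. **Ground reaction** — whatever force the whole-human momentum balance
   requires, with the centre of pressure enforcing the angular-momentum
   balance about the lab origin. Both balances close to < 1e-6 N (observed
   ~1e-13) at every frame before noise, so the generated trial is
   dynamically consistent by construction and identical seeds give
   bit-identical bundles.
5. **Markers** — forward-kinematics anatomical markers (nine, at joint
   centres and segment ends) plus the eight box corners; optional i.i.d.
   Gaussian noise per axis per frame (`marker_noise_sd`, default 0).

What the generator does **not** emulate: soft-tissue artifact, force-plate
and load-cell noise, torso twist or any out-of-plane motion, inter-cycle
variability of a human operator (cycles are identical up to marker noise),
and grip-force transition shapes other than the smoothstep (the true shape
of human load transfer is unknown; the ramp duration is a parameter to
sweep, not an estimate of reality). Passing tests therefore demonstrate
correctness of the analysis chain and the *structural* consequences of the
hand-load simplifications — error localization at phase boundaries, the
overestimation direction, residual blow-up — not quantitative agreement
with any particular laboratory recording.

## Key parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| box mass | 15 | kg | below the usual industrial lifting limit |
| shelf / table height | 0.33 / 0.78 | m | study conditions |
| cycle rate | 10 | cycles/min | paced execution |
| move fraction | 1/3 of cycle | – | 2 s moves + 1 s dwells at default pace |
| grip ramp | 0.3 | s | ≈15% of a phase; swept 0.1–0.5 in the studies |
| marker noise SD | 0 (generator), 0.3 mm in noisy studies | m | optical capture scale |
| filter | 4th-order Butterworth, 10 Hz, zero-phase | – | standard biomechanics conditioning |
| spike threshold | 10 × MAD of 2nd difference, 5 mm floor | – | floor keeps smooth motion over long plateaus unflagged |
| grip detector prominence | 25% of trajectory range | – | separates surface plateaus |
| SO reserve weight | 1 (torque-optimal normalized) | – | reserves cheap where no muscles exist, muscles preferred elsewhere |
| residual normalization | 100 N / 100 N·m | – | reporting only |

## Numerical choices

* Zero-phase (forward–backward) filtering: no lag, so peak times are not
  shifted; the effective attenuation is the squared single-pass Butterworth
  response (and, exactly, the analytic response at the bilinear prewarped
  frequencies — the tests verify both).
* Grip events: `find_peaks` (prominence ≥ 25% of range) locates the
  surface plateaus; each departure/arrival is refined to the last/first
  sample within a noise-scaled tolerance of the plateau level. Plateau
  levels are medians of tight bands at the extremes, and the noise scale is
  a low quantile of |second difference| so motion curvature cannot inflate
  it. Noise-free events are recovered within one marker frame (±10 ms).
* Quartile windows on the 101-point grid are lower-closed: samples 25, 50,
  75% belong to the lower window, giving 26/25/25/25 samples. The
  windowing identity — whole-phase RMSE² equals the count-weighted mean of
  quartile RMSE² — holds exactly with these counts.
* Peak search splits the phase at 50%; each half's peak is its highest
  interior local maximum, ties to the earlier sample; a half without an
  interior maximum falls back (flagged) to its boundary maximum.
* Greenhouse–Geisser correction is applied unconditionally (no Mauchly
  gatekeeping): simpler and conservative. Degenerate inputs (identical
  conditions at machine precision) return F = 0, p = 1 via a round-off
  guard on the sums of squares.
* Near-zero-force COP: a handle load cell's centre of pressure is
  undefined as the force crosses zero; synthetic records pin it to the
  handle centre, and downstream code never divides by measured force.
* The L5S1 reaction sign convention is "force on the superior body";
  resultants are unaffected by this choice.

## Problem sizes

The test suite and acceptance script run single-cycle (8 s) to five-cycle
(32 s) trials at 100/1000 Hz, three seeds per condition in sweeps, and five
repetitions for the repeated-measures statistics — sizes at which every
qualitative effect of interest (boundary-error localization and growth,
overestimation direction, compliance pattern, ANOVA significance) is
already stable and the full suite completes in well under a minute.

## Known limitations

* Planar symmetric reduction only; asymmetric lifting, torso twist and
  frontal-plane effects are out of scope by design.
* Two lumped muscles per joint reproduce torque balance and the muscle
  -compression contribution to JRFs, but absolute JRF magnitudes are not
  comparable to many-muscle 3D models (our peaks are ~2.3–2.7 kN where
  rich lumbar models report ~5–7 kN for similar tasks); conclusions are
  drawn from *differences between approaches*, which share the model.
* Rigid tendon, no activation dynamics, no wrapping surfaces.
* The grip-ramp shape is an assumption; only its duration is studied.
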