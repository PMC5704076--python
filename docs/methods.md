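# Model and methods

`legsearch` simulates the searching movements of a stick-insect front leg
restricted to a vertical plane, the brief obstacle perturbations used to
probe them, and the staged motor recovery that follows.  This note documents
the model equations, the calibrated defaults and why they are what they are,
the numerical choices, and the known limitations.

## The reduced one-leg model

Only two joints move: the coxa–trochanter (CTr) joint, whose elevation angle
β is set by the antagonistic levator/depressor muscle pair, and the
femur–tibia (FTi) joint, whose interior angle γ (180° = stretched, flexion
downward) is set by the extensor/flexor pair.  The tarsus direction α is
purely kinematic: with femur length L_f and tibia length L_t (defaults 13
and 12 mm),

    α = atan2(L_f sin β + L_t sin(β − (180° − γ)),
              L_f cos β + L_t cos(β − (180° − γ))).

Each muscle pair is driven by a local network: a two-cell central pattern
generator (CPG), four inhibitory premotor interneurons (INs) that relay the
CPG rhythm to the motoneurons by phasic inhibition, and four motoneurons
(one fast and one slow per muscle).  The levator–depressor (LD) network has
CPG cells C3/C4, INs 7–10 and MN(LF/LS/DF/DS); the extensor–flexor (EF)
network has C5/C6, INs 13–16 and MN(EF/ES/FF/FS).  MNs receive a uniform
central drive `g_MN`; the premotor INs can be silenced individually by
central conductances `g_d7..g_d10`, `g_d13..g_d16` (all zero by default).

The two networks are coupled only through two-valued sensory conductances:
the γ signal gates `g_γ` onto IN12, which excites both LD CPG cells, and
the β signal gates `g_β` onto IN18, which excites the extensor-side cell
C6.  Each gate is `g_high` when its angle is at or above its threshold
(β_thr, γ_thr) and `g_low` below, with no hysteresis, evaluated on the
instantaneous angle every integration step (an optional first-order sensory
filter defaults to off).  Ties go high.  Whether the β gate should share the
γ gate's polarity is not constrained by the biology we model; it is a config
switch (`beta_high_above`, default true).

### Cell and unit dynamics

CPG cells are two-variable relaxation oscillators with a persistent inward
(sodium-like) current, instantaneous activation m∞(V) and slow inactivation
h:

    C_m dV/dt = −g_L (V−E_L) − g_NaP m∞(V) h (V−E_Na)
                − g_inh (V−E_inh) − g_exc (V−E_exc)
    dh/dt    = (h∞(V) − h) / τ_h(V),   τ_h = τ_h_max / cosh((V−θ_h)/2k_h)

with m∞, h∞ logistic (θ_m = −37 mV, k_m = 6; θ_h = −48 mV, k_h = 6),
C_m = 60 pF, g_L = 2.8 nS, E_L = −68 mV, g_NaP = 10 nS.  Cell output (also
the presynaptic release variable of the mutual inhibition) is a sigmoid of
V (half-point −43 mV, slope 2 mV).  INs and MNs are first-order units,
τ du/dt = σ(I) − u, with a sharp logistic σ (half 0.55, slope 0.07), τ = 10
ms (INs) and 5 ms (MNs); their activity is the unit output in [0, 1].

Operating points (the load-bearing calibration choices):

* **LD CPG is conditional.**  C3/C4 have no direct central drive
  (`g_app3 = g_app4 = 0`); they oscillate only while IN12 is driven by a
  high γ gate (weight 0.5).  A low γ gate therefore suspends the LD rhythm;
  all four LD MNs are then disinhibited and the co-contracted muscles pull β
  to ≈ 17.5°, just above the highest femur threshold (16°) — which is
  exactly what re-arms the β gate and lets the rhythm restart.  This is also
  why only a narrow band of high β thresholds can sustain the rhythm in the
  switching regime.
* **EF is an asymmetric pair.**  C5 (flexor side, `g_app5 = 0.3`) sits in
  its burst-capable range; C6 (extensor side, `g_app6 = 0.6`) dominates
  whenever the β gate is high (weight 2.6 pins its voltage independently of
  h).  When β drops below β_thr the gate releases C6, C5 fires one flexion
  burst (duration set by its own τ_h = 550 ms), and C6 — whose h recovered
  during the burst — retakes.  C5's de-inactivation is slowed 2.5× relative
  to its inactivation, so the burst is a one-shot per release.  The LD pair
  uses τ_h_max = 2400 ms, giving a free period of ≈ 1.14 s.

### Muscles and joints

Muscle activation follows MN output with a first-order lag (fast pools
25–40 ms, slow pools 100–250 ms), capped by the pool's recruited fraction.
Joints are overdamped and massless: each muscle is a rotational spring with
stiffness `passive + activation × gain` pulling toward its own rest angle,
and the angular velocity is the net torque (unit damping, deg/ms).  γ is
clamped to (0°, 180°] with a dead stop at full stretch.  The passive terms
(5×10⁻⁵ deg/ms per deg each) are the residual rigidity that holds posture
when the MNs fall silent; with a typical posture they allow < 0.5° of drift
per 100 ms.  Rest angles and gains (levator 35°, depressor −8°, extensor
176°, flexor 82°; fast gains 1–9 ×10⁻³) were calibrated once so the
unperturbed rhythm spans β ∈ [−5.6°, 34.5°] and γ ∈ [122°, 174.5°], with α
covering ≈ [−33°, 31°].  The asymmetric levator/depressor gains place the
co-contraction equilibrium at ≈ 17.5° (see above); the extensor acts mainly
through its slow muscle, which makes the re-extension ramp quasi-linear and
shapes the state-diagram diagonals.

## The obstacle protocol

Contact is a kinematic freeze plus MN silencing, not a force: once armed
(default after 5 s, guaranteeing ≥ 3 established cycles), the first
*downward* crossing of the tarsus angle α through the obstacle position PO
freezes both joint angles and multiplies every MN input by zero for the
contact duration (default 100 ms).  From the removal instant:

* all slow MNs ramp linearly back to full drive within 200 ms,
* the single fast extensor and flexor MNs return immediately,
* the fast levator and depressor pools are gradually recruited: their
  recruited fraction ramps to 1 over `base_duration × rf(PO)` with
  `base_duration` = 500 ms and rf linearly interpolated in PO between
  configured endpoints, floored at 1.  Two interpolation sets exist — set A
  for low femur thresholds (β_thr ≤ 10°), set B for high ones — with
  separate levator and depressor lines; their endpoint values are
  placeholders read off a published figure without printed numbers, and are
  meant to be overridden.  Recruitment is continuous by default; a
  quantized mode recruits in `n_units` (default 5) discrete steps.

## Analysis layer

* **Cycles** are delimited at successive upward mean-crossings with a 5%
  hysteresis band; partial end cycles are dropped.
* **State diagrams** average the (β, γ) loop over whole cycles on a common
  phase grid; the post-removal loop uses the last three whole cycles (the
  recovered regime), while cessation/alternation are measured on the whole
  post segment.
* **Loop classification**: the cycle-averaged loop is normalized (translation
  and uniform scaling invariant), resampled by arc length, simplified by
  iterative vertex pruning with tolerance 5% of the bounding-box diagonal,
  and its *dominant* corners — turns of at least 45° — are counted; ≤ 3 is
  triangular, ≥ 4 quadrilateral.  Loops in which one (both) angle's range is
  below 2° are degenerate-line (quiescent).  The original distinction is
  made by eye; both the tolerance and the corner threshold are config knobs.
* **Cessation**: sliding-window (800 ms) peak-to-peak amplitude below 2° for
  at least 500 ms.  The window should be of the order of the oscillation
  period; the defaults suit the ≈ 1.1 s rhythm.
* **Alternating amplitudes**: peak heights above the trace mean on a lightly
  smoothed copy; flagged when the successive differences alternate in sign
  for ≥ 4 consecutive pairs with > 10% relative difference; fewer than six
  peaks leave the flag undetermined.

## What the model reproduces, and what it does not

With the frozen defaults the model shows: a tonic γ-gating regime at
γ_thr = 83° and a switching regime at 145°; triangular pre-contact state
diagrams in the tonic regime for β_thr ∈ {−4°, 4°} and quadrilateral ones in
the switching regime for all three β thresholds; post-removal γ cessation
(a stretched, bobbing leg) over wide contiguous PO bands at β_thr = −4°,
shorter bands at 4°, and none at 16°; and the staged recovery timings.

Known limitations, found and kept honest during calibration:

* At (γ_thr = 83°, β_thr = 16°) the pre-contact loop classifies
  quadrilateral, not triangular: during the long sub-threshold window the
  extensor-side cell's unaided high state decays with its inactivation
  variable, briefly disinhibiting the flexor and adding a second small γ dip
  (two extra loop corners).  Every attempted remedy broke other presets; the
  loop-shape geometry is knife-edged in this architecture.
* No alternating-amplitude γ oscillations arise anywhere in the scanned
  PO × preset space: the one-shot flexion burst is strictly 1:1-locked to
  the femur gate and the post-removal amplitude recovers within a cycle, so
  the model has no period-2 regime at these parameters.
* The γ oscillation floor is ≈ 122° rather than the ≈ 85° seen in the
  animal; deeper flexion dips traded off against single-dip loop geometry.
* The angular ranges are narrower than experimental ones generally — a
  property shared with the modeling study this re-implements, which kept a
  single parameter set rather than re-fitting per behavior.

## Numerics and reproducibility

Fixed-step explicit RK4, default dt = 0.1 ms; gates and protocol multipliers
are evaluated once per step and held across the four stages.  Halving dt
changes the 10 s angle trajectories by well under 0.5°.  The integrator is a
numba-compiled kernel over a flat 40-dimensional state; a plain-numpy
reference implementation of the same equations lives in `network.py` and is
cross-checked against the kernel in the tests.  There is no randomness
anywhere in the core model: all states start from the resting point with a
fixed +1 mV offset on C3 (so the half-centers leave the symmetric state
deterministically), and identical configurations yield bit-identical
traces.  Seeds appear only in the synthetic fixture generator's optional
noise.  Default problem sizes — 10–12 s free runs and ≈ 15 s perturbation
runs at 1 ms recording — were chosen so a full preset sweep remains
interactive on a single CPU.
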