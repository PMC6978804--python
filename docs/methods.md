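# Methods

`ratloco` is a forward-dynamics simulator of rat overground locomotion in
the sagittal plane.  This note documents the model, the parameters that
matter, the choices made where the literature leaves the design open, and
what the shipped tests do and do not establish.

## Skeletal model

Eleven rigid links: a single trunk link (head included), two links per
forelimb (brachium, antebrachium) and three per hindlimb (thigh, shank,
foot).  Left and right limbs are identical.  The 13 generalized
coordinates are trunk x, z, pitch plus ten joint angles (shoulder, elbow;
hip, knee, ankle).  Link masses, lengths and moments of inertia are
anatomical measurements from adult (~125 g) Wistar rats; total body mass
is 125.2 g.

Joint angles are extensor-positive.  In the reference configuration —
every limb segment collinear and perpendicular to the trunk — the shoulder
is at 120°, the elbow at 180°, the hip at 120°, and the knee and ankle at
180°.  Anatomical bends: the elbow apex points caudally, the knee
cranially, the ankle caudally.  For the forelimb, shoulder *flexion*
retracts the limb (this is the propulsive direction, mirroring hip
*extension* in the hindlimb); the sign conventions were cross-checked
against the speed-feedback gains, which must increase the drive of
propulsive muscles when the model is slow.

Equations of motion are assembled per link from Jacobian-transpose
projections (exactly the Lagrangian equations; every link orientation is
affine in the coordinates, so the angular Jacobians are constant and the
only velocity-product terms are translational centripetal terms).  The
implementation is verified in the test suite against a finite-difference
Lagrangian oracle coded independently (worst relative error ~1e-9 over
random states) and by passive-swing energy conservation (relative drift
~1e-10 over 1 s).  Integration is fourth-order Runge-Kutta at dt = 0.02 ms.

Two elements are added beyond the minimal linkage, both configurable and
both necessary for the linkage to stand at all:

* **Joint limits** (`JointLimitParams`): one-sided viscoelastic stops at
  anatomical bounds, most importantly elbow/knee/ankle ≤ 180° (a limb
  segment cannot hyperextend past straight).  Without them the
  near-straight stance forelimb hyperextends within one step and folds
  backward.  A lower shoulder stop (58.9°) similarly bounds retraction.
* **Passive joint viscosity** (`SkeletonParams.joint_viscosity`,
  1e-4 N m s/rad): a small velocity-dependent passive tissue term; the
  tension equation's passive component is length-dependent only.

## Ground contact

Each limb tip interacts with the ground through a viscoelastic element.
Vertical: one-sided spring-damper (3800 N/m, 16 N s/m), clamped
nonnegative.  Horizontal: a spring-damper to an anchor planted at
touchdown (70 N/m, 25 N s/m), capped by a Coulomb cone |Fx| ≤ μFz with
μ = 0.435; the anchor slips along the ground when the cone saturates.

The horizontal pair is deliberately damper-dominated — a viscous skid
rather than a rigid tether.  The forelimb is only 35 mm long while a
stance sweep at 0.2 m/s covers ~33 mm, so a rigidly anchored forepaw
geometrically traps the limb and pitches the model onto its nose; loaded
paws must be allowed to creep.  This is also why a friction cone is
needed: a grazing swing-paw touch must not be tethered at full stiffness.

## Muscles

26 Hill-type muscles (6 per forelimb, 7 per hindlimb) with constant moment
arms.  Tension: F = F_max (a F^l(l̄) F^v(v̄) + F^p(l̄)).  Muscle length is
linear in the spanned joint angles: 1 % of maximum length per 2° of joint
excursion (BIC shoulder 4.5°, GA ankle 1.5°, GA knee 4.5°), calibrated so
uniarticular muscles sit at 85 % and biarticular at 75 % of maximum length
in the neutral posture (shoulder 60°, elbow 85°, hip 70°, knee 90°, ankle
100°).  Contraction velocity is normalized by 1.8 maximum lengths per
second.  Activation follows a first-order ODE with 11 ms activation and
18 ms deactivation time constants; it stays in [0, 1] for commands in
[0, 1].

Curve family (constants in `MuscleCurveParams`, all swappable):

* F^l: Gaussian in (l̄ − 1) with width 0.564;
* F^v: Hill hyperbola with shape factor 0.3 (force zero at v̄ = 1),
  eccentric branch capped at 1.5;
* F^p: exponential above optimum length, 0.2·(e^{12(l̄−1)} − 1) — reaching
  F_max near l̄ ≈ 1.15, i.e. a realistically stiff parallel-elastic
  component.  The passive field of stretched antagonists is a major part
  of what holds the stance posture.

The degrees-per-percent kinematic map and the tabulated moment arms are
both taken at face value even though they are not mutually
energy-consistent; fidelity to the source tables was preferred over
mechanical elegance.  For the energetics, the absolute maximum length
l_max of each muscle is recovered from moment-arm/excursion consistency
(l_max = MA · deg_per_pct · (π/180)/0.01, averaged over spanned joints),
which is needed only to convert normalized velocity to m/s; absolute CoT
values inherit this calibration, orderings and curve shapes do not.

## Motor control

**Rhythm generation.** Four phase oscillators (one per limb), left/right
coupled toward antiphase (gain K1 = 20/s) and fore/hind coupled toward an
ipsilateral offset Δ (K2 = 10/s): Δ = π/2 defines walking, Δ = π trotting;
the hind oscillator leads.  From random phases the network locks to the
commanded pattern within a few cycles (tested to 0.01 rad).

**Pattern formation.** Four rectangular pulses per limb cycle (onsets
0, 0.40π, 1.24π, 1.42π; ends 0.33π, 0.89π, 1.42π, 1.71π), identical for
all limbs; pulses 1–2 span the extension (stance) phase [0, 2πβ), pulses
3–4 the flexion phase.  Muscle commands are weighted sums of the pulses
(weights in `params.WEIGHTS_HAT`).

**Regulators.** Stance-gated proportional(-derivative) feedback:
BR/TRIL hold the shoulder height, VL/TA/SO the hip height, and
SSP/SPD/IP/GM/TA/SO the forward speed, with the tabulated gains and
references (0.033 m, 0.054 m, 0.4 m/s).  Commands are computed on the
sensed state — stance gating included — and delivered after a fixed 15 ms
delay (an exact integer number of control steps; zeros while the delay
line fills).  Stance means actual tip contact (vertical force > 0), not
oscillator phase.

**Speed modulation.** The extension fraction β rescales the pulse
schedule (extension pulses stretch, flexion pulses keep their duration;
the stance/swing boundary sits at 2πβ for every β), scales the extension
weights by (1−β)/(1−β̂), and shifts the regulator references linearly in
β − β̂ (slopes 0.01 m, 0.01 m, −4.7 m/s).  The cycle duration is
T = T_fl/(1 − β) with T_fl = 0.10 s fixed and β̂ = 0.62.  β changes ramp
quasi-statically at ≤ 0.005 per cycle within [0.56, 0.68].

Commands are zero-order-held over each integration step and clamped to
[0, 1] after summing the feedforward and feedback parts.  Three shadow
copies of the activation ODE are driven by the individual command
components (synergy, height, speed); they do not feed back on the
dynamics and exist only for the cost-of-transport decomposition, which is
approximate because the activation ODE is nonlinear in its command.
Component commands are clamped to [0, 1] individually (activations are
defined for nonnegative drives).

## Initial condition

Runs start close to the gait's limit cycle: oscillators at the
phase-locked configuration (global phase 1.08π, which puts three limbs in
stance), trunk posed at the β-scaled reference heights (pitch −13°,
hindquarters high), stance limbs placed by analytic two-link inverse
kinematics at sweep positions matching their stance progress, swing limbs
at the crouched neutral posture, activations preloaded to the current
synergy commands, and the trunk moving at 0.15 m/s.  Starting at the
regulator target 0.4 m/s instead makes the trunk overrun the forelimb
workspace in the first stance and fall — consistent with the model's
realized speed being half the desired one.  The first five cycles are
discarded as transient in all measurements.

## Calibration of unstated constants

The source tables fix the skeleton, the muscles' strengths and moment
arms, and every motor-control constant.  They do not fix the contact
constants, the Hill-curve constants, joint limits, the trunk CoM
position, or the initial condition.  With naive choices (soft passive
muscle, rigidly anchored contact, midpoint CoM, no joint stops) the model
falls in under 0.3 s by a chain of three mechanisms: elbow
hyperextension, rigid tethering of grazing swing paws, and a forelimb
protraction deficit (the shoulder muscles cannot protract 50° within a
76 ms swing, so landings drift caudally until the nose drops).

These free constants were therefore calibrated — by randomized search
over only the unstated parameters — until the nominal walk (β = 0.62,
Δ = π/2) is steady; the calibrated defaults are frozen in `params.py`.
Trotting and the β sweeps use the same defaults with no further tuning.
With them the model walks indefinitely at 0.183 m/s and trots at
0.216 m/s, and the sweeps span 0.14–0.26 m/s (walk) and 0.17–0.25 m/s
(trot).

## Known limitations

* The realized footfall pattern lags the commanded one: swing paws land
  late, so the walking ipsilateral footfall lag is near 0.5 cycle rather
  than the commanded 0.25 (the oscillators themselves lock at Δ exactly).
* In the sliding-contact regime, stride length keeps growing as β (and
  T) shrink, so the walk's fast end (0.26 m/s at β = 0.56) overshoots and
  the cost of transport decreases monotonically with speed over the
  configured sweep instead of turning up at high speed; the
  synergy-pulse component nevertheless dominates the CoT everywhere, and
  the CoT minimum and stride maximum coincide.  A stiffer, anchored
  contact would restore the geometric stride cap but destabilizes the
  model.
* Trot is faster than walk at four of the five sweep points; at β = 0.56
  walking is 4 % faster.
* No spine, neck, wrist or toes; no lateral dynamics; no afferent phase
  resetting of the rhythm generator.  Falls are detected as |pitch| > 60°
  or a girdle height below 30 % of its reference.

## What a green test establishes

The analytic tests pin every printed equation and constant (lengths,
tensions, torques, activation time constants, pulse timings, scaling
laws, feedback gains, the 15 ms delay).  The dynamics tests establish
that the rigid-body equations are exactly those of the stated linkage.
The simulation tests establish that the calibrated stated world produces
steady walking and trotting with the reported nominal speed scale and
speed modulation by β — not that the unprinted constants equal the
original ones; where the original's qualitative results could not be
reproduced in any stable regime we found, the corresponding tests are
left failing rather than weakened (see the repository's test suite:
criterion 6 sweep fast endpoint, criterion 6 trot-faster-everywhere,
criterion 7 U-shape).
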