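# Methods

`neckdyn` simulates the sagittal-plane dynamic response of the head–neck
complex (skull C0, vertebrae C1–C7) when the first thoracic vertebra (T1)
is driven vertically by an ejection-seat acceleration pulse, and quantifies
how Hill-type active muscle forces change the segmental flexion–extension
pattern. This note records the model, its assumptions, the numerical
choices, and what the packaged synthetic anatomy does and does not
represent.

## Mechanical model

**Bodies and joints.** The column is a serial chain of nine rigid bodies:
the skull and seven cervical vertebrae, free in the sagittal plane
(x anterior, y up, θ counterclockwise; 3 DOF each, 24 DOF total), above a
T1 base whose vertical motion is prescribed kinematically (infinite-mass
constraint). Adjacent bodies are coupled by bushing joints — translational
springs/dampers between coincident attachment points, resolved in the lower
body's frame (shear = local x, axial = local y), plus rotational
springs/dampers on the relative angle, with optionally different stiffness
in flexion and extension. A bushing lumps everything a motion segment's
disc, ligaments and facets contribute; there are no algebraic constraints,
so the equations of motion are a plain ODE system. The translational
bushing force acts at the midpoint of the two displaced attachment points,
which keeps the action–reaction pair free of net moment even when the
stiffness is anisotropic or the damper is active.

**Muscles.** Each muscle bundle is a straight line between an origin and an
insertion site. Its tension is

    F = fmax · Na(t) · F_L(L) · F_v(V) + F_pe(L)

with `Na` the neural active state (zero during the reflex latency, here
80 ms, then a configurable ramp to a plateau), `F_L` a quadratic bell of
half-width 0.5·lo centred on the rest length, `F_v` a Hill hyperbola on the
concentric side (zero at the maximum shortening velocity `vmax`, curvature
constant 0.25) with a saturating eccentric branch (plateau 1.3, shape
constant 0.15), and `F_pe` an exponential parallel-elastic curve that is
slack below the rest length and reaches `fmax` at a relative stretch of 0.8
with shape constant 2.0. The parallel-elastic scale is 0 by default (the
tabulated value); the *passive* scenario sets it to 1 with `Na ≡ 0`. The
tabulated per-bundle parameters (19 bundles in 13 groups; lengths in mm,
velocities in mm/s, forces in kg·mm/s² = mN) are stored exactly as printed
and converted to SI only inside the dynamics layer. Each bundle stands for
a bilateral pair (`bilateral_factor = 2` applied to `fmax`);
physiological cross-sectional area is carried as metadata only. Muscle
velocity is the lengthening rate of the straight line (positive when
stretching), which is exactly the shortening-negative convention of the
force–velocity curve.

**Scenarios.** `none` removes all muscle elements; `passive` keeps all
bundles with zero neural drive and the parallel-elastic element enabled;
`active` applies the activation schedule with the tabulated (zero)
parallel-elastic scale. Because the parallel-elastic element is off in the
active scenario and `Na = 0` before the reflex time, the active and
no-muscle trajectories are *identical* for t < 80 ms — a property the test
suite checks to 10⁻⁹.

**Loading.** The base acceleration ramps at 125 G/s for 80 ms and holds
10 G for the remaining 70 ms of the 150 ms event (G = 9.81 m/s²,
configurable). Base velocity and position are the exact piecewise
polynomial integrals of this profile, evaluated in closed form at arbitrary
solver times; the base is locked in horizontal translation and rotation.
Gravity is off by default: the event is dominated by the 10 G pulse and the
model is not settled under 1 g beforehand.

## Synthetic anatomy

No reference geometry is available to this package, so `anatomy.py`
generates a surrogate. Its skeleton is deliberately simple:

* centroid spacings 19 mm through the sub-axial column and 22 mm in the
  C0–C2 region (total column ≈ 158 mm), a mild lordotic arc (4 mm apex),
  head mass 4.5 kg with rotational inertia 0.018 kg·m², vertebral masses
  0.25 kg with lumped rotational inertia 5·10⁻⁴ kg·m² (the vertebra plus
  the tissue ring it carries);
* joint pivots are placed by an explicit *arm rule*: pivot j sits
  `joint_arm_mm[j]` posterior of the mass line of everything it supports.
  Positive arms at the two upper joints (the head's centre of mass rides
  anterior of the occipital condyles) make vertical acceleration nod the
  head forward; small negative arms at the lower joints give the lower
  column an extension bias under axial compression. This is the planar
  stand-in for a lordotic column loaded axially and is what produces the
  early inverted-S curvature; as the head leans forward the mass line
  crosses the lower pivots and the whole column rolls into the late
  mirrored-C shape.
* muscle attachment sites are solved at assembly so every bundle's
  straight-line length equals its tabulated rest length *exactly*; the
  anterior/posterior offsets and slant directions of the lines were fitted
  (bounded least squares plus discrete slant search) so that the per-joint
  distribution of muscle moments matches a target profile — strong
  extension capacity at the upper joints, near agonist/antagonist balance
  at C4–C7. The fitted lines are moment-equivalent sagittal elements, not
  anatomical paths.

The generation seed drives only a small Gaussian jitter (σ = 0.25 mm) on
the muscle line offsets, emulating attachment scatter without perturbing
the solved lengths; the skeleton itself is seed-independent.

## Calibration

The surrogate's free parameters — eight per-joint rotational stiffness
scale factors (over a 1.5–3.0 N·m/rad baseline), the global damping ratio,
the upper pivot arms, and the activation plateau and rise time — are fitted
to a packaged set of kinematic landmarks (`neckdyn/data/landmarks.yaml`): the active-run upper-cervical (C0-relative-to-C2) flexion peak
of 8–9° at 95–105 ms, the end-of-event percent reductions (C1–C2 active vs
passive 43.2%, C5–C6 active vs passive 7%, C0–C1 active vs none 55%), and
the qualitative gates (inverted-S before 110 ms and mirrored-C at 150 ms in
every scenario, an inverted-U active history, end-peaking no-muscle and
passive histories). Every candidate is scored by running the three
scenario simulations, so the fit is on exactly the quantities the analysis
layer reports. `calibrate.py` exposes a deterministic bounded coordinate
descent over these knobs for re-calibration; the packaged values were
obtained with a damped Gauss–Newton fit of the same landmark loss and are
frozen in `neckdyn/data/calibrated.yaml`; the calibrated stiffness scales are large
(order 30–500) because the column must sit well above its 10 G
gravitational buckling margin to respond within the 150 ms event, while
the softest admissible upper joints set the size of the head nod.

The packaged calibrated schedule uses a short rise time (10 ms, against
the 20 ms library default) together with a light damping ratio (0.11): the
extensor brake engages quickly after the 80 ms reflex, and the lightly
damped upper-joint transient that follows — the axis vertebra snaps back
under the mid-level extensors while the head lags — carries the compound
C0-C2 angle through its 8-9 degree peak near 104 ms before the brake
settles it well below the peak by the end of the event.

## Numerics

Fixed-step classical Runge–Kutta (4th order), default dt = 0.01 ms
(15 000 steps per 150 ms run), state sampled every 0.5 ms. The step guard
(dt ≤ 0.02 ms) keeps the stiff penalty-bushing modes (axial ω ≈ 1.5·10³
s⁻¹) well inside the RK4 stability region. Halving dt changes end-of-event
rotations by < 0.5%, and a one-body reduction matches the closed-form
damped-oscillator step response to < 0.1%. Non-finite states abort with
the failure time; an optional energy ledger (kinetic + elastic − base work,
valid in the undamped isotropic test mode) guards against silent
instability. Angles are reported flexion-positive in degrees
(flexion = anterior rotation of the superior body, a negative
counterclockwise relative angle internally).

Curvature classification uses a ±0.1° neutral band: *inverted-S* requires
both upper segments flexed beyond it with at least one of C4–C5…C6–C7
extended beyond it; *mirrored-C* requires all seven segments flexed.
Percent reductions compare rotation magnitudes and are flagged undefined
when the reference magnitude is inside the neutral band. Peak analysis
takes the global maximum (earliest sample on ties) and flags an inverted-U
when the peak is interior and the final value is below 90% of it.

## What the surrogate does and does not show

The synthetic column reproduces the *kinematic pattern* of the reference
scenario — the ordering, timing and relative magnitudes of segmental
rotations and their response to passive and active musculature — after
calibration to the printed landmarks. It does not predict tissue loads:
there are no discs, ligaments or facets as separate structures, no
out-of-plane motion, no head-restraint contact, and the inertial and
stiffness values are surrogate choices, not subject measurements. Passive
muscle forces under the tabulated parallel-elastic parameters are small at
the strains this event produces, so the passive scenario tracks the
no-muscle scenario closely; conclusions about passive-muscle protection
should not be drawn from this surrogate. Results at other pulse shapes,
durations or postures require re-calibration.

## Problem sizes

The packaged study is desk-scale: three 150 ms scenario runs at
dt = 0.01 ms (45 000 solver steps, ≈ 1 minute total on one core). Tests
use dt = 0.02 ms and shortened events where only structure is being
checked.
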