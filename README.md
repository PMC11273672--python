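# neckdyn

Sagittal-plane multibody simulation of the pilot head–neck complex under
ejection-seat loading, with Hill-type active muscle mechanics.

During an emergency ejection the torso is accelerated vertically at around
10 G. The unconstrained head and cervical spine respond with a
characteristic sequence: the lower segments are driven into extension while
the head nods forward (an *inverted-S* curvature), then the whole column
rolls into flexion (a *mirrored-C*). Whether and how much active neck
muscle contraction protects the spine during this event is the question
this package quantifies.

`neckdyn` models the skull (C0) and cervical vertebrae C1–C7 as a planar
chain of rigid bodies over a kinematically driven T1 base, coupled by
visco-elastic bushing joints, with 13 neck muscle groups discretised into
19 straight-line bundles. Each bundle produces the classic Hill-type
contractile force

    F_CE(t) = F_max · N_a(t) · F_L(L) · F_v(V)

where `N_a(t)` is the neural active state (zero before an 80 ms reflex
delay, then ramping to a plateau), `F_L` the active force–length curve and
`F_v` the force–velocity curve, plus an exponential parallel-elastic term
that engages beyond the rest length. The T1 base follows the standard
ejection pulse: 125 G/s ramp for 80 ms, then 10 G held to 150 ms. Three
scenarios are compared — no muscles, passive muscles, active muscles — and
the post-processing reports segmental rotation histories,
inverted-S / mirrored-C curvature labels, peak (inverted-U) analysis of the
upper-cervical C0–C2 compound angle, and cross-scenario percent-reduction
tables.

Because no reference geometry ships with the package, the anatomy is a
*synthetic surrogate* generated by `neckdyn.anatomy` and calibrated
(`neckdyn.calibrate`) against published kinematic landmarks; see
`docs/methods.md` for the model, its assumptions, and exactly what the
surrogate does and does not represent.

## Worked example

```python
from neckdyn.config import default_run_config
from neckdyn.pipeline import run_pipeline

cfg = default_run_config(seed=1)          # packaged calibrated study
summary = run_pipeline(cfg, "results/run1")

active = summary["scenarios"]["active"]["series"]["C0-C2"]
print(round(active["peak_deg"], 2), round(active["peak_time_ms"], 1),
      active["inverted_u"])
```

prints the active-scenario upper-cervical peak, for example

```
8.41 104.5 True
```

i.e. the compound C0–C2 flexion under active muscles peaks at ~8.4° around
104 ms after ejection onset and then falls back — the inverted-U that
distinguishes the active response from the no-muscle and passive runs,
which keep flexing to the end of the event. `results/run1/` holds the
trajectory and rotation CSVs for all three scenarios, the curvature
timelines, the reduction table at 150 ms, and a `summary.json` sufficient
to re-run the study bit-identically.

The same study from the shell:

```
neckdyn reproduce --seed 1 --out results/run1
neckdyn simulate --scenario active --seed 1 --out results/active-only
neckdyn analyze --run-dir results/run1 --at 150
```

## Package layout

| module | contents |
| --- | --- |
| `neckdyn.muscle` | Hill-type bundle mechanics and the packaged muscle parameter table |
| `neckdyn.loading` | ejection pulse and its exact base-motion integrals |
| `neckdyn.anatomy` | synthetic rigid-body surrogate (bodies, bushings, muscle routing) |
| `neckdyn.dynamics` | planar multibody assembly and fixed-step RK4 integration |
| `neckdyn.analysis` | rotations, curvature classification, peaks, reduction tables |
| `neckdyn.calibrate` | landmark evaluation and coordinate-descent calibration |
| `neckdyn.config` / `neckdyn.pipeline` / `neckdyn.cli` | run configuration, end-to-end pipeline, command line |
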