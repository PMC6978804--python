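# ratloco

Forward-dynamics simulation of rat overground locomotion in the sagittal
plane, for researchers in computational neuromechanics who want a
self-contained quadruped model to study gait generation, speed modulation
and locomotor energetics.

## The model

* **Skeleton** — eleven rigid links (trunk with head, 2-link forelimbs,
  3-link hindlimbs; 13 DoF; 125.2 g total mass from anatomical
  measurements), Lagrangian dynamics integrated with RK4 at dt = 0.02 ms,
  viscoelastic tip–ground contact with a Coulomb friction cone.
* **Muscles** — 26 Hill-type muscles with constant moment arms:
  F = F_max (a·F^l(l̄)·F^v(v̄) + F^p(l̄)), lengths linear in joint angles
  (1 % of l_max per 2° of excursion; 85 %/75 % uni/biarticular at the
  neutral posture), first-order activation dynamics
  (τ_act = 11 ms, τ_deact = 18 ms).
* **Spinal CPG** — four coupled phase oscillators
  (φ̇ = 2π/T − K₁sin(φ − φ_contra − π) − K₂sin(φ − φ_ipsi ± Δ)) feeding
  four rectangular synergy pulses per limb cycle; muscle commands are
  weighted pulse sums.  The gait is set solely by the ipsilateral phase
  offset: Δ = π/2 walks, Δ = π trots.
* **Brainstem/cerebellar regulators** — stance-gated posture (shoulder and
  hip height) and speed feedback, delivered with a 15 ms sensorimotor
  delay.
* **Speed control** — the extension fraction β rescales pulse timing,
  extension-pulse amplitudes and regulator references at fixed flexion
  duration T_fl = 0.10 s (cycle T = T_fl/(1−β), nominal β̂ = 0.62).
* **Energetics** — per-cycle muscle work η₊ + ¼η₋, stride length D, cost
  of transport ε = W/D, decomposed into synergy / posture / speed
  components via shadow activation dynamics.

See `docs/methods.md` for assumptions, parameter provenance, the
calibration of constants the source tables leave open, and known
limitations.

## Worked example

```sh
ratloco simulate --duration 6 --out walk_run
```

prints, with the default (nominal walking) configuration:

```
status: ok
mean speed: 0.183 m/s over 10 cycles (T = 0.263 s)
CoT: 0.719 J/m (syn 0.374, height 0.057, speed 0.003)
wrote: walk_run/trajectory.csv, walk_run/events.csv, walk_run/energetics.csv, walk_run/config_resolved.yaml
```

The model walks steadily at 0.18 m/s with the commanded 0.263 s cycle;
the cost of transport is dominated by the feedforward synergy pulses,
with small posture- and speed-regulator contributions.  Switching
`--gait trot` changes only Δ and yields a faster gait (0.216 m/s) with
diagonal limb pairing; `ratloco sweep --gait walk` ramps β over
[0.56, 0.68] and writes the speed/CoT tables (speeds fall from ~0.26 to
~0.14 m/s as β grows).  The same functionality is available from Python:

```python
from ratloco import SimConfig, simulate, analyze
metrics = analyze(simulate(SimConfig(duration=6.0)))
print(metrics.mean_speed, metrics.cot)
```

## Acceptance script

`scripts/acceptance.py` recomputes the model's headline quantities from
scratch — activation rise/decay time constants fitted to the integrated
activation ODE, neutral-posture normalized muscle lengths, the nominal
walking speed, and the extreme steady speeds of the trot and walk β
sweeps — by running the simulator and writes them to a JSON report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
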