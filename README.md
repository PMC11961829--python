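# softmpm

Material point method (MPM) simulation of clampable, gel-like soft tissue —
the kind of viscoelastic–plastic material a surgeon grips and removes during
transforaminal endoscopic lumbar discectomy (the nucleus pulposus of the
intervertebral disc). The package is aimed at surgical-simulation and
soft-tissue biomechanics developers who need a real-time-style particle
solver whose material can stretch several times its length, creep, relax,
and tear, together with the impulse-based force signal a haptic device
would render.

## The model

**Solver.** A 2-D/3-D moving-least-squares MPM with APIC (affine
particle-in-cell) transfers on a regular grid with quadratic B-spline
weights ω. One frame runs: particle-to-grid (scatter mass
`m_i = Σ ω m_p` and momentum
`(mv)_i = Σ ω [m v + (m C − (4Δt/Δx²) V⁰ P Fᵀ)(x_i − x_p)]`),
grid boundary handling (`v_i = (mv)_i/m_i` plus a slip condition),
grid-to-particle (`ṽ_p = Σ ω v_i`, `C_p = (4/Δx²) Σ ω v_i (x_i−x_p)ᵀ`),
and a collision/update step. Collisions enter the deformation update
through the previous frame's nodal velocity increments:
`F ← (I + Δt (C + ΔC)) F` with `ΔC = (4/Δx²) Σ ω Δv_i (x_i−x_p)ᵀ`.

**Material.** Compressible Neo-Hookean with a multiplicative
elastic/plastic split `F = F_E F_P` in which plastic flow is purely
volumetric. Each frame the elastic volume ratio is relaxed toward the band
`[1−θ_C, 1+θ_S]`:

    J_E = J + k_c (1−θ_C − J)   below the band
    J_E = J                     inside
    J_E = J − k_s (J − 1 − θ_S) above

carried statefully across frames (the excess decays geometrically with
per-frame ratio `1−k_s`), and the Lamé coefficients harden with plastic
compaction: `μ(J_P) = μ₀ e^{ξ(1−J_P)}`. The first Piola–Kirchhoff stress is

    P = μ(J_P)(F_E − F_E^{−T}) + λ(J_P) log(J_E) F_E^{−T}.

Held strain therefore relaxes its stress, held load creeps, and large
stretch softens the material until it tears.

**Clamp.** The surgical clamp is two cubic collision boxes at the tool tip.
Closing the jaws captures particles: their clamp-frame coordinates are
frozen and replayed under the moving pose. The force sent to a feedback
device is the impulse-rate reaction `F = −Σ m_p (v_p − ṽ_p)/Δt`.

## Worked example

```python
import numpy as np
from softmpm import MaterialParams, SimConfig, SpecimenSpec, run_relaxation

cfg = SimConfig(domain_extent=(96, 32))          # 96x32 nodes, dx = 2.5 mm
spec = SpecimenSpec(extents=(0.05, 0.0125),      # 5 x 1.25 cm slab
                    particles_per_cell=4)
params = MaterialParams()                        # E = 10 kPa, theta_s = 0.1

curve = run_relaxation(spec, cfg, params, target_strain=0.2,
                       ramp_duration=0.1, hold_duration=0.2, seed=1)
h = curve.hold_start
print(f"held strain        : {curve.strain[h]:.4f}")
print(f"stress at hold     : {curve.stress[h]:.1f} Pa")
print(f"stress after 0.2 s : {curve.stress[-1]:.1f} Pa")
print(f"grip force at hold : {curve.force[h]:.2f} N/m")
```

prints

```
held strain        : 0.2043
stress at hold     : 1994.8 Pa
stress after 0.2 s : 1196.4 Pa
grip force at hold : 15.24 N/m
```

The slab is gripped at both ends, ramped to 20% elongation and held. The
held strain exceeds the extension limit θ_S = 0.1, so the elastic volume
excess bleeds into plastic flow frame by frame: the axial engineering
stress decays from ~2.0 kPa toward a plateau — stress relaxation — while
the strain stays exactly constant. A `run_creep` call shows the mirror
behaviour (strain growth at decelerating rate under constant load) and
`run_tear` pulls the specimen to complete failure through the four stages
elastic → plastic → tearing → broken, which `segment_stages` labels.

The same experiments are available from the shell:

```
softmpm run relax --out-dir out          # writes relax_curve.csv + manifest
softmpm run tear  --config my.toml --seed 3
softmpm clamp-demo --trajectory traj.csv # force log for a scripted clamp
softmpm make-specimen                    # particle cloud as CSV + VTK
```

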