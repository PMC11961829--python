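# Methods

## Model overview

`softmpm` simulates a soft, gel-like tissue specimen as a collection of
material points carrying mass, velocity, an affine velocity matrix `C`
(APIC), a deformation gradient `F`, and a scalar plastic volume ratio
`J_P`. A transient background grid with quadratic B-spline interpolation
(3-node stencil per axis) solves momentum each frame. The constitutive
model is compressible Neo-Hookean with a volumetric elastic/plastic split:
all plastic flow is a pure dilation, so the split is fully described by
how the total volume ratio `J = det F` is divided into `J_E · J_P`.

The elastic ratio is confined to `[1 − θ_C, 1 + θ_S]` by a per-frame
relaxation: when the candidate ratio `J / J_P` leaves the band, the excess
is reduced by the fraction `k_c` (compression side) or `k_s` (extension
side) and the removed volume change is ratcheted into `J_P`. Iterating at
a held total deformation gives an exact geometric decay of the elastic
excess with per-frame ratio `1 − k_s` — the closed form the relaxation
tests use as an oracle. The Lamé coefficients carry an exponential
hardening `μ(J_P) = μ₀ e^{ξ(1−J_P)}`: compaction stiffens, dilation
softens, and sustained stretch therefore weakens the material until it
fails.

The elastic gradient is reconstructed from the total one as
`F_E = (J_E/J)^{1/d} F`, which makes `det F_E = J_E` hold in any dimension;
a `scaling_mode="literal"` option keeps the linear prefactor `(J_E/J)`
instead for comparison. Two plasticity modes exist: `stateful` (default;
`J_P` persists across frames, producing relaxation and creep) and
`stateless` (the split is re-derived from the total `J` every frame and a
held strain holds its stress — retained because the comparison is the
clearest demonstration of why statefulness is needed).

## Frame loop

1. **Particle to grid.** The previous frame's nodal velocity-increment
   field (produced by collisions or prescribed motion) is gathered into an
   affine correction `ΔC`; `F` is advanced with `C + ΔC`; stress is
   evaluated; mass and momentum are scattered, the momentum with the APIC
   affine term using `C` (not `C + ΔC`) plus the MLS-MPM stress term
   `−(4Δt/Δx²) V⁰ P Fᵀ (x_i − x_p)`. The `4/Δx²` factors are the inverse
   inertia tensor of the quadratic B-spline and are not configurable.
2. **Grid interaction.** Nodal velocity is momentum over mass on active
   nodes (mass above `1e−12` of the mean particle mass). Within
   `bc_margin` cells of a domain face the inward velocity component is
   zeroed (slip; a sticky variant zeroes all components). Optional per-frame
   damping multiplies all nodal velocities by `1 − damping`.
3. **Grid to particle.** Velocities and `C` are gathered; particles
   flagged `FIXED` receive zero velocity (a per-particle Dirichlet
   constraint); a temporary position is advanced.
4. **Collide and update.** The clamp (or an experiment's position
   override) rewrites positions; velocities are recomputed from actual
   displacements; per-particle velocity increments are scattered back to
   the grid for the next frame's step 1; the output force is
   `−Σ m_p (v_p − ṽ_p)/Δt`.

Scatters run through `np.bincount` over flattened node indices on one
thread, so identical configurations and seeds reproduce trajectories
bit-for-bit.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `mu0` | 5000 Pa | shear Lamé coefficient (E = 10 kPa at ν = 0) |
| `lambda0` | 0 Pa | second Lamé coefficient |
| `xi` | 3 | plastic hardening/softening exponent |
| `theta_c`, `theta_s` | 0.05, 0.10 | elastic volume-ratio limits |
| `k_c`, `k_s` | 5e−4 | per-frame viscous flow fractions |
| `dx` | 2.5 mm | grid spacing |
| `dt` | 1e−4 s | frame length |
| density | 1000 kg/m³ | tissue density |

Three of these deserve justification, because the design space was
genuinely open (no material constants for this tissue model are
established) and the choices interact:

* **`lambda0 = 0` (zero Poisson ratio).** The plasticity and viscosity of
  this model act exclusively on the *volume* ratio. At ν = 0 a uniaxial
  stretch produces no lateral contraction, so `J = 1 + ε` exactly: the
  elastic limits `θ_C`, `θ_S` correspond directly to engineering strains
  and the viscous machinery engages at observable strain levels. At
  tissue-like ν ≈ 0.4 stretch is nearly isochoric — `J` barely moves, the
  volumetric flow never activates at moderate strain, and what flow occurs
  concentrates at the Poisson-mismatch stress singularity at rigid grip
  corners, tearing specimens at the grips. A compressible setting is also
  physically defensible for this tissue on creep time scales: the gel
  loses fluid under load, which is precisely the volumetric flow the model
  abstracts.
* **`k = 5e−4` per frame.** The viscosity constants are per-frame decay
  fractions, so the physical relaxation time is `dt/k = 0.2 s`. This sits
  well above the elastic wave transit time of the default specimen
  (≈ 25 ms) — the material is genuinely rate-dependent rather than
  rate-independent plastic, which is what stabilises it against instant
  strain localisation — and well below the run length, so relaxation and
  creep are visible within a run.
* **`xi = 3`.** Softening must be strong enough that a torn specimen's
  stress collapses toward zero, but weak enough that creep decelerates
  toward a steady state; at large `xi` the softening feeds back into the
  flow and creep accelerates tertiary-style instead.

## Specimen and experiments

The specimen generator samples a rectangular thin slab on a jittered
per-cell sublattice (`particles_per_cell` a perfect per-axis power; jitter
a fraction of the sub-spacing). Total mass equals density × slab volume
exactly by construction. A band at one axial end is designated *fixed*,
one at the other *loaded*; band membership is snapped to grid-cell
boundaries so no cell ever mixes driven and free particles.

In the characterization runs both bands are enforced as **grid-level
Dirichlet constraints**: the node columns covering a band are assigned the
prescribed velocity (zero, or the drive velocity) after the boundary
treatment, and the constraint impulse is recorded as the grip reaction
force. Grips are rig, not tissue: enforcing them on the grid keeps the
velocity field inside the grip rigid, so grip particles' deformation
gradients do not integrate fictitious interface stretch — overriding
particle positions directly was found to fracture the grip interface
spuriously. The particle-level `FIXED` status remains available and is
used outside the experiment protocol.

Observables: strain is the engineering elongation of the particle
bounding extent along the pull axis; stress is the mean axial first
Piola–Kirchhoff component over the specimen core (excluding both bands
plus a 5% skirt), i.e. engineering stress.

* **Tear** — the driven grip moves at 0.25 m/s for 0.8 s (final nominal
  strain ≈ 1.8 on the 11 cm default slab). The curve passes the four
  stages; the stage detector defines stage boundaries operationally:
  departure from the initial linear fit by >5% relative residual sustained
  over 5 samples (elastic → plastic), the global stress peak (plastic →
  tearing), and the first sample below 10% of the peak (tearing →
  broken).
* **Creep** — a constant engineering stress (default 1300 Pa, just above
  the flow threshold `≈ μ₀·(a−1/a)` at `J = 1+θ_S`) is applied as a
  constant total force spread over the load band, brought up over a 0.04 s
  cosine ramp (a dead-weight rig does not impose a perfect step; an exact
  step merely rings the elastic modes). Strain rises quickly, then creeps
  at a decreasing rate toward a quasi-steady state.
* **Stress relaxation** — the driven grip ramps to 20% elongation with a
  smooth cosine profile over 0.2 s and holds for 0.3 s. During the hold
  the stress decays monotonically toward a plateau with the constitutive
  geometric rate.

The runs use light per-frame grid damping (0.002; creep 0.005) during
loading and strong damping (0.2) during the relaxation hold. This is the
quasi-static convention of bench material testing: the damping drag at
protocol speeds is tens of Pa against kPa-scale material stress, and in
the hold phase nothing should move at all, so the measured decay is the
constitutive relaxation rather than elastic ringing superimposed on it.

## What the synthetic specimen does and does not show

The generator emulates a homogeneous, isotropic, rectangular tissue layer
with uniform density and sampling jitter as the only heterogeneity.
Passing tests therefore demonstrate the solver's transfer properties, the
constitutive model's relaxation/creep/tear phenomenology, and the clamp
mechanics — not quantitative agreement with any real nucleus-pulposus
measurement. Real tissue is anisotropic, layered, regionally
inhomogeneous, and its viscoelasticity is not purely volumetric; none of
that is represented. Curve *shapes* (four-stage tear, decelerating creep,
monotone relaxation to a plateau) are the claims under test, not absolute
stress magnitudes.

## Numerical choices

* Quadratic B-spline kernel, fixed 3-node stencil; `bc_margin ≥ 2` cells
  so stencils never leave the grid.
* Volume ratios are floored at `1e−6` before logarithms; a non-positive
  `det F` aborts the frame with its index.
* Inactive-node threshold `1e−12 ×` mean particle mass prevents division
  blow-up.
* A warning is emitted when `Δt·max|v| > Δx/2` (explicit-update
  stability).
* Frame 0 takes a zero velocity-increment field (the `ΔC` correction needs
  a previous frame).
* Orientation keyframes interpolate by normalised linear interpolation;
  positions and jaw openings linearly.
* Curve CSVs print floats with 17 significant digits, so identical runs
  produce byte-identical files.

## Known limitations

* The viscosity constants are per-frame quantities; changing `dt` changes
  the physical relaxation time unless `k` is rescaled with it.
* Grip regions are rigid; no compliance or finite grip friction is
  modelled.
* The 2-D default treats the slab as unit-depth plane geometry; 3-D is
  supported but roughly an order of magnitude slower per frame.
* Tension beyond several hundred percent local stretch eventually
  separates particles beyond kernel support ("numerical fracture"); in the
  tear run this coincides with intended material failure, but it bounds
  how far a *non*-softening material could be stretched faithfully.
* The output force is the raw per-frame impulse rate; filtering for a
  physical haptic device is out of scope.
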