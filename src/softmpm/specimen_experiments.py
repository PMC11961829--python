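"""Specimen generation and material-characterization experiments.

The fixture is a rectangular thin-layered slab sampled with a jittered
sublattice of particles per grid cell, with a *fixed* band at one axial end
and a *load* band at the other.  Three scripted experiments probe the
constitutive model the way a bench tensile rig would:

* **tear** -- the load band is displaced at constant rate until the specimen
  breaks; the stress-strain curve passes through an elastic stage, a plastic
  plateau, a trembling tearing stage, and collapse to (near) zero.
* **creep** -- a constant engineering stress is applied to the load band;
  strain grows quickly at first and then approaches a steady state.
* **relaxation** -- the load band is ramped to a target strain and held; the
  held stress decays geometrically toward a plateau.

Strain is the engineering elongation of the particle bounding extent along
the pull axis; stress is the band-averaged axial first Piola-Kirchhoff
component over the specimen's core (between the two bands), which is the
engineering-stress convention.  Loading is kinematic (prescribed band
displacement) so the curves characterise the material, not a tool model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .material_model import MaterialParams
from .mpm_core import (
    GridState,
    ParticleState,
    ParticleStatus,
    SimConfig,
    SimulationError,
    advance_frame,
)

__all__ = [
    "SpecimenSpec",
    "ExperimentCurve",
    "StageSegmentation",
    "AnalysisError",
    "make_slab",
    "band_mask",
    "run_tear",
    "run_creep",
    "run_relaxation",
    "segment_stages",
]

PULL_AXIS = 0


class AnalysisError(ValueError):
    pass


@dataclass
class SpecimenSpec:
    """Slab geometry and sampling for the simulated tissue specimen.

    ``fixed_band`` / ``load_band`` are fractional intervals of the slab
    length along the pull axis; particles whose rest position falls in the
    fixed band are Dirichlet-constrained, those in the load band are driven
    by the experiment.  ``jitter`` perturbs the regular sublattice by a
    uniform fraction of the sub-spacing, seeding the inhomogeneity that
    localises tearing.
    """

    extents: Tuple[float, ...] = (0.11, 0.025)
    origin: Optional[Tuple[float, ...]] = None
    particles_per_cell: int = 9
    jitter: float = 0.2
    density: float = 1000.0
    fixed_band: Tuple[float, float] = (0.0, 0.08)
    load_band: Tuple[float, float] = (0.92, 1.0)

    def __post_init__(self) -> None:
        self.extents = tuple(float(e) for e in self.extents)
        if any(e <= 0 for e in self.extents):
            raise ValueError("extents must be positive")
        if self.particles_per_cell < 1:
            raise ValueError("particles_per_cell must be >= 1")
        if not 0.0 <= self.jitter <= 1.0:
            raise ValueError("jitter must lie in [0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")
        f0, f1 = self.fixed_band
        l0, l1 = self.load_band
        if not (0 <= f0 < f1 <= 1 and 0 <= l0 < l1 <= 1):
            raise ValueError("bands must be non-empty fractions of [0, 1]")
        if max(f0, l0) < min(f1, l1):
            raise ValueError("fixed_band and load_band must be disjoint")

    def resolved_origin(self, cfg: SimConfig) -> np.ndarray:
        """Lower slab corner: near the low-x margin, centred transversely."""
        if self.origin is not None:
            return np.asarray(self.origin, dtype=float)
        origin = np.empty(cfg.d)
        origin[PULL_AXIS] = (cfg.bc_margin + 2) * cfg.dx
        for a in range(cfg.d):
            if a != PULL_AXIS:
                size = (cfg.domain_extent[a] - 1) * cfg.dx
                origin[a] = 0.5 * (size - self.extents[a])
        return origin


@dataclass
class ExperimentCurve:
    """Per-frame time series of an experiment.

    ``force`` is the axial reaction on the driven band (N; N per unit depth
    in 2-D).  ``hold_start`` marks the first hold frame of a relaxation run.
    """

    time: np.ndarray
    strain: np.ndarray
    stress: np.ndarray
    force: np.ndarray
    hold_start: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.strain) == len(self.stress) == len(self.force) == n):
            raise ValueError("curve series must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class StageSegmentation:
    """Tear-curve stages: elastic (A), plastic (B), tearing (C), broken (D)."""

    breakpoints: List[float]
    labels: List[str]

    def __post_init__(self) -> None:
        if len(self.labels) > 4:
            raise ValueError("at most 4 stages")
        if len(self.breakpoints) != max(len(self.labels) - 1, 0):
            raise ValueError("need one breakpoint between consecutive stages")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")


def make_slab(
    spec: SpecimenSpec, cfg: SimConfig, seed: Optional[int] = None
) -> ParticleState:
    """Sample the slab into particles on a jittered per-cell sublattice.

    Each grid cell holds ``particles_per_cell`` particles (a perfect
    per-axis power), every particle carrying mass
    ``density * dx^d / particles_per_cell`` so the total mass equals
    density times slab volume.  Deterministic for a given seed.
    """
    d = cfg.d
    ppa = int(round(spec.particles_per_cell ** (1.0 / d)))
    if ppa**d != spec.particles_per_cell:
        raise ValueError(
            "particles_per_cell must be a perfect per-axis power (e.g. 4, 9 in 2-D)"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    origin = spec.resolved_origin(cfg)

    n_cells = [max(1, int(round(spec.extents[a] / cfg.dx))) for a in range(d)]
    h = cfg.dx / ppa
    axes = [origin[a] + (np.arange(n_cells[a] * ppa) + 0.5) * h for a in range(d)]
    mesh = np.meshgrid(*axes, indexing="ij")
    x = np.stack([m.ravel() for m in mesh], axis=1)
    if spec.jitter > 0:
        x = x + spec.jitter * h * rng.uniform(-0.5, 0.5, size=x.shape)

    hi_corner = origin + np.array([n_cells[a] * cfg.dx for a in range(d)])
    margin_lo = (cfg.bc_margin + 1) * cfg.dx
    for a in range(d):
        size = (cfg.domain_extent[a] - 1) * cfg.dx
        if origin[a] < margin_lo or hi_corner[a] > size - margin_lo:
            raise ValueError(
                f"slab exceeds the usable domain along axis {a}; "
                "enlarge domain_extent or shrink the specimen"
            )

    n = x.shape[0]
    particles = ParticleState.zeros(n, d)
    particles.x = x
    cell_vol = cfg.dx**d
    particles.m = np.full(n, spec.density * cell_vol / spec.particles_per_cell)
    particles.V0 = np.full(n, cell_vol / spec.particles_per_cell)
    fixed = band_mask(spec, cfg, x, spec.fixed_band)
    particles.status[fixed] = ParticleStatus.FIXED
    return particles


def band_mask(
    spec: SpecimenSpec, cfg: SimConfig, positions: np.ndarray, band: Tuple[float, float]
) -> np.ndarray:
    """Particles whose axial position fraction lies in ``band`` (rest frame).

    Band boundaries are snapped to grid-cell boundaries so a single cell is
    never split between driven and free particles -- a mid-cell split would
    impose an enormous intra-cell velocity gradient and spuriously tear the
    interface.
    """
    origin = spec.resolved_origin(cfg)
    n_cells = max(1, int(round(spec.extents[PULL_AXIS] / cfg.dx)))
    lo = int(round(band[0] * n_cells))
    hi = int(round(band[1] * n_cells))
    cell = np.floor((positions[:, PULL_AXIS] - origin[PULL_AXIS]) / cfg.dx)
    return (cell >= lo) & (cell < max(hi, lo + 1))


def _core_mask(spec, cfg, positions) -> np.ndarray:
    """Measurement band: the specimen core between fixed and load bands."""
    lo = max(spec.fixed_band[1], 0.0) + 0.05
    hi = min(spec.load_band[0], 1.0) - 0.05
    mask = band_mask(spec, cfg, positions, (lo, hi))
    if not np.any(mask):  # degenerate band layout: fall back to everything
        mask = np.ones(positions.shape[0], dtype=bool)
    return mask


def _measure(particles: ParticleState, core: np.ndarray, L0: float):
    xs = particles.x[:, PULL_AXIS]
    strain = (xs.max() - xs.min() - L0) / L0
    stress = particles.stress[core, PULL_AXIS, PULL_AXIS].mean()
    return strain, stress


def _check_finite(particles: ParticleState, frame: int) -> None:
    if not (
        np.all(np.isfinite(particles.x)) and np.all(np.isfinite(particles.stress))
    ):
        raise SimulationError("non-finite particle field", frame=frame)


# per-frame grid damping for the characterization runs: bench material
# tests are quasi-static and heavily damped, which the plastic flow alone
# does not provide inside the elastic band.  The loading value is kept
# small so the drag stress it implies stays negligible against the
# material stress at protocol speeds; the relaxation hold, where nothing
# should move, is damped hard so the measured decay is the constitutive
# relaxation rather than elastic ringing.
EXPERIMENT_DAMPING = 0.002
HOLD_DAMPING = 0.2
CREEP_DAMPING = 0.005


def _experiment_cfg(cfg: SimConfig, damping: Optional[float]) -> SimConfig:
    from dataclasses import replace

    if damping is None:
        damping = EXPERIMENT_DAMPING
    return replace(cfg, damping=damping)


class GripConstraint:
    """Grid-level Dirichlet grips for the two specimen bands.

    The fixed band's node columns are pinned to zero velocity; the driven
    band's node span -- which travels with the prescribed displacement --
    is set to the prescribed velocity.  Enforcing grips on the grid rather
    than by overriding particle positions keeps the velocity field seen by
    grip particles rigid, so their deformation gradients do not integrate
    fictitious interface stretch, while tension is transmitted through the
    tissue's own stress field exactly as in a bench rig.  The per-frame
    constraint impulse is recorded so the grip reaction force can be
    logged.
    """

    def __init__(self, spec: SpecimenSpec, cfg: SimConfig,
                 displacement_of: Optional[Callable[[float], float]] = None):
        origin = spec.resolved_origin(cfg)
        L = spec.extents[PULL_AXIS]
        n_cells = max(1, int(round(L / cfg.dx)))
        self.dx = cfg.dx
        self.x_start = origin[PULL_AXIS]
        f_hi = int(round(spec.fixed_band[1] * n_cells))
        self.fixed_lo = max(int(np.floor(self.x_start / cfg.dx)) - 1, 0)
        self.fixed_hi = int(np.floor(self.x_start / cfg.dx)) + f_hi  # inclusive
        l_lo = int(round(spec.load_band[0] * n_cells))
        self.driven_x_lo = self.x_start + l_lo * cfg.dx
        self.driven_x_hi = self.x_start + n_cells * cfg.dx
        self.displacement_of = displacement_of
        self.force_fixed = np.zeros(cfg.d)
        self.force_driven = np.zeros(cfg.d)

    def _axial_slice(self, lo: int, hi: int, cfg: SimConfig):
        lo = max(lo, 0)
        hi = min(hi, cfg.domain_extent[PULL_AXIS] - 1)
        sel = [slice(None)] * cfg.d
        sel[PULL_AXIS] = slice(lo, hi + 1)
        return tuple(sel)

    def _impose(self, grid: GridState, cfg: SimConfig, sel, v_target: np.ndarray):
        old = grid.velocity[sel]
        impulse = (grid.mass[sel][..., None] * (v_target - old)).sum(
            axis=tuple(range(old.ndim - 1))
        )
        grid.velocity[sel] = v_target
        return impulse / cfg.dt

    def __call__(self, grid: GridState, cfg: SimConfig, frame: int) -> None:
        sel = self._axial_slice(self.fixed_lo, self.fixed_hi, cfg)
        self.force_fixed = self._impose(grid, cfg, sel, np.zeros(cfg.d))
        if self.displacement_of is None:
            return
        t0, t1 = frame * cfg.dt, (frame + 1) * cfg.dt
        delta0 = self.displacement_of(t0)
        u = (self.displacement_of(t1) - delta0) / cfg.dt
        lo = int(np.floor((self.driven_x_lo + delta0) / self.dx))
        hi = int(np.ceil((self.driven_x_hi + delta0) / self.dx)) + 1
        v_target = np.zeros(cfg.d)
        v_target[PULL_AXIS] = u
        sel = self._axial_slice(lo, hi, cfg)
        self.force_driven = self._impose(grid, cfg, sel, v_target)


def _run(
    spec: SpecimenSpec,
    cfg: SimConfig,
    params: MaterialParams,
    frames: int,
    seed: Optional[int],
    displacement_of: Optional[Callable[[float], float]] = None,
    f_ext_of: Optional[Callable[[ParticleState], np.ndarray]] = None,
    progress: Optional[Callable[[int, int], None]] = None,
    damping_of: Optional[Callable[[int], float]] = None,
) -> Tuple[ExperimentCurve, ParticleState]:
    particles = make_slab(spec, cfg, seed=seed)
    core = _core_mask(spec, cfg, particles.x)
    L0 = particles.x[:, PULL_AXIS].max() - particles.x[:, PULL_AXIS].min()
    grid = GridState.zeros(cfg)
    grip = GripConstraint(spec, cfg, displacement_of)

    time = np.empty(frames)
    strain = np.empty(frames)
    stress = np.empty(frames)
    force = np.empty(frames)
    from dataclasses import replace as _replace

    for k in range(frames):
        f_ext = f_ext_of(particles) if f_ext_of is not None else None
        if damping_of is not None:
            damping = damping_of(k)
            if damping != cfg.damping:
                cfg = _replace(cfg, damping=damping)
        advance_frame(
            particles, grid, params, cfg, grid_constraint=grip, f_ext=f_ext,
            frame=k,
        )
        _check_finite(particles, k)
        time[k] = (k + 1) * cfg.dt
        strain[k], stress[k] = _measure(particles, core, L0)
        # grip force on the tissue along the pull axis (tension positive
        # while pulling); the fixed grip carries the mirror reaction
        if displacement_of is not None:
            force[k] = grip.force_driven[PULL_AXIS]
        else:
            force[k] = -grip.force_fixed[PULL_AXIS]
        if progress is not None:
            progress(k + 1, frames)
    curve = ExperimentCurve(time=time, strain=strain, stress=stress, force=force)
    return curve, particles


def run_tear(
    spec: SpecimenSpec,
    cfg: SimConfig,
    params: MaterialParams,
    pull_rate: float = 0.25,
    duration: float = 0.8,
    seed: Optional[int] = None,
    progress=None,
) -> ExperimentCurve:
    """Constant-rate tensile pull to failure.

    The load band moves at ``pull_rate`` (m/s) along the pull axis for
    ``duration`` seconds; the specimen passes through elastic loading, a
    plastic plateau, tearing, and complete separation.
    """
    cfg = _experiment_cfg(cfg, None)
    frames = max(1, int(round(duration / cfg.dt)))
    curve, _ = _run(
        spec, cfg, params, frames, seed,
        displacement_of=lambda t: pull_rate * t, progress=progress,
    )
    return curve


def run_creep(
    spec: SpecimenSpec,
    cfg: SimConfig,
    params: MaterialParams,
    applied_stress: float = 1300.0,
    duration: float = 0.4,
    load_ramp: float = 0.04,
    seed: Optional[int] = None,
    progress=None,
) -> ExperimentCurve:
    """Constant-stress creep test.

    The applied engineering stress is converted to a constant total axial
    force (stress times the undeformed cross-section) spread uniformly over
    the load-band particles and added to the grid momentum every frame.
    The load is brought up over a short cosine ramp (``load_ramp`` seconds,
    a small fraction of the run) -- a dead-weight rig does not impose a
    perfect step either, and an exact step merely rings the specimen's
    elastic modes.
    """
    cfg = _experiment_cfg(cfg, CREEP_DAMPING)
    frames = max(1, int(round(duration / cfg.dt)))
    particles0 = make_slab(spec, cfg, seed=seed)
    load = band_mask(spec, cfg, particles0.x, spec.load_band)
    cross_section = float(np.prod(spec.extents[1:])) if cfg.d > 1 else 1.0
    total_force = applied_stress * cross_section
    per_particle = total_force / max(int(load.sum()), 1)
    f_ext = np.zeros((particles0.n, cfg.d))
    f_ext[load, PULL_AXIS] = per_particle
    frame_box = [0]

    def f_ext_of(p):
        t = (frame_box[0] + 1) * cfg.dt
        frame_box[0] += 1
        if load_ramp <= 0 or t >= load_ramp:
            return f_ext
        return f_ext * (0.5 * (1.0 - np.cos(np.pi * t / load_ramp)))

    curve, _ = _run(
        spec, cfg, params, frames, seed, f_ext_of=f_ext_of, progress=progress
    )
    return curve


def run_relaxation(
    spec: SpecimenSpec,
    cfg: SimConfig,
    params: MaterialParams,
    target_strain: float = 0.2,
    hold_duration: float = 0.3,
    ramp_duration: float = 0.2,
    seed: Optional[int] = None,
    progress=None,
) -> ExperimentCurve:
    """Ramp-and-hold stress-relaxation test.

    The load band is displaced to ``target_strain`` with a smooth cosine
    ramp over ``ramp_duration`` (gentle enough to avoid exciting elastic
    ringing), then held fixed for ``hold_duration`` while the internal
    stress relaxes.  ``curve.hold_start`` indexes the first hold frame.
    """
    cfg = _experiment_cfg(cfg, None)
    ramp_frames = max(1, int(round(ramp_duration / cfg.dt)))
    hold_frames = max(1, int(round(hold_duration / cfg.dt)))
    frames = ramp_frames + hold_frames
    L0 = spec.extents[PULL_AXIS]
    D = target_strain * L0

    def displacement(t: float) -> float:
        if t >= ramp_duration:
            return D
        return 0.5 * D * (1.0 - np.cos(np.pi * t / ramp_duration))

    curve, _ = _run(
        spec, cfg, params, frames, seed, displacement_of=displacement,
        progress=progress,
        damping_of=lambda k: cfg.damping if k < ramp_frames else HOLD_DAMPING,
    )
    curve.hold_start = ramp_frames
    return curve


def segment_stages(
    curve: ExperimentCurve,
    linearity_tol: float = 0.05,
    break_fraction: float = 0.10,
    consecutive: int = 5,
) -> StageSegmentation:
    """Segment a tear curve into the elastic/plastic/tearing/broken stages.

    Operational definitions: the elastic stage ends where the stress departs
    from the initial linear fit by more than ``linearity_tol`` relative
    residual (sustained over ``consecutive`` samples); the plastic stage
    ends at the global stress peak; the tearing stage ends at the first
    sample whose stress magnitude falls below ``break_fraction`` of the
    peak.  Returns fewer stages when a run ends before later stages occur.
    """
    n = len(curve)
    if n < 20:
        raise AnalysisError("curve too short to segment (< 20 samples)")
    s = curve.strain
    sigma = curve.stress
    peak_idx = int(np.argmax(sigma))
    peak = float(sigma[peak_idx])
    if peak <= 0:
        return StageSegmentation(breakpoints=[], labels=["elastic"])

    # initial linear fit over the first twentieth of the run (>= 10 samples)
    w = max(10, n // 20)
    coeffs = np.polyfit(s[:w], sigma[:w], 1)
    pred = np.polyval(coeffs, s)
    rel = np.abs(sigma - pred) / np.maximum(np.abs(pred), 0.05 * peak)
    above = rel > linearity_tol
    ab_idx = None
    run = 0
    for i in range(w, n):
        run = run + 1 if above[i] else 0
        if run >= consecutive:
            ab_idx = i - consecutive + 1
            break
    if ab_idx is None:
        return StageSegmentation(breakpoints=[], labels=["elastic"])

    labels = ["elastic", "plastic"]
    breakpoints = [float(s[ab_idx])]
    if peak_idx <= ab_idx:
        return StageSegmentation(breakpoints=breakpoints, labels=labels)
    labels.append("tearing")
    breakpoints.append(float(s[peak_idx]))

    broken = np.flatnonzero(np.abs(sigma[peak_idx:]) < break_fraction * peak)
    if len(broken) == 0:
        return StageSegmentation(breakpoints=breakpoints, labels=labels)
    cd_idx = peak_idx + int(broken[0])
    labels.append("broken")
    breakpoints.append(float(s[cd_idx]))
    return StageSegmentation(breakpoints=breakpoints, labels=labels)
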