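"""Optimized MPM frame loop: particle-grid transfers with collision feedback.

One frame runs four steps on a regular background grid with quadratic
B-spline interpolation (3-node stencil per axis):

1. *Particle to grid* -- the previous frame's nodal velocity increments
   (produced by collisions / prescribed motion) are gathered into an affine
   velocity correction ``dC``, the deformation gradient is advanced with
   ``C + dC``, and mass and momentum (APIC affine term plus the MLS-MPM
   stress term ``-(4 dt / dx^2) V0 P F^T (x_i - x_p)``) are scattered.
2. *Grid interaction* -- nodal velocity = momentum / mass on active nodes;
   boundary margins apply a slip (or sticky) condition.
3. *Grid to particle* -- velocities and the affine matrix ``C`` are gathered
   back; a temporary position ``x_tilde`` is advanced.
4. *Update particle and force* -- collisions override positions, velocities
   are recomputed from actual displacements, and the per-particle velocity
   increments are scattered back to the grid for the next frame's step 1.
   The clamp reaction force is the negative of the total particle impulse
   rate.

All transfers are vectorised over particles; scatters use ``np.bincount``
over flattened node indices, which accumulates in a fixed order and keeps
runs bit-reproducible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Callable, Optional, Tuple

import numpy as np

from .material_model import MaterialParams, pk_stress, split_deformation

__all__ = [
    "SimConfig",
    "ParticleStatus",
    "ParticleState",
    "GridState",
    "SimulationError",
    "OutOfDomainError",
    "kernel_weights",
    "p2g",
    "grid_update",
    "g2p",
    "finalize_frame",
    "advance_frame",
]


class SimulationError(RuntimeError):
    """Raised when a frame cannot be completed; carries the frame index."""

    def __init__(self, message: str, frame: Optional[int] = None):
        self.frame = frame
        if frame is not None:
            message = f"frame {frame}: {message}"
        super().__init__(message)


class OutOfDomainError(SimulationError):
    pass


class ParticleStatus(IntEnum):
    FREE = 0
    FIXED = 1
    CAPTURED = 2


@dataclass
class SimConfig:
    """Grid, time-step and boundary configuration.

    ``domain_extent`` is the per-axis node count; node ``i`` sits at
    ``i * dx``.  ``bc_margin`` is the boundary band thickness in cells and
    must cover the quadratic B-spline support radius (>= 2).  ``damping`` is
    an optional per-frame grid velocity decay factor in [0, 1) used to run
    quasi-static loading protocols.
    """

    d: int = 2
    dx: float = 2.5e-3
    dt: float = 1e-4
    domain_extent: Tuple[int, ...] = (160, 40)
    bc_margin: int = 2
    gravity: Optional[Tuple[float, ...]] = None
    seed: int = 0
    boundary: str = "slip"
    damping: float = 0.0

    def __post_init__(self) -> None:
        self.domain_extent = tuple(int(n) for n in self.domain_extent)
        self.validate()

    def validate(self) -> None:
        if self.d not in (2, 3):
            raise ValueError("d must be 2 or 3")
        if not self.dx > 0:
            raise ValueError("dx must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if len(self.domain_extent) != self.d:
            raise ValueError("domain_extent must have one node count per axis")
        if any(n < 8 for n in self.domain_extent):
            raise ValueError("domain_extent node counts must be >= 8")
        if self.bc_margin < 2:
            raise ValueError("bc_margin must be >= 2 cells")
        if self.gravity is not None and len(self.gravity) != self.d:
            raise ValueError("gravity must have d components")
        if self.boundary not in ("slip", "sticky"):
            raise ValueError("boundary must be 'slip' or 'sticky'")
        if not 0.0 <= self.damping < 1.0:
            raise ValueError("damping must lie in [0, 1)")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.domain_extent))


@dataclass
class ParticleState:
    """Struct-of-arrays particle collection.

    ``J_P`` is the persistent plastic volume ratio (stateful plasticity);
    ``J_E`` and ``stress`` are diagnostics refreshed each frame by
    :func:`p2g`.  ``rel_offset`` holds the clamp-frame coordinates of a
    captured particle and is meaningful only while ``status == CAPTURED``.

"""

    x: np.ndarray
    v: np.ndarray
    C: np.ndarray
    F: np.ndarray
    J_P: np.ndarray
    m: np.ndarray
    V0: np.ndarray
    dv: np.ndarray
    status: np.ndarray
    rel_offset: np.ndarray
    J_E: np.ndarray
    stress: np.ndarray

    @classmethod
    def zeros(cls, n: int, d: int) -> "ParticleState":
        eye = np.broadcast_to(np.eye(d), (n, d, d)).copy()
        return cls(
            x=np.zeros((n, d)),
            v=np.zeros((n, d)),
            C=np.zeros((n, d, d)),
            F=eye,
            J_P=np.ones(n),
            m=np.ones(n),
            V0=np.ones(n),
            dv=np.zeros((n, d)),
            status=np.full(n, ParticleStatus.FREE, dtype=np.int8),
            rel_offset=np.zeros((n, d)),
            J_E=np.ones(n),
            stress=np.zeros((n, d, d)),
        )

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]

    def copy(self) -> "ParticleState":
        return ParticleState(
            **{k: getattr(self, k).copy() for k in self.__dataclass_fields__}
        )


@dataclass
class GridState:
    """Nodal fields.  ``dv`` persists between frames (collision feedback)."""

    mass: np.ndarray
    momentum: np.ndarray
    velocity: np.ndarray
    dv: np.ndarray
    mean_particle_mass: float = 0.0

    @classmethod
    def zeros(cls, cfg: SimConfig) -> "GridState":
        shape = cfg.domain_extent
        return cls(
            mass=np.zeros(shape),
            momentum=np.zeros(shape + (cfg.d,)),
            velocity=np.zeros(shape + (cfg.d,)),
            dv=np.zeros(shape + (cfg.d,)),
        )

    def reset(self) -> None:
        """Clear the per-frame fields, keeping ``dv`` for the next step 1."""
        self.mass[...] = 0.0
        self.momentum[...] = 0.0
        self.velocity[...] = 0.0


# inactive-node threshold relative to the mean particle mass
_ACTIVE_REL = 1e-12


def _axis_weights(fx: np.ndarray) -> np.ndarray:
    """Quadratic B-spline weights for fractional offsets ``fx`` in [0.5, 1.5).

    Returns shape ``(3,) + fx.shape`` for stencil offsets 0, 1, 2.
    """
    return np.stack(
        [
            0.5 * (1.5 - fx) ** 2,
            0.75 - (fx - 1.0) ** 2,
            0.5 * (fx - 0.5) ** 2,
        ]
    )


def _stencil(x: np.ndarray, dx: float):
    """Batched stencil: base node index and per-axis weights for positions."""
    gx = x / dx
    base = np.floor(gx - 0.5).astype(np.int64)
    fx = gx - base
    return base, _axis_weights(fx)  # base (n, d); w (3, n, d)


def kernel_weights(x, dx: float):
    """Quadratic B-spline stencil for a single position.

    Returns ``(base, weights)``: the lowest node index of the 3^d stencil and
    the weight tensor of shape ``(3,) * d``.  Weights sum to one and have
    zero first moment about the particle.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    base, w = _stencil(x, dx)
    d = x.shape[1]
    axes = [w[:, 0, a] for a in range(d)]
    full = axes[0]
    for a in range(1, d):
        full = np.multiply.outer(full, axes[a])
    return base[0], full


def _check_domain(base: np.ndarray, cfg: SimConfig, frame: Optional[int] = None):
    res = np.asarray(cfg.domain_extent)
    bad = np.any((base < 0) | (base + 2 >= res), axis=1)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise OutOfDomainError(
            f"particle {idx} left the valid grid domain", frame=frame
        )


def _offsets(d: int):
    return list(itertools.product(range(3), repeat=d))


def _offset_terms(base, w, offset, cfg: SimConfig, x: np.ndarray):
    """Weight, flat node index and node-minus-particle vector for one offset."""
    d = cfg.d
    w_o = w[offset[0], :, 0]
    for a in range(1, d):
        w_o = w_o * w[offset[a], :, a]
    idx = base + np.asarray(offset)
    flat = np.ravel_multi_index(tuple(idx[:, a] for a in range(d)), cfg.domain_extent)
    dpos = idx * cfg.dx - x
    return w_o, flat, dpos


def _all_offset_terms(base, w, cfg: SimConfig, x: np.ndarray):
    """Stacked stencil terms: weights (K, n), flat indices (K, n),
    node-minus-particle vectors (K, n, d) for all K = 3^d offsets."""
    d = cfg.d
    offsets = np.asarray(_offsets(d))  # (K, d)
    W = w[offsets[:, 0], :, 0]
    for a in range(1, d):
        W = W * w[offsets[:, a], :, a]
    idx = base[None, :, :] + offsets[:, None, :]  # (K, n, d)
    flat = np.ravel_multi_index(
        tuple(idx[..., a] for a in range(d)), cfg.domain_extent
    )
    dpos = idx * cfg.dx - x[None, :, :]
    return W, flat, dpos


def p2g(
    particles: ParticleState,
    grid: GridState,
    params: MaterialParams,
    cfg: SimConfig,
    f_ext: Optional[np.ndarray] = None,
    frame: Optional[int] = None,
) -> GridState:
    """Particle-to-grid transfer (step 1).

    Gathers the previous frame's nodal velocity increments into the affine
    correction ``dC``, advances ``F`` with ``C + dC``, evaluates the
    constitutive stress, and scatters mass and momentum.  ``f_ext`` is an
    optional per-particle external force ``(n, d)`` whose impulse ``dt * f``
    is scattered with the same weights (used for constant-load creep tests).
    Updates the persistent plastic state in stateful mode.
    """
    d, dx, dt = cfg.d, cfg.dx, cfg.dt
    x = particles.x
    base, w = _stencil(x, dx)
    _check_domain(base, cfg, frame)

    W, FLAT, DPOS = _all_offset_terms(base, w, cfg, x)

    gdv = grid.dv.reshape(-1, d)
    wdv = W[..., None] * gdv[FLAT]  # (K, n, d)
    dC = (4.0 / dx**2) * np.matmul(wdv.transpose(1, 2, 0), DPOS.transpose(1, 0, 2))

    C_eff = particles.C + dC
    F_new = (np.eye(d) + dt * C_eff) @ particles.F
    det = np.linalg.det(F_new)
    if np.any(det <= 0) or not np.all(np.isfinite(F_new)):
        idx = int(np.argmax((det <= 0) | ~np.isfinite(det)))
        raise SimulationError(
            f"deformation gradient of particle {idx} became degenerate",
            frame=frame,
        )

    split = split_deformation(F_new, particles.J_P, params)
    P = pk_stress(split, params)
    particles.F = F_new
    particles.J_E = np.asarray(split.J_E, dtype=float)
    particles.stress = P
    if params.plasticity_mode == "stateful":
        particles.J_P = np.asarray(split.J_P, dtype=float)

    m = particles.m
    affine = (
        m[:, None, None] * particles.C
        - (4.0 * dt / dx**2) * particles.V0[:, None, None] * (P @ np.swapaxes(F_new, -1, -2))
    )
    mv = m[:, None] * particles.v
    if f_ext is not None:
        mv = mv + dt * f_ext

    grid.reset()
    n_nodes = cfg.n_nodes
    mom = grid.momentum.reshape(-1, d)
    mass = grid.mass.reshape(-1)
    flat_all = FLAT.ravel()
    mass += np.bincount(flat_all, weights=(W * m).ravel(), minlength=n_nodes)
    affine_term = np.matmul(
        DPOS.transpose(1, 0, 2), affine.transpose(0, 2, 1)
    ).transpose(1, 0, 2)  # (K, n, d): affine @ (x_i - x_p)
    contrib = W[..., None] * (mv[None, :, :] + affine_term)
    for a in range(d):
        mom[:, a] += np.bincount(flat_all, weights=contrib[..., a].ravel(),
                                 minlength=n_nodes)
    grid.mean_particle_mass = float(m.mean())
    return grid


def grid_update(grid: GridState, cfg: SimConfig) -> GridState:
    """Grid interaction (step 2): nodal velocities plus boundary conditions.

    Nodes with mass below ``1e-12`` of the mean particle mass stay inactive.
    Within ``bc_margin`` cells of a domain face the velocity component
    directed toward that face is zeroed (slip); the sticky variant zeroes
    all components.
    """
    active = grid.mass > _ACTIVE_REL * grid.mean_particle_mass
    v = np.zeros_like(grid.momentum)
    v[active] = grid.momentum[active] / grid.mass[active, None]
    if cfg.gravity is not None:
        v[active] += cfg.dt * np.asarray(cfg.gravity)
    d, margin = cfg.d, cfg.bc_margin
    for a in range(d):
        lo = [slice(None)] * d
        lo[a] = slice(0, margin)
        hi = [slice(None)] * d
        hi[a] = slice(cfg.domain_extent[a] - margin, None)
        if cfg.boundary == "slip":
            v[tuple(lo) + (a,)] = np.maximum(v[tuple(lo) + (a,)], 0.0)
            v[tuple(hi) + (a,)] = np.minimum(v[tuple(hi) + (a,)], 0.0)
        else:
            v[tuple(lo)] = 0.0
            v[tuple(hi)] = 0.0
    if cfg.damping:
        v *= 1.0 - cfg.damping
    grid.velocity = v
    return grid


def g2p(
    grid: GridState, particles: ParticleState, cfg: SimConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Grid-to-particle transfer (step 3).

    Returns ``(v_tilde, x_tilde)`` -- the temporary velocities and advanced
    positions -- and refreshes the per-particle affine matrix ``C``.
    Particles flagged ``FIXED`` receive zero velocity and keep their
    position (a local Dirichlet constraint).
    """
    d, dx, dt = cfg.d, cfg.dx, cfg.dt
    x = particles.x
    base, w = _stencil(x, dx)
    gv = grid.velocity.reshape(-1, d)

    W, FLAT, DPOS = _all_offset_terms(base, w, cfg, x)
    wvi = W[..., None] * gv[FLAT]  # (K, n, d)
    v_tilde = wvi.sum(axis=0)
    C_new = (4.0 / dx**2) * np.matmul(wvi.transpose(1, 2, 0), DPOS.transpose(1, 0, 2))

    fixed = particles.status == ParticleStatus.FIXED
    v_tilde[fixed] = 0.0
    x_tilde = x + dt * v_tilde
    x_tilde[fixed] = x[fixed]
    particles.C = C_new
    return v_tilde, x_tilde


def finalize_frame(
    particles: ParticleState,
    grid: GridState,
    x_old: np.ndarray,
    x_new: np.ndarray,
    v_tilde: np.ndarray,
    cfg: SimConfig,
) -> None:
    """Step 4 bookkeeping after collision resolution.

    Velocities are recomputed from the actual displacements, the velocity
    increments ``dv = v - v_tilde`` are stored per particle, and their
    mass-weighted average is scattered to ``grid.dv`` for the next frame's
    affine correction.
    """
    d, dt = cfg.d, cfg.dt
    v_new = (x_new - x_old) / dt
    dv_p = v_new - v_tilde
    particles.x = x_new
    particles.v = v_new
    particles.dv = dv_p

    base, w = _stencil(x_old, cfg.dx)
    n_nodes = cfg.n_nodes
    num = np.zeros((n_nodes, d))
    m = particles.m
    W, FLAT, _ = _all_offset_terms(base, w, cfg, x_old)
    flat_all = FLAT.ravel()
    contrib = (W * m)[..., None] * dv_p[None, :, :]
    for a in range(d):
        num[:, a] += np.bincount(flat_all, weights=contrib[..., a].ravel(),
                                 minlength=n_nodes)
    mass = grid.mass.reshape(-1)
    active = mass > _ACTIVE_REL * grid.mean_particle_mass
    gdv = np.zeros((n_nodes, d))
    gdv[active] = num[active] / mass[active, None]
    grid.dv = gdv.reshape(grid.dv.shape)


def advance_frame(
    particles: ParticleState,
    grid: GridState,
    params: MaterialParams,
    cfg: SimConfig,
    clamp_n=None,
    clamp_n1=None,
    override: Optional[Callable[[int, np.ndarray, ParticleState], np.ndarray]] = None,
    f_ext: Optional[np.ndarray] = None,
    grid_constraint: Optional[Callable[[GridState, "SimConfig", int], None]] = None,
    frame: int = 0,
) -> np.ndarray:
    """Advance one frame and return the output force (Newtons, d-vector).

    Executes p2g -> grid interaction -> g2p -> collide -> finalize in order.
    ``clamp_n`` / ``clamp_n1`` are the rigid clamp poses bracketing the
    frame; ``override`` may rewrite positions after collision (used for
    prescribed kinematic loading); ``grid_constraint`` may rewrite nodal
    velocities after the boundary treatment (Dirichlet grips).  The
    returned force is the impulse-rate reaction
    ``-sum_p m_p (v_p - v_tilde_p) / dt`` fed to a force-feedback device.
    """
    from .clamp_interaction import collide, output_force

    x_old = particles.x.copy()
    p2g(particles, grid, params, cfg, f_ext=f_ext, frame=frame)
    grid_update(grid, cfg)
    if grid_constraint is not None:
        grid_constraint(grid, cfg, frame)
    v_tilde, x_tilde = g2p(grid, particles, cfg)
    x_new = x_tilde
    if clamp_n1 is not None:
        x_new = collide(x_tilde, particles, clamp_n, clamp_n1)
    if override is not None:
        x_new = override(frame, x_new, particles)
    finalize_frame(particles, grid, x_old, x_new, v_tilde, cfg)
    vmax = float(np.abs(particles.v).max(initial=0.0))
    if cfg.dt * vmax > 0.5 * cfg.dx:
        warnings.warn(
            f"frame {frame}: dt*|v|max = {cfg.dt * vmax:.3g} exceeds half the "
            f"grid spacing; the explicit update may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    return output_force(particles, cfg.dt)
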