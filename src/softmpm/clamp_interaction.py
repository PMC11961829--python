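"""Rigid clamp model: two cubic jaw boxes, particle capture, and force output.

The surgical clamp is reduced to two oriented cubic collision boxes placed
symmetrically about the tool tip along the jaw axis (local axis 1).  When the
jaws close below ``closed_threshold``, particles inside either box are
*captured*: their clamp-frame coordinates are frozen and each subsequent
frame their world position is recovered by applying the current clamp pose to
that stored offset, so gripped tissue follows the tool rigidly.  Opening the
jaws releases them.  Open jaws still push free particles out to the nearest
box face so the tool can probe without gripping.

The force delivered to a haptic device is the reaction to the net impulse
the clamp gives the particles in one frame:
``F = -sum_p m_p (v_p - v_tilde_p) / dt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .mpm_core import ParticleState, ParticleStatus

__all__ = [
    "ClampState",
    "ForceSample",
    "ClampTrajectory",
    "jaw_boxes",
    "collide",
    "output_force",
]

JAW_AXIS = 1  # local axis along which the two jaw boxes separate


@dataclass
class ClampState:
    """Rigid pose and jaw opening of the clamp tip.

    ``opening`` is the jaw half-separation: box centres sit at
    ``+/- opening`` along the jaw axis in the clamp frame.  ``orientation``
    is a proper rotation matrix (columns = clamp axes in world frame).
    """

    position: np.ndarray
    orientation: np.ndarray
    opening: float
    box_half_extent: np.ndarray
    closed_threshold: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.box_half_extent = np.asarray(self.box_half_extent, dtype=float)
        d = self.position.shape[0]
        R = self.orientation
        if R.shape != (d, d) or not np.allclose(R @ R.T, np.eye(d), atol=1e-8):
            raise ValueError("orientation must be an orthonormal d x d matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("orientation must be a proper rotation (det=+1)")
        if self.opening < 0:
            raise ValueError("opening must be non-negative")
        if np.any(self.box_half_extent <= 0):
            raise ValueError("box_half_extent components must be positive")

    @property
    def d(self) -> int:
        return self.position.shape[0]

    @property
    def closed(self) -> bool:
        return self.opening <= self.closed_threshold

    def to_local(self, x: np.ndarray) -> np.ndarray:
        """World -> clamp-frame coordinates (row-wise for (n, d) input)."""
        return (np.asarray(x) - self.position) @ self.orientation

    def to_world(self, local: np.ndarray) -> np.ndarray:
        return self.position + np.asarray(local) @ self.orientation.T


@dataclass
class ForceSample:
    """One frame of force-feedback output."""

    frame: int
    force: np.ndarray

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force must be finite")


def _box_centers_local(c: ClampState) -> np.ndarray:
    centers = np.zeros((2, c.d))
    centers[0, JAW_AXIS] = c.opening
    centers[1, JAW_AXIS] = -c.opening
    return centers


def jaw_boxes(c: ClampState) -> List[Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """World-frame jaw boxes as ``(center, orientation, half_extent)`` pairs."""
    return [
        (c.to_world(center), c.orientation.copy(), c.box_half_extent.copy())
        for center in _box_centers_local(c)
    ]


def _inside_masks(local: np.ndarray, c: ClampState) -> np.ndarray:
    """(n, 2) bool: membership of each particle in each jaw box."""
    centers = _box_centers_local(c)
    delta = local[:, None, :] - centers[None, :, :]
    return np.all(np.abs(delta) <= c.box_half_extent, axis=2)


def collide(
    x_tilde: np.ndarray,
    particles: ParticleState,
    c_n: Optional[ClampState],
    c_n1: ClampState,
) -> np.ndarray:
    """Resolve clamp/particle interaction for one frame.

    Returns the post-collision positions and updates capture status and the
    stored clamp-frame offsets in place.  Rules, evaluated against the
    end-of-frame pose ``c_n1``:

    * captured + jaws still closed -> position = pose applied to the stored
      offset (rigid carry);
    * captured + jaws opened past the threshold -> released, keeps
      ``x_tilde``;
    * free inside a box + jaws closed -> captured at ``x_tilde``;
    * free inside a box + jaws open -> pushed to the nearest box face;
    * free outside -> untouched.
    """
    x_new = x_tilde.copy()
    status = particles.status
    captured = status == ParticleStatus.CAPTURED

    if c_n1.closed:
        if np.any(captured):
            x_new[captured] = c_n1.to_world(particles.rel_offset[captured])
    else:
        status[captured] = ParticleStatus.FREE

    free = status == ParticleStatus.FREE
    if not np.any(free):
        return x_new
    local = c_n1.to_local(x_tilde[free])
    inside = _inside_masks(local, c_n1)
    any_inside = np.any(inside, axis=1)
    if not np.any(any_inside):
        return x_new

    free_idx = np.flatnonzero(free)
    hit_idx = free_idx[any_inside]
    hit_local = local[any_inside]
    if c_n1.closed:
        status[hit_idx] = ParticleStatus.CAPTURED
        particles.rel_offset[hit_idx] = hit_local
        # captured at x_tilde: pose applied to the stored offset is x_tilde
    else:
        # non-penetration: project to the nearest face of the containing box
        centers = _box_centers_local(c_n1)
        which = np.argmax(inside[any_inside], axis=1)
        delta = hit_local - centers[which]
        he = c_n1.box_half_extent
        depth = he - np.abs(delta)  # > 0 inside, per axis
        axis = np.argmin(depth, axis=1)
        rows = np.arange(len(axis))
        sign = np.where(delta[rows, axis] >= 0, 1.0, -1.0)
        delta[rows, axis] = sign * he[axis]
        x_new[hit_idx] = c_n1.to_world(centers[which] + delta)
    return x_new


def output_force(
    particles: ParticleState, dt: float, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Impulse-rate reaction force on the tool, ``-sum m_p dv_p / dt``.

    ``mask`` restricts the sum to a subset of particles (e.g. a kinematically
    driven band when measuring a specimen reaction instead of the clamp).
    Exactly zero when no particle's velocity was altered.
    """
    dv = particles.dv
    m = particles.m
    if mask is not None:
        dv = dv[mask]
        m = m[mask]
    return -(m[:, None] * dv).sum(axis=0) / dt


class ClampTrajectory:
    """Piecewise-linear keyframed clamp motion.

    Keyframes carry time, position, orientation (rotation angle in 2-D,
    quaternion in 3-D) and jaw opening.  Positions and openings interpolate
    linearly; orientations by normalised linear interpolation of quaternions
    (2-D angles interpolate directly).  The CSV layout is
    ``time, x, y[, z], angle | qw, qx, qy, qz, opening``.
    """

    def __init__(
        self,
        times: np.ndarray,
        positions: np.ndarray,
        orientations: np.ndarray,
        openings: np.ndarray,
        box_half_extent,
        closed_threshold: float,
    ):
        self.times = np.asarray(times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("trajectory needs at least one keyframe")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("keyframe times must be strictly increasing")
        self.positions = np.asarray(positions, dtype=float)
        self.orientations = np.asarray(orientations, dtype=float)
        self.openings = np.asarray(openings, dtype=float)
        self.box_half_extent = np.asarray(box_half_extent, dtype=float)
        self.closed_threshold = float(closed_threshold)
        self.d = self.positions.shape[1]

    @classmethod
    def from_csv(cls, path, box_half_extent, closed_threshold: float, d: int = 2):
        data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        ncol_orient = 1 if d == 2 else 4
        expected = 1 + d + ncol_orient + 1
        if data.shape[1] != expected:
            raise ValueError(
                f"trajectory CSV must have {expected} columns for d={d}"
            )
        times = data[:, 0]
        positions = data[:, 1 : 1 + d]
        orientations = data[:, 1 + d : 1 + d + ncol_orient]
        openings = data[:, -1]
        return cls(
            times, positions, orientations, openings, box_half_extent, closed_threshold
        )

    def _orientation_matrix(self, q: np.ndarray) -> np.ndarray:
        if self.d == 2:
            a = float(q[0])
            ca, sa = np.cos(a), np.sin(a)
            return np.array([[ca, -sa], [sa, ca]])
        from scipy.spatial.transform import Rotation

        q = q / np.linalg.norm(q)
        # stored as (w, x, y, z); scipy wants (x, y, z, w)
        return Rotation.from_quat(np.r_[q[1:], q[0]]).as_matrix()

    def pose_at(self, t: float) -> ClampState:
        times = self.times
        t = float(np.clip(t, times[0], times[-1]))
        j = int(np.searchsorted(times, t, side="right"))
        j = min(max(j, 1), len(times) - 1) if len(times) > 1 else 0
        if len(times) == 1:
            pos, q, opening = self.positions[0], self.orientations[0], self.openings[0]
        else:
            i = j - 1
            s = (t - times[i]) / (times[j] - times[i])
            pos = (1 - s) * self.positions[i] + s * self.positions[j]
            qi, qj = self.orientations[i], self.orientations[j]
            if self.d == 3 and np.dot(qi, qj) < 0:
                qj = -qj
            q = (1 - s) * qi + s * qj
            opening = (1 - s) * self.openings[i] + s * self.openings[j]
        return ClampState(
            position=pos,
            orientation=self._orientation_matrix(np.atleast_1d(q)),
            opening=float(opening),
            box_half_extent=self.box_half_extent,
            closed_threshold=self.closed_threshold,
        )
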