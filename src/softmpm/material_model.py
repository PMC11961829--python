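"""Viscoelastic-plastic Neo-Hookean constitutive model for gel-like soft tissue.

The tissue (modelled on the nucleus pulposus of the intervertebral disc) is a
compressible Neo-Hookean solid with a multiplicative elastic/plastic split of
the deformation gradient, ``F = F_E F_P``.  Plastic flow is purely volumetric:
the elastic volume ratio ``J_E = det(F_E)`` is confined to the band
``[1 - theta_c, 1 + theta_s]``.  When the candidate elastic volume ratio
leaves that band, the excess is relaxed back toward the limit at a per-frame
rate set by the viscosity constants ``k_c`` (compression) and ``k_s``
(extension); the removed volume change accumulates as plastic flow.  Carried
across frames (the *stateful* mode) this produces geometric per-frame decay of
elastic excess -- i.e. stress relaxation under a held strain, and creep under
a held load.  The Lame coefficients harden exponentially with plastic
compaction (``J_P < 1``) and soften with plastic dilation (``J_P > 1``),
which is what lets a stretched specimen weaken and eventually tear.

All operations accept batched deformation gradients of shape ``(..., d, d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "MaterialParams",
    "DeformationSplit",
    "hardened_lame",
    "clamp_volume_ratio",
    "split_deformation",
    "energy_density",
    "pk_stress",
]

# floor applied to volume ratios before taking logs
_LOG_FLOOR = 1e-6

_PLASTICITY_MODES = ("stateless", "stateful")
_SCALING_MODES = ("det_consistent", "literal")


def lame_from_elastic_moduli(youngs: float, poisson: float) -> Tuple[float, float]:
    """Convert (E, nu) to the Lame pair (mu, lambda)."""
    if youngs <= 0:
        raise ValueError("youngs_modulus must be positive")
    if not -1.0 < poisson < 0.5:
        raise ValueError("poisson_ratio must lie in (-1, 0.5)")
    mu = youngs / (2.0 * (1.0 + poisson))
    lam = youngs * poisson / ((1.0 + poisson) * (1.0 - 2.0 * poisson))
    return mu, lam


@dataclass
class MaterialParams:
    """Constitutive constants.

    Parameters
    ----------
    mu0, lambda0 : float
        Initial (un-hardened) Lame coefficients in Pa.  Defaults correspond
        to E = 10 kPa (the order of magnitude of soft gel-like tissue) at
        zero Poisson ratio.  The zero-lambda default makes the volume ratio
        track the axial stretch directly (J = 1 + strain in uniaxial
        loading), which is the regime this volumetric plasticity is built
        around: the elastic limits theta_c/theta_s then correspond to
        engineering strains, and a rigid grip is kinematically compatible
        with uniform stretch (no Poisson-mismatch stress concentration at
        the grip corners).
    xi : float
        Plastic hardening coefficient (dimensionless).  The effective Lame
        coefficients are ``mu0 * exp(xi * (1 - J_P))``; positive ``xi``
        stiffens compacted material and weakens dilated material.  The
        default is moderate: strong enough that a torn specimen's stress
        collapses, weak enough that creep decelerates toward a steady
        state instead of running away tertiary-style.
    theta_c, theta_s : float
        Compression and extension limit ratios bounding the elastic volume
        ratio to ``[1 - theta_c, 1 + theta_s]``.
    k_c, k_s : float
        Viscosity constants in [0, 1]: the fraction of the out-of-band
        elastic volume excess converted to plastic flow per frame.  They are
        per-frame rates, so the physical relaxation time scale is
        ``dt / k`` -- frame-rate dependent by construction.  The defaults
        give ``dt/k = 0.2 s`` at the default time step, a relaxation time
        well above the elastic wave transit time of the default specimen
        (so the material is genuinely viscoelastic rather than
        rate-independent plastic) and well below the length of a
        characterization run (so relaxation and creep are visible).
    plasticity_mode : {"stateful", "stateless"}
        ``stateful`` carries the plastic volume ratio ``J_P`` across frames
        (elastic excess decays geometrically -> stress relaxation, creep);
        ``stateless`` re-derives the split from the total ``J`` every frame
        and exhibits no relaxation.  Stateful is the default.
    scaling_mode : {"det_consistent", "literal"}
        How the elastic gradient is rescaled from the total one.
        ``det_consistent`` uses ``F_E = (J_E/J)^(1/d) F`` so that
        ``det(F_E) = J_E`` in any dimension; ``literal`` uses the linear
        prefactor ``F_E = (J_E/J) F``.
    """

    mu0: float = 5000.0
    lambda0: float = 0.0
    xi: float = 3.0
    theta_c: float = 0.05
    theta_s: float = 0.10
    k_c: float = 5e-4
    k_s: float = 5e-4
    plasticity_mode: str = "stateful"
    scaling_mode: str = "det_consistent"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.mu0 > 0:
            raise ValueError("mu0 must be positive")
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be non-negative")
        if not 0.0 < self.theta_c < 1.0:
            raise ValueError("theta_c must lie in (0, 1)")
        if not self.theta_s > 0:
            raise ValueError("theta_s must be positive")
        if not 0.0 <= self.k_c <= 1.0:
            raise ValueError("k_c must lie in [0, 1]")
        if not 0.0 <= self.k_s <= 1.0:
            raise ValueError("k_s must lie in [0, 1]")
        if self.plasticity_mode not in _PLASTICITY_MODES:
            raise ValueError(
                f"plasticity_mode must be one of {_PLASTICITY_MODES}"
            )
        if self.scaling_mode not in _SCALING_MODES:
            raise ValueError(f"scaling_mode must be one of {_SCALING_MODES}")

    @classmethod
    def from_elastic_moduli(
        cls, youngs: float, poisson: float, **kwargs
    ) -> "MaterialParams":
        mu, lam = lame_from_elastic_moduli(youngs, poisson)
        return cls(mu0=mu, lambda0=lam, **kwargs)

    def with_(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)


@dataclass
class DeformationSplit:
    """Elastic/plastic decomposition of a (batch of) deformation gradient(s).

    ``F_E @ F_P`` reconstructs the total gradient; ``J_E * J_P = J``.  The
    plastic part is a pure dilation here (plastic flow is volumetric), so
    ``F_P = (J_P)^(1/d) I`` in the default scaling mode.
    """

    F_E: np.ndarray
    F_P: np.ndarray
    J: np.ndarray
    J_E: np.ndarray
    J_P: np.ndarray


def hardened_lame(J_P, params: MaterialParams):
    """Plastic-hardened Lame coefficients ``(mu, lambda)``.

    ``mu = mu0 * exp(xi (1 - J_P))`` and likewise for lambda: compaction
    (``J_P < 1``) stiffens, dilation softens.
    """
    J_P = np.asarray(J_P, dtype=float)
    if np.any(J_P <= 0):
        raise ValueError("plastic volume ratio J_P must be positive")
    h = np.exp(params.xi * (1.0 - J_P))
    return params.mu0 * h, params.lambda0 * h


def clamp_volume_ratio(J, params: MaterialParams):
    """Relax the elastic volume ratio toward the band ``[1-theta_c, 1+theta_s]``.

    Identity inside the band; outside, the excess is reduced by the fraction
    ``k_c`` (below) or ``k_s`` (above).  Continuous at both breakpoints and
    monotone non-decreasing for ``k`` in [0, 1].
    """
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("volume ratio J must be positive")
    lo = 1.0 - params.theta_c
    hi = 1.0 + params.theta_s
    out = np.where(J < lo, J + params.k_c * (lo - J), J)
    out = np.where(J > hi, J - params.k_s * (J - hi), out)
    if out.ndim == 0:
        return float(out)
    return out


def split_deformation(
    F, prior_J_P=1.0, params: MaterialParams | None = None
) -> DeformationSplit:
    """Split total deformation gradient(s) into elastic and plastic parts.

    In stateless mode the candidate elastic ratio is the total ``J``; in
    stateful mode it is ``J / prior_J_P`` (the previously accumulated plastic
    dilation is first removed, so repeated application relaxes the elastic
    excess geometrically).  The candidate is then passed through
    :func:`clamp_volume_ratio` and the elastic gradient is rescaled from the
    total one so its determinant equals the clamped ratio.
    """
    if params is None:
        params = MaterialParams()
    F = np.asarray(F, dtype=float)
    d = F.shape[-1]
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    if params.plasticity_mode == "stateful":
        prior = np.asarray(prior_J_P, dtype=float)
        if np.any(prior <= 0):
            raise ValueError("prior plastic volume ratio must be positive")
        candidate = J / prior
    else:
        candidate = J
    J_E = np.asarray(clamp_volume_ratio(candidate, params))
    J_P = J / J_E
    if params.scaling_mode == "det_consistent":
        scale = (J_E / J) ** (1.0 / d)
    else:
        scale = J_E / J
    F_E = scale[..., None, None] * F
    F_P = np.linalg.inv(F_E) @ F
    return DeformationSplit(F_E=F_E, F_P=F_P, J=J, J_E=J_E, J_P=J_P)


def _log_J_E(split: DeformationSplit) -> np.ndarray:
    J_E = np.asarray(split.J_E, dtype=float)
    if np.any(J_E <= 0):
        raise ValueError("elastic volume ratio J_E must be positive")
    return np.log(np.maximum(J_E, _LOG_FLOOR))


def energy_density(split: DeformationSplit, params: MaterialParams):
    """Strain-energy density per unit reference volume.

    ``psi = mu/2 (tr(F_E^T F_E) - d) - mu log(J_E) + lambda/2 log^2(J_E)``
    with the Lame coefficients hardened by the plastic state.  Reduces to the
    plain Neo-Hookean energy when no plastic flow has occurred.
    """
    mu, lam = hardened_lame(split.J_P, params)
    d = split.F_E.shape[-1]
    tr = np.einsum("...ij,...ij->...", split.F_E, split.F_E)
    logJ = _log_J_E(split)
    psi = 0.5 * mu * (tr - d) - mu * logJ + 0.5 * lam * logJ**2
    if np.ndim(psi) == 0:
        return float(psi)
    return psi


def pk_stress(split: DeformationSplit, params: MaterialParams) -> np.ndarray:
    """First Piola-Kirchhoff stress of the hardened Neo-Hookean energy.

    ``P = mu (F_E - F_E^{-T}) + lambda log(J_E) F_E^{-T}``; exactly zero at
    the rest state and equal to the gradient of :func:`energy_density` with
    respect to ``F`` wherever no plastic flow occurs.
    """
    mu, lam = hardened_lame(split.J_P, params)
    F_E = split.F_E
    FinvT = np.swapaxes(np.linalg.inv(F_E), -1, -2)
    logJ = _log_J_E(split)
    mu = np.asarray(mu)
    term = (lam * logJ) if np.ndim(logJ) else lam * logJ
    P = mu[..., None, None] * (F_E - FinvT) + np.asarray(term)[..., None, None] * FinvT
    return P
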