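"""Closed-form moment relations for stochastic gene expression.

The central quantity is the noise-mean scaling constant ``Omega`` defined by

    CV^2 = Omega / M,

where ``M`` is the mean single-cell protein number and ``CV^2`` its squared
coefficient of variation.  Omega is a signal-to-noise inflation factor:
Omega = 1 for Poissonian expression, larger under translational bursting or
promoter locking.  When protein numbers are Gamma distributed (the common
empirical finding for E. coli in balanced growth), Omega is exactly the Gamma
scale parameter and the skewness follows as S = 2 * sqrt(Omega / M).

Two analytic results connect Omega to kinetic parameters:

* one rate-limiting step transcription with translation and first-order
  RNA/protein decay gives ``Omega = 1 + k2 / (lambda1 + lambda2)``;
* a promoter that stochastically locks (ON -> OFF at ``k_minus``) and unlocks
  (OFF -> ON at ``k_plus``) inflates Omega relative to the always-ON model by
  a factor proportional to ``1 + k1 * k_minus / (k_plus + k_minus)**2``.

All functions are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GammaSpec",
    "cv2_from_omega",
    "predicted_skewness",
    "analytic_omega_one_step",
    "omega_ratio_on_off",
    "omega_ratio_peak",
    "gamma_from_moments",
    "moments_from_gamma",
]


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution parameterized by (shape, scale).

    For a protein-number ensemble with mean M and scaling constant Omega,
    shape = M / Omega and scale = Omega, so that mean = shape * scale and
    CV^2 = 1 / shape.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("GammaSpec requires shape > 0 and scale > 0")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def cv2(self) -> float:
        return 1.0 / self.shape

    @property
    def skewness(self) -> float:
        return 2.0 / np.sqrt(self.shape)

    @property
    def omega(self) -> float:
        return self.scale


def _require_positive(name: str, value) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ValueError(f"{name} must be strictly positive")


def cv2_from_omega(M, omega):
    """Squared coefficient of variation implied by the scaling CV^2 = Omega/M."""
    _require_positive("M", M)
    if np.any(np.asarray(omega) < 0):
        raise ValueError("omega must be non-negative")
    return omega / np.asarray(M, dtype=float)


def predicted_skewness(M, omega):
    """Skewness S = 2 * sqrt(Omega / M) of a Gamma protein-number distribution.

    Equivalent to the Gamma identity S = 2 / sqrt(shape) with shape = M/Omega.
    Only meaningful for ensembles that are well described by a Gamma law; callers
    should gate on a goodness-of-fit or noise-floor check first.
    """
    _require_positive("M", M)
    _require_positive("omega", omega)
    return 2.0 * np.sqrt(np.asarray(omega, dtype=float) / np.asarray(M, dtype=float))


def analytic_omega_one_step(k2, lambda1, lambda2):
    """Omega of the one-rate-limiting-step expression model.

    Omega = 1 + k2 / (lambda1 + lambda2), where k2 is the translation rate per
    RNA and lambda1, lambda2 the RNA and protein decay rates (all in 1/s).
    Equals 1 (Poisson) when translation is negligible and grows with the
    translational burst size.
    """
    k2 = np.asarray(k2, dtype=float)
    denom = np.asarray(lambda1, dtype=float) + np.asarray(lambda2, dtype=float)
    if np.any(k2 < 0):
        raise ValueError("k2 must be non-negative")
    if np.any(denom <= 0):
        raise ValueError("lambda1 + lambda2 must be strictly positive")
    return 1.0 + k2 / denom


def omega_ratio_on_off(k1, k_plus, k_minus):
    """Omega inflation factor of the ON-OFF (telegraph) promoter model.

    Returns ``1 + k1 * k_minus / (k_plus + k_minus)**2``, which is
    *proportional* to the ratio Omega_perturbed / Omega_reference when a
    locking step emerges; the proportionality constant is left to downstream
    fits (see :mod:`coldshock.dynamics`).  k1 is the transcription rate from
    the active promoter, k_minus the ON->OFF locking rate and k_plus the
    OFF->ON unlocking rate.
    """
    k1 = np.asarray(k1, dtype=float)
    kp = np.asarray(k_plus, dtype=float)
    km = np.asarray(k_minus, dtype=float)
    if np.any(k1 < 0) or np.any(kp < 0) or np.any(km < 0):
        raise ValueError("rates must be non-negative")
    if np.any(kp + km <= 0):
        raise ValueError("k_plus + k_minus must be strictly positive")
    return 1.0 + k1 * km / (kp + km) ** 2


def omega_ratio_peak(k1, k_plus):
    """Maximum of :func:`omega_ratio_on_off` over k_minus at fixed k_plus.

    The factor 1 + k1*k-/(k+ + k-)^2 is maximized at k_minus = k_plus, where it
    equals 1 + k1 / (4 * k_plus).
    """
    _require_positive("k_plus", k_plus)
    k1 = np.asarray(k1, dtype=float)
    if np.any(k1 < 0):
        raise ValueError("k1 must be non-negative")
    return 1.0 + k1 / (4.0 * np.asarray(k_plus, dtype=float))


def gamma_from_moments(M: float, omega: float) -> GammaSpec:
    """Gamma spec matching a mean M and scaling constant Omega exactly."""
    _require_positive("M", M)
    _require_positive("omega", omega)
    return GammaSpec(shape=float(M) / float(omega), scale=float(omega))


def moments_from_gamma(spec: GammaSpec) -> tuple[float, float]:
    """Inverse of :func:`gamma_from_moments`: (mean, omega)."""
    return spec.mean, spec.scale
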