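"""Hazard-to-probability transforms and 2x2 covariance/precision algebra.

Competing-risks demography for dead-recovery (band-recovery) models: annual
hunting and natural mortality are modelled as constant-within-year hazard
rates ``h_kappa`` and ``h_eta``.  Annual survival is ``S = exp(-(h_kappa +
h_eta))`` and the probability of dying of each cause is the hazard's share of
total mortality.  A recovered band further requires the bird to be retrieved
(probability ``1 - c`` with crippling loss ``c``) and reported (probability
``b``), giving the band-recovery probability ``f = kappa * (1 - c) * b``.

The module also provides the exact 2x2 covariance matrix

    Sigma = [[s1^2,      s1*s2*rho],
             [s1*s2*rho, s2^2     ]]

and its closed-form inverse (the precision matrix), plus *deliberately
incorrect* precision-matrix constructions that have appeared in the applied
literature.  Those are quarantined behind ``flawed_precision_*`` names: they
are diagnostic objects for demonstrating how mis-specifying a precision
matrix corrupts the implied correlation, and are never used for inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConstantRates",
    "HazardPoint",
    "DemographicProbs",
    "CovarianceSpec",
    "Matrix2x2",
    "FlawedPrecisionSpec",
    "hazards_to_probs",
    "covariance_matrix",
    "precision_matrix",
    "flawed_precision_reciprocal",
    "flawed_precision_diagonal",
    "implied_correlation",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class ConstantRates:
    """Fixed crippling-loss probability ``c`` and band-reporting probability ``b``."""

    c: float = 0.2
    b: float = 0.5

    def __post_init__(self) -> None:
        for name in ("c", "b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class HazardPoint:
    """Annual hunting (``h_kappa``) and natural (``h_eta``) mortality hazard rates."""

    h_kappa: float
    h_eta: float

    def __post_init__(self) -> None:
        for name in ("h_kappa", "h_eta"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class DemographicProbs:
    """Annual survival ``S``, natural mortality ``eta``, hunting mortality
    ``kappa`` and band-recovery ``f`` probabilities; ``S + eta + kappa = 1``."""

    S: float
    eta: float
    kappa: float
    f: float


@dataclass(frozen=True)
class CovarianceSpec:
    """Standard deviations and correlation of a bivariate normal.

    Order convention: component 1 is the hunting-hazard (or survival) axis,
    component 2 the natural-hazard (or recovery) axis.
    """

    sigma1: float
    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0.0 and math.isfinite(self.sigma1)):
            raise ValueError(f"sigma1 must be > 0, got {self.sigma1}")
        if not (self.sigma2 > 0.0 and math.isfinite(self.sigma2)):
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")


@dataclass(frozen=True)
class Matrix2x2:
    """A symmetric 2x2 matrix with a semantic role tag.

    ``role`` is ``"covariance"`` or ``"precision"``; entries are row-major.
    """

    a11: float
    a12: float
    a21: float
    a22: float
    role: str = "covariance"

    def __post_init__(self) -> None:
        if self.role not in ("covariance", "precision"):
            raise ValueError(f"unknown role {self.role!r}")
        if abs(self.a12 - self.a21) > _SYM_TOL * max(1.0, abs(self.a12)):
            raise ValueError("matrix is not symmetric within tolerance")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=float)

    @property
    def determinant(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    def is_positive_definite(self) -> bool:
        # 2x2: leading minor plus determinant suffice (Sylvester).
        return self.a11 > 0.0 and self.determinant > 0.0


@dataclass(frozen=True)
class FlawedPrecisionSpec:
    """Hyperparameters (omega11, omega22, rho_star) of the flawed
    precision-matrix construction reproduced by :func:`flawed_precision_diagonal`."""

    omega11: float
    omega22: float
    rho_star: float

    def __post_init__(self) -> None:
        if not (self.omega11 > 0.0 and math.isfinite(self.omega11)):
            raise ValueError(f"omega11 must be > 0, got {self.omega11}")
        if not (self.omega22 > 0.0 and math.isfinite(self.omega22)):
            raise ValueError(f"omega22 must be > 0, got {self.omega22}")
        if not (-1.0 < self.rho_star < 1.0):
            raise ValueError(f"rho_star must lie in (-1, 1), got {self.rho_star}")


def hazards_to_probs(h: HazardPoint, rates: ConstantRates) -> DemographicProbs:
    """Transform competing mortality hazards into annual probabilities.

    ``S = exp(-(h_kappa + h_eta))``; the complement ``1 - S`` is split between
    causes proportionally to their hazards; ``f = kappa * (1 - c) * b``.

    The double limit ``h_kappa = h_eta = 0`` is taken continuously:
    ``S = 1`` and both mortality probabilities are zero.
    """
    hk, he = h.h_kappa, h.h_eta
    total = hk + he
    S = math.exp(-total)
    if total == 0.0:
        kappa = eta = 0.0
    else:
        dead = -math.expm1(-total)  # 1 - S, accurate for small hazards
        kappa = dead * hk / total
        eta = dead * he / total
    f = kappa * (1.0 - rates.c) * rates.b
    return DemographicProbs(S=S, eta=eta, kappa=kappa, f=f)


def covariance_matrix(spec: CovarianceSpec) -> Matrix2x2:
    """Build the 2x2 covariance matrix from (sigma1, sigma2, rho)."""
    off = spec.sigma1 * spec.sigma2 * spec.rho
    return Matrix2x2(spec.sigma1**2, off, off, spec.sigma2**2, role="covariance")


def precision_matrix(spec: CovarianceSpec) -> Matrix2x2:
    """Closed-form inverse of :func:`covariance_matrix`.

    With ``d = sigma1^2 sigma2^2 (1 - rho^2)`` (the determinant), the inverse is
    ``[[sigma2^2, -sigma1 sigma2 rho], [-sigma1 sigma2 rho, sigma1^2]] / d``.
    """
    s1, s2, rho = spec.sigma1, spec.sigma2, spec.rho
    d = s1**2 * s2**2 * (1.0 - rho**2)
    off = -s1 * s2 * rho / d
    return Matrix2x2(s2**2 / d, off, off, s1**2 / d, role="precision")


def flawed_precision_reciprocal(sigma_s: float, sigma_f: float, rho_star: float) -> Matrix2x2:
    """INCORRECT precision matrix: reciprocal-covariance entries, reproduced verbatim.

    Returns ``[[1/sigma_s^2, rho*/(sigma_s sigma_f)], [rho*/(sigma_s sigma_f),
    1/sigma_f^2]]``.  This is *not* the inverse of the covariance matrix built
    from the same parameters (its product with that covariance is not the
    identity whenever ``rho* != 0``); it exists purely so the distortion it
    induces can be measured.  Never use for inference.
    """
    if not (sigma_s > 0.0 and math.isfinite(sigma_s)):
        raise ValueError(f"sigma_s must be > 0, got {sigma_s}")
    if not (sigma_f > 0.0 and math.isfinite(sigma_f)):
        raise ValueError(f"sigma_f must be > 0, got {sigma_f}")
    if not (-1.0 < rho_star < 1.0):
        raise ValueError(f"rho_star must lie in (-1, 1), got {rho_star}")
    off = rho_star / (sigma_s * sigma_f)
    return Matrix2x2(1.0 / sigma_s**2, off, off, 1.0 / sigma_f**2, role="precision")


def flawed_precision_diagonal(spec: FlawedPrecisionSpec) -> Matrix2x2:
    """INCORRECT precision matrix parameterized directly by its diagonal.

    Returns ``[[w11, sqrt(w11 w22) r*], [sqrt(w11 w22) r*, w22]]``.  The matrix
    is positive definite for ``|r*| < 1``, so it *is* a valid precision matrix
    — but the correlation of the bivariate normal it parameterizes is ``-r*``,
    the sign-flip of what its author intended (see
    :func:`implied_correlation`).  Quarantined diagnostic; never used for
    inference.
    """
    off = math.sqrt(spec.omega11 * spec.omega22) * spec.rho_star
    return Matrix2x2(spec.omega11, off, off, spec.omega22, role="precision")


def implied_correlation(precision: Matrix2x2 | np.ndarray) -> float:
    """Correlation of the bivariate normal parameterized by a precision matrix.

    Numerically inverts the precision matrix to a covariance and returns
    ``cov12 / sqrt(cov11 * cov22)``.  Raises on non-positive-definite input.
    """
    if isinstance(precision, Matrix2x2):
        if precision.role != "precision":
            raise ValueError("expected a matrix tagged as a precision matrix")
        arr = precision.as_array()
    else:
        arr = np.asarray(precision, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError(f"expected 2x2 matrix, got shape {arr.shape}")
        if abs(arr[0, 1] - arr[1, 0]) > _SYM_TOL * max(1.0, abs(arr[0, 1])):
            raise ValueError("precision matrix is not symmetric")
    if not (arr[0, 0] > 0.0 and np.linalg.det(arr) > 0.0):
        raise ValueError("precision matrix is not positive definite")
    cov = np.linalg.inv(arr)
    return float(cov[0, 1] / math.sqrt(cov[0, 0] * cov[1, 1]))
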