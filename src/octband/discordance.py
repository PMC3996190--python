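"""Relative-error discordance classification with a Gaussian confidence band.

An eye is assigned to the reference class when the relative error between its
measured target feature V and the value V_p predicted by the reference-trained
regressor,

    eps = (V_p - V) / V,

falls inside the band [mu - c*sigma, mu + c*sigma], where mu and sigma are the
mean and sd of the relative errors observed on the reference training set and
c is chosen through the Gaussian error function

    S(c) = erf(c / sqrt(2)),

the central probability mass of a normal distribution within +/- c sd
(c = 1.65 corresponds to 90% coverage).  Errors are computed on the original
target scale, where division by V is meaningful.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from scipy import special

from .errors import ValidationError

DEFAULT_C = 1.65


class BandLabel(str, enum.Enum):
    IN_REFERENCE_CLASS = "IN_REFERENCE_CLASS"
    OUT_OF_REFERENCE_CLASS = "OUT_OF_REFERENCE_CLASS"


def relative_error(v_pred, v_measured, *, absolute: bool = False):
    """Signed relative error (V_p - V) / V, elementwise.

    ``absolute=True`` returns |V_p - V| / |V| (one-sided mode; the default
    signed form is what the two-sided Gaussian band assumes).
    """
    v_pred = np.asarray(v_pred, dtype=float)
    v_measured = np.asarray(v_measured, dtype=float)
    if np.any(v_measured == 0):
        idx = np.flatnonzero(np.atleast_1d(v_measured) == 0)
        raise ValidationError(
            f"relative_error: measured value is 0 at position(s) {idx.tolist()}"
        )
    eps = (v_pred - v_measured) / v_measured
    if absolute:
        eps = np.abs(eps)
    return float(eps) if eps.ndim == 0 else eps


def gaussian_error_function(c: float) -> float:
    """Coverage S(c) = erf(c / sqrt(2)) of the band mu +/- c*sigma, c > 0."""
    if c <= 0:
        raise ValidationError(f"gaussian_error_function: c = {c} must be > 0")
    return float(special.erf(c / np.sqrt(2.0)))


def c_from_coverage(coverage: float) -> float:
    """Inverse of :func:`gaussian_error_function` on (0, 1)."""
    if not 0.0 < coverage < 1.0:
        raise ValidationError(f"c_from_coverage: coverage {coverage} outside (0, 1)")
    return float(np.sqrt(2.0) * special.erfinv(coverage))


@dataclasses.dataclass(frozen=True)
class ErrorBand:
    """Gaussian reference band for relative errors."""

    mu: float
    sigma: float
    c: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError(f"ErrorBand: sigma {self.sigma} < 0")
        if self.c <= 0:
            raise ValidationError(f"ErrorBand: c {self.c} must be > 0")

    @property
    def lower(self) -> float:
        return self.mu - self.c * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + self.c * self.sigma

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    @property
    def coverage(self) -> float:
        return gaussian_error_function(self.c)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "c": self.c,
            "coverage": self.coverage,
            "interval": list(self.interval),
        }


def fit_error_band(training_errors, c: float = DEFAULT_C) -> ErrorBand:
    """Band from the sample mean and sd (ddof=1) of the training errors.

    Requires at least two finite errors; a degenerate sd of 0 yields a point
    interval.
    """
    eps = np.asarray(training_errors, dtype=float).ravel()
    if eps.size < 2:
        raise ValidationError(
            f"fit_error_band: need >= 2 training errors, got {eps.size}"
        )
    if not np.isfinite(eps).all():
        raise ValidationError("fit_error_band: non-finite training errors")
    return ErrorBand(mu=float(eps.mean()), sigma=float(eps.std(ddof=1)), c=float(c))


def classify(eps, band: ErrorBand):
    """IN_REFERENCE_CLASS iff lower <= eps <= upper (closed interval).

    Accepts a scalar or an array; returns a label or an array of booleans
    (True = in band) for vectorized use.
    """
    arr = np.asarray(eps, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("classify: non-finite relative error")
    inside = (arr >= band.lower) & (arr <= band.upper)
    if arr.ndim == 0:
        return (
            BandLabel.IN_REFERENCE_CLASS
            if bool(inside)
            else BandLabel.OUT_OF_REFERENCE_CLASS
        )
    return inside
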