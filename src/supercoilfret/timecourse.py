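"""One-phase association fit of the fraction-unwound time course.

After the unwinding enzyme is added, the unwound fraction relaxes toward its
equilibrium value following first-order kinetics,

    f(t) = y0 + (plateau - y0) * (1 - exp(-k t)),

with t in minutes and k in 1/min.  The plateau reports the equilibrium extent
of unwinding, y0 the pre-existing unwound fraction, and k the apparent
association rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError

#: Sanity bounds on the fraction parameters; generous enough to tolerate
#: noise at the physical boundaries 0 and 1.
FRACTION_BOUNDS = (-0.2, 1.2)


@dataclass(frozen=True)
class TimeCoursePoint:
    """Unwound fraction measured at one timepoint."""

    t: float  # minutes
    f_unwound: float
    n_total: int = 0  # classified molecules behind the fraction (0 = unknown)

    def __post_init__(self):
        if self.t < 0:
            raise InvalidParameterError("timepoint must be non-negative")
        if not (0.0 <= self.f_unwound <= 1.0):
            raise InvalidParameterError("f_unwound must lie in [0, 1]")


def one_phase_association(t, y0, plateau, k):
    """Model function f(t) = y0 + (plateau - y0)(1 - exp(-k t))."""
    t = np.asarray(t, dtype=float)
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


@dataclass(frozen=True)
class AssociationFit:
    """Fitted one-phase association parameters with standard errors."""

    y0: float
    plateau: float
    k: float  # 1/min
    y0_se: float
    plateau_se: float
    k_se: float
    fit_residual: float
    increasing: bool
    k_identifiable: bool = True

    @property
    def k_per_second(self) -> float:
        return self.k / 60.0

    def predict(self, t):
        return one_phase_association(t, self.y0, self.plateau, self.k)


def fit_one_phase_association(
    points: Sequence[TimeCoursePoint],
    weights: Sequence[float] | None = None,
) -> AssociationFit:
    """Nonlinear least-squares fit of the one-phase association model.

    Parameters
    ----------
    points
        At least 4 points covering at least 3 distinct times.
    weights
        Optional per-point standard deviations (e.g. binomial errors
        ``sqrt(f(1-f)/n)``); used as ``sigma`` for inverse-variance
        weighting.

    Notes
    -----
    Initialization: y0 from the earliest point, plateau from the latest,
    k = 1/median(t).  A constant series is returned un-fitted with
    ``k_identifiable=False``; a decreasing series fits normally and is
    flagged via ``increasing=False``.
    """
    pts = sorted(points, key=lambda p: p.t)
    t = np.array([p.t for p in pts], dtype=float)
    f = np.array([p.f_unwound for p in pts], dtype=float)
    if t.size < 4 or np.unique(t).size < 3:
        raise InsufficientDataError(
            "association fit requires >= 4 points with >= 3 distinct times"
        )

    if np.ptp(f) < 1e-12:
        c = float(f[0])
        return AssociationFit(
            y0=c, plateau=c, k=float("nan"),
            y0_se=0.0, plateau_se=0.0, k_se=float("nan"),
            fit_residual=0.0, increasing=True, k_identifiable=False,
        )

    sigma = None
    if weights is not None:
        sigma = np.asarray(weights, dtype=float)
        if sigma.shape != t.shape:
            raise InvalidParameterError("weights must match the number of points")
        sigma = np.maximum(sigma, 1e-6)

    median_t = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
    p0 = (float(f[0]), float(f[-1]), 1.0 / median_t)
    lo, hi = FRACTION_BOUNDS
    bounds = ([lo, lo, 1e-9], [hi, hi, np.inf])
    try:
        popt, pcov = curve_fit(
            one_phase_association, t, f, p0=p0, sigma=sigma,
            absolute_sigma=sigma is not None, bounds=bounds, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "one-phase association fit did not converge", details=str(exc)
        ) from exc

    se = np.sqrt(np.diag(pcov))
    resid = f - one_phase_association(t, *popt)
    return AssociationFit(
        y0=float(popt[0]),
        plateau=float(popt[1]),
        k=float(popt[2]),
        y0_se=float(se[0]),
        plateau_se=float(se[1]),
        k_se=float(se[2]),
        fit_residual=float(np.sum(resid**2)),
        increasing=bool(popt[1] >= popt[0]),
    )


def binomial_weights(points: Sequence[TimeCoursePoint], floor: float = 1e-3) -> np.ndarray:
    """Binomial standard deviations ``sqrt(f(1-f)/n)`` for weighting the fit.

    Points with unknown counts (``n_total == 0``) receive the floor value.
    """
    pts = sorted(points, key=lambda p: p.t)
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        if p.n_total > 0:
            out[i] = max(np.sqrt(p.f_unwound * (1 - p.f_unwound) / p.n_total), floor)
        else:
            out[i] = floor
    return out
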