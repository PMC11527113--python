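"""Dwell-time survival analysis and kinetic rate decomposition.

Dwell times drawn from a single-rate exit process are exponential; the
empirical survival function (1 - CDF) of the collected dwells is fitted with

    y = y0 + A1 * exp(-k t)                                          (decay)

to estimate the exit rate k.  When the bound state exits through two
competing channels (dissociation at rate k_minus1 versus conversion to the
sliding clamp at rate k2), the fitted k is the composite k_minus1 + k2 and
the branch counts N2 (clamp formations) and N_minus1 (plain dissociations)
split it exactly:

    k2 = k * N2 / (N2 + N_minus1),    k_minus1 = k * N_minus1 / (N2 + N_minus1).

The association side is characterized by the event frequency k1 (binding
events per molecule per second at fixed protein concentration) and, in the
two-state binding assay, by the pseudo-first-order association rate k'_on
fitted from the waiting times between events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

#: Minimum number of dwells for a survival-curve fit.
MIN_DWELLS = 10


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival function of a set of dwell times.

    Without censoring, at the i-th sorted duration (1-based) survival equals
    1 - i/n, so the curve is right-continuous and reaches 0 at the longest
    dwell.  With right-censored observations the Kaplan-Meier product-limit
    estimate is used instead and the curve carries points at the complete
    (uncensored) dwell times only.
    """

    durations: np.ndarray
    survival: np.ndarray
    n_censored: int = 0

    @property
    def n(self) -> int:
        return self.durations.size


def one_minus_cdf(
    durations: Sequence[float], censored: Sequence[bool] | None = None
) -> SurvivalCurve:
    """Empirical 1-CDF of the dwell times.

    With ``censored=None`` all durations are complete dwells and the curve
    is the plain empirical survival function (sorted durations, survival =
    1 - i/n).  Passing a boolean right-censoring flag per duration switches
    to the Kaplan-Meier product-limit estimate: censored sojourns (cut off
    by the end of the observation window) contribute to the risk set up to
    their truncation time without being counted as exits.  Dropping them
    instead would condition on completion within the window and bias the
    dwell sample short.
    """
    d = np.asarray(durations, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise InvalidParameterError("durations must be positive and finite")

    if censored is None:
        if d.size < MIN_DWELLS:
            raise InsufficientDataError(
                f"survival curve requires >= {MIN_DWELLS} durations, got {d.size}"
            )
        d = np.sort(d)
        surv = 1.0 - np.arange(1, d.size + 1) / d.size
        return SurvivalCurve(durations=d, survival=surv)

    c = np.asarray(censored, dtype=bool)
    if c.shape != d.shape:
        raise InvalidParameterError("censored flags must match the durations")
    n_events = int(np.count_nonzero(~c))
    if n_events < MIN_DWELLS:
        raise InsufficientDataError(
            f"survival curve requires >= {MIN_DWELLS} complete dwells, got {n_events}"
        )
    # product-limit estimate; ties broken with events before censorings
    order = np.lexsort((c, d))
    d, c = d[order], c[order]
    at_risk = d.size - np.arange(d.size)
    surv = np.cumprod(np.where(c, 1.0, 1.0 - 1.0 / at_risk))
    keep = ~c
    return SurvivalCurve(
        durations=d[keep], survival=surv[keep], n_censored=int(np.count_nonzero(c))
    )


def exponential_decay(t, y0, a1, k):
    t = np.asarray(t, dtype=float)
    return y0 + a1 * np.exp(-k * t)


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential decay fit ``y = y0 + A1 exp(-k t)``."""

    y0: float
    a1: float
    k: float  # 1/s
    y0_se: float
    a1_se: float
    k_se: float
    fit_residual: float


def fit_single_exponential(curve: SurvivalCurve, fix_y0: float | None = None) -> ExpFit:
    """Least-squares single-exponential fit of a survival curve.

    Initialization: A1 = 1, y0 = 0, k = 1/mean(durations).  If ``fix_y0`` is
    given the offset is held at that value and only A1 and k are fitted.
    """
    t = curve.durations
    y = curve.survival
    k0 = 1.0 / float(np.mean(t))
    try:
        if fix_y0 is None:
            popt, pcov = curve_fit(
                exponential_decay, t, y, p0=(0.0, 1.0, k0),
                bounds=([-1.0, 0.0, 1e-12], [1.0, 2.0, np.inf]), maxfev=20000,
            )
            y0, a1, k = popt
            se = np.sqrt(np.diag(pcov))
            y0_se, a1_se, k_se = se
        else:
            def model(tt, a1, k):
                return exponential_decay(tt, fix_y0, a1, k)

            popt, pcov = curve_fit(
                model, t, y, p0=(1.0, k0),
                bounds=([0.0, 1e-12], [2.0, np.inf]), maxfev=20000,
            )
            a1, k = popt
            y0 = fix_y0
            se = np.sqrt(np.diag(pcov))
            y0_se, (a1_se, k_se) = 0.0, se
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "single-exponential fit did not converge", details=str(exc)
        ) from exc

    resid = y - exponential_decay(t, y0, a1, k)
    return ExpFit(
        y0=float(y0), a1=float(a1), k=float(k),
        y0_se=float(y0_se), a1_se=float(a1_se), k_se=float(k_se),
        fit_residual=float(np.sum(resid**2)),
    )


def exponential_rate_mle(durations: Sequence[float]) -> float:
    """Maximum-likelihood exit rate 1/mean for uncensored exponential dwells.

    Provided as an independent cross-check of the survival-curve fit; the
    two agree within a few percent on clean data.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise InsufficientDataError("no durations")
    return float(1.0 / np.mean(d))


def decompose_rates(k: float, n2: int, n_minus1: int) -> tuple[float, float]:
    """Split a composite exit rate by the observed branch counts.

    Returns ``(k2, k_minus1)`` with ``k2 = k * N2/(N2+N_minus1)`` and
    ``k_minus1 = k * N_minus1/(N2+N_minus1)``.  Pure algebra, no fitting.
    """
    if not np.isfinite(k) or k <= 0:
        raise InvalidParameterError(f"composite rate must be positive, got {k}")
    if n2 < 0 or n_minus1 < 0:
        raise InvalidParameterError("branch counts must be non-negative")
    total = n2 + n_minus1
    if total == 0:
        raise InvalidParameterError(
            "decomposition undefined: both branch counts are zero"
        )
    return k * n2 / total, k * n_minus1 / total


def decomposition_errors(
    k: float, k_se: float, n2: int, n_minus1: int
) -> tuple[float, float]:
    """Delta-method standard errors for the decomposed rates.

    Combines the fit error on k with the binomial error on the branch
    fraction p = N2/(N2+N_minus1):  var(k2) = p^2 var(k) + k^2 var(p).
    """
    total = n2 + n_minus1
    if total == 0:
        raise InvalidParameterError("both branch counts are zero")
    p = n2 / total
    var_p = p * (1 - p) / total
    se_k2 = math.sqrt(p * p * k_se * k_se + k * k * var_p)
    se_km1 = math.sqrt((1 - p) ** 2 * k_se * k_se + k * k * var_p)
    return se_k2, se_km1


def estimate_k1(n_events: int, n_molecules: int, observation_time: float) -> float:
    """Binding-event frequency per molecule per second (pseudo-first-order).

    ``n_events`` is the number of detected binding events pooled over
    ``n_molecules`` molecules each observed for ``observation_time`` seconds.
    """
    if n_molecules <= 0:
        raise InvalidParameterError("n_molecules must be positive")
    if observation_time <= 0:
        raise InvalidParameterError("observation_time must be positive")
    if n_events < 0:
        raise InvalidParameterError("event count must be non-negative")
    return n_events / (n_molecules * observation_time)


@dataclass(frozen=True)
class AdpKinetics:
    """Association/dissociation rates from the repetitive-binding assay."""

    k_off: float
    k_off_se: float
    k_on_pseudo: float
    k_on_pseudo_se: float
    ton_fit: ExpFit
    toff_fit: ExpFit


def estimate_adp_kinetics(
    ton: Sequence[float],
    toff: Sequence[float],
    ton_censored: Sequence[bool] | None = None,
    toff_censored: Sequence[bool] | None = None,
) -> AdpKinetics:
    """Dissociation and pseudo-first-order association rates.

    ``k_off`` is the survival-fit rate of the bound dwell times (t_on) and
    ``k'_on`` the survival-fit rate of the waiting times between events
    (t_off).  Right-censored sojourns may be included via the censoring
    flags (Kaplan-Meier survival construction).
    """
    ton_fit = fit_single_exponential(one_minus_cdf(ton, ton_censored))
    toff_fit = fit_single_exponential(one_minus_cdf(toff, toff_censored))
    return AdpKinetics(
        k_off=ton_fit.k,
        k_off_se=ton_fit.k_se,
        k_on_pseudo=toff_fit.k,
        k_on_pseudo_se=toff_fit.k_se,
        ton_fit=ton_fit,
        toff_fit=toff_fit,
    )


@dataclass
class RateSet:
    """Kinetic outputs of one experimental condition.

    All rates in 1/s.  ``k`` is the composite exit rate of the specifically
    bound state; when ``k_minus1`` and ``k2`` come from one decomposition of
    ``k`` they satisfy ``k_minus1 + k2 == k`` to machine precision.
    """

    label: str = ""
    k: float | None = None
    k_se: float | None = None
    k1: float | None = None
    k_minus1: float | None = None
    k_minus1_se: float | None = None
    k2: float | None = None
    k2_se: float | None = None
    k_on_pseudo: float | None = None
    k_on_pseudo_se: float | None = None
    k_off: float | None = None
    k_off_se: float | None = None

    def __post_init__(self):
        for name in ("k", "k1", "k_minus1", "k2", "k_on_pseudo", "k_off"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        if self.k is not None and self.k_minus1 is not None and self.k2 is not None:
            if abs((self.k_minus1 + self.k2) - self.k) > 1e-9 * max(self.k, 1.0):
                raise InvalidParameterError(
                    "k_minus1 + k2 must equal the composite rate k"
                )

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}
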