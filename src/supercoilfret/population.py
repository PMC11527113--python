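"""Three-Gaussian FRET-histogram decomposition and the fraction-unwound statistic.

Equilibrium FRET histograms of the unwinding assay show three populations:
a low-FRET donor-only artifact peak (molecules whose acceptor contributes no
sensitized emission), the unwound (R-loop) population, and the fully wound
high-FRET population.  The histogram is fitted with a weighted sum of three
Gaussian densities; the intersection points of adjacent components define the
classification thresholds that split molecules into artifact / unwound /
wound, from which the fraction of unwound molecules among all signal
molecules is computed.
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
    UndefinedFractionError,
)

#: Lower bound on fitted component widths, in FRET units.  Prevents the
#: optimizer from collapsing a component onto a single histogram bin.
SIGMA_FLOOR = 0.005

#: Default histogram bin width in FRET units.
DEFAULT_BIN_WIDTH = 0.02


@dataclass(frozen=True)
class GaussianComponent:
    """One weighted Gaussian population in a FRET histogram."""

    weight: float
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise InvalidParameterError(f"component sd must be > 0, got {self.sd}")
        if self.weight < 0:
            raise InvalidParameterError(f"component weight must be >= 0, got {self.weight}")

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mean) / self.sd
        return self.weight * np.exp(-0.5 * z * z) / (self.sd * math.sqrt(2 * math.pi))


@dataclass(frozen=True)
class Intersection:
    """Crossing point of two weighted Gaussians, with a fallback flag.

    ``fallback`` is True when no crossing lies strictly between the two means
    (one component dominates throughout) and the sd-weighted midpoint was
    returned instead.
    """

    x: float
    fallback: bool = False

    def __float__(self) -> float:
        return self.x


@dataclass(frozen=True)
class MixtureFit:
    """Result of a three-Gaussian histogram fit.

    Components are sorted by increasing mean; ``thresholds`` are the
    intersection points between components 1/2 and 2/3.
    """

    components: tuple[GaussianComponent, GaussianComponent, GaussianComponent]
    thresholds: tuple[Intersection, Intersection]
    fit_residual: float
    bin_width: float

    def __post_init__(self):
        means = [c.mean for c in self.components]
        if not (means[0] < means[1] < means[2]):
            raise InvalidParameterError("component means must be strictly increasing")

    @property
    def lower(self) -> float:
        return self.thresholds[0].x

    @property
    def upper(self) -> float:
        return self.thresholds[1].x

    def classification_rule(self) -> "ClassificationRule":
        return ClassificationRule(lower=self.lower, upper=self.upper)

    def pdf(self, x):
        return sum(c.pdf(x) for c in self.components)


@dataclass(frozen=True)
class ClassificationRule:
    """FRET window splitting molecules into unwound / wound / excluded.

    A value E is *unwound* iff ``lower < E < upper`` and counts toward the
    molecule total iff ``E > lower``; values at or below ``lower`` belong to
    the donor-only artifact peak and are excluded entirely.  Comparisons are
    strict, so a value exactly at a threshold falls outside the window.
    """

    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower < self.upper):
            raise InvalidParameterError(
                f"require lower < upper, got ({self.lower}, {self.upper})"
            )

    def is_unwound(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v > self.lower) & (v < self.upper)

    def is_counted(self, values) -> np.ndarray:
        return np.asarray(values, dtype=float) > self.lower


#: Fixed windows used in the reference analysis of the single PAM-proximal
#: mismatch and the triple PAM-distal mismatch experiments.
PAM_PROXIMAL_RULE = ClassificationRule(lower=0.14, upper=0.47)
PAM_DISTAL_RULE = ClassificationRule(lower=0.18, upper=0.51)


def _mixture_density(x, w1, m1, s1, w2, m2, s2, w3, m3, s3):
    out = np.zeros_like(x)
    for w, m, s in ((w1, m1, s1), (w2, m2, s2), (w3, m3, s3)):
        z = (x - m) / s
        out += w * np.exp(-0.5 * z * z) / (s * math.sqrt(2 * math.pi))
    return out


def fit_three_gaussians(
    values: Sequence[float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    init_means: Sequence[float] | None = None,
) -> MixtureFit:
    """Least-squares fit of a three-Gaussian mixture to the binned density.

    Parameters
    ----------
    values
        FRET efficiencies pooled over molecules (>= 100 required).
    bin_width
        Histogram bin width in FRET units.
    init_means
        Optional three initial mean guesses; defaults to the 10th/50th/90th
        percentiles of the data.

    Returns
    -------
    MixtureFit with components sorted by mean and the two intersection
    thresholds between adjacent components.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise InsufficientDataError(
            f"three-Gaussian fit requires >= 100 values, got {v.size}"
        )
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    spread = float(np.ptp(v))
    if spread < 1e-12 or np.std(v) < 1e-12:
        raise FitFailureError("zero-variance histogram: all FRET values identical")

    lo = math.floor(v.min() / bin_width) * bin_width
    hi = math.ceil(v.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 3)
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (v.size * bin_width)

    if init_means is None:
        init_means = np.percentile(v, [10, 50, 90])
    init_means = np.sort(np.asarray(init_means, dtype=float))
    if np.any(np.diff(init_means) < 1e-6):
        # e.g. heavily peaked data: spread the guesses over the data range
        init_means = lo + np.array([0.2, 0.5, 0.8]) * (hi - lo)
    sd0 = max(spread / 12.0, 2 * SIGMA_FLOOR)
    p0 = []
    for m in init_means:
        p0.extend([1.0 / 3.0, m, sd0])

    lower_bounds = [0.0, lo - spread, SIGMA_FLOOR] * 3
    upper_bounds = [np.inf, hi + spread, max(spread, 1.0)] * 3

    try:
        popt, _ = curve_fit(
            _mixture_density,
            centers,
            density,
            p0=p0,
            bounds=(lower_bounds, upper_bounds),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "three-Gaussian fit did not converge", details=str(exc)
        ) from exc

    residual = float(np.sum((density - _mixture_density(centers, *popt)) ** 2))
    comps = sorted(
        (
            GaussianComponent(weight=popt[3 * i], mean=popt[3 * i + 1], sd=popt[3 * i + 2])
            for i in range(3)
        ),
        key=lambda c: c.mean,
    )
    means = [c.mean for c in comps]
    if min(np.diff(means)) < 1e-9:
        raise FitFailureError(
            "degenerate mixture: two components converged onto the same mean",
            details={"means": means},
        )
    thresholds = (
        gaussian_intersection(comps[0], comps[1]),
        gaussian_intersection(comps[1], comps[2]),
    )
    return MixtureFit(
        components=tuple(comps),
        thresholds=thresholds,
        fit_residual=residual,
        bin_width=bin_width,
    )


def gaussian_intersection(c1: GaussianComponent, c2: GaussianComponent) -> Intersection:
    """Crossing point of two weighted Gaussian densities between their means.

    Solves ``w1 N(x; m1, s1) = w2 N(x; m2, s2)`` (a quadratic in x after
    taking logs) and returns the root strictly inside ``(m1, m2)``.  If no
    root lies between the means — one component dominates the whole interval
    — the sd-weighted midpoint ``(s2*m1 + s1*m2)/(s1 + s2)`` is returned with
    ``fallback=True``.
    """
    if c2.mean <= c1.mean:
        if c2.mean == c1.mean:
            raise InvalidParameterError("components must have distinct means")
        c1, c2 = c2, c1
    if c1.weight <= 0 or c2.weight <= 0:
        raise InvalidParameterError("both component weights must be > 0")

    m1, s1, w1 = c1.mean, c1.sd, c1.weight
    m2, s2, w2 = c2.mean, c2.sd, c2.weight
    log_term = math.log((w1 * s2) / (w2 * s1))

    if abs(s1 - s2) < 1e-14:
        # equal variances: the quadratic degenerates to a line
        s2_ = s1 * s1
        x = 0.5 * (m1 + m2) + s2_ * log_term / (m2 - m1)
        roots = [x]
    else:
        a = 1.0 / (2 * s2 * s2) - 1.0 / (2 * s1 * s1)
        b = m1 / (s1 * s1) - m2 / (s2 * s2)
        c = m2 * m2 / (2 * s2 * s2) - m1 * m1 / (2 * s1 * s1) + log_term
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]

    inside = [x for x in roots if m1 < x < m2]
    if inside:
        return Intersection(x=min(inside, key=lambda x: abs(x - 0.5 * (m1 + m2))))
    return Intersection(x=(s2 * m1 + s1 * m2) / (s1 + s2), fallback=True)


@dataclass(frozen=True)
class UnwoundFraction:
    """Fraction of unwound molecules with the raw classification counts."""

    fraction: float
    n_unwound: int
    n_total: int
    n_excluded: int


def fraction_unwound(values: Sequence[float], rule: ClassificationRule) -> UnwoundFraction:
    """Unwound fraction ``N(lower < E < upper) / N(E > lower)``.

    Values at or below ``rule.lower`` (the donor-only artifact peak) are
    excluded from numerator and denominator alike.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    counted = rule.is_counted(v)
    n_total = int(np.count_nonzero(counted))
    if n_total == 0:
        raise UndefinedFractionError(
            f"no FRET values above the lower threshold {rule.lower}"
        )
    n_unwound = int(np.count_nonzero(rule.is_unwound(v)))
    return UnwoundFraction(
        fraction=n_unwound / n_total,
        n_unwound=n_unwound,
        n_total=n_total,
        n_excluded=int(v.size - n_total),
    )
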