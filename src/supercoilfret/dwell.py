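"""Trajectory idealization, dwell extraction and binding-event segmentation.

Two complementary discretizations are provided:

* :func:`hmm_idealize` — a per-trace maximum-likelihood Gaussian-emission
  hidden Markov model (EM training followed by Viterbi decoding) that turns a
  noisy FRET trajectory into a discrete state path.  Used for the continuous
  two-state wound/unwound dynamics.
* :func:`segment_binding_events` — deterministic intensity/FRET-threshold
  segmentation of protein-binding movies, where a binding event is a rise of
  total fluorescence out of darkness and the FRET level within the event
  distinguishes specific mismatch binding (high FRET) from the sliding-clamp
  state (low FRET).

Dwell records and event records carry explicit censoring flags: sojourns
truncated by the start or end of the observation window must not enter rate
fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM

# the EM monitor logs a warning for sub-tolerance negative log-likelihood
# deltas (numerical convergence); keep the per-trace fits quiet
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

from .errors import (
    ConfigurationError,
    ContractViolationError,
    InvalidParameterError,
)
from .traces import FretTrajectory, Trace

Outcome = Literal["dissociated", "clamp"]

#: Minimum number of consecutive low-FRET frames required to call a
#: sliding-clamp conversion (suppresses single-frame noise artifacts).
MIN_CLAMP_FRAMES = 3


# ---------------------------------------------------------------------------
# HMM idealization
# ---------------------------------------------------------------------------

@dataclass
class IdealizedPath:
    """Discrete state path of one trajectory.

    States are relabeled in increasing emission-mean order, so state 0 is
    always the lowest-FRET state.
    """

    states: np.ndarray  # int label per donor-excitation frame
    means: np.ndarray  # emission mean per state
    sds: np.ndarray  # emission sd per state
    log_likelihood: float
    frame_interval: float
    converged: bool = True
    degenerate: bool = False

    def __len__(self) -> int:
        return self.states.size


def _fill_nan_labels(labels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Assign each frame the label of its nearest preceding valid frame.

    Leading invalid frames take the first valid label.
    """
    pos = np.flatnonzero(valid)
    if pos.size == 0:
        return np.zeros(valid.size, dtype=int)
    prev = np.searchsorted(pos, np.arange(valid.size), side="right") - 1
    prev = np.clip(prev, 0, pos.size - 1)
    return np.asarray(labels, dtype=int)[prev]


def hmm_idealize(
    traj: FretTrajectory,
    n_states: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> IdealizedPath:
    """Maximum-likelihood two-state (or three-state) idealization of a trace.

    A Gaussian-emission HMM is trained per trajectory by EM (at most
    ``max_iter`` iterations, log-likelihood tolerance ``tol``) from a
    deterministic initialization — state means at the 25th/75th percentiles
    of the data (25/50/75 for three states), equal variances, uniform start
    and transition probabilities — and the Viterbi path is returned.  The
    procedure is deterministic given the trajectory.

    Degenerate trajectories (essentially constant signal) return an all-zero
    path with ``degenerate=True`` instead of raising.
    """
    if n_states not in (2, 3):
        raise InvalidParameterError("n_states must be 2 or 3")
    if len(traj) < 10:
        raise ContractViolationError(
            f"trajectory has {len(traj)} frames; >= 10 required for idealization"
        )

    e = traj.E
    valid = np.isfinite(e)
    x = e[valid].reshape(-1, 1)
    if x.size < 10 or float(np.std(x)) < 1e-6:
        mean = float(np.mean(x)) if x.size else float("nan")
        return IdealizedPath(
            states=np.zeros(len(traj), dtype=int),
            means=np.full(n_states, mean),
            sds=np.zeros(n_states),
            log_likelihood=float("nan"),
            frame_interval=traj.frame_interval,
            converged=True,
            degenerate=True,
        )

    percentiles = (25, 75) if n_states == 2 else (25, 50, 75)
    means0 = np.percentile(x, percentiles).reshape(-1, 1)
    var0 = max(float(np.var(x)), 1e-6)

    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="stmc",
        min_covar=1e-6,
    )
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.transmat_ = np.full((n_states, n_states), 1.0 / n_states)
    model.means_ = means0
    model.covars_ = np.full((n_states, 1), var0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x)
        converged = bool(model.monitor_.converged)
        logprob, labels = model.decode(x)

    fitted_means = model.means_.ravel()
    fitted_sds = np.sqrt(model.covars_.reshape(n_states, -1)[:, 0])
    order = np.argsort(fitted_means)
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(n_states)
    labels = relabel[labels]
    means = fitted_means[order]
    sds = fitted_sds[order]

    sep = np.min(np.diff(means)) if n_states > 1 else np.inf
    degenerate = bool(sep < max(np.max(sds) * 0.1, 1e-4))

    states = _fill_nan_labels(labels, valid)
    return IdealizedPath(
        states=states,
        means=means,
        sds=sds,
        log_likelihood=float(logprob),
        frame_interval=traj.frame_interval,
        converged=converged,
        degenerate=degenerate,
    )


def threshold_idealize(traj: FretTrajectory, split: float) -> IdealizedPath:
    """Two-state idealization by a fixed FRET threshold.

    Frame-wise rule: state 1 iff E > split.  Serves as a transparent
    reference discretization against which the HMM path can be compared.
    """
    e = traj.E
    valid = np.isfinite(e)
    labels = (e[valid] > split).astype(int)
    states = _fill_nan_labels(labels, valid)
    means = np.array([
        float(np.mean(e[valid][labels == 0])) if np.any(labels == 0) else np.nan,
        float(np.mean(e[valid][labels == 1])) if np.any(labels == 1) else np.nan,
    ])
    return IdealizedPath(
        states=states,
        means=means,
        sds=np.full(2, np.nan),
        log_likelihood=float("nan"),
        frame_interval=traj.frame_interval,
    )


# ---------------------------------------------------------------------------
# Dwell extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DwellRecord:
    """One maximal sojourn of an idealized path in a single state."""

    state: int
    duration: float  # seconds = run length * frame interval
    censored_left: bool
    censored_right: bool
    next_state: int | None  # None at the end of the trace

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right


def extract_dwells(
    path: IdealizedPath, frame_interval: float | None = None
) -> list[DwellRecord]:
    """Dwell records for each maximal constant-state run of the path.

    The first and last runs are flagged left-/right-censored: their true
    durations extend beyond the observation window.
    """
    if frame_interval is None:
        frame_interval = path.frame_interval
    s = np.asarray(path.states)
    if s.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [s.size]))
    records = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        records.append(
            DwellRecord(
                state=int(s[a]),
                duration=float((b - a) * frame_interval),
                censored_left=(i == 0),
                censored_right=(i == len(starts) - 1),
                next_state=int(s[b]) if b < s.size else None,
            )
        )
    return records


def uncensored_durations(dwells: Sequence[DwellRecord], state: int) -> np.ndarray:
    """Durations of uncensored dwells in ``state``, ready for rate fitting."""
    return np.array(
        [d.duration for d in dwells if d.state == state and not d.censored]
    )


# ---------------------------------------------------------------------------
# Binding-event segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventRecord:
    """One protein-binding event with its kinetic outcome.

    ``t_sb`` is the dwell of the initial high-FRET (specifically bound)
    segment; ``outcome`` says whether it ended by dissociation (return to
    darkness) or by conversion to the low-FRET sliding clamp.
    ``preceding_wait`` is the darkness interval before the event (the
    waiting time t_off); ``wait_censored`` marks waits truncated by the
    start of the observation window.
    """

    molecule_id: int
    t_start: float
    t_end: float  # end of the bound run within the donor window
    t_sb: float
    outcome: Outcome | None
    preceding_wait: float
    censored_left: bool = False
    censored_right: bool = False
    wait_censored: bool = False

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right

    @property
    def uncensored(self) -> bool:
        return not self.censored and self.outcome is not None


def segment_binding_events(
    trace: Trace,
    intensity_threshold: float,
    fret_split: float,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    min_clamp_frames: int = MIN_CLAMP_FRAMES,
) -> list[EventRecord]:
    """Detect binding events in a protein-binding movie and label outcomes.

    An event is a maximal run of donor-excitation frames whose raw total
    intensity (donor + acceptor) exceeds ``intensity_threshold``.  Within an
    event, frames are split at ``fret_split`` into high (specific binding)
    and low (sliding clamp); ``t_sb`` is the duration of the initial
    contiguous high-FRET segment.  The outcome is ``"clamp"`` when that
    segment is immediately followed by at least ``min_clamp_frames``
    consecutive low-FRET frames, ``"dissociated"`` when the event ends from
    the high state; shorter low-FRET runs bounded by high frames on both
    sides are absorbed as noise.  Events touching either end of the
    observation window are censored.
    """
    bg_total = background_donor + background_acceptor
    if intensity_threshold <= bg_total:
        raise ConfigurationError(
            f"intensity threshold {intensity_threshold} must exceed the "
            f"summed background level {bg_total}"
        )

    idx = trace.schedule.donor_frames()
    if idx.size == 0:
        raise ContractViolationError("trace has no donor-excitation frames")
    dt = trace.frame_interval
    donor = trace.donor[idx]
    acceptor = trace.acceptor[idx]
    total = donor + acceptor
    bound = total > intensity_threshold

    a = acceptor - background_acceptor
    d = donor - background_donor
    denom = a + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, a / denom, np.nan)
    high = e > fret_split  # NaN compares False -> treated as low

    boundaries = np.flatnonzero(np.diff(bound.astype(int)))
    starts = [0] if bound[0] else []
    starts += [b + 1 for b in boundaries if not bound[b]]
    ends = [b + 1 for b in boundaries if bound[b]]
    if bound[-1]:
        ends.append(bound.size)

    events: list[EventRecord] = []
    prev_end = 0  # donor-window frame where the current darkness began
    first_event = True
    for s0, s1 in zip(starts, ends):
        censored_left = s0 == 0
        censored_right = s1 == bound.size
        wait_frames = s0 - prev_end
        # the darkness preceding the first event started before observation
        wait_censored = first_event
        first_event = False
        prev_end = s1

        ev_high = high[s0:s1]
        high_idx = np.flatnonzero(ev_high)
        if high_idx.size == 0:
            continue  # no specific-binding signature; not a scored event
        i = int(high_idx[0])
        n_ev = ev_high.size
        outcome: Outcome | None = None
        sb_end = i
        while True:
            j = i
            while j < n_ev and ev_high[j]:
                j += 1
            sb_end = j
            # low run following the high segment
            m = j
            while m < n_ev and not ev_high[m]:
                m += 1
            low_len = m - j
            if low_len >= min_clamp_frames:
                outcome = "clamp"
                break
            if m >= n_ev:
                # event ends from the high state (short low tail = noise)
                outcome = None if censored_right else "dissociated"
                break
            i = m  # absorb the short low run and keep scanning

        events.append(
            EventRecord(
                molecule_id=trace.molecule_id,
                t_start=float(s0 * dt),
                t_end=float(s1 * dt),
                t_sb=float((sb_end - int(high_idx[0])) * dt),
                outcome=outcome,
                preceding_wait=float(wait_frames * dt),
                censored_left=censored_left,
                censored_right=censored_right and outcome is None,
                wait_censored=wait_censored,
            )
        )
    return events


def count_branches(events: Sequence[EventRecord]) -> tuple[int, int]:
    """Branch counts ``(N2, N_minus1)`` over uncensored events.

    N2 counts sliding-clamp conversions, N_minus1 plain dissociations;
    censored events contribute to neither.
    """
    n2 = sum(1 for e in events if e.uncensored and e.outcome == "clamp")
    nm1 = sum(1 for e in events if e.uncensored and e.outcome == "dissociated")
    return n2, nm1


def derive_fret_split(event_values: Sequence[float], default: float = 0.5) -> float:
    """Data-driven high/low FRET split from the event-frame FRET histogram.

    Fits two Gaussians to the pooled in-event FRET values and returns their
    intersection; falls back to ``default`` when the histogram is unimodal
    (e.g. a no-clamp dataset) or the fit fails.
    """
    from .population import GaussianComponent, gaussian_intersection
    from scipy.optimize import curve_fit as _curve_fit
    import math as _math

    v = np.asarray(event_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        return default

    def two_gauss(x, w1, m1, s1, w2, m2, s2):
        out = np.zeros_like(x)
        for w, m, s in ((w1, m1, s1), (w2, m2, s2)):
            z = (x - m) / s
            out += w * np.exp(-0.5 * z * z) / (s * _math.sqrt(2 * _math.pi))
        return out

    counts, edges = np.histogram(v, bins=50, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    m_lo, m_hi = np.percentile(v, [20, 80])
    try:
        popt, _ = _curve_fit(
            two_gauss, centers, counts,
            p0=(0.5, m_lo, 0.08, 0.5, m_hi, 0.08),
            bounds=([0, -0.5, 0.005, 0, -0.5, 0.005], [np.inf, 1.5, 1.0, np.inf, 1.5, 1.0]),
            maxfev=10000,
        )
        c1 = GaussianComponent(weight=popt[0], mean=popt[1], sd=popt[2])
        c2 = GaussianComponent(weight=popt[3], mean=popt[4], sd=popt[5])
        if abs(c1.mean - c2.mean) < 0.1:
            return default
        return gaussian_intersection(c1, c2).x
    except Exception:
        return default
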