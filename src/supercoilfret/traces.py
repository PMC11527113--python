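"""Two-color intensity trajectories, FRET computation and molecule filters.

A movie in these experiments alternates between two excitation lasers: the
donor laser reports FRET (donor + sensitized acceptor emission), while direct
acceptor excitation reports whether the acceptor dye is present and
photoactive at all.  The :class:`ExcitationSchedule` records which frames were
acquired under which laser; :class:`Trace` couples the per-frame intensities
of one molecule to that schedule.

FRET efficiency is computed as the background-corrected proximity ratio

    E = (I_A - b_A) / ((I_A - b_A) + gamma * (I_D - b_D))

with ``gamma`` (detection-efficiency correction) defaulting to 1.  Frames in
which the corrected total intensity is non-positive (both dyes dark) carry no
distance information and are marked NaN rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import ContractViolationError, InvalidParameterError

Channel = Literal["donor_ex", "acceptor_ex"]

DONOR_EX: Channel = "donor_ex"
ACCEPTOR_EX: Channel = "acceptor_ex"


@dataclass(frozen=True)
class ExcitationSchedule:
    """Ordered, contiguous excitation segments covering ``[0, n_frames)``.

    Each segment is ``(start_frame, end_frame, channel)`` with 0-based,
    half-open frame ranges.
    """

    segments: tuple[tuple[int, int, Channel], ...]

    def __post_init__(self):
        if not self.segments:
            raise ContractViolationError("schedule must contain at least one segment")
        prev_end = 0
        for start, end, channel in self.segments:
            if channel not in (DONOR_EX, ACCEPTOR_EX):
                raise ContractViolationError(f"unknown excitation channel {channel!r}")
            if start != prev_end:
                raise ContractViolationError(
                    f"segments must be contiguous: segment starts at {start}, "
                    f"previous ended at {prev_end}"
                )
            if end <= start:
                raise ContractViolationError("empty or inverted schedule segment")
            prev_end = end

    @property
    def n_frames(self) -> int:
        return self.segments[-1][1]

    def channel_mask(self, channel: Channel) -> np.ndarray:
        """Boolean mask over frames acquired under ``channel``."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for start, end, ch in self.segments:
            if ch == channel:
                mask[start:end] = True
        return mask

    def donor_frames(self) -> np.ndarray:
        return np.flatnonzero(self.channel_mask(DONOR_EX))

    def final_acceptor_segment(self) -> tuple[int, int]:
        """Frame range of the last direct acceptor-excitation segment."""
        for start, end, ch in reversed(self.segments):
            if ch == ACCEPTOR_EX:
                return start, end
        raise ContractViolationError(
            f"schedule {self.segments!r} contains no acceptor-excitation segment"
        )

    # -- standard acquisition layouts ------------------------------------

    @classmethod
    def cas9_snapshot(cls) -> "ExcitationSchedule":
        """Short movie: 10 donor-excitation frames then 10 acceptor frames."""
        return cls(((0, 10, DONOR_EX), (10, 20, ACCEPTOR_EX)))

    @classmethod
    def cas9_dynamics(cls) -> "ExcitationSchedule":
        """Long donor-excitation movie flanked by acceptor-check frames."""
        return cls(((0, 10, ACCEPTOR_EX), (10, 990, DONOR_EX), (990, 1000, ACCEPTOR_EX)))

    @classmethod
    def muts_adp(cls) -> "ExcitationSchedule":
        """10 + 980 + 10 frame layout used for binding/dissociation movies."""
        return cls(((0, 10, ACCEPTOR_EX), (10, 990, DONOR_EX), (990, 1000, ACCEPTOR_EX)))

    @classmethod
    def muts_atp(cls) -> "ExcitationSchedule":
        """10 + 1480 + 10 frame layout used for sliding-clamp movies."""
        return cls(((0, 10, ACCEPTOR_EX), (10, 1490, DONOR_EX), (1490, 1500, ACCEPTOR_EX)))


@dataclass
class Trace:
    """Per-frame donor/acceptor intensities of one molecule."""

    molecule_id: int
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    schedule: ExcitationSchedule
    condition: str = ""

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = self.schedule.n_frames
        if self.donor.shape != (n,) or self.acceptor.shape != (n,):
            raise ContractViolationError(
                f"trace length must match schedule length {n}; got donor "
                f"{self.donor.shape}, acceptor {self.acceptor.shape}"
            )
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be positive")


@dataclass
class FretTrajectory:
    """FRET efficiency per donor-excitation frame, with frame times in seconds."""

    molecule_id: int
    E: np.ndarray
    times: np.ndarray
    frame_interval: float
    condition: str = ""

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.E.shape != self.times.shape:
            raise ContractViolationError("E and times must have equal length")

    def __len__(self) -> int:
        return self.E.size


def compute_fret(
    trace: Trace,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    gamma: float = 1.0,
) -> FretTrajectory:
    """Proximity-ratio FRET efficiency over the donor-excitation frames.

    Frames whose corrected total intensity is <= 0 are returned as NaN.
    """
    if not np.isfinite(gamma) or gamma <= 0:
        raise InvalidParameterError(f"gamma must be positive and finite, got {gamma}")
    if not (np.isfinite(background_donor) and np.isfinite(background_acceptor)):
        raise InvalidParameterError("backgrounds must be finite")

    idx = trace.schedule.donor_frames()
    a = trace.acceptor[idx] - background_acceptor
    d = trace.donor[idx] - background_donor
    denom = a + gamma * d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, a / denom, np.nan)
    times = idx * trace.frame_interval
    return FretTrajectory(
        molecule_id=trace.molecule_id,
        E=e,
        times=times,
        frame_interval=trace.frame_interval,
        condition=trace.condition,
    )


def acceptor_present(trace: Trace, threshold: float, background: float = 0.0) -> bool:
    """True iff the molecule shows a live acceptor in the final check segment.

    The median acceptor intensity over the last direct acceptor-excitation
    segment must exceed ``background + threshold``.  Molecules failing this
    test have an inactive, missing or bleached acceptor and are excluded from
    FRET analysis.
    """
    start, end = trace.schedule.final_acceptor_segment()
    return float(np.median(trace.acceptor[start:end])) > background + threshold


def filter_acceptor_present(
    traces: Sequence[Trace], threshold: float, background: float = 0.0
) -> list[Trace]:
    """Subset of ``traces`` passing :func:`acceptor_present`. Never mutates."""
    return [t for t in traces if acceptor_present(t, threshold, background)]


#: 0-based slice of donor-excitation frames used for population histograms
#: (ordinal frames three to seven of the FRET trajectory).
HISTOGRAM_FRAME_SLICE = slice(2, 7)


def select_histogram_frames(traj: FretTrajectory) -> np.ndarray:
    """The five FRET values entering the population histogram.

    Ordinal donor-excitation frames 3..7 (1-based), i.e. indices 2..6.  NaN
    frames (no measurable signal) are dropped, so fewer than five values may
    be returned.
    """
    if len(traj) < 7:
        raise ContractViolationError(
            f"trajectory of molecule {traj.molecule_id} has {len(traj)} "
            "donor-excitation frames; at least 7 are required"
        )
    vals = traj.E[HISTOGRAM_FRAME_SLICE]
    return vals[np.isfinite(vals)]
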