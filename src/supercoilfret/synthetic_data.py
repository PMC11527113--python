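"""Seeded synthetic single-molecule FRET datasets for both experiment archetypes.

Two generative archetypes are covered:

* **Unwinding snapshots** — each molecule is an immobilized plasmid carrying a
  donor/acceptor pair across the protospacer.  At every sampled timepoint the
  molecule is unwound with probability
  ``f(t) = y0 + (plateau - y0)(1 - exp(-k t))`` and its histogram FRET values
  are drawn from the corresponding Gaussian population (a donor-only artifact
  population is mixed in with a fixed weight).  The state is drawn at the
  sampling instant (quasi-static approximation): the short movies integrate
  over ~1 s of dynamics, far below the minutes-scale relaxation they sample.
* **Protein-binding movies** — the acceptor sits on the DNA near a mismatch
  and the donor on the protein.  Binding events arrive as a renewal process
  (exponential waits from the previous event's end at rate ``k_arrival``);
  each bound sojourn lasts ``Exp(k_dissoc + k_clamp)`` and exits either to
  darkness (dissociation) or to the low-FRET sliding-clamp state with
  probability ``k_clamp / (k_dissoc + k_clamp)``.

Continuous-time state paths are generated with the Gillespie algorithm and
rendered to per-frame donor/acceptor intensities under an excitation
schedule, with Gaussian (optionally Poisson) channel noise, photobleaching,
and inactive-acceptor molecules.  One master seed determines everything;
per-molecule streams are derived from the molecule index, so a dataset is
bit-identical for identical configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ContractViolationError, InvalidParameterError
from .traces import (
    ACCEPTOR_EX,
    DONOR_EX,
    ExcitationSchedule,
    Trace,
)

# state labels, shared with the truth tables
WOUND, UNWOUND = 0, 1
DARK, BOUND, CLAMP = 0, 1, 2


class Emission(NamedTuple):
    """Gaussian FRET emission of one kinetic state."""

    mean: float
    sd: float


def _as_emission(value) -> Emission:
    em = Emission(*value)
    if not (0.0 <= em.mean <= 1.0):
        raise InvalidParameterError(f"FRET mean must lie in [0, 1], got {em.mean}")
    if em.sd < 0:
        raise InvalidParameterError(f"FRET sd must be >= 0, got {em.sd}")
    return em


def _check_rate(name: str, value: float, allow_zero: bool = True):
    if not np.isfinite(value) or value < 0 or (value == 0 and not allow_zero):
        raise InvalidParameterError(f"{name} must be a finite non-negative rate, got {value}")


# ---------------------------------------------------------------------------
# Kinetic schemes
# ---------------------------------------------------------------------------

@dataclass
class TwoStateKinetics:
    """Reversible wound <-> unwound dynamics (rates k1 and k-1, in 1/s)."""

    k_unwind: float
    k_rewind: float
    fret_wound: Emission = Emission(0.72, 0.02)
    fret_unwound: Emission = Emission(0.30, 0.02)

    def __post_init__(self):
        _check_rate("k_unwind", self.k_unwind)
        _check_rate("k_rewind", self.k_rewind)
        self.fret_wound = _as_emission(self.fret_wound)
        self.fret_unwound = _as_emission(self.fret_unwound)

    def transitions(self):
        return {
            WOUND: ((self.k_unwind, UNWOUND),),
            UNWOUND: ((self.k_rewind, WOUND),),
        }

    def emissions(self):
        return {WOUND: self.fret_wound, UNWOUND: self.fret_unwound}

    start_state = WOUND


@dataclass
class SnapshotKinetics:
    """One-phase association population dynamics for the snapshot assay.

    ``k_assoc`` is in 1/min; ``y0`` and ``plateau`` are unwound fractions.
    Each FRET population is a Gaussian; ``donor_only_weight`` is the
    probability that a molecule belongs to the donor-only artifact peak
    (the unwound/wound split of the remaining signal molecules is dictated
    by the association law, not by free weights).
    """

    k_assoc: float
    plateau: float
    y0: float
    fret_donor_only: Emission = Emission(0.06, 0.04)
    fret_unwound: Emission = Emission(0.32, 0.06)
    fret_wound: Emission = Emission(0.72, 0.07)
    donor_only_weight: float = 0.15

    def __post_init__(self):
        _check_rate("k_assoc", self.k_assoc)
        if not (0.0 <= self.y0 <= self.plateau <= 1.0):
            raise InvalidParameterError(
                f"require 0 <= y0 <= plateau <= 1, got y0={self.y0}, plateau={self.plateau}"
            )
        if not (0.0 <= self.donor_only_weight < 1.0):
            raise InvalidParameterError("donor_only_weight must lie in [0, 1)")
        self.fret_donor_only = _as_emission(self.fret_donor_only)
        self.fret_unwound = _as_emission(self.fret_unwound)
        self.fret_wound = _as_emission(self.fret_wound)

    def fraction_unwound_at(self, t_minutes: float) -> float:
        return self.y0 + (self.plateau - self.y0) * (1.0 - math.exp(-self.k_assoc * t_minutes))

    def component_emissions(self) -> tuple[Emission, Emission, Emission]:
        """(donor-only, unwound, wound) populations, indexed 0/1/2."""
        return (self.fret_donor_only, self.fret_unwound, self.fret_wound)


@dataclass
class BindingKinetics:
    """Protein binding / dissociation / sliding-clamp scheme (rates in 1/s).

    ``k_arrival`` is the pseudo-first-order binding rate per molecule (the
    waiting time from the end of one event to the next arrival is
    exponential at this rate); the bound state exits at ``k_dissoc +
    k_clamp`` and branches to the clamp with probability
    ``k_clamp / (k_dissoc + k_clamp)``; the clamp leaves the field of view
    at ``clamp_exit``.  Set ``k_clamp = 0`` for the no-clamp (ADP) archetype.
    """

    k_arrival: float
    k_dissoc: float
    k_clamp: float = 0.0
    clamp_exit: float = 0.5
    fret_specific: Emission = Emission(0.75, 0.05)
    fret_clamp: Emission = Emission(0.28, 0.05)
    # optional second specific-binding emission (mixed mono/di-labeled
    # protein preparations); off by default
    fret_specific_alt: Emission | None = None
    alt_fraction: float = 0.0

    def __post_init__(self):
        for name in ("k_arrival", "k_dissoc", "k_clamp", "clamp_exit"):
            _check_rate(name, getattr(self, name))
        self.fret_specific = _as_emission(self.fret_specific)
        self.fret_clamp = _as_emission(self.fret_clamp)
        if self.fret_specific_alt is not None:
            self.fret_specific_alt = _as_emission(self.fret_specific_alt)
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise InvalidParameterError("alt_fraction must lie in [0, 1]")
        if self.alt_fraction > 0 and self.fret_specific_alt is None:
            raise InvalidParameterError(
                "alt_fraction > 0 requires fret_specific_alt"
            )
        if self.fret_specific.mean <= self.fret_clamp.mean:
            raise InvalidParameterError(
                "specific-binding FRET mean must exceed the sliding-clamp mean"
            )

    def draw_emission(self, state: int, rng: np.random.Generator) -> Emission | None:
        em = self.emissions()[state]
        if (
            state == BOUND
            and self.alt_fraction > 0
            and rng.random() < self.alt_fraction
        ):
            em = self.fret_specific_alt
        return em

    def transitions(self):
        return {
            DARK: ((self.k_arrival, BOUND),),
            BOUND: ((self.k_dissoc, DARK), (self.k_clamp, CLAMP)),
            CLAMP: ((self.clamp_exit, DARK),),
        }

    def emissions(self):
        return {DARK: None, BOUND: self.fret_specific, CLAMP: self.fret_clamp}

    start_state = DARK

    @property
    def branch_probability(self) -> float:
        """Probability that a bound sojourn ends in clamp formation."""
        total = self.k_dissoc + self.k_clamp
        return self.k_clamp / total if total > 0 else 0.0


Kinetics = Union[TwoStateKinetics, SnapshotKinetics, BindingKinetics]


@dataclass
class NoiseModel:
    """Camera/channel noise at fixed total emitted intensity.

    Gaussian noise of ``intensity_sd`` is added independently to each
    channel on top of a constant per-channel ``background``.  With
    ``shot_noise=True`` the channel means are drawn from Poisson
    distributions instead.
    """

    total_intensity: float = 1000.0
    intensity_sd: float = 60.0
    background: float = 50.0
    shot_noise: bool = False

    def __post_init__(self):
        if self.total_intensity <= 0:
            raise InvalidParameterError("total_intensity must be positive")
        if self.intensity_sd < 0 or self.background < 0:
            raise InvalidParameterError("intensity_sd and background must be >= 0")


@dataclass
class PhotophysicsModel:
    """Dye photophysics: bleaching rates and label defects.

    Bleach rates are per second of excitation of the respective dye.  In the
    protein-binding archetype the donor arrives fresh with each event, so
    its bleach clock restarts per bound sojourn; dyes fixed on the DNA
    accumulate exposure over the whole movie.
    """

    donor_bleach: float = 0.001
    acceptor_bleach: float = 0.0005
    inactive_acceptor_fraction: float = 0.05
    labeled_fraction: float = 1.0

    def __post_init__(self):
        _check_rate("donor_bleach", self.donor_bleach)
        _check_rate("acceptor_bleach", self.acceptor_bleach)
        for name in ("inactive_acceptor_fraction", "labeled_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimConfig:
    """Full generative specification of one synthetic dataset."""

    seed: int
    n_molecules: int
    frame_interval: float
    schedule: ExcitationSchedule
    kinetics: Kinetics
    noise: NoiseModel = field(default_factory=NoiseModel)
    photophysics: PhotophysicsModel = field(default_factory=PhotophysicsModel)
    condition: str = ""

    def __post_init__(self):
        if self.n_molecules < 1:
            raise InvalidParameterError("n_molecules must be >= 1")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames

    @property
    def movie_duration(self) -> float:
        return self.n_frames * self.frame_interval

    def donor_window_duration(self) -> float:
        """Observed donor-excitation time per molecule, in seconds."""
        return int(self.schedule.channel_mask(DONOR_EX).sum()) * self.frame_interval

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        kin_type = type(self.kinetics).__name__
        d = {
            "seed": self.seed,
            "n_molecules": self.n_molecules,
            "frame_interval": self.frame_interval,
            "schedule": [list(seg) for seg in self.schedule.segments],
            "kinetics": {"type": kin_type, **_kinetics_dict(self.kinetics)},
            "noise": asdict(self.noise),
            "photophysics": asdict(self.photophysics),
            "condition": self.condition,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kin = dict(d["kinetics"])
        kin_type = kin.pop("type")
        kin_cls = {
            "TwoStateKinetics": TwoStateKinetics,
            "SnapshotKinetics": SnapshotKinetics,
            "BindingKinetics": BindingKinetics,
        }[kin_type]
        for key, val in list(kin.items()):
            if key.startswith("fret_") and val is not None:
                kin[key] = Emission(*val)
        schedule = ExcitationSchedule(
            tuple((int(s), int(e), str(c)) for s, e, c in d["schedule"])
        )
        return cls(
            seed=int(d["seed"]),
            n_molecules=int(d["n_molecules"]),
            frame_interval=float(d["frame_interval"]),
            schedule=schedule,
            kinetics=kin_cls(**kin),
            noise=NoiseModel(**d.get("noise", {})),
            photophysics=PhotophysicsModel(**d.get("photophysics", {})),
            condition=d.get("condition", ""),
        )


def _kinetics_dict(kin: Kinetics) -> dict:
    d = {}
    for key, val in asdict(kin).items():
        d[key] = list(val) if isinstance(val, tuple) else val
    return d


def molecule_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-molecule random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


# ---------------------------------------------------------------------------
# Continuous-time Markov paths (Gillespie)
# ---------------------------------------------------------------------------

@dataclass
class StatePath:
    """Piecewise-constant state path: states with entry/exit times."""

    states: np.ndarray
    entry: np.ndarray
    exit: np.ndarray
    truncated: bool  # True when the final sojourn was cut at the duration

    @property
    def duration(self) -> float:
        return float(self.exit[-1])

    def state_at_times(self, times: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.exit, times, side="right")
        idx = np.clip(idx, 0, self.states.size - 1)
        return self.states[idx], idx


def simulate_ctmc_path(
    kinetics: TwoStateKinetics | BindingKinetics,
    duration: float,
    rng: np.random.Generator,
    start_state: int | None = None,
) -> StatePath:
    """Gillespie simulation of the kinetic scheme over ``duration`` seconds.

    Sojourn times in each state are exponential with the state's total exit
    rate; the exit branch is chosen with probability proportional to the
    branch rates.  A state with zero total exit rate is absorbing.  The
    final sojourn is cut at ``duration`` and flagged via ``truncated``.
    """
    if duration <= 0 or not np.isfinite(duration):
        raise InvalidParameterError("duration must be positive and finite")
    table = kinetics.transitions()
    state = kinetics.start_state if start_state is None else start_state
    if state not in table:
        raise InvalidParameterError(f"unknown start state {state}")

    states, entries, exits = [], [], []
    t = 0.0
    truncated = True
    while t < duration:
        rates = np.array([r for r, _ in table[state]], dtype=float)
        targets = [s for _, s in table[state]]
        total = rates.sum()
        if total == 0.0:
            states.append(state)
            entries.append(t)
            exits.append(duration)
            truncated = True
            break
        dwell = rng.exponential(1.0 / total)
        t_exit = t + dwell
        states.append(state)
        entries.append(t)
        if t_exit >= duration:
            exits.append(duration)
            truncated = True
            break
        exits.append(t_exit)
        u = rng.random() * total
        state = targets[int(np.searchsorted(np.cumsum(rates), u, side="right"))]
        t = t_exit
        truncated = False
    return StatePath(
        states=np.array(states, dtype=int),
        entry=np.array(entries),
        exit=np.array(exits),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------

def render_trace(
    path: StatePath,
    config: SimConfig,
    rng: np.random.Generator,
    molecule_id: int = 0,
) -> Trace:
    """Render a state path to per-frame donor/acceptor intensities.

    During donor-excitation frames an emitting state with (sojourn-drawn)
    FRET value E yields acceptor ``background + E*total`` and donor
    ``background + (1-E)*total`` before noise; direct acceptor-excitation
    frames report ``background + total`` while the acceptor is present,
    active and unbleached.  Dark states and bleached dyes emit background
    only.
    """
    sched = config.schedule
    dt = config.frame_interval
    n = sched.n_frames
    if path.duration < n * dt - 1e-9:
        raise ContractViolationError(
            f"state path covers {path.duration:.3f}s but the schedule needs {n * dt:.3f}s"
        )

    noise = config.noise
    pp = config.photophysics
    kin = config.kinetics
    emissions = kin.emissions()

    mid_times = (np.arange(n) + 0.5) * dt
    frame_state, frame_sojourn = path.state_at_times(mid_times)

    # one FRET draw per sojourn (state-to-state heterogeneity); NaN = dark
    draw_emission = getattr(kin, "draw_emission", None)
    e_soj = np.full(path.states.size, np.nan)
    for s in range(path.states.size):
        state = int(path.states[s])
        em = draw_emission(state, rng) if draw_emission else emissions.get(state)
        if em is not None:
            e_soj[s] = rng.normal(em.mean, em.sd) if em.sd > 0 else em.mean
    e_frame = e_soj[frame_sojourn]

    donor_mask = sched.channel_mask(DONOR_EX)
    acceptor_mask = sched.channel_mask(ACCEPTOR_EX)
    emitting = np.isfinite(e_frame)

    labeled = bool(rng.random() < pp.labeled_fraction)
    acceptor_active = bool(rng.random() >= pp.inactive_acceptor_fraction)

    donor_on = donor_mask & emitting & labeled
    donor_alive = np.ones(n, dtype=bool)
    if pp.donor_bleach > 0:
        if isinstance(kin, BindingKinetics):
            # fresh dye with each binding event: bleach clock per sojourn
            for s in np.unique(frame_sojourn[donor_on]):
                frames = np.flatnonzero(donor_on & (frame_sojourn == s))
                t_bleach = rng.exponential(1.0 / pp.donor_bleach)
                n_alive = int(t_bleach / dt)
                donor_alive[frames[n_alive:]] = False
        else:
            exposure = np.cumsum(donor_on) * dt  # exposure up to and incl. frame
            t_bleach = rng.exponential(1.0 / pp.donor_bleach)
            donor_alive[(exposure - dt) >= t_bleach] = False
    donor_live = donor_on & donor_alive

    # acceptor excitation: sensitized (FRET) frames plus direct-excitation frames
    acc_excited = (donor_live & acceptor_active) | acceptor_mask
    acc_alive = np.ones(n, dtype=bool)
    if pp.acceptor_bleach > 0 and acceptor_active:
        exposure = np.cumsum(acc_excited) * dt
        t_bleach = rng.exponential(1.0 / pp.acceptor_bleach)
        acc_alive[(exposure - dt) >= t_bleach] = False
    acceptor_ok = acceptor_active & acc_alive

    total = noise.total_intensity
    donor_sig = np.zeros(n)
    acc_sig = np.zeros(n)
    fret_frames = donor_live & acceptor_ok
    donor_only_frames = donor_live & ~acceptor_ok
    donor_sig[fret_frames] = (1.0 - e_frame[fret_frames]) * total
    acc_sig[fret_frames] = e_frame[fret_frames] * total
    donor_sig[donor_only_frames] = total
    direct_frames = acceptor_mask & acceptor_ok
    acc_sig[direct_frames] = total

    if noise.shot_noise:
        donor_int = rng.poisson(donor_sig + noise.background).astype(float)
        acc_int = rng.poisson(acc_sig + noise.background).astype(float)
    else:
        donor_int = donor_sig + noise.background + rng.normal(0.0, noise.intensity_sd, n)
        acc_int = acc_sig + noise.background + rng.normal(0.0, noise.intensity_sd, n)

    return Trace(
        molecule_id=molecule_id,
        donor=donor_int,
        acceptor=acc_int,
        frame_interval=dt,
        schedule=sched,
        condition=config.condition,
    )


# ---------------------------------------------------------------------------
# Experiment-level generators
# ---------------------------------------------------------------------------

@dataclass
class TraceSet:
    """Rendered traces with the generative ground truth."""

    traces: list[Trace]
    truth_events: pd.DataFrame
    paths: list[StatePath]
    config: SimConfig


def _binding_truth_rows(molecule_id: int, path: StatePath) -> list[dict]:
    rows = []
    for i, s in enumerate(path.states):
        if s != BOUND:
            continue
        censored = (i == path.states.size - 1) and path.truncated
        next_state = int(path.states[i + 1]) if i + 1 < path.states.size else -1
        rows.append(
            {
                "molecule_id": molecule_id,
                "t_start": float(path.entry[i]),
                "duration": float(path.exit[i] - path.entry[i]),
                "outcome": (
                    "censored" if censored
                    else ("clamp" if next_state == CLAMP else "dissociated")
                ),
            }
        )
    return rows


def simulate_binding_experiment(config: SimConfig) -> TraceSet:
    """Full protein-binding movie dataset (traces + ground-truth events)."""
    if not isinstance(config.kinetics, BindingKinetics):
        raise InvalidParameterError("config.kinetics must be BindingKinetics")
    traces, paths, rows = [], [], []
    duration = config.movie_duration + config.frame_interval
    for i in range(config.n_molecules):
        rng = molecule_rng(config.seed, i)
        path = simulate_ctmc_path(config.kinetics, duration, rng)
        traces.append(render_trace(path, config, rng, molecule_id=i))
        paths.append(path)
        rows.extend(_binding_truth_rows(i, path))
    truth = pd.DataFrame(rows, columns=["molecule_id", "t_start", "duration", "outcome"])
    return TraceSet(traces=traces, truth_events=truth, paths=paths, config=config)


def simulate_two_state_experiment(config: SimConfig) -> TraceSet:
    """Two-state (wound/unwound) dynamics dataset with per-frame truth.

    ``truth_events`` holds one row per (molecule, donor-excitation frame)
    with the generative state.
    """
    if not isinstance(config.kinetics, TwoStateKinetics):
        raise InvalidParameterError("config.kinetics must be TwoStateKinetics")
    traces, paths, rows = [], [], []
    duration = config.movie_duration + config.frame_interval
    donor_idx = config.schedule.donor_frames()
    mid = (donor_idx + 0.5) * config.frame_interval
    for i in range(config.n_molecules):
        rng = molecule_rng(config.seed, i)
        path = simulate_ctmc_path(config.kinetics, duration, rng)
        traces.append(render_trace(path, config, rng, molecule_id=i))
        paths.append(path)
        states, _ = path.state_at_times(mid)
        rows.append(states)
    truth = pd.DataFrame(
        {
            "molecule_id": np.repeat(np.arange(config.n_molecules), donor_idx.size),
            "frame": np.tile(donor_idx, config.n_molecules),
            "state": np.concatenate(rows),
        }
    )
    return TraceSet(traces=traces, truth_events=truth, paths=paths, config=config)


@dataclass
class SnapshotDataset:
    """Snapshot FRET values per timepoint with generative labels.

    ``values[j]`` is the (n_molecules, 5) array of histogram FRET values at
    timepoint j; ``components[j]`` labels each molecule 0 (donor-only
    artifact), 1 (unwound) or 2 (wound).
    """

    timepoints: np.ndarray  # minutes; a single NaN marks an equilibrium draw
    values: list[np.ndarray]
    components: list[np.ndarray]
    fractions: np.ndarray  # generative unwound fraction at each timepoint
    config: SimConfig
    traces: list[list[Trace]] | None = None

    def pooled_values(self) -> np.ndarray:
        return np.concatenate([v.ravel() for v in self.values])


#: Timepoint grid (minutes) of the unwinding time-course experiment.
SNAPSHOT_TIMEPOINTS = (1.0, 2.0, 3.0, 4.0, 7.0, 10.0, 13.0, 20.0, 30.0, 45.0, 60.0)

#: Number of donor-excitation frames in a snapshot movie.
_SNAPSHOT_DONOR_FRAMES = 10


def simulate_snapshot_experiment(
    config: SimConfig,
    timepoints: Sequence[float] | None = None,
    f_unwound: float | None = None,
    return_traces: bool = False,
) -> SnapshotDataset:
    """Snapshot datasets at the given timepoints (or a fixed fraction).

    For each timepoint ``t`` every molecule is unwound with probability
    ``f(t)`` from the one-phase association law (or with the explicit
    ``f_unwound`` for an equilibrium dataset); donor-only artifact molecules
    are drawn with probability ``donor_only_weight``.  Ten donor-excitation
    FRET values per molecule are drawn from the molecule's Gaussian
    population; the five histogram values are frames 3–7 of those.  With
    ``return_traces=True`` full 20-frame traces are rendered as well.
    """
    kin = config.kinetics
    if not isinstance(kin, SnapshotKinetics):
        raise InvalidParameterError("config.kinetics must be SnapshotKinetics")
    if f_unwound is not None:
        if not (0.0 <= f_unwound <= 1.0):
            raise InvalidParameterError("f_unwound must lie in [0, 1]")
        tps = np.array([np.nan])
        fracs = np.array([f_unwound])
    else:
        if timepoints is None or len(timepoints) == 0:
            raise InvalidParameterError("timepoints must be a non-empty list")
        tps = np.asarray(timepoints, dtype=float)
        if np.any(tps < 0) or np.any(np.diff(tps) < 0):
            raise InvalidParameterError("timepoints must be non-negative and sorted")
        fracs = np.array([kin.fraction_unwound_at(t) for t in tps])

    ems = kin.component_emissions()
    means = np.array([e.mean for e in ems])
    sds = np.array([e.sd for e in ems])
    n = config.n_molecules

    values, components, traces = [], [], []
    for j, f in enumerate(fracs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(j,)))
        donor_only = rng.random(n) < kin.donor_only_weight
        unwound = rng.random(n) < f
        comp = np.where(donor_only, 0, np.where(unwound, 1, 2))
        e10 = rng.normal(
            means[comp][:, None], sds[comp][:, None], size=(n, _SNAPSHOT_DONOR_FRAMES)
        )
        values.append(e10[:, 2:7].copy())
        components.append(comp)
        if return_traces:
            traces.append(_render_snapshot_traces(config, e10, comp, rng))

    return SnapshotDataset(
        timepoints=tps,
        values=values,
        components=components,
        fractions=fracs,
        config=config,
        traces=traces if return_traces else None,
    )


def _render_snapshot_traces(
    config: SimConfig, e10: np.ndarray, comp: np.ndarray, rng: np.random.Generator
) -> list[Trace]:
    """Vectorized rendering of 20-frame snapshot movies.

    Donor-only artifact molecules keep a live direct-excitation acceptor
    (they model acceptors photophysically dark for FRET that survive the
    presence filter); a separate ``inactive_acceptor_fraction`` population
    is dark under direct excitation and is removed by the filter.
    """
    sched = config.schedule
    noise = config.noise
    pp = config.photophysics
    n, n_donor = e10.shape
    donor_idx = sched.donor_frames()
    if donor_idx.size != n_donor:
        raise ContractViolationError(
            f"snapshot schedule must have {n_donor} donor-excitation frames"
        )
    n_frames = sched.n_frames
    total = noise.total_intensity

    inactive = rng.random(n) < pp.inactive_acceptor_fraction

    donor = np.full((n, n_frames), noise.background)
    acceptor = np.full((n, n_frames), noise.background)
    e_eff = np.where(inactive[:, None], 0.0, e10)
    donor[:, donor_idx] += (1.0 - e_eff) * total
    acceptor[:, donor_idx] += e_eff * total
    acc_idx = np.flatnonzero(sched.channel_mask(ACCEPTOR_EX))
    acceptor[:, acc_idx] += np.where(inactive[:, None], 0.0, total)

    donor += rng.normal(0.0, noise.intensity_sd, donor.shape)
    acceptor += rng.normal(0.0, noise.intensity_sd, acceptor.shape)

    return [
        Trace(
            molecule_id=i,
            donor=donor[i],
            acceptor=acceptor[i],
            frame_interval=config.frame_interval,
            schedule=sched,
            condition=config.condition,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Standard configurations
# ---------------------------------------------------------------------------

def cas9_snapshot_config(
    seed: int,
    n_molecules: int = 5000,
    kinetics: SnapshotKinetics | None = None,
    condition: str = "",
) -> SimConfig:
    """Snapshot archetype: 10 + 10 frame movies at 50 ms."""
    if kinetics is None:
        kinetics = SnapshotKinetics(k_assoc=0.3, plateau=0.79, y0=0.35)
    return SimConfig(
        seed=seed,
        n_molecules=n_molecules,
        frame_interval=0.05,
        schedule=ExcitationSchedule.cas9_snapshot(),
        kinetics=kinetics,
        condition=condition,
    )


def cas9_dynamics_config(
    seed: int,
    n_molecules: int = 100,
    k_unwind: float = 0.5,
    k_rewind: float = 0.5,
    condition: str = "",
    **kinetics_kwargs,
) -> SimConfig:
    """Two-state dynamics archetype: 980 donor frames at 50 ms."""
    return SimConfig(
        seed=seed,
        n_molecules=n_molecules,
        frame_interval=0.05,
        schedule=ExcitationSchedule.cas9_dynamics(),
        kinetics=TwoStateKinetics(k_unwind=k_unwind, k_rewind=k_rewind, **kinetics_kwargs),
        condition=condition,
    )


def muts_adp_config(
    seed: int,
    k_dissoc: float,
    n_molecules: int = 700,
    k_arrival: float = 0.02,
    condition: str = "",
) -> SimConfig:
    """No-clamp binding archetype: 10 + 980 + 10 frames at 200 ms."""
    return SimConfig(
        seed=seed,
        n_molecules=n_molecules,
        frame_interval=0.2,
        schedule=ExcitationSchedule.muts_adp(),
        kinetics=BindingKinetics(k_arrival=k_arrival, k_dissoc=k_dissoc, k_clamp=0.0),
        condition=condition,
    )


def muts_atp_config(
    seed: int,
    k_dissoc: float = 0.2,
    k_clamp: float = 0.1,
    n_molecules: int = 400,
    k_arrival: float = 0.02,
    condition: str = "",
) -> SimConfig:
    """Sliding-clamp binding archetype: 10 + 1480 + 10 frames at 50 ms."""
    return SimConfig(
        seed=seed,
        n_molecules=n_molecules,
        frame_interval=0.05,
        schedule=ExcitationSchedule.muts_atp(),
        kinetics=BindingKinetics(k_arrival=k_arrival, k_dissoc=k_dissoc, k_clamp=k_clamp),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_traces_hdf5(traces: Sequence[Trace], path) -> None:
    """Write traces to HDF5: one group per molecule with donor/acceptor
    datasets and the excitation schedule; timestamps disabled so identical
    datasets produce byte-identical files."""
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        for t in traces:
            g = f.create_group(f"mol_{t.molecule_id:06d}")
            g.create_dataset("donor", data=t.donor, track_times=False)
            g.create_dataset("acceptor", data=t.acceptor, track_times=False)
            seg = np.array(
                [[s, e, 0 if c == DONOR_EX else 1] for s, e, c in t.schedule.segments],
                dtype=np.int64,
            )
            g.create_dataset("schedule", data=seg, track_times=False)
            g.attrs["molecule_id"] = t.molecule_id
            g.attrs["frame_interval"] = t.frame_interval
            g.attrs["condition"] = t.condition


def read_traces_hdf5(path) -> list[Trace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            seg = g["schedule"][()]
            schedule = ExcitationSchedule(
                tuple(
                    (int(s), int(e), DONOR_EX if c == 0 else ACCEPTOR_EX)
                    for s, e, c in seg
                )
            )
            traces.append(
                Trace(
                    molecule_id=int(g.attrs["molecule_id"]),
                    donor=g["donor"][()],
                    acceptor=g["acceptor"][()],
                    frame_interval=float(g.attrs["frame_interval"]),
                    schedule=schedule,
                    condition=str(g.attrs.get("condition", "")),
                )
            )
    return traces


def write_index_csv(traceset: TraceSet, path) -> None:
    """Flat per-molecule audit index (id, condition, truth summary)."""
    truth = traceset.truth_events
    rows = []
    for t in traceset.traces:
        if "outcome" in truth.columns:
            sub = truth[truth.molecule_id == t.molecule_id]
            summary = ";".join(sub.outcome.tolist())
        else:
            sub = truth[truth.molecule_id == t.molecule_id]
            summary = f"n_frames={len(sub)}"
        rows.append(
            {
                "molecule_id": t.molecule_id,
                "condition": t.condition,
                "truth_summary": summary,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
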