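"""End-to-end analysis pipelines combining the individual stages.

These are the routines the command-line interface and the reproduction
scripts call: simulate or load a dataset, run the stage-wise analysis
(filtering, classification or segmentation, survival fitting, rate
decomposition) and return plain result objects that serialize to JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import dwell, kinetics, population, timecourse
from .errors import InsufficientDataError
from .synthetic_data import (
    SNAPSHOT_TIMEPOINTS,
    BindingKinetics,
    SimConfig,
    SnapshotDataset,
    SnapshotKinetics,
    TraceSet,
    cas9_snapshot_config,
    muts_adp_config,
    muts_atp_config,
    simulate_binding_experiment,
    simulate_snapshot_experiment,
)
from .traces import Trace, filter_acceptor_present


def default_intensity_threshold(config: SimConfig) -> float:
    """Event-detection threshold halfway between darkness and the bound level."""
    n = config.noise
    return 2 * n.background + 0.5 * n.total_intensity


def default_fret_split(kin: BindingKinetics) -> float:
    """High/low FRET split halfway between the two bound-state means."""
    return 0.5 * (kin.fret_specific.mean + kin.fret_clamp.mean)


def acceptor_filter_threshold(config: SimConfig) -> float:
    """Direct-excitation presence threshold: half the single-dye intensity."""
    return 0.5 * config.noise.total_intensity


# ---------------------------------------------------------------------------
# Binding-movie analysis (ADP / ATP archetypes)
# ---------------------------------------------------------------------------

@dataclass
class BindingAnalysis:
    """Rates and intermediate records from one binding-movie dataset."""

    rates: kinetics.RateSet
    events: list[dwell.EventRecord]
    n_molecules: int
    observation_time: float
    n2: int = 0
    n_minus1: int = 0
    composite_fit: kinetics.ExpFit | None = None
    adp: kinetics.AdpKinetics | None = None

    def to_dict(self) -> dict:
        d = {
            "rates": self.rates.to_dict(),
            "n_events": len(self.events),
            "n_uncensored_events": sum(1 for e in self.events if e.uncensored),
            "n_molecules": self.n_molecules,
            "observation_time_s": self.observation_time,
            "N2": self.n2,
            "N_minus1": self.n_minus1,
        }
        if self.composite_fit is not None:
            d["composite_fit"] = vars(self.composite_fit)
        return d


def _waiting_times(
    events: Sequence[dwell.EventRecord], observation_time: float
) -> tuple[list[float], list[bool]]:
    """Waiting times (t_off) with right-censoring flags.

    A wait between two observed events is complete; the darkness from a
    molecule's last event to the window end is a right-censored wait.  The
    first wait of each molecule starts before observation (left truncation)
    and is dropped.
    """
    by_mol: dict[int, list[dwell.EventRecord]] = {}
    for e in events:
        by_mol.setdefault(e.molecule_id, []).append(e)
    toff, cen = [], []
    for evs in by_mol.values():
        evs = sorted(evs, key=lambda e: e.t_start)
        for e in evs:
            if not e.wait_censored and e.preceding_wait > 0:
                toff.append(e.preceding_wait)
                cen.append(False)
        trailing = observation_time - evs[-1].t_end
        if trailing > 0:
            toff.append(trailing)
            cen.append(True)
    return toff, cen


def analyze_binding_traces(
    traces: Sequence[Trace],
    mode: Literal["adp", "atp"],
    intensity_threshold: float,
    fret_split: float,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    acceptor_threshold: float | None = None,
    label: str = "",
) -> BindingAnalysis:
    """Segment binding events and estimate the kinetic rates.

    ``mode="adp"`` runs the two-state analysis (k_off from the bound dwells,
    pseudo-first-order k'_on from the waiting times); ``mode="atp"`` fits the
    composite exit rate of the specifically bound state and splits it by the
    clamp/dissociation branch counts.
    """
    if acceptor_threshold is not None:
        traces = filter_acceptor_present(
            traces, acceptor_threshold, background=background_acceptor
        )
    if not traces:
        raise InsufficientDataError("no traces pass the acceptor-presence filter")

    events: list[dwell.EventRecord] = []
    for t in traces:
        events.extend(
            dwell.segment_binding_events(
                t,
                intensity_threshold=intensity_threshold,
                fret_split=fret_split,
                background_donor=background_donor,
                background_acceptor=background_acceptor,
            )
        )

    donor_frames = traces[0].schedule.donor_frames().size
    observation_time = donor_frames * traces[0].frame_interval
    n_mol = len(traces)
    k1 = kinetics.estimate_k1(len(events), n_mol, observation_time)

    # bound dwells: complete sojourns plus right-censored ones (high segment
    # truncated by the window end); left-truncated events are dropped
    ton, ton_cen = [], []
    for e in events:
        if e.censored_left or e.t_sb <= 0:
            continue
        if e.censored_right and e.outcome is None:
            ton.append(e.t_sb)
            ton_cen.append(True)
        elif e.outcome is not None:
            ton.append(e.t_sb)
            ton_cen.append(False)

    if mode == "adp":
        toff, toff_cen = _waiting_times(events, observation_time)
        adp = kinetics.estimate_adp_kinetics(ton, toff, ton_cen, toff_cen)
        rates = kinetics.RateSet(
            label=label,
            k1=k1,
            k_off=adp.k_off,
            k_off_se=adp.k_off_se,
            k_on_pseudo=adp.k_on_pseudo,
            k_on_pseudo_se=adp.k_on_pseudo_se,
        )
        return BindingAnalysis(
            rates=rates,
            events=events,
            n_molecules=n_mol,
            observation_time=observation_time,
            composite_fit=adp.ton_fit,
            adp=adp,
        )

    # ATP archetype: composite rate + branch-ratio decomposition
    fit = kinetics.fit_single_exponential(kinetics.one_minus_cdf(ton, ton_cen))
    n2, nm1 = dwell.count_branches(events)
    k2, km1 = kinetics.decompose_rates(fit.k, n2, nm1)
    k2_se, km1_se = kinetics.decomposition_errors(fit.k, fit.k_se, n2, nm1)
    rates = kinetics.RateSet(
        label=label,
        k=fit.k,
        k_se=fit.k_se,
        k1=k1,
        k2=k2,
        k2_se=k2_se,
        k_minus1=km1,
        k_minus1_se=km1_se,
    )
    return BindingAnalysis(
        rates=rates,
        events=events,
        n_molecules=n_mol,
        observation_time=observation_time,
        n2=n2,
        n_minus1=nm1,
        composite_fit=fit,
    )


def analyze_binding_dataset(dataset: TraceSet, mode: Literal["adp", "atp"]) -> BindingAnalysis:
    """Run :func:`analyze_binding_traces` with thresholds from the config."""
    cfg = dataset.config
    kin = cfg.kinetics
    return analyze_binding_traces(
        dataset.traces,
        mode=mode,
        intensity_threshold=default_intensity_threshold(cfg),
        fret_split=default_fret_split(kin),
        background_donor=cfg.noise.background,
        background_acceptor=cfg.noise.background,
        acceptor_threshold=acceptor_filter_threshold(cfg),
        label=cfg.condition,
    )


# ---------------------------------------------------------------------------
# Equilibrium population analysis
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumResult:
    mixture: population.MixtureFit | None
    rule: population.ClassificationRule
    fraction: population.UnwoundFraction

    def to_dict(self) -> dict:
        d = {
            "f_unwound": self.fraction.fraction,
            "n_unwound": self.fraction.n_unwound,
            "n_total": self.fraction.n_total,
            "n_excluded": self.fraction.n_excluded,
            "rule": {"lower": self.rule.lower, "upper": self.rule.upper},
        }
        if self.mixture is not None:
            d["mixture"] = {
                "components": [vars(c) for c in self.mixture.components],
                "thresholds": [self.mixture.lower, self.mixture.upper],
                "fit_residual": self.mixture.fit_residual,
            }
        return d


def analyze_equilibrium_values(
    values: Sequence[float],
    rule: population.ClassificationRule | None = None,
    bin_width: float = population.DEFAULT_BIN_WIDTH,
) -> EquilibriumResult:
    """Three-Gaussian classification of pooled histogram FRET values.

    With ``rule=None`` the classification window is derived from the fitted
    mixture's intersection thresholds; a fixed window (e.g. the reference
    PAM-proximal / PAM-distal rules) may be supplied instead.
    """
    mixture = None
    if rule is None:
        mixture = population.fit_three_gaussians(values, bin_width=bin_width)
        rule = mixture.classification_rule()
    frac = population.fraction_unwound(values, rule)
    return EquilibriumResult(mixture=mixture, rule=rule, fraction=frac)


# ---------------------------------------------------------------------------
# Snapshot time-course analysis
# ---------------------------------------------------------------------------

@dataclass
class TimeCourseResult:
    points: list[timecourse.TimeCoursePoint]
    fit: timecourse.AssociationFit
    rule: population.ClassificationRule
    mixture: population.MixtureFit | None

    def to_dict(self) -> dict:
        return {
            "points": [vars(p) for p in self.points],
            "fit": {
                k: getattr(self.fit, k)
                for k in ("y0", "plateau", "k", "y0_se", "plateau_se", "k_se",
                          "fit_residual", "increasing", "k_identifiable")
            },
            "k_per_second": self.fit.k_per_second,
            "rule": {"lower": self.rule.lower, "upper": self.rule.upper},
        }


def analyze_snapshot_timecourse(
    dataset: SnapshotDataset,
    rule: population.ClassificationRule | None = None,
    threshold_strategy: Literal["pooled", "per-timepoint"] = "pooled",
    bin_width: float = population.DEFAULT_BIN_WIDTH,
    weighted: bool = True,
) -> TimeCourseResult:
    """Fraction-unwound time course and its one-phase association fit.

    Classification thresholds come from a three-Gaussian fit of either the
    pooled histogram over all timepoints (default; every population is well
    represented there) or each timepoint separately, unless a fixed ``rule``
    is supplied.
    """
    mixture = None
    if rule is None and threshold_strategy == "pooled":
        mixture = population.fit_three_gaussians(dataset.pooled_values(), bin_width=bin_width)
        rule = mixture.classification_rule()

    points = []
    for j, t in enumerate(dataset.timepoints):
        vals = dataset.values[j].ravel()
        if rule is None:  # per-timepoint strategy
            fit_j = population.fit_three_gaussians(vals, bin_width=bin_width)
            rule_j = fit_j.classification_rule()
        else:
            rule_j = rule
        frac = population.fraction_unwound(vals, rule_j)
        points.append(
            timecourse.TimeCoursePoint(t=float(t), f_unwound=frac.fraction, n_total=frac.n_total)
        )

    weights = timecourse.binomial_weights(points) if weighted else None
    fit = timecourse.fit_one_phase_association(points, weights=weights)
    final_rule = rule if rule is not None else population.ClassificationRule(0.0, 1.0)
    return TimeCourseResult(points=points, fit=fit, rule=final_rule, mixture=mixture)


# ---------------------------------------------------------------------------
# Parameter-recovery round trips
# ---------------------------------------------------------------------------

def recover_adp_koff(
    seed: int,
    k_dissoc: float,
    n_molecules: int = 700,
    k_arrival: float = 0.02,
) -> dict:
    """Simulate the no-clamp archetype and re-estimate its dissociation rate."""
    cfg = muts_adp_config(seed, k_dissoc=k_dissoc, n_molecules=n_molecules, k_arrival=k_arrival)
    dataset = simulate_binding_experiment(cfg)
    result = analyze_binding_dataset(dataset, mode="adp")
    return {
        "generative_k_off": k_dissoc,
        "recovered_k_off": result.rates.k_off,
        "recovered_k_on_pseudo": result.rates.k_on_pseudo,
        "recovered_k1": result.rates.k1,
        "n_uncensored_events": sum(1 for e in result.events if e.uncensored),
        "n_molecules": result.n_molecules,
    }


def recover_atp_rates(
    seed: int,
    k_dissoc: float = 0.2,
    k_clamp: float = 0.1,
    n_molecules: int = 400,
    k_arrival: float = 0.02,
) -> dict:
    """Simulate the clamp archetype and re-estimate (k, k2, k_minus1)."""
    cfg = muts_atp_config(
        seed, k_dissoc=k_dissoc, k_clamp=k_clamp, n_molecules=n_molecules, k_arrival=k_arrival
    )
    dataset = simulate_binding_experiment(cfg)
    result = analyze_binding_dataset(dataset, mode="atp")
    return {
        "generative": {"k": k_dissoc + k_clamp, "k2": k_clamp, "k_minus1": k_dissoc},
        "recovered": {
            "k": result.rates.k,
            "k2": result.rates.k2,
            "k_minus1": result.rates.k_minus1,
            "k1": result.rates.k1,
        },
        "N2": result.n2,
        "N_minus1": result.n_minus1,
    }


def recover_equilibrium_fraction(
    seed: int,
    f_unwound: float,
    n_molecules: int = 5000,
) -> dict:
    """Simulate an equilibrium snapshot and re-estimate the unwound fraction."""
    cfg = cas9_snapshot_config(seed, n_molecules=n_molecules)
    dataset = simulate_snapshot_experiment(cfg, f_unwound=f_unwound)
    result = analyze_equilibrium_values(dataset.values[0].ravel())
    return {
        "generative_f_unwound": f_unwound,
        "recovered_f_unwound": result.fraction.fraction,
        "thresholds": [result.rule.lower, result.rule.upper],
        "n_values": int(dataset.values[0].size),
    }


def recover_timecourse(
    seed: int,
    plateau: float,
    y0: float = 0.35,
    k_assoc: float = 0.3,
    n_molecules: int = 5000,
    timepoints: Sequence[float] = SNAPSHOT_TIMEPOINTS,
) -> dict:
    """Simulate the snapshot time course and re-fit the association model."""
    kin = SnapshotKinetics(k_assoc=k_assoc, plateau=plateau, y0=y0)
    cfg = cas9_snapshot_config(seed, n_molecules=n_molecules, kinetics=kin)
    dataset = simulate_snapshot_experiment(cfg, timepoints=timepoints)
    result = analyze_snapshot_timecourse(dataset)
    return {
        "generative": {"plateau": plateau, "y0": y0, "k_assoc": k_assoc},
        "recovered": {
            "plateau": result.fit.plateau,
            "y0": result.fit.y0,
            "k_assoc": result.fit.k,
        },
        "points": [(p.t, p.f_unwound) for p in result.points],
    }
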