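"""Idealization, dwell extraction, binding-event segmentation."""

import numpy as np
import pytest

import supercoilfret as sf
from supercoilfret.dwell import MIN_CLAMP_FRAMES, uncensored_durations
from supercoilfret.errors import ConfigurationError, ContractViolationError
from supercoilfret.synthetic_data import BOUND

from conftest import make_constant_trace


def _traj(e, dt=0.05):
    e = np.asarray(e, dtype=float)
    return sf.FretTrajectory(0, e, np.arange(e.size) * dt, dt)


class TestHmmIdealize:
    def test_noiseless_alternating_trace_recovered_exactly(self):
        e = np.tile([0.2] * 5 + [0.7] * 5, 4)
        path = sf.hmm_idealize(_traj(e))
        expected = np.tile([0] * 5 + [1] * 5, 4)
        np.testing.assert_array_equal(path.states, expected)
        assert path.means[0] == pytest.approx(0.2, abs=1e-6)
        assert path.means[1] == pytest.approx(0.7, abs=1e-6)

    def test_constant_trace_flags_degeneracy(self):
        path = sf.hmm_idealize(_traj(np.full(50, 0.5)))
        assert path.degenerate
        assert np.all(path.states == 0)

    def test_short_trace_rejected(self):
        with pytest.raises(ContractViolationError):
            sf.hmm_idealize(_traj(np.linspace(0, 1, 8)))

    def test_deterministic_given_trajectory(self):
        rng = np.random.default_rng(0)
        e = np.where(rng.random(200) < 0.5, 0.3, 0.6) + rng.normal(0, 0.05, 200)
        p1 = sf.hmm_idealize(_traj(e))
        p2 = sf.hmm_idealize(_traj(e))
        np.testing.assert_array_equal(p1.states, p2.states)
        assert p1.log_likelihood == p2.log_likelihood

    def test_misclassification_low_on_synthetic_dynamics(self, clean_photophysics):
        """Frame error < 2% against ground truth on two-state traces with
        well-separated emissions (means 0.3/0.6, state noise ~0.05)."""
        cfg = sf.cas9_dynamics_config(
            seed=51, n_molecules=25, k_unwind=0.5, k_rewind=0.5,
            fret_wound=(0.6, 0.0), fret_unwound=(0.3, 0.0),
        )
        cfg.photophysics = clean_photophysics
        ds = sf.simulate_two_state_experiment(cfg)
        truth = ds.truth_events
        mistakes = total = 0
        for tr in ds.traces:
            traj = sf.compute_fret(tr, 50.0, 50.0)
            path = sf.hmm_idealize(traj)
            gen = truth[truth.molecule_id == tr.molecule_id].state.values
            mistakes += int(np.sum(path.states != 1 - gen))  # wound=high FRET
            total += gen.size
        assert mistakes / total < 0.02

    def test_threshold_oracle_agreement(self, clean_photophysics):
        """HMM and half-way threshold idealization agree on > 98% of frames."""
        cfg = sf.cas9_dynamics_config(
            seed=52, n_molecules=10, k_unwind=0.5, k_rewind=0.5,
            fret_wound=(0.6, 0.0), fret_unwound=(0.3, 0.0),
        )
        cfg.photophysics = clean_photophysics
        ds = sf.simulate_two_state_experiment(cfg)
        agree = total = 0
        for tr in ds.traces:
            traj = sf.compute_fret(tr, 50.0, 50.0)
            hmm = sf.hmm_idealize(traj)
            thr = sf.threshold_idealize(traj, 0.45)
            agree += int(np.sum(hmm.states == thr.states))
            total += len(hmm)
        assert agree / total > 0.98


class TestExtractDwells:
    def test_run_lengths_and_censoring_flags(self):
        path = sf.IdealizedPath(
            states=np.array([0, 0, 1, 1, 1, 0]),
            means=np.array([0.3, 0.6]), sds=np.array([0.05, 0.05]),
            log_likelihood=0.0, frame_interval=0.05,
        )
        dwells = sf.extract_dwells(path)
        assert [(d.state, d.duration) for d in dwells] == [
            (0, pytest.approx(0.10)), (1, pytest.approx(0.15)), (0, pytest.approx(0.05)),
        ]
        assert dwells[0].censored_left and not dwells[0].censored_right
        assert not dwells[1].censored
        assert dwells[2].censored_right
        assert dwells[0].next_state == 1 and dwells[2].next_state is None

    def test_single_state_path_fully_censored(self):
        path = sf.IdealizedPath(
            states=np.zeros(30, dtype=int),
            means=np.array([0.5]), sds=np.array([0.05]),
            log_likelihood=0.0, frame_interval=0.1,
        )
        (dwell,) = sf.extract_dwells(path)
        assert dwell.censored_left and dwell.censored_right
        assert dwell.duration == pytest.approx(3.0)

    def test_durations_sum_to_trace_duration(self):
        rng = np.random.default_rng(13)
        states = (rng.random(500) < 0.5).astype(int)
        path = sf.IdealizedPath(
            states=states, means=np.array([0.3, 0.6]), sds=np.array([0.05, 0.05]),
            log_likelihood=0.0, frame_interval=0.05,
        )
        dwells = sf.extract_dwells(path)
        assert sum(d.duration for d in dwells) == pytest.approx(500 * 0.05)

    def test_uncensored_dwell_mean_matches_exit_rate(self, clean_photophysics):
        """~10k uncensored dwells at a 0.5/s exit rate average 2 s (within 2%).

        Long traces (1000 s of donor excitation) keep the censoring loss of
        long dwells negligible next to the 2 s mean.
        """
        cfg = sf.SimConfig(
            seed=53, n_molecules=20, frame_interval=0.05,
            schedule=sf.ExcitationSchedule(((0, 20_000, "donor_ex"),)),
            kinetics=sf.TwoStateKinetics(
                0.5, 0.5, fret_wound=(0.6, 0.0), fret_unwound=(0.3, 0.0)
            ),
            photophysics=clean_photophysics,
        )
        ds = sf.simulate_two_state_experiment(cfg)
        dwells = []
        for tr in ds.traces:
            traj = sf.compute_fret(tr, 50.0, 50.0)
            dwells += sf.extract_dwells(sf.threshold_idealize(traj, 0.45))
        durations = np.concatenate(
            [uncensored_durations(dwells, 0), uncensored_durations(dwells, 1)]
        )
        assert durations.size > 8000
        assert durations.mean() == pytest.approx(2.0, rel=0.02)


class TestSegmentBindingEvents:
    def _event_trace(self, switch_frame=None, start=100, end=150, n=300, dt=0.05):
        """Noiseless trace, dark except one event at [start, end)."""
        sched = sf.ExcitationSchedule(((0, n, "donor_ex"),))
        donor = np.zeros(n)
        acceptor = np.zeros(n)
        hi = slice(start, end if switch_frame is None else switch_frame)
        donor[hi] = 250.0
        acceptor[hi] = 750.0  # E = 0.75
        if switch_frame is not None:
            lo = slice(switch_frame, end)
            donor[lo] = 750.0
            acceptor[lo] = 250.0  # E = 0.25
        return sf.Trace(0, donor, acceptor, dt, sched)

    def test_clamp_event_geometry(self):
        trace = self._event_trace(switch_frame=130)
        (ev,) = sf.segment_binding_events(trace, intensity_threshold=500, fret_split=0.5)
        assert ev.t_sb == pytest.approx(1.5)
        assert ev.outcome == "clamp"
        assert ev.t_start == pytest.approx(100 * 0.05)
        assert ev.t_end == pytest.approx(150 * 0.05)

    def test_dissociation_event(self):
        trace = self._event_trace()
        (ev,) = sf.segment_binding_events(trace, intensity_threshold=500, fret_split=0.5)
        assert ev.outcome == "dissociated"
        assert ev.t_sb == pytest.approx(2.5)
        assert ev.wait_censored  # first darkness began before the window

    def test_short_low_run_absorbed_as_noise(self):
        trace = self._event_trace()
        # inject a 2-frame FRET dip inside the high segment
        trace.donor[120:122], trace.acceptor[120:122] = 750.0, 250.0
        (ev,) = sf.segment_binding_events(trace, intensity_threshold=500, fret_split=0.5)
        assert ev.outcome == "dissociated"
        assert ev.t_sb == pytest.approx(2.5)
        assert MIN_CLAMP_FRAMES == 3

    def test_event_truncated_by_window_end_is_censored(self):
        trace = self._event_trace(start=280, end=300)
        (ev,) = sf.segment_binding_events(trace, intensity_threshold=500, fret_split=0.5)
        assert ev.censored_right and ev.outcome is None

    def test_threshold_below_background_rejected(self):
        trace = make_constant_trace(100, 100, sf.ExcitationSchedule(((0, 20, "donor_ex"),)))
        with pytest.raises(ConfigurationError):
            sf.segment_binding_events(
                trace, intensity_threshold=150, fret_split=0.5,
                background_donor=100, background_acceptor=100,
            )

    def test_adp_archetype_has_no_clamp_outcomes(self):
        cfg = sf.muts_adp_config(seed=61, k_dissoc=0.204, n_molecules=40)
        ds = sf.simulate_binding_experiment(cfg)
        events = []
        for tr in ds.traces:
            events += sf.segment_binding_events(
                tr, intensity_threshold=600, fret_split=0.5,
                background_donor=50, background_acceptor=50,
            )
        assert len(events) > 50
        assert all(e.outcome != "clamp" for e in events)

    def test_atp_branch_fraction_recovered(self):
        """Clamp fraction among uncensored events matches k2/(k-1+k2)."""
        cfg = sf.muts_atp_config(seed=62, k_dissoc=0.2, k_clamp=0.3, n_molecules=500)
        ds = sf.simulate_binding_experiment(cfg)
        events = []
        for tr in ds.traces:
            events += sf.segment_binding_events(
                tr, intensity_threshold=600, fret_split=0.5,
                background_donor=50, background_acceptor=50,
            )
        n2, nm1 = sf.count_branches(events)
        assert n2 + nm1 >= 400
        assert n2 / (n2 + nm1) == pytest.approx(0.6, abs=0.05)


class TestCountBranches:
    def test_censored_events_excluded(self):
        def ev(outcome, censored=False):
            return sf.EventRecord(
                molecule_id=0, t_start=0.0, t_end=1.0, t_sb=1.0,
                outcome=None if censored else outcome,
                preceding_wait=1.0, censored_right=censored,
            )

        events = [ev("clamp")] * 30 + [ev("dissociated")] * 20 + [ev(None, censored=True)] * 5
        assert sf.count_branches(events) == (30, 20)

    def test_empty_list(self):
        assert sf.count_branches([]) == (0, 0)


class TestCensoringBias:
    """Naive uncensored-only rate fits are accurate for dwells much shorter
    than the window and biased high when dwells approach the window length."""

    def _naive_rate(self, k, seed, window=200.0, n_paths=400, k_arrival=0.2):
        kin = sf.BindingKinetics(k_arrival=k_arrival, k_dissoc=k)
        dur = []
        for i in range(n_paths):
            rng = np.random.default_rng(seed * 10_000 + i)
            path = sf.simulate_ctmc_path(kin, window, rng)
            for j, s in enumerate(path.states):
                if s == BOUND and not (j == path.states.size - 1 and path.truncated):
                    dur.append(path.exit[j] - path.entry[j])
        return sf.fit_single_exponential(sf.one_minus_cdf(dur)).k

    def test_accurate_for_short_dwells(self):
        assert self._naive_rate(0.5, seed=7) == pytest.approx(0.5, rel=0.05)

    def test_biased_high_for_long_dwells(self):
        # mean dwell 50 s against a 200 s window: documented upward bias
        assert self._naive_rate(0.02, seed=8, k_arrival=0.02) >= 0.02
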