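"""Generator statistics, determinism, rendering contracts and file I/O."""

import numpy as np
import pytest
from scipy import stats

import supercoilfret as sf
from supercoilfret.errors import ContractViolationError, InvalidParameterError
from supercoilfret.synthetic_data import BOUND, UNWOUND


class TestCtmcPath:
    def test_zero_rewind_rate_is_absorbing(self):
        kin = sf.TwoStateKinetics(k_unwind=1.0, k_rewind=0.0)
        rng = np.random.default_rng(0)
        path = sf.simulate_ctmc_path(kin, 100.0, rng, start_state=UNWOUND)
        assert np.all(path.states == UNWOUND)
        assert path.duration == 100.0

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            sf.TwoStateKinetics(k_unwind=-1.0, k_rewind=0.5)
        with pytest.raises(InvalidParameterError):
            sf.simulate_ctmc_path(
                sf.TwoStateKinetics(1.0, 1.0), duration=-5.0,
                rng=np.random.default_rng(0),
            )

    @staticmethod
    def _bound_sojourns(kin, duration, seed):
        rng = np.random.default_rng(seed)
        path = sf.simulate_ctmc_path(kin, duration, rng)
        idx = np.flatnonzero(path.states == BOUND)
        if path.truncated and idx.size and idx[-1] == path.states.size - 1:
            idx = idx[:-1]
        durations = path.exit[idx] - path.entry[idx]
        exits = path.states[idx + 1]
        return durations, exits

    def test_branch_probability_closed_form(self):
        """Over ~1e5 bound-state exits the clamp fraction equals
        k2/(k-1+k2) = 0.6 within 0.01."""
        kin = sf.BindingKinetics(k_arrival=5.0, k_dissoc=0.2, k_clamp=0.3)
        durations, exits = self._bound_sojourns(kin, 350_000.0, seed=1)
        assert durations.size > 100_000
        assert np.mean(exits == 2) == pytest.approx(0.6, abs=0.01)

    def test_mean_bound_sojourn_closed_form(self):
        """Mean bound dwell equals 1/(k-1+k2) = 2.0 s within 2%."""
        kin = sf.BindingKinetics(k_arrival=5.0, k_dissoc=0.2, k_clamp=0.3)
        durations, _ = self._bound_sojourns(kin, 350_000.0, seed=2)
        assert durations.mean() == pytest.approx(2.0, rel=0.02)

    def test_sojourns_pass_ks_test_against_exponential(self):
        """10k noiseless bound sojourns are exponential with the total exit
        rate (one-sample KS at alpha = 0.01)."""
        kin = sf.BindingKinetics(k_arrival=5.0, k_dissoc=0.2, k_clamp=0.3)
        durations, _ = self._bound_sojourns(kin, 40_000.0, seed=3)
        durations = durations[:10_000]
        res = stats.kstest(durations, "expon", args=(0, 2.0))
        assert res.pvalue > 0.01


class TestRenderTrace:
    def _noiseless_config(self, kin):
        return sf.SimConfig(
            seed=0, n_molecules=1, frame_interval=0.05,
            schedule=sf.ExcitationSchedule.cas9_snapshot(), kinetics=kin,
            noise=sf.NoiseModel(total_intensity=1000, intensity_sd=0, background=0),
            photophysics=sf.PhotophysicsModel(0, 0, 0, 1),
        )

    def test_noiseless_single_state_rendering(self):
        kin = sf.TwoStateKinetics(0.0, 0.0, fret_wound=(0.6, 0.0), fret_unwound=(0.3, 0.0))
        cfg = self._noiseless_config(kin)
        path = sf.simulate_ctmc_path(kin, 2.0, np.random.default_rng(0))
        trace = sf.render_trace(path, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(trace.acceptor[:10], 600.0)
        np.testing.assert_allclose(trace.donor[:10], 400.0)
        np.testing.assert_allclose(trace.acceptor[10:], 1000.0)  # direct excitation

    def test_short_path_rejected(self):
        kin = sf.TwoStateKinetics(0.0, 0.0)
        cfg = self._noiseless_config(kin)
        path = sf.simulate_ctmc_path(kin, 0.5, np.random.default_rng(0))
        with pytest.raises(ContractViolationError):
            sf.render_trace(path, cfg, np.random.default_rng(0))

    def test_all_inactive_acceptors_fail_presence_filter(self):
        kin = sf.TwoStateKinetics(0.5, 0.5)
        cfg = self._noiseless_config(kin)
        cfg.photophysics = sf.PhotophysicsModel(0, 0, 1.0, 1.0)
        path = sf.simulate_ctmc_path(kin, 2.0, np.random.default_rng(0))
        trace = sf.render_trace(path, cfg, np.random.default_rng(0))
        assert not sf.acceptor_present(trace, threshold=500.0)

    def test_inactive_fraction_binomial(self):
        """With 10% inactive acceptors, 500 +- 40 of 5000 molecules fail the
        direct-excitation presence filter (binomial sd ~21, 2 sd margin)."""
        kin = sf.SnapshotKinetics(k_assoc=0.3, plateau=0.79, y0=0.35)
        cfg = sf.cas9_snapshot_config(seed=71, n_molecules=5000, kinetics=kin)
        cfg.photophysics = sf.PhotophysicsModel(0.0, 0.0, 0.10, 1.0)
        ds = sf.simulate_snapshot_experiment(cfg, f_unwound=0.5, return_traces=True)
        kept = sf.filter_acceptor_present(ds.traces[0], threshold=500.0, background=50.0)
        removed = 5000 - len(kept)
        assert removed == pytest.approx(500, abs=40)


class TestReproducibility:
    def test_identical_config_reproduces_identical_dataset(self):
        cfg = sf.muts_adp_config(seed=5, k_dissoc=0.2, n_molecules=8)
        d1 = sf.simulate_binding_experiment(cfg)
        d2 = sf.simulate_binding_experiment(cfg)
        for a, b in zip(d1.traces, d2.traces):
            np.testing.assert_array_equal(a.donor, b.donor)
            np.testing.assert_array_equal(a.acceptor, b.acceptor)
        assert d1.truth_events.equals(d2.truth_events)

    def test_different_seed_differs(self):
        a = sf.simulate_binding_experiment(sf.muts_adp_config(5, 0.2, n_molecules=3))
        b = sf.simulate_binding_experiment(sf.muts_adp_config(6, 0.2, n_molecules=3))
        assert not np.array_equal(a.traces[0].donor, b.traces[0].donor)

    def test_hdf5_round_trip_and_byte_identity(self, tmp_path):
        cfg = sf.muts_adp_config(seed=5, k_dissoc=0.2, n_molecules=4)
        ds = sf.simulate_binding_experiment(cfg)
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        sf.write_traces_hdf5(ds.traces, p1)
        sf.write_traces_hdf5(ds.traces, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = sf.read_traces_hdf5(p1)
        assert len(back) == 4
        for a, b in zip(ds.traces, back):
            np.testing.assert_array_equal(a.donor, b.donor)
            assert a.schedule == b.schedule
            assert a.frame_interval == b.frame_interval

    def test_config_dict_round_trip(self):
        cfg = sf.muts_atp_config(seed=9, k_dissoc=0.2, k_clamp=0.1, n_molecules=3)
        back = sf.SimConfig.from_dict(cfg.to_dict())
        assert back.schedule == cfg.schedule
        assert back.kinetics == cfg.kinetics
        assert back.noise == cfg.noise
        assert back.photophysics == cfg.photophysics


class TestSnapshotExperiment:
    def test_empty_timepoints_rejected(self):
        cfg = sf.cas9_snapshot_config(seed=0, n_molecules=10)
        with pytest.raises(InvalidParameterError):
            sf.simulate_snapshot_experiment(cfg, timepoints=[])

    def test_association_law_boundaries(self):
        """Unwound fraction ~ y0 at t=0 and ~ plateau as t -> infinity."""
        kin = sf.SnapshotKinetics(k_assoc=0.2, plateau=0.79, y0=0.35)
        cfg = sf.cas9_snapshot_config(seed=73, n_molecules=5000, kinetics=kin)
        ds = sf.simulate_snapshot_experiment(cfg, timepoints=[0.0, 1000 / 0.2])
        for j, expected in enumerate([0.35, 0.79]):
            comp = ds.components[j]
            signal = comp[comp != 0]
            frac = np.mean(signal == 1)
            assert frac == pytest.approx(expected, abs=0.02)

    def test_association_law_closed_form_midpoint(self):
        """f(5 min) = 0.35 + 0.44 (1 - e^-1) = 0.628 for k = 0.2/min."""
        kin = sf.SnapshotKinetics(k_assoc=0.2, plateau=0.79, y0=0.35)
        cfg = sf.cas9_snapshot_config(seed=74, n_molecules=5000, kinetics=kin)
        ds = sf.simulate_snapshot_experiment(cfg, timepoints=[5.0])
        comp = ds.components[0]
        signal = comp[comp != 0]
        expected = 0.35 + (0.79 - 0.35) * (1 - np.exp(-1.0))
        assert np.mean(signal == 1) == pytest.approx(expected, abs=0.02)

    def test_values_shape_and_frame_selection_consistency(self, clean_photophysics):
        """Histogram values equal ordinal frames 3..7 of the rendered movie's
        FRET trajectory up to channel noise."""
        kin = sf.SnapshotKinetics(k_assoc=0.3, plateau=0.79, y0=0.35)
        cfg = sf.cas9_snapshot_config(seed=75, n_molecules=50, kinetics=kin)
        cfg.photophysics = clean_photophysics
        ds = sf.simulate_snapshot_experiment(cfg, f_unwound=0.5, return_traces=True)
        assert ds.values[0].shape == (50, 5)
        for i, tr in enumerate(ds.traces[0][:10]):
            traj = sf.compute_fret(tr, 50.0, 50.0)
            got = sf.select_histogram_frames(traj)
            np.testing.assert_allclose(got, ds.values[0][i], atol=0.3)


class TestBindingExperiment:
    def test_labeling_heterogeneity_broadens_event_fret(self):
        """With a second specific-binding emission enabled, bound-sojourn
        FRET values are drawn from a two-component mixture."""
        base = dict(k_arrival=0.5, k_dissoc=0.2, fret_specific=(0.75, 0.01))
        kin = sf.BindingKinetics(**base, fret_specific_alt=(0.55, 0.01), alt_fraction=0.5)
        cfg = sf.SimConfig(
            seed=1, n_molecules=1, frame_interval=0.2,
            schedule=sf.ExcitationSchedule.muts_adp(), kinetics=kin,
            noise=sf.NoiseModel(intensity_sd=0.0, background=0.0),
            photophysics=sf.PhotophysicsModel(0, 0, 0, 1),
        )
        rng = np.random.default_rng(2)
        path = sf.simulate_ctmc_path(kin, cfg.movie_duration + 1, rng)
        trace = sf.render_trace(path, cfg, rng)
        e = sf.compute_fret(trace).E
        e = e[np.isfinite(e) & (e > 0.3)]
        assert np.any(np.abs(e - 0.55) < 0.05) and np.any(np.abs(e - 0.75) < 0.05)
        with pytest.raises(InvalidParameterError):
            sf.BindingKinetics(**base, alt_fraction=0.5)


    def test_no_clamp_transitions_without_clamp_rate(self):
        cfg = sf.muts_adp_config(seed=81, k_dissoc=0.3, n_molecules=30)
        ds = sf.simulate_binding_experiment(cfg)
        assert not (ds.truth_events.outcome == "clamp").any()

    def test_event_count_matches_renewal_expectation(self):
        """Arrivals are a renewal process: waits Exp(k_arrival) from the
        previous event's end, so the expected number of arrivals per
        molecule is T / (1/k_arrival + E[bound duration])."""
        k_arr, k_off, window = 0.05, 0.204, 196.0
        cfg = sf.muts_adp_config(seed=82, k_dissoc=k_off, n_molecules=200, k_arrival=k_arr)
        ds = sf.simulate_binding_experiment(cfg)
        n_events = len(ds.truth_events)
        expected = 200 * (window + 4.0) / (1 / k_arr + 1 / k_off)
        assert n_events == pytest.approx(expected, rel=0.06)

    def test_mean_bound_dwell_matches_dissociation_rate(self):
        """Mean uncensored bound dwell = 1/k_dissoc within 3%."""
        cfg = sf.muts_adp_config(seed=83, k_dissoc=0.204, n_molecules=500)
        ds = sf.simulate_binding_experiment(cfg)
        unc = ds.truth_events[ds.truth_events.outcome != "censored"]
        assert unc.duration.mean() == pytest.approx(1 / 0.204, rel=0.03)
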