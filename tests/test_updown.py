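"""Despiking, two-Gaussian fits, moving-average state segmentation and the
per-condition state statistics."""

import numpy as np
import pytest

from pause_ephys.core import EpochSet, SpikeTrain, Trace, ValidationError
from pause_ephys.experiments import mixture_recovery_errors
from pause_ephys.synth import SimConfig, UpDownParams, default_light_epochs, simulate_updown_trace
from pause_ephys.updown import (
    DOWN,
    UP,
    SegmentationParams,
    StateSegmentation,
    allpoints_gaussian_fit,
    condition_windows,
    peak_potential,
    remove_spikes,
    segment_states,
    state_statistics,
    transition_slope,
    up_state_average,
)
from conftest import square_wave_trace


class TestRemoveSpikes:
    def test_no_spikes_is_identity(self, rng):
        tr = Trace(samples=rng.normal(size=1000), fs=1000.0)
        empty = SpikeTrain(times=[], t_start=0.0, t_stop=1.0)
        np.testing.assert_array_equal(remove_spikes(tr, empty).samples, tr.samples)

    def test_spike_on_linear_ramp_restored_exactly(self):
        fs = 1000.0
        ramp = np.linspace(-80.0, -60.0, 1000)
        spiked = ramp.copy()
        spiked[495:505] += 40.0
        train = SpikeTrain(times=[0.5], t_start=0.0, t_stop=1.0)
        clean = remove_spikes(Trace(samples=spiked, fs=fs), train, blank=(0.01, 0.01))
        np.testing.assert_allclose(clean.samples, ramp, atol=1e-9)

    def test_overlapping_blanks_merge_into_single_span(self):
        fs = 1000.0
        ramp = np.linspace(0.0, 10.0, 2000)
        spiked = ramp.copy()
        spiked[995:1025] = 99.0
        train = SpikeTrain(times=[1.0, 1.012], t_start=0.0, t_stop=2.0)
        clean = remove_spikes(Trace(samples=spiked, fs=fs), train, blank=(0.012, 0.012))
        # overlapping windows interpolate across the union, restoring the ramp
        np.testing.assert_allclose(clean.samples, ramp, atol=1e-9)


class TestGaussianFit:
    def test_recovery_within_point_three_mv(self):
        for seed in (0, 1, 2):
            e_down, e_up = mixture_recovery_errors(seed, n_samples=50_000)
            assert e_down < 0.3 and e_up < 0.3

    def test_identical_samples_rejected(self):
        with pytest.raises(ValidationError):
            allpoints_gaussian_fit(np.full(1000, -70.0))

    def test_component_ordering_invariant(self, rng):
        x = np.concatenate([rng.normal(-60, 2, 3000), rng.normal(-75, 2, 3000)])
        fit = allpoints_gaussian_fit(x)
        assert fit.m_down < fit.m_up

    def test_mirror_symmetry(self, rng):
        x = np.concatenate([rng.normal(-72, 2, 20000), rng.normal(-56, 2, 20000)])
        fit = allpoints_gaussian_fit(x)
        mid = -64.0
        assert abs(mid - fit.m_down) == pytest.approx(abs(fit.m_up - mid), abs=0.15)

    def test_unimodal_data_flagged(self, rng):
        fit = allpoints_gaussian_fit(rng.normal(-65, 2, 10000))
        assert fit.unimodal


class TestSegmentation:
    def test_square_wave_boundaries_recovered(self):
        tr, onsets = square_wave_trace()
        seg = segment_states(tr)
        params = SegmentationParams()
        ups = seg.of_state(UP)
        assert len(ups) == 20
        det = np.array([a for a, _ in ups])
        for t in onsets[1:-1]:
            assert np.min(np.abs(det - t)) <= params.slow_window / 2
            assert np.min(np.abs(det - t)) <= 0.05  # and in fact much tighter

    def test_constant_trace_is_single_down_segment(self):
        tr = Trace(samples=np.full(5000, -70.0), fs=1000.0)
        seg = segment_states(tr)
        assert seg.segments == ((DOWN, 0.0, 5.0),)

    def test_short_up_excursion_removed(self):
        fs = 1000.0
        x = np.full(6000, -75.0)
        x[3000:3150] = -55.0  # 0.15 s < the 0.2 s UP filter
        seg = segment_states(Trace(samples=x, fs=fs))
        assert seg.of_state(UP) == []

    def test_tiles_and_alternates_on_noisy_two_state_data(self):
        cfg = SimConfig(seed=9, updown=UpDownParams(duration=30.0, fs=1000.0))
        sim = simulate_updown_trace(cfg, EpochSet(epochs=np.empty((0, 2))))
        clean = remove_spikes(sim.trace, sim.spikes)
        seg = segment_states(clean)
        lo, hi = seg.span
        assert lo == clean.t_start and hi == pytest.approx(clean.t_stop)
        for (s0, _, e0), (s1, a1, _) in zip(seg.segments, seg.segments[1:]):
            assert s0 != s1 and e0 == a1
        assert all(b - a >= 0.2 - 1e-9 for a, b in seg.of_state(UP))

    def test_trace_shorter_than_slow_window_rejected(self):
        tr = Trace(samples=np.zeros(100), fs=1000.0)
        with pytest.raises(ValidationError):
            segment_states(tr)

    def test_noiseless_boundaries_match_ground_truth(self):
        """Zero-noise simulation: every detected transition sits on a true one,
        and every well-separated true UP dwell is recovered."""
        params = UpDownParams(duration=120.0, fs=500.0, s_down=0.0, s_up=0.0)
        cfg = SimConfig(seed=11, updown=params)
        sim = simulate_updown_trace(cfg, EpochSet(epochs=np.empty((0, 2))))
        clean = remove_spikes(sim.trace, sim.spikes)
        seg = segment_states(clean)
        true_edges = np.array(
            [a for _, a, _ in sim.states.segments[1:]]  # interior transitions
        )
        tol = 0.5 * params.rise_10_90 / 0.8 + 0.02  # half the transition ramp
        for _, a, b in seg.segments[1:-1]:
            assert np.min(np.abs(true_edges - a)) <= tol
        # recovery of unambiguous true UP dwells (long, flanked by long DOWNs)
        truth = sim.states.segments
        det_onsets = np.array([a for a, _ in seg.of_state(UP)])
        for i, (s, a, b) in enumerate(truth):
            if s != UP or b - a < 0.35 or i in (0, len(truth) - 1):
                continue
            if truth[i - 1][2] - truth[i - 1][1] < 0.35 or truth[i + 1][2] - truth[i + 1][1] < 0.35:
                continue
            assert np.min(np.abs(det_onsets - a)) <= tol


class TestConditionWindows:
    def test_five_second_pause_layout(self):
        ep = EpochSet(epochs=[(10.0, 15.0)])
        (w,) = condition_windows(ep, width=5.0, post_gap=10.0)
        assert w.before == (5.0, 10.0)
        assert w.during == (10.0, 15.0)
        assert w.after == (25.0, 30.0)

    def test_epoch_shorter_than_window_rejected(self):
        ep = EpochSet(epochs=[(10.0, 11.0)])
        with pytest.raises(ValidationError):
            condition_windows(ep, width=5.0)

    def test_one_triple_per_epoch_and_range_skipping(self):
        ep = EpochSet(epochs=[(10.0, 15.0), (40.0, 45.0)])
        assert len(condition_windows(ep, width=5.0, post_gap=10.0)) == 2
        with pytest.warns(UserWarning, match="skipped"):
            wins = condition_windows(ep, width=5.0, post_gap=10.0, t_stop=35.0)
        assert len(wins) == 1


class TestUpStateAverage:
    def test_identical_events_average_to_single_event(self):
        tr, _ = square_wave_trace()
        seg = segment_states(tr)
        t, avg = up_state_average(tr, seg, half_width=0.3)
        # interior of the plateau sits 20 mV above the pre-onset baseline
        center = np.abs(t) < 0.15
        np.testing.assert_allclose(avg[center], 20.0, atol=0.05)

    def test_baselines_mapped_to_zero(self):
        fs = 1000.0
        x = np.full(4000, -75.0)
        x[1000:1400] = -55.0
        x[2800:3200] = -50.0
        x[2000:2800] = -70.0  # second event rides a different baseline
        tr = Trace(samples=x, fs=fs)
        seg = StateSegmentation(
            segments=(
                (DOWN, 0.0, 1.0),
                (UP, 1.0, 1.4),
                (DOWN, 1.4, 2.8),
                (UP, 2.8, 3.2),
                (DOWN, 3.2, 4.0),
            )
        )
        t, avg = up_state_average(tr, seg, half_width=0.1)
        np.testing.assert_allclose(avg[np.abs(t) < 0.05], 20.0, atol=1e-9)

    def test_ramp_onset_slope_preserved(self):
        """Averaging identical ramp-onset events preserves the ramp slope."""
        fs = 1000.0
        event = np.concatenate(
            [np.full(200, -75.0), np.linspace(-75, -55, 100), np.full(300, -55.0)]
        )
        x = np.concatenate([np.full(500, -75.0)] + [event] * 5 + [np.full(500, -75.0)])
        tr = Trace(samples=x, fs=fs)
        segs = []
        t0 = 0.5
        segs.append((DOWN, 0.0, t0 + 0.2))
        for _ in range(5):
            segs.append((UP, t0 + 0.2, t0 + 0.6))
            segs.append((DOWN, t0 + 0.6, t0 + 0.8))
            t0 += 0.6
        segs[-1] = (DOWN, segs[-1][1], tr.t_stop)
        seg = StateSegmentation(segments=tuple(segs))
        t, avg = up_state_average(tr, seg, half_width=0.4)
        sel = ~np.isnan(avg)
        slope = transition_slope(avg[sel], fs, baseline=0.0)
        assert slope == pytest.approx(200.0, rel=0.05)


class TestSlopeAndPeak:
    def test_linear_ramp_slope_exact(self):
        ramp = np.linspace(-80.0, -60.0, 101)  # 100 ms at 1 kHz
        assert transition_slope(ramp, 1000.0) == pytest.approx(200.0, rel=1e-9)

    def test_time_dilation_halves_slope(self):
        ramp = np.linspace(-80.0, -60.0, 101)
        assert transition_slope(ramp, 500.0) == pytest.approx(100.0, rel=1e-9)

    def test_sigmoid_matches_dense_numerical_oracle(self):
        """Logistic rise: regression oracle on the analytic 10-90% region."""
        fs = 100000.0
        k, t_mid = 80.0, 0.05
        t = np.arange(0, 0.1, 1 / fs)
        v = -80.0 + 20.0 / (1.0 + np.exp(-k * (t - t_mid)))
        got = transition_slope(v, fs, baseline=-80.0)
        # oracle: closed-form 10%/90% crossing times, dense regression between
        t10 = t_mid + np.log(0.1 / 0.9) / k
        t90 = t_mid + np.log(0.9 / 0.1) / k
        tt = np.linspace(t10, t90, 100001)
        vv = -80.0 + 20.0 / (1.0 + np.exp(-k * (tt - t_mid)))
        oracle = np.polyfit(tt, vv, 1)[0]
        assert got == pytest.approx(oracle, rel=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            transition_slope(np.array([-80.0, -60.0]), 1000.0)

    def test_flat_plateau_peak(self):
        assert peak_potential(np.full(100, -55.0)) == -55.0

    def test_triangle_central_half_mean(self):
        n = 40000
        half = np.linspace(-70.0, -50.0, n // 2, endpoint=False)
        tri = np.concatenate([half, half[::-1]])
        assert peak_potential(tri) == pytest.approx(-55.0, abs=0.01)

    def test_single_sample_event(self):
        assert peak_potential(np.array([-61.0])) == -61.0


class TestStateStatistics:
    def test_zero_spikes_gives_zero_up_firing_rate(self):
        tr, _ = square_wave_trace(n_cycles=10)
        seg = segment_states(tr)
        empty = SpikeTrain(times=[], t_start=0.0, t_stop=tr.t_stop)
        st = state_statistics(seg, tr, empty, (0.5, 8.5))
        assert st.ap_rate_in_up == 0.0
        assert st.n_up > 0

    def test_square_wave_durations_and_frequency(self):
        tr, _ = square_wave_trace(n_cycles=20)  # 0.5 s DOWN / 0.4 s UP
        seg = segment_states(tr)
        st = state_statistics(seg, tr, SpikeTrain(times=[], t_start=0.0, t_stop=tr.t_stop), (1.0, 17.0))
        assert st.up_duration == pytest.approx(0.4, abs=0.05)
        assert st.down_duration == pytest.approx(0.5, abs=0.05)
        assert st.up_frequency == pytest.approx(1.0 / 0.9, rel=0.15)

    def test_window_without_up_states_has_absent_up_stats(self):
        tr = Trace(samples=np.full(10000, -70.0) + np.sin(np.arange(10000)) * 0.01, fs=1000.0)
        seg = segment_states(tr)
        st = state_statistics(seg, tr, SpikeTrain(times=[], t_start=0.0, t_stop=10.0), (0.0, 10.0))
        assert st.up_duration is None and st.up_frequency is None
        assert st.ap_rate_in_up is None

    def test_pause_deltas_have_correct_sign_in_potentials_and_firing(self):
        """Hyperpolarization and in-UP firing drop recovered on a short recording."""
        epochs = default_light_epochs(n=6, duration=5.0, interval=30.0, first_onset=10.0)
        params = UpDownParams(duration=float(epochs.offsets[-1] + 16.0), fs=500.0)
        cfg = SimConfig(seed=21, updown=params)
        sim = simulate_updown_trace(cfg, epochs)
        clean = remove_spikes(sim.trace, sim.spikes)
        seg = segment_states(clean)
        wins = condition_windows(epochs, width=5.0, t_start=0.0, t_stop=clean.t_stop)
        before = [state_statistics(seg, clean, sim.spikes, w.before) for w in wins]
        during = [state_statistics(seg, clean, sim.spikes, w.during) for w in wins]

        def mean(stats, attr):
            vals = [getattr(s, attr) for s in stats if getattr(s, attr) is not None]
            return np.mean(vals)

        assert mean(during, "down_potential") < mean(before, "down_potential")
        assert mean(during, "up_potential") < mean(before, "up_potential")
        assert mean(during, "ap_rate_in_up") < mean(before, "ap_rate_in_up")
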