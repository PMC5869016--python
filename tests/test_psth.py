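"""PSTH construction and the CUSUM significance machinery, checked against
hand computations and a brute-force oracle."""

import numpy as np
import pytest

from pause_ephys.core import EpochSet, SpikeTrain, ValidationError
from pause_ephys.experiments import bruteforce_cusum, random_psths
from pause_ephys.psth import (
    BaselineStats,
    Psth,
    baseline_stats,
    build_psth,
    critical_coefficient,
    cusum,
    group_psth,
    rebound_analysis,
    significant_bins,
)


def psth_from_counts(mean_counts, bin_width=0.25, n_pre=4):
    """A PSTH whose first n_pre bins lie before the alignment event."""
    mean_counts = np.asarray(mean_counts, dtype=float)
    edges = (np.arange(mean_counts.size + 1) - n_pre) * bin_width
    return Psth(bin_edges=edges, mean_counts=mean_counts, n_trials=1)


class TestBuildPsth:
    def test_spike_at_onset_lands_in_first_poststim_bin(self):
        train = SpikeTrain(times=[10.0], t_start=0.0, t_stop=20.0)
        events = EpochSet(epochs=[(10.0, 11.0)])
        p = build_psth(train, events, window=(-1.0, 1.0), bin_width=0.1)
        assert p.mean_counts[p.bins_in(0.0, 0.1)[0]] == 1.0
        assert p.mean_counts.sum() == 1.0

    def test_empty_train_gives_zero_psth(self, one_second_epochs):
        train = SpikeTrain(times=[], t_start=0.0, t_stop=600.0)
        p = build_psth(train, one_second_epochs)
        assert np.all(p.mean_counts == 0)

    def test_repeated_spike_gives_unit_mean_count(self, one_second_epochs):
        times = one_second_epochs.onsets + 0.25
        train = SpikeTrain(times=times, t_start=0.0, t_stop=600.0)
        p = build_psth(train, one_second_epochs, window=(-1.0, 1.0), bin_width=0.1)
        b = p.bins_in(0.2, 0.3)[0]
        assert p.mean_counts[b] == 1.0
        assert p.mean_counts.sum() == 1.0
        assert p.rate[b] == pytest.approx(10.0)  # 1 spike / 0.1 s bin

    def test_window_must_be_bin_multiple(self, one_second_epochs, periodic_train):
        with pytest.raises(ValidationError):
            build_psth(periodic_train, one_second_epochs, window=(-1.0, 1.05), bin_width=0.1)


class TestBaseline:
    def test_hand_computed_mean_and_sample_sd(self):
        p = psth_from_counts([2, 1, 3, 2, 0, 0])
        base = baseline_stats(p, (-1.0, 0.0))
        assert base.mu == pytest.approx(2.0)
        assert base.sigma == pytest.approx(0.8165, abs=1e-4)
        assert base.n1 == 4

    def test_constant_baseline_has_zero_sd(self):
        base = baseline_stats(psth_from_counts([2, 2, 2, 2, 1]), (-1.0, 0.0))
        assert base.sigma == 0.0

    def test_one_second_reference_at_100ms_bins_has_ten_bins(self, one_second_epochs, periodic_train):
        p = build_psth(periodic_train, one_second_epochs, window=(-1.0, 1.0), bin_width=0.1)
        assert baseline_stats(p, (-1.0, 0.0)).n1 == 10

    def test_single_reference_bin_rejected(self):
        with pytest.raises(ValidationError):
            baseline_stats(psth_from_counts([2, 1, 0], n_pre=1), (-0.25, 0.0))


class TestCriticalCoefficient:
    @pytest.mark.parametrize("alpha,z", [(0.01, 2.33), (0.05, 1.65)])
    def test_printed_constants(self, alpha, z):
        assert critical_coefficient(alpha) == z

    def test_general_mode_normal_quantile(self):
        assert critical_coefficient(0.05, paper_exact=False) == pytest.approx(1.6449, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.7, -0.1])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValidationError):
            critical_coefficient(alpha, paper_exact=False)


class TestCusum:
    def test_hand_computed_decrease_crossing(self):
        """Baseline mu=2, sigma=0.8165; all-zero analysis bins cross at bin 1."""
        p = psth_from_counts([2, 1, 3, 2, 0, 0, 0])
        base = baseline_stats(p, (-1.0, 0.0))
        res = cusum(p, base, alpha=0.05)
        assert res.s[0] == pytest.approx(-2.0)
        assert res.boundary[0] == pytest.approx(1.65 * 0.81649658, abs=1e-4)  # 1.347
        assert res.first_crossing_decrease == 0
        assert res.first_crossing_increase is None

    def test_null_analysis_never_crosses(self):
        p = psth_from_counts([2, 1, 3, 2, 2, 2, 2, 2])
        base = baseline_stats(p, (-1.0, 0.0))
        res = cusum(p, base, alpha=0.05)
        np.testing.assert_allclose(res.s, 0.0)
        assert res.first_crossing_decrease is None
        assert res.first_crossing_increase is None

    def test_sustained_one_sigma_increase_crosses_eventually(self):
        base_counts = [2.0, 1.0, 3.0, 2.0]
        mu, sigma = 2.0, np.std(base_counts, ddof=1)
        p = psth_from_counts(base_counts + [mu + sigma] * 50)
        res = cusum(p, baseline_stats(p, (-1.0, 0.0)), alpha=0.05)
        # linear growth of S_r beats the sqrt(r) boundary
        assert res.first_crossing_increase is not None

    def test_degenerate_baseline_rejected(self):
        p = psth_from_counts([2, 2, 2, 2, 0, 0])
        with pytest.raises(ValidationError, match="degenerate"):
            cusum(p, baseline_stats(p, (-1.0, 0.0)))

    def test_boundary_monotone_and_linear_in_sigma(self):
        p = psth_from_counts([2, 1, 3, 2, 0, 0, 0, 0])
        base = baseline_stats(p, (-1.0, 0.0))
        res = cusum(p, base, alpha=0.05)
        assert np.all(np.diff(res.boundary) > 0)
        doubled = BaselineStats(mu=base.mu, sigma=2 * base.sigma, n1=base.n1, window=base.window)
        res2 = cusum(p, doubled, alpha=0.05)
        np.testing.assert_allclose(res2.boundary, 2 * res.boundary)

    @pytest.mark.parametrize("chunk", range(5))
    def test_matches_bruteforce_oracle_on_random_psths(self, chunk):
        rng = np.random.default_rng(500 + chunk)
        for p, ref in random_psths(rng, 30):
            base = baseline_stats(p, ref)
            if base.sigma == 0:
                continue
            res = cusum(p, base, alpha=0.05)
            s, bound, dec, inc = bruteforce_cusum(
                p.mean_counts[base.n1 :], base.mu, base.sigma, res.z
            )
            np.testing.assert_allclose(res.s, s, atol=1e-12)
            np.testing.assert_allclose(res.boundary, bound, atol=1e-12)
            assert res.first_crossing_decrease == dec
            assert res.first_crossing_increase == inc


class TestSignificantBins:
    def test_two_sd_exceedance_without_crossing_is_not_flagged(self):
        # a single deep bin flanked by high bins: S_r never reaches the boundary
        p = psth_from_counts([2, 1, 3, 2, 4.0, 0.2, 4.0])
        base = baseline_stats(p, (-1.0, 0.0))
        res = cusum(p, base, alpha=0.05)
        assert res.first_crossing_decrease is None
        flags, latency = significant_bins(p, base, res, "decrease")
        assert not flags.any() and latency is None

    def test_flag_and_onset_latency_at_first_bin(self):
        p = psth_from_counts([2, 1, 3, 2, 0, 0, 0])
        base = baseline_stats(p, (-1.0, 0.0))
        res = cusum(p, base, alpha=0.05)
        flags, latency = significant_bins(p, base, res, "decrease")
        assert flags[0] and latency == pytest.approx(0.0)


class TestRebound:
    def test_flat_psth_shows_no_recovery_or_rebound(self):
        p = psth_from_counts([2, 1, 3, 2] * 4, n_pre=8)
        original = baseline_stats(p, (-2.0, 0.0))
        res = rebound_analysis(p, 1.0, (0.5, 1.0), original, alpha=0.05)
        assert res.recovery_latency is None
        assert res.rebound_duration == 0.0

    def test_constructed_rebound_duration_recovered(self, one_second_epochs):
        """5x baseline burst for 150 ms after light offset."""
        rng = np.random.default_rng(7)
        trains = []
        duration = 600.0
        base_rate, burst_rate = 4.0, 20.0
        times = np.sort(rng.uniform(0, duration, size=rng.poisson(base_rate * duration)))
        inside = one_second_epochs.contains(times)  # inhibited to 50% during light
        keep = ~inside | (rng.uniform(size=times.size) < 0.5)
        times = times[keep]
        bursts = []
        for _, off in one_second_epochs:
            n = rng.poisson((burst_rate - base_rate) * 0.15)
            bursts.append(rng.uniform(off, off + 0.15, size=n))
        times = np.unique(np.concatenate([times, *bursts]))
        train = SpikeTrain(times=times, t_start=0.0, t_stop=duration)
        p = build_psth(train, one_second_epochs, window=(-1.0, 2.0), bin_width=0.05)
        original = baseline_stats(p, (-1.0, 0.0))
        res = rebound_analysis(p, 1.0, (0.5, 1.0), original, alpha=0.05)
        assert res.rebound_duration == pytest.approx(0.15, abs=0.05)  # one bin
        assert res.recovery_latency is not None and res.recovery_latency <= 0.1

    def test_new_reference_must_end_at_offset(self):
        p = psth_from_counts([2, 1, 3, 2] * 4, n_pre=8)
        original = baseline_stats(p, (-2.0, 0.0))
        with pytest.raises(ValidationError):
            rebound_analysis(p, 1.0, (1.0, 1.5), original)


class TestGroupPsth:
    def test_idempotent_on_identical_inputs(self):
        p = psth_from_counts([2, 1, 3, 2, 0, 0])
        g = group_psth([p, p])
        np.testing.assert_allclose(g.mean_counts, p.mean_counts)
        assert g.n_trials == 2

    def test_arithmetic_mean_of_rates(self):
        p1 = psth_from_counts([1.0] * 6)
        p3 = psth_from_counts([3.0] * 6)
        np.testing.assert_allclose(group_psth([p1, p3]).mean_counts, 2.0)

    def test_mismatched_binning_rejected(self):
        p1 = psth_from_counts([1.0] * 6, bin_width=0.25)
        p2 = psth_from_counts([1.0] * 6, bin_width=0.1)
        with pytest.raises(ValidationError):
            group_psth([p1, p2])
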