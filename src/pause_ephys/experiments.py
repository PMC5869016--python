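"""Seeded benchmark experiments exercising the pipeline end to end.

Each function simulates data with the default study conditions (light-pulse
geometry, firing rates, effect sizes), runs the corresponding analysis and
returns the measured performance.  They are shared by the test suite and by
the reproduction script, so every reported number is recomputed at run time.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import synth, updown
from .psth import Psth, baseline_stats, build_psth, cusum, group_psth, significant_bins

__all__ = [
    "bruteforce_cusum",
    "random_psths",
    "cusum_oracle_agreement",
    "type1_error_rate",
    "onset_latency_replicates",
    "pause_effect_recovery",
    "mixture_recovery_errors",
]


# --------------------------------------------------------------------------- #
# CUSUM oracle equivalence
# --------------------------------------------------------------------------- #


def bruteforce_cusum(
    x: Sequence[float], mu: float, sigma: float, z: float
) -> tuple[np.ndarray, np.ndarray, int | None, int | None]:
    """Literal loop recomputation of the CUSUM series and crossings.

    Independent of the vectorized implementation: sums residuals bin by bin
    and scans for the first boundary touch in each direction.
    """
    s, bound = [], []
    total = 0.0
    dec = inc = None
    for r, xi in enumerate(x, start=1):
        total += xi - mu
        b = z * sigma * np.sqrt(r)
        s.append(total)
        bound.append(b)
        if dec is None and total <= -b:
            dec = r - 1
        if inc is None and total >= b:
            inc = r - 1
    return np.asarray(s), np.asarray(bound), dec, inc


def random_psths(rng: np.random.Generator, n: int, max_bins: int = 50):
    """Random PSTH/baseline pairs for the oracle-equivalence check."""
    for _ in range(n):
        n_base = int(rng.integers(2, 12))
        n_analysis = int(rng.integers(1, max_bins - n_base + 1))
        bin_width = float(rng.choice([0.01, 0.05, 0.1]))
        n_trials = int(rng.integers(1, 30))
        lam = float(rng.uniform(0.05, 3.0))
        counts = rng.poisson(lam, size=(n_trials, n_base + n_analysis))
        edges = (np.arange(n_base + n_analysis + 1) - n_base) * bin_width
        p = Psth(bin_edges=edges, mean_counts=counts.mean(0), n_trials=n_trials, counts=counts)
        yield p, (-n_base * bin_width, 0.0)


def cusum_oracle_agreement(seed: int, n: int = 500, max_bins: int = 50) -> float:
    """Fraction of random PSTHs on which the CUSUM implementation matches the
    brute-force oracle exactly (series, boundary and crossing indices)."""
    rng = np.random.default_rng(seed)
    matched = 0
    checked = 0
    for p, ref in random_psths(rng, n, max_bins):
        base = baseline_stats(p, ref)
        if base.sigma == 0:
            continue  # degenerate baseline is rejected by both routes
        alpha = float(rng.choice([0.01, 0.05]))
        res = cusum(p, base, alpha=alpha)
        x = p.mean_counts[base.n1 :]
        s, bound, dec, inc = bruteforce_cusum(x, base.mu, base.sigma, res.z)
        checked += 1
        if (
            np.allclose(res.s, s, rtol=0, atol=1e-12)
            and np.allclose(res.boundary, bound, rtol=0, atol=1e-12)
            and res.first_crossing_decrease == dec
            and res.first_crossing_increase == inc
        ):
            matched += 1
    return matched / checked


# --------------------------------------------------------------------------- #
# false-positive rate on unmodulated cells
# --------------------------------------------------------------------------- #


def type1_error_rate(
    seed: int,
    n_cells: int = 1000,
    n_trials: int = 10,
    alpha: float = 0.05,
    bin_width: float = 0.1,
) -> float:
    """Per-cell decrease-flag rate of the full procedure on homogeneous
    Poisson cells (1.5 Hz baseline, no modulation): nominally ~alpha."""
    cfg = replace(synth.SimConfig(seed=seed), spn=replace(synth.SpnParams(), depth=0.0))
    epochs = synth.default_light_epochs(n=n_trials, duration=1.0, interval=50.0)
    duration = float(epochs.offsets[-1] + 5.0)
    rng = cfg.rng("spn")
    flags = 0
    for _ in range(n_cells):
        train, _ = synth.simulate_spn_train(cfg, epochs, duration=duration, rng=rng)
        p = build_psth(train, epochs, window=(-1.0, 1.0), bin_width=bin_width)
        base = baseline_stats(p, (-1.0, 0.0))
        if base.sigma == 0:
            continue  # no baseline variability: procedure cannot flag anything
        res = cusum(p, base, alpha=alpha)
        _, latency = significant_bins(p, base, res, "decrease")
        flags += latency is not None
    return flags / n_cells


# --------------------------------------------------------------------------- #
# group onset-latency recovery
# --------------------------------------------------------------------------- #


def onset_latency_replicates(
    seed: int,
    n_replicates: int = 20,
    n_cells: int = 200,
    n_trials: int = 10,
    alpha: float = 0.01,
    bin_width: float = 0.1,
) -> list[float | None]:
    """Group CUSUM onset latency over seeded replicates of the SPN experiment
    (44% inhibition starting 0.4 s after light onset; 1 s light pulses)."""
    cfg = synth.SimConfig(seed=seed)
    epochs = synth.default_light_epochs(n=n_trials, duration=1.0, interval=50.0)
    duration = float(epochs.offsets[-1] + 5.0)
    rng = cfg.rng("spn")
    latencies: list[float | None] = []
    for _ in range(n_replicates):
        psths = []
        for _ in range(n_cells):
            train, _ = synth.simulate_spn_train(cfg, epochs, duration=duration, rng=rng)
            psths.append(build_psth(train, epochs, window=(-1.0, 2.0), bin_width=bin_width))
        group = group_psth(psths)
        base = baseline_stats(group, (-1.0, 0.0))
        res = cusum(group, base, alpha=alpha)
        _, latency = significant_bins(group, base, res, "decrease")
        latencies.append(latency)
    return latencies


def group_inhibition_pct(
    seed: int, n_cells: int = 200, n_trials: int = 10, bin_width: float = 0.1
) -> float:
    """Percent firing inhibition of the simulated SPN group during the
    inhibited part of a 1 s light pulse, relative to the pre-light baseline."""
    cfg = synth.SimConfig(seed=seed)
    epochs = synth.default_light_epochs(n=n_trials, duration=1.0, interval=50.0)
    duration = float(epochs.offsets[-1] + 5.0)
    rng = cfg.rng("spn")
    psths = []
    for _ in range(n_cells):
        train, _ = synth.simulate_spn_train(cfg, epochs, duration=duration, rng=rng)
        psths.append(build_psth(train, epochs, window=(-1.0, 1.0), bin_width=bin_width))
    group = group_psth(psths)
    base = baseline_stats(group, (-1.0, 0.0))
    delay = cfg.spn.onset_delay
    inhibited = group.mean_counts[group.bins_in(delay, 1.0)]
    return 100.0 * (1.0 - float(np.mean(inhibited)) / base.mu)


def cin_rebound_metrics(
    seed: int,
    n_cells: int = 16,
    n_trials: int = 10,
    light_duration: float = 1.0,
    bin_width: float = 0.01,
) -> tuple[float, float]:
    """Rebound onset and duration (ms) of the simulated CIN group PSTH.

    Onset is the left edge of the first post-offset bin exceeding the
    pre-light baseline mean by 2 SD; duration is the length of the first
    contiguous run of such bins.
    """
    psths = []
    epochs = synth.default_light_epochs(n=n_trials, duration=light_duration, interval=50.0)
    duration = float(epochs.offsets[-1] + 5.0)
    ss = np.random.SeedSequence([seed, 77])
    for child in ss.spawn(n_cells):
        cfg = synth.SimConfig(seed=int(child.generate_state(1)[0] % (2**31)))
        train, _ = synth.simulate_cin_train(cfg, epochs, duration=duration)
        psths.append(build_psth(train, epochs, window=(-1.0, 2.0), bin_width=bin_width))
    group = group_psth(psths)
    base = baseline_stats(group, (-1.0, 0.0))
    post = group.bins_in(light_duration, 2.0)
    above = group.mean_counts[post] > base.mu + 2.0 * base.sigma
    hit = np.flatnonzero(above)
    if hit.size == 0:
        return np.nan, 0.0
    onset = float(group.bin_edges[post[hit[0]]]) - light_duration
    run = hit[0]
    while run < above.size and above[run]:
        run += 1
    return onset * 1e3, (run - hit[0]) * bin_width * 1e3


# --------------------------------------------------------------------------- #
# UP/DOWN pause-effect recovery
# --------------------------------------------------------------------------- #


def _pooled_condition_measures(
    seg, trace, spikes, windows: list[tuple[float, float]], fit_max: int = 60_000
) -> dict[str, float]:
    """Pool UP durations, spikes-in-UP and membrane samples across windows.

    An UP state belongs to a window when its onset falls inside it.
    """
    ups = np.asarray(seg.of_state(updown.UP), dtype=float).reshape(-1, 2)
    win = np.asarray(sorted(windows), dtype=float).reshape(-1, 2)
    idx = np.searchsorted(win[:, 0], ups[:, 0], side="right") - 1
    in_win = (idx >= 0) & (ups[:, 0] < win[np.clip(idx, 0, None), 1])
    sel = ups[in_win]
    durations = sel[:, 1] - sel[:, 0]
    n_spikes = int(
        np.sum(
            np.searchsorted(spikes.times, sel[:, 1], side="left")
            - np.searchsorted(spikes.times, sel[:, 0], side="left")
        )
    )
    up_time = float(durations.sum())
    samples = np.concatenate([trace.slice(w0, w1) for w0, w1 in win])
    fit = updown.allpoints_gaussian_fit(samples, max_samples=fit_max)
    return {
        "m_down": fit.m_down,
        "m_up": fit.m_up,
        "up_duration": float(np.mean(durations)) if durations.size else np.nan,
        "ap_rate_in_up": n_spikes / up_time if up_time > 0 else np.nan,
        "n_up": int(durations.size),
    }


def pause_effect_recovery(
    seed: int,
    n_seeds: int = 50,
    n_epochs: int = 500,
    fs: float = 500.0,
    window_width: float = 5.0,
) -> pd.DataFrame:
    """Recover the pause effects (hyperpolarization, UP shortening, in-UP
    firing drop) from seeded two-state simulations.

    Each seed simulates one long whole-cell recording with 5 s light epochs at
    the standard 30 s cadence, despikes it, segments UP/DOWN states, and pools
    the before/during condition windows.  The recording length (``n_epochs``)
    is set by an a-priori power analysis: the 0.03 s shift of an exponential
    UP dwell (SD = mean = 0.42 s) needs on the order of a thousand UP states
    per condition before its sign is recovered reliably within a single
    recording.  Returns one row per seed with the during-minus-before deltas.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    epochs = synth.default_light_epochs(n=n_epochs, duration=5.0, interval=30.0, first_onset=10.0)
    duration = float(epochs.offsets[-1] + 16.0)  # room for the last after-window
    for child in ss.spawn(n_seeds):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(
            synth.SimConfig(seed=child_seed),
            updown=replace(synth.UpDownParams(), fs=fs, duration=duration),
        )
        sim = synth.simulate_updown_trace(cfg, epochs)
        clean = updown.remove_spikes(sim.trace, sim.spikes)
        seg = updown.segment_states(clean)
        wins = updown.condition_windows(
            epochs, width=window_width, post_gap=10.0, t_start=clean.t_start, t_stop=clean.t_stop
        )
        before = _pooled_condition_measures(seg, clean, sim.spikes, [w.before for w in wins])
        during = _pooled_condition_measures(seg, clean, sim.spikes, [w.during for w in wins])
        rows.append(
            {
                "seed": child_seed,
                "d_m_down": during["m_down"] - before["m_down"],
                "d_m_up": during["m_up"] - before["m_up"],
                "d_up_duration": during["up_duration"] - before["up_duration"],
                "d_ap_rate": during["ap_rate_in_up"] - before["ap_rate_in_up"],
                "m_down_before": before["m_down"],
                "m_up_before": before["m_up"],
                "n_up_before": before["n_up"],
                "n_up_during": during["n_up"],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# two-Gaussian fit accuracy
# --------------------------------------------------------------------------- #


def mixture_recovery_errors(
    seed: int,
    n_samples: int = 50_000,
    m_down: float = -72.0,
    m_up: float = -56.0,
    s_down: float = 2.0,
    s_up: float = 3.0,
    w_down: float = 0.55,
) -> tuple[float, float]:
    """Absolute errors (mV) of the fitted component means on a known mixture."""
    rng = np.random.default_rng(seed)
    n_down = rng.binomial(n_samples, w_down)
    x = np.concatenate(
        [
            rng.normal(m_down, s_down, size=n_down),
            rng.normal(m_up, s_up, size=n_samples - n_down),
        ]
    )
    rng.shuffle(x)
    fit = updown.allpoints_gaussian_fit(x)
    return abs(fit.m_down - m_down), abs(fit.m_up - m_up)
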