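"""UP/DOWN membrane-state analysis of whole-cell traces.

Under ketamine/xylazine anesthesia the membrane potential of a spiny
projection neuron alternates between a hyperpolarized DOWN state and a
near-threshold UP state, producing a bimodal all-points amplitude histogram.
This module despikes the trace, fits a two-Gaussian mixture to the amplitude
distribution, segments states by a fast/slow moving-average crossover, and
computes the per-condition state statistics (potentials, dwell durations,
UP frequency and amplitude, within-UP firing rate, and the 10-90% rising
slope of the DOWN-to-UP transition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import linregress
from sklearn.mixture import GaussianMixture

from .core import EpochSet, SpikeTrain, Trace, ValidationError

__all__ = [
    "GaussianPair",
    "SegmentationParams",
    "StateSegmentation",
    "StateStats",
    "ConditionWindows",
    "remove_spikes",
    "allpoints_gaussian_fit",
    "segment_states",
    "condition_windows",
    "state_statistics",
    "up_state_average",
    "transition_slope",
    "peak_potential",
]

UP, DOWN = "UP", "DOWN"


@dataclass(frozen=True)
class GaussianPair:
    """Two-Gaussian fit of the all-points membrane-potential histogram.

    Components are ordered so ``m_down < m_up``.  ``unimodal`` flags fits where
    the separation of the means is smaller than the sum of the component SDs,
    i.e. the data carry little evidence of two states.
    """

    w_down: float
    w_up: float
    m_down: float  # mV
    m_up: float  # mV
    s_down: float  # mV
    s_up: float  # mV
    unimodal: bool = False

    def __post_init__(self) -> None:
        if not (self.w_down > 0 and self.w_up > 0):
            raise ValidationError("mixture weights must be positive")
        if abs(self.w_down + self.w_up - 1.0) > 1e-6:
            raise ValidationError("mixture weights must sum to 1")
        if not self.m_down < self.m_up:
            raise ValidationError("components must be ordered m_down < m_up")
        if not (self.s_down > 0 and self.s_up > 0):
            raise ValidationError("component SDs must be positive")

    @property
    def amplitude(self) -> float:
        """UP-state amplitude, ``m_up - m_down`` (mV)."""
        return self.m_up - self.m_down


@dataclass(frozen=True)
class SegmentationParams:
    """Moving-average crossover parameters.

    The fast average tracks the instantaneous state; the slow average spans
    at least a full UP/DOWN cycle, so it settles between the two potential
    levels and acts as an adaptive threshold that the fast average crosses at
    each transition.  UP (and, symmetrically, DOWN) excursions shorter than
    the minimum duration are merged into the flanking state; the
    membrane-state literature applies the 0.2 s filter to UP states and we
    extend it symmetrically to suppress state chatter.
    """

    fast_window: float = 0.005  # s
    slow_window: float = 1.5  # s
    min_up_duration: float = 0.2  # s
    min_down_duration: float = 0.2  # s

    def __post_init__(self) -> None:
        if not 0 < self.fast_window < self.slow_window:
            raise ValidationError("need 0 < fast_window < slow_window")
        if self.min_up_duration < 0 or self.min_down_duration < 0:
            raise ValidationError("minimum durations must be >= 0")


@dataclass(frozen=True)
class StateSegmentation:
    """Alternating UP/DOWN intervals tiling a trace."""

    segments: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((str(s), float(a), float(b)) for s, a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        for state, a, b in segs:
            if state not in {UP, DOWN}:
                raise ValidationError(f"unknown state {state!r}")
            if not a < b:
                raise ValidationError("segment must satisfy t_start < t_end")
        for (s0, _, e0), (s1, a1, _) in zip(segs, segs[1:]):
            if abs(e0 - a1) > 1e-9:
                raise ValidationError("segments must be contiguous")
            if s0 == s1:
                raise ValidationError("segment states must alternate")

    def __len__(self) -> int:
        return len(self.segments)

    def of_state(self, state: str) -> list[tuple[float, float]]:
        return [(a, b) for s, a, b in self.segments if s == state]

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0][1], self.segments[-1][2]


@dataclass(frozen=True)
class ConditionWindows:
    """Before/during/after analysis windows for one light epoch."""

    before: tuple[float, float]
    during: tuple[float, float]
    after: tuple[float, float]


@dataclass(frozen=True)
class StateStats:
    """Per-window state statistics; UP fields are None when the window holds no UP state."""

    up_potential: float | None  # mV, UP Gaussian mean
    down_potential: float | None  # mV, DOWN Gaussian mean
    up_duration: float | None  # s, mean dwell
    down_duration: float | None  # s, mean dwell
    up_frequency: float | None  # Hz, UP onsets per second of window
    up_amplitude: float | None  # mV, m_up - m_down
    w_up: float | None  # mixture weight of the UP component
    ap_rate_in_up: float | None  # Hz, spikes per second of UP time
    slope_10_90: float | None  # mV/s, mean DOWN->UP transition slope
    n_up: int
    n_down: int


# --------------------------------------------------------------------------- #
# despiking
# --------------------------------------------------------------------------- #


def remove_spikes(
    trace: Trace, spikes: SpikeTrain, blank: tuple[float, float] = (0.001, 0.004)
) -> Trace:
    """Blank action potentials by linear interpolation.

    Samples within ``[t - pre, t + post]`` of each spike are replaced by the
    straight line joining the window-edge samples; overlapping windows are
    merged into a single interpolation span.
    """
    pre, post = blank
    if pre < 0 or post < 0 or pre + post <= 0:
        raise ValidationError("blank windows must be positive")
    if spikes.n_spikes == 0:
        return trace
    n = trace.n_samples
    iv = []
    for t in spikes.times:
        i0 = int(np.floor((t - pre - trace.t_start) * trace.fs))
        i1 = int(np.ceil((t + post - trace.t_start) * trace.fs))
        iv.append((max(i0, 0), min(i1, n - 1)))
    iv.sort()
    merged = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = trace.samples.copy()
    for a, b in merged:
        lo = a - 1 if a > 0 else b + 1
        hi = b + 1 if b + 1 < n else a - 1
        if lo < 0 and hi >= n:
            continue  # blank covers the whole trace; nothing to anchor on
        if a == 0:
            out[a : b + 1] = out[min(hi, n - 1)]
        elif b == n - 1:
            out[a:] = out[a - 1]
        else:
            out[a : b + 1] = np.interp(np.arange(a, b + 1), [a - 1, b + 1], [out[a - 1], out[b + 1]])
    return Trace(samples=out, fs=trace.fs, t_start=trace.t_start)


# --------------------------------------------------------------------------- #
# all-points two-Gaussian fit
# --------------------------------------------------------------------------- #


def allpoints_gaussian_fit(
    trace: Trace | np.ndarray,
    window: tuple[float, float] | None = None,
    max_samples: int | None = None,
    max_iter: int = 500,
) -> GaussianPair:
    """Maximum-likelihood two-Gaussian fit of the amplitude distribution.

    Initialization is deterministic: component means start at the 25th/75th
    percentiles of the data with equal weights, so the fit is a pure function
    of the samples.  ``max_samples`` optionally thins the data with a uniform
    stride (deterministic) to bound the EM cost on long traces.
    """
    if isinstance(trace, Trace):
        x = trace.slice(*window) if window is not None else trace.samples
    else:
        x = np.asarray(trace, dtype=float)
        if window is not None:
            raise ValidationError("window requires a Trace input")
    if x.size < 10:
        raise ValidationError("too few samples for a two-component fit")
    if np.std(x) == 0:
        raise ValidationError("zero-variance data: all samples identical")
    if max_samples is not None and x.size > max_samples:
        stride = int(np.ceil(x.size / max_samples))
        x = x[::stride]
    q25, q75 = np.percentile(x, [25, 75])
    var0 = max(np.var(x) / 4.0, 1e-6)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        weights_init=[0.5, 0.5],
        means_init=[[q25], [q75]],
        precisions_init=[1.0 / var0, 1.0 / var0],
        max_iter=max_iter,
        tol=1e-6,
        reg_covar=1e-9,
    )
    gm.fit(x.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"two-Gaussian fit did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.4g})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    (m_down, m_up), (s_down, s_up), (w_down, w_up) = means[order], sds[order], weights[order]
    return GaussianPair(
        w_down=float(w_down),
        w_up=float(w_up),
        m_down=float(m_down),
        m_up=float(m_up),
        s_down=float(s_down),
        s_up=float(s_up),
        unimodal=bool(m_up - m_down < s_down + s_up),
    )


# --------------------------------------------------------------------------- #
# moving-average crossover segmentation
# --------------------------------------------------------------------------- #


def _run_bounds(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal constant runs of a boolean array: (starts, ends_exclusive, values)."""
    change = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [mask.size]])
    return starts, ends, mask[starts]


def segment_states(trace: Trace, params: SegmentationParams | None = None) -> StateSegmentation:
    """Detect UP/DOWN states by a fast/slow moving-average crossover.

    A sample is provisionally UP when the fast moving average exceeds the slow
    one.  UP runs shorter than ``min_up_duration`` are merged into the flanking
    DOWN state; interior DOWN runs shorter than ``min_down_duration`` are then
    merged into the flanking UP state.  The result alternates and tiles the
    trace exactly.
    """
    params = params or SegmentationParams()
    n_slow = int(round(params.slow_window * trace.fs))
    if n_slow >= trace.n_samples:
        raise ValidationError("trace shorter than the slow moving-average window")
    n_fast = max(int(round(params.fast_window * trace.fs)), 1)
    fast = uniform_filter1d(trace.samples, size=n_fast, mode="nearest")
    slow = uniform_filter1d(trace.samples, size=max(n_slow, 1), mode="nearest")
    up = fast > slow
    min_up_n = int(round(params.min_up_duration * trace.fs))
    min_down_n = int(round(params.min_down_duration * trace.fs))
    # pass 1: remove short UP excursions (incl. boundary chatter)
    starts, ends, vals = _run_bounds(up)
    lens = ends - starts
    vals = vals & (lens >= min_up_n)
    up = np.repeat(vals, lens)
    # pass 2: absorb short interior DOWN gaps into the surrounding UP state
    starts, ends, vals = _run_bounds(up)
    lens = ends - starts
    if vals.size > 2:
        interior = np.ones(vals.size, dtype=bool)
        interior[0] = interior[-1] = False
        vals = vals | (~vals & interior & (lens < min_down_n))
        up = np.repeat(vals, lens)
    starts, ends, vals = _run_bounds(up)
    segs = []
    for a, b, val in zip(starts, ends, vals):
        t0 = trace.t_start + a / trace.fs
        t1 = trace.t_start + b / trace.fs
        segs.append((UP if val else DOWN, t0, t1))
    return StateSegmentation(segments=tuple(segs))


def condition_windows(
    epochs: EpochSet,
    width: float = 5.0,
    post_gap: float = 10.0,
    pre: float | None = None,
    t_start: float | None = None,
    t_stop: float | None = None,
) -> list[ConditionWindows]:
    """Before/during/after windows for each light epoch.

    ``before = [onset - pre, onset)``, ``during = [onset, onset + width)``,
    ``after = [offset + post_gap, offset + post_gap + width)``; ``pre``
    defaults to ``width``.  Epochs shorter than ``width`` raise; window triples
    reaching beyond the recording limits (when given) are skipped with a
    warning.
    """
    pre = width if pre is None else pre
    out = []
    for onset, offset in epochs:
        if offset - onset + 1e-9 < width:
            raise ValidationError("epoch shorter than the during-window width")
        w = ConditionWindows(
            before=(onset - pre, onset),
            during=(onset, onset + width),
            after=(offset + post_gap, offset + post_gap + width),
        )
        lo = w.before[0]
        hi = w.after[1]
        if (t_start is not None and lo < t_start) or (t_stop is not None and hi > t_stop):
            warnings.warn(
                f"epoch ({onset:g}, {offset:g}): condition windows extend beyond the "
                "recording; skipped",
                stacklevel=2,
            )
            continue
        out.append(w)
    return out


# --------------------------------------------------------------------------- #
# per-window statistics
# --------------------------------------------------------------------------- #


def _extract_up_event(
    trace: Trace, t0: float, t1: float, baseline_pre: float = 0.05
) -> tuple[np.ndarray, int]:
    """Event waveform from ``t0 - baseline_pre`` to ``t1`` and the onset index."""
    i0 = max(trace.index_at(t0 - baseline_pre), 0)
    on = trace.index_at(t0)
    i1 = trace.index_at(t1)
    return trace.samples[i0 : i1 + 1], on - i0


def transition_slope(
    event: np.ndarray, fs: float, baseline: float | None = None
) -> float:
    """Slope of the DOWN-to-UP transition in mV/s.

    Least-squares slope over the rising-phase samples between the 10% and 90%
    amplitude points (relative to ``baseline``, the first sample when not
    given): from the last sample at/below 10% preceding the first sample
    at/above 90% of the peak amplitude.
    """
    event = np.asarray(event, dtype=float)
    if event.size < 3:
        raise ValidationError("event too short for a slope fit")
    base = float(event[0]) if baseline is None else float(baseline)
    rel = event - base
    peak = int(np.argmax(rel))
    amp = rel[peak]
    if amp <= 0:
        raise ValidationError("event has no rising phase above baseline")
    hi_cross = np.nonzero(rel[: peak + 1] >= 0.9 * amp)[0]
    i90 = int(hi_cross[0]) if hi_cross.size else peak
    lo_cross = np.nonzero(rel[: i90 + 1] <= 0.1 * amp)[0]
    i10 = int(lo_cross[-1]) if lo_cross.size else 0
    sel = np.arange(i10, i90 + 1)
    if sel.size < 3:
        raise ValidationError("fewer than 3 samples in the 10-90% rising region")
    t = sel / fs
    return float(linregress(t, event[sel]).slope)


def peak_potential(event: np.ndarray) -> float:
    """Mean of the samples in the central 50% of the event's time span (mV)."""
    event = np.asarray(event, dtype=float)
    if event.size == 0:
        raise ValidationError("empty event")
    n = event.size
    lo, hi = n // 4, int(np.ceil(3 * n / 4))
    if lo >= hi:
        return float(np.mean(event))
    return float(np.mean(event[lo:hi]))


def up_state_average(
    trace: Trace,
    seg: StateSegmentation,
    window: tuple[float, float] | None = None,
    half_width: float = 0.5,
    baseline_pre: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Center-aligned, baseline-scaled average of UP-state waveforms.

    Each UP event (onset inside ``window`` when given) is time-centered on its
    midpoint and offset so the mean of the ``baseline_pre`` seconds before its
    onset maps to 0 mV; events are then averaged point-wise on a fixed
    ``+-half_width`` grid (samples outside an event's recording range are
    ignored).  Returns (time offsets, mean waveform).
    """
    offsets = np.arange(-half_width, half_width + 0.5 / trace.fs, 1.0 / trace.fs)
    rows = []
    for t0, t1 in seg.of_state(UP):
        if window is not None and not (window[0] <= t0 < window[1]):
            continue
        base_seg = trace.slice(t0 - baseline_pre, t0)
        if base_seg.size == 0:
            continue
        base = float(np.mean(base_seg))
        mid = 0.5 * (t0 + t1)
        idx = np.round((mid + offsets - trace.t_start) * trace.fs).astype(int)
        row = np.full(offsets.size, np.nan)
        ok = (idx >= 0) & (idx < trace.n_samples)
        row[ok] = trace.samples[idx[ok]] - base
        rows.append(row)
    if not rows:
        raise ValidationError("no UP states to average")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(np.vstack(rows), axis=0)
    return offsets, avg


def state_statistics(
    seg: StateSegmentation,
    trace: Trace,
    spikes: SpikeTrain,
    window: tuple[float, float],
    baseline_pre: float = 0.05,
    fit_max_samples: int | None = 100_000,
) -> StateStats:
    """State statistics for one condition window.

    Segments belong to the window by their onset.  Potentials and mixture
    weight come from a two-Gaussian fit restricted to the window's samples;
    the within-UP firing rate divides the spikes falling inside the window's
    UP segments by their total duration; the 10-90% slope is averaged over the
    window's DOWN-to-UP transitions.
    """
    w0, w1 = window
    ups = [(a, b) for a, b in seg.of_state(UP) if w0 <= a < w1]
    downs = [(a, b) for a, b in seg.of_state(DOWN) if w0 <= a < w1]
    try:
        fit = allpoints_gaussian_fit(trace, window=window, max_samples=fit_max_samples)
    except (ValidationError, RuntimeError):
        fit = None
    up_dur = float(np.mean([b - a for a, b in ups])) if ups else None
    down_dur = float(np.mean([b - a for a, b in downs])) if downs else None
    up_freq = len(ups) / (w1 - w0)
    ap_rate = None
    if ups:
        tot = sum(b - a for a, b in ups)
        n_sp = sum(int(np.sum((spikes.times >= a) & (spikes.times < b))) for a, b in ups)
        ap_rate = n_sp / tot
    slopes = []
    for a, b in ups:
        event, onset = _extract_up_event(trace, a, b, baseline_pre)
        if onset <= 0:
            continue
        base = float(np.mean(event[:onset]))
        try:
            slopes.append(transition_slope(event, trace.fs, baseline=base))
        except ValidationError:
            continue
    return StateStats(
        up_potential=fit.m_up if fit and ups else None,
        down_potential=fit.m_down if fit else None,
        up_duration=up_dur,
        down_duration=down_dur,
        up_frequency=up_freq if ups else None,
        up_amplitude=fit.amplitude if fit and ups else None,
        w_up=fit.w_up if fit and ups else None,
        ap_rate_in_up=ap_rate,
        slope_10_90=float(np.mean(slopes)) if slopes else None,
        n_up=len(ups),
        n_down=len(downs),
    )
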