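"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators are phenomenological emulations of the recordings the analyses
were designed for:

* tonically firing cholinergic interneurons (CINs) modelled as a gamma
  renewal process (regular, low-CV firing), silenced inside light epochs and
  followed by a brief rebound burst;
* sparsely firing spiny projection neurons (SPNs) as an inhomogeneous Poisson
  process whose rate drops by a configurable depth starting a fixed delay
  after light onset;
* two-state (UP/DOWN) membrane potential as a semi-Markov alternation with
  exponential dwell times, state-dependent Gaussian noise, finite-rise
  transitions, and pause-dependent hyperpolarization / UP shortening;
* juxtacellular traces as noise plus a stereotyped spike waveform;
* EPSP sweep sets as sums of alpha-function responses with geometric
  per-pulse facilitation;
* current-step protocols as leaky-integrator responses with a threshold
  current above which the spike count grows linearly.

Every generator is a pure function of (config, epochs): a fixed seed gives
identical output, and each returns machine-readable ground truth sufficient
to score the downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import EpochSet, SpikeTrain, SweepSet, Trace
from .spikes import StepProtocol
from .updown import DOWN, UP, StateSegmentation

__all__ = [
    "CinParams",
    "SpnParams",
    "UpDownParams",
    "JuxtaParams",
    "EpspParams",
    "StepParams",
    "SimConfig",
    "UpDownSim",
    "simulate_cin_train",
    "simulate_spn_train",
    "simulate_updown_trace",
    "simulate_juxta_trace",
    "simulate_epsp_sweeps",
    "simulate_step_protocol",
    "default_light_epochs",
]

# stage offsets keep the per-generator random streams independent
_STAGE = {"cin": 1, "spn": 2, "updown": 3, "juxta": 4, "epsp": 5, "steps": 6}


@dataclass(frozen=True)
class CinParams:
    """Tonic CIN firing: gamma renewal at ~4 Hz with shape 4, giving ISIs
    spanning roughly 0.14-0.9 s; complete silencing during light; rebound
    burst ~70 ms after offset lasting ~140 ms."""

    rate: float = 4.0  # Hz
    shape: float = 4.0  # gamma renewal shape (CV = 1/sqrt(shape))
    rebound_multiplier: float = 5.0  # rebound rate / baseline rate
    rebound_onset: float = 0.07  # s after light offset
    rebound_onset_jitter: float = 0.01  # SD of per-epoch onset jitter, s
    rebound_duration: float = 0.14  # s


@dataclass(frozen=True)
class SpnParams:
    """Sparse SPN firing with delayed-onset inhibition during light: baseline
    1.5 Hz, rate dropping by ``depth`` (fractional, 43.7% by default) from
    ``onset_delay`` after light onset until light offset."""

    baseline_rate: float = 1.5  # Hz
    onset_delay: float = 0.4  # s
    depth: float = 0.437  # fraction of baseline removed


@dataclass(frozen=True)
class UpDownParams:
    """Two-state membrane potential with pause effects.

    Dwell times are exponential (UP 0.42 s / DOWN 0.51 s; UP mean shortens to
    0.39 s during light).  State potentials sit at -71.6 / -56.4 mV and shift
    by the pause deltas during light.  DOWN-to-UP transitions are linear ramps
    with a 10-90% rise time chosen so the rising slope is ~146 mV/s before
    and ~128 mV/s during a pause.  Poisson spikes occur within UP states
    (1.94 Hz before/after, 0.86 Hz during light)."""

    fs: float = 1000.0  # Hz
    duration: float = 60.0  # s
    up_mean: float = 0.42  # s
    down_mean: float = 0.51  # s
    pause_up_mean: float = 0.39  # s
    m_down: float = -71.6  # mV
    m_up: float = -56.4  # mV
    pause_down_shift: float = -1.2  # mV
    pause_up_shift: float = -1.4  # mV
    s_down: float = 2.0  # mV noise SD in DOWN
    s_up: float = 3.0  # mV noise SD in UP
    rise_10_90: float = 0.104  # s -> slope (m_up-m_down)/(rise/0.8) ~ 146 mV/s
    pause_rise_10_90: float = 0.119  # s -> ~128 mV/s
    ap_rate_up: float = 1.94  # Hz within UP, outside light
    ap_rate_up_pause: float = 0.86  # Hz within UP, during light
    ap_amplitude: float = 45.0  # mV above local potential
    ap_width: float = 0.002  # s


@dataclass(frozen=True)
class JuxtaParams:
    """High-pass-filtered juxtacellular signal: white noise plus a stereotyped
    biphasic spike waveform at each spike time."""

    fs: float = 20000.0  # Hz
    noise_sd: float = 0.2  # mV
    amplitude: float = 2.0  # mV, positive peak
    width_sigma: float = 0.0004  # s, Gaussian width of the main lobe
    undershoot: float = 0.3  # fraction of amplitude


@dataclass(frozen=True)
class EpspParams:
    """10-stimulus 25 Hz EPSP trains built from alpha functions.

    The k-th EPSP amplitude is ``a1 * f**(k-1)`` with ``f`` tuned so the
    last/first ratio matches the target for each condition (before: first
    4.3 mV, ratio 1.59; pause: first 5.16 mV, ratio 1.29)."""

    fs: float = 10000.0  # Hz
    n_stim: int = 10
    stim_rate: float = 25.0  # Hz
    first_stim: float = 0.1  # s from sweep start
    tau: float = 0.004  # s, alpha-function time constant
    tail: float = 0.2  # s after the last stimulus
    n_sweeps: int = 10  # per condition
    noise_sd: float = 0.1  # mV
    first_before: float = 4.3  # mV
    ratio_before: float = 1.59
    first_pause: float = 5.16  # mV
    ratio_pause: float = 1.29


@dataclass(frozen=True)
class StepParams:
    """500 ms current steps at 20 pA increments with a threshold current above
    which the spike count increases linearly."""

    fs: float = 10000.0  # Hz
    start_current: float = 260.0  # pA
    increment: float = 20.0  # pA
    n_steps: int = 8
    step_duration: float = 0.5  # s
    pre: float = 0.1  # s before the step
    post: float = 0.1  # s after the step
    rest: float = -80.0  # mV
    input_resistance: float = 0.05  # mV/pA (50 MOhm)
    tau_m: float = 0.02  # s membrane time constant
    threshold_current: float = 320.0  # pA
    spikes_per_increment: float = 1.0  # extra spikes per +20 pA above threshold
    spike_peak: float = 20.0  # mV
    noise_sd: float = 0.0  # mV


@dataclass(frozen=True)
class SimConfig:
    """Root configuration: one seed, one parameter block per generator."""

    seed: int = 0
    cin: CinParams = field(default_factory=CinParams)
    spn: SpnParams = field(default_factory=SpnParams)
    updown: UpDownParams = field(default_factory=UpDownParams)
    juxta: JuxtaParams = field(default_factory=JuxtaParams)
    epsp: EpspParams = field(default_factory=EpspParams)
    steps: StepParams = field(default_factory=StepParams)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STAGE[stage]]))


def default_light_epochs(
    n: int = 10, duration: float = 1.0, interval: float = 50.0, first_onset: float = 10.0
) -> EpochSet:
    """Light pulses delivered at a fixed interval (0.5/1 s pulses every 50 s
    for spike-train experiments; 5 s pulses every 30 s for whole-cell ones)."""
    onsets = first_onset + interval * np.arange(n)
    return EpochSet(epochs=np.column_stack([onsets, onsets + duration]), label="light")


# --------------------------------------------------------------------------- #
# spike-train generators
# --------------------------------------------------------------------------- #


def _renewal_train(rng: np.random.Generator, rate: float, shape: float, t0: float, t1: float) -> np.ndarray:
    """Gamma renewal spike times in [t0, t1)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    mean_isi = 1.0 / rate
    n_guess = int((t1 - t0) * rate * 1.5 + 20)
    times = []
    t = t0 + rng.gamma(shape, mean_isi / shape)
    while t < t1:
        times.append(t)
        t += rng.gamma(shape, mean_isi / shape)
        if len(times) > 100 * n_guess:  # safety, unreachable in practice
            break
    return np.asarray(times)


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _finalize(times: np.ndarray, t_start: float, t_stop: float, unit_id: str) -> SpikeTrain:
    times = np.unique(times[(times >= t_start) & (times < t_stop)])
    return SpikeTrain(times=times, t_start=t_start, t_stop=t_stop, unit_id=unit_id)


def simulate_cin_train(
    cfg: SimConfig, epochs: EpochSet, duration: float = 100.0, unit_id: str = "cin0"
) -> tuple[SpikeTrain, dict[str, Any]]:
    """Tonic CIN spiking, fully silenced inside light epochs, with rebound.

    Returns the train plus ground truth (silenced windows and per-epoch
    rebound windows)."""
    p = cfg.cin
    rng = cfg.rng("cin")
    base = _renewal_train(rng, p.rate, p.shape, 0.0, duration)
    if len(epochs):
        base = base[~epochs.contains(base)]
    rebound_windows = []
    extra = []
    for _, offset in epochs:
        onset = max(p.rebound_onset + rng.normal(0.0, p.rebound_onset_jitter), 0.0)
        w0 = offset + onset
        w1 = w0 + p.rebound_duration
        rebound_windows.append((w0, w1))
        if w0 < duration:
            extra.append(
                _poisson_times(rng, (p.rebound_multiplier - 1.0) * p.rate, w0, min(w1, duration))
            )
    times = np.sort(np.concatenate([base, *extra])) if extra else base
    truth = {
        "rate": p.rate,
        "silenced": [tuple(e) for e in epochs] if len(epochs) else [],
        "rebound_windows": rebound_windows,
        "rebound_rate": p.rebound_multiplier * p.rate,
    }
    return _finalize(times, 0.0, duration, unit_id), truth


def simulate_spn_train(
    cfg: SimConfig,
    epochs: EpochSet,
    duration: float = 100.0,
    unit_id: str = "spn0",
    rng: np.random.Generator | None = None,
) -> tuple[SpikeTrain, dict[str, Any]]:
    """Inhomogeneous Poisson SPN spiking with delayed inhibition during light.

    The rate is ``baseline`` everywhere except from ``onset + delay`` to each
    epoch's offset, where it is ``baseline * (1 - depth)``.  A private ``rng``
    may be supplied to draw many cells from one stream."""
    p = cfg.spn
    rng = cfg.rng("spn") if rng is None else rng
    times = _poisson_times(rng, p.baseline_rate, 0.0, duration)
    if len(epochs) and p.depth > 0:
        inhibited = np.zeros(times.size, dtype=bool)
        for onset, offset in epochs:
            inhibited |= (times >= onset + p.onset_delay) & (times < offset)
        keep = ~inhibited | (rng.uniform(size=times.size) < 1.0 - p.depth)
        times = times[keep]
    truth = {
        "baseline_rate": p.baseline_rate,
        "onset_delay": p.onset_delay,
        "depth": p.depth,
        "inhibited_windows": [(a + p.onset_delay, b) for a, b in epochs],
    }
    return _finalize(times, 0.0, duration, unit_id), truth


# --------------------------------------------------------------------------- #
# membrane-potential generators
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class UpDownSim:
    """Output bundle of the two-state membrane simulation."""

    trace: Trace
    states: StateSegmentation
    spikes: SpikeTrain
    truth: dict[str, Any]


def simulate_updown_trace(cfg: SimConfig, epochs: EpochSet) -> UpDownSim:
    p = cfg.updown
    rng = cfg.rng("updown")
    fs, duration = p.fs, p.duration

    # --- semi-Markov state sequence (dwell parameters set at dwell onset) ---
    segs: list[tuple[str, float, float]] = []
    t, state = 0.0, DOWN
    in_pause = epochs.contains
    while t < duration:
        if state == UP:
            mean = p.pause_up_mean if in_pause(np.array([t]))[0] else p.up_mean
        else:
            mean = p.down_mean
        dwell = rng.exponential(mean)
        segs.append((state, t, min(t + dwell, duration)))
        t += dwell
        state = UP if state == DOWN else DOWN
    truth_seg = StateSegmentation(segments=tuple(segs))

    # --- target potential: piecewise levels joined by linear ramps ---
    def level(state: str, when: float) -> float:
        pause = in_pause(np.array([when]))[0]
        if state == UP:
            return p.m_up + (p.pause_up_shift if pause else 0.0)
        return p.m_down + (p.pause_down_shift if pause else 0.0)

    xp = [0.0]
    yp = [level(segs[0][0], 0.0)]
    for (s0, _, e0), (s1, a1, _) in zip(segs, segs[1:]):
        pause = in_pause(np.array([a1]))[0]
        rise = p.pause_rise_10_90 if pause else p.rise_10_90
        ramp = rise / 0.8  # full 0-100% ramp duration for a linear transition
        xp += [a1 - ramp / 2.0, a1 + ramp / 2.0]
        yp += [level(s0, e0 - 1e-9), level(s1, a1)]
    xp.append(duration)
    yp.append(level(segs[-1][0], duration - 1e-9))
    xp = np.maximum.accumulate(np.asarray(xp))
    xp += np.arange(xp.size) * 1e-9  # strictly increasing knots
    tgrid = np.arange(int(round(duration * fs))) / fs
    v = np.interp(tgrid, xp, np.asarray(yp))

    # --- state-dependent noise ---
    sd = np.full(tgrid.size, p.s_down)
    for s, a, b in segs:
        if s == UP:
            i0, i1 = int(a * fs), int(b * fs)
            sd[i0:i1] = p.s_up
    v = v + rng.normal(size=tgrid.size) * sd

    # --- Poisson spikes within UP states, with a brief AP transient ---
    spike_times = []
    half_w = max(int(round(p.ap_width * fs / 2)), 1)
    bump = p.ap_amplitude * (1.0 - np.abs(np.arange(-half_w, half_w + 1)) / (half_w + 1))
    for s, a, b in segs:
        if s != UP:
            continue
        rate = p.ap_rate_up_pause if in_pause(np.array([a]))[0] else p.ap_rate_up
        spike_times.append(_poisson_times(rng, rate, a, b))
    st = np.unique(np.concatenate(spike_times)) if spike_times else np.empty(0)
    for tsp in st:
        i = int(round(tsp * fs))
        lo, hi = max(i - half_w, 0), min(i + half_w + 1, v.size)
        v[lo:hi] += bump[lo - (i - half_w) : hi - (i - half_w)]

    trace = Trace(samples=v, fs=fs, t_start=0.0)
    spikes = _finalize(st, 0.0, trace.duration, "updown0")
    truth = {
        "m_down": p.m_down,
        "m_up": p.m_up,
        "pause_down_shift": p.pause_down_shift,
        "pause_up_shift": p.pause_up_shift,
        "up_mean": p.up_mean,
        "pause_up_mean": p.pause_up_mean,
        "down_mean": p.down_mean,
        "ap_rate_up": p.ap_rate_up,
        "ap_rate_up_pause": p.ap_rate_up_pause,
        "slope": (p.m_up - p.m_down) / (p.rise_10_90 / 0.8),
        "pause_slope": (p.m_up - p.m_down) / (p.pause_rise_10_90 / 0.8),
    }
    return UpDownSim(trace=trace, states=truth_seg, spikes=spikes, truth=truth)


def simulate_juxta_trace(
    cfg: SimConfig, train: SpikeTrain, duration: float | None = None
) -> Trace:
    """White noise plus a stereotyped biphasic waveform at each spike time.

    Waveforms of spikes closer than the template width simply sum."""
    p = cfg.juxta
    rng = cfg.rng("juxta")
    duration = train.t_stop - train.t_start if duration is None else duration
    n = int(round(duration * p.fs))
    v = rng.normal(0.0, p.noise_sd, size=n) if p.noise_sd > 0 else np.zeros(n)
    half = int(round(4 * p.width_sigma * p.fs))
    tt = np.arange(-half, half + 1) / p.fs
    template = p.amplitude * (
        np.exp(-0.5 * (tt / p.width_sigma) ** 2)
        - p.undershoot * np.exp(-0.5 * ((tt - 2 * p.width_sigma) / (2 * p.width_sigma)) ** 2)
    )
    for t in train.times:
        i = int(round((t - train.t_start) * p.fs))
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        v[lo:hi] += template[lo - (i - half) : hi - (i - half)]
    return Trace(samples=v, fs=p.fs, t_start=train.t_start)


# --------------------------------------------------------------------------- #
# EPSP sweeps and current steps
# --------------------------------------------------------------------------- #


def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak alpha function ``(t/tau) * exp(1 - t/tau)`` for t >= 0."""
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
    return out


def simulate_epsp_sweeps(cfg: SimConfig) -> tuple[SweepSet, dict[str, Any]]:
    """Facilitating 10-pulse 25 Hz EPSP trains for the before/pause conditions.

    Returns the sweep set plus the true per-stimulus amplitudes per condition."""
    p = cfg.epsp
    rng = cfg.rng("epsp")
    stim = p.first_stim + np.arange(p.n_stim) / p.stim_rate
    dur = stim[-1] + p.tail
    tgrid = np.arange(int(round(dur * p.fs))) / p.fs
    truth: dict[str, Any] = {"stim_times": stim.tolist()}
    sweeps, labels = [], []
    for condition, a1, ratio in [
        ("before", p.first_before, p.ratio_before),
        ("pause", p.first_pause, p.ratio_pause),
    ]:
        f = ratio ** (1.0 / (p.n_stim - 1))
        amps = a1 * f ** np.arange(p.n_stim)
        template = np.zeros_like(tgrid)
        for t0, a in zip(stim, amps):
            template += a * _alpha(tgrid - t0, p.tau)
        truth[condition] = {"amplitudes": amps.tolist(), "ratio_last_first": float(ratio)}
        for _ in range(p.n_sweeps):
            noise = rng.normal(0.0, p.noise_sd, size=tgrid.size) if p.noise_sd > 0 else 0.0
            sweeps.append(template + noise)
            labels.append(condition)
    return (
        SweepSet(sweeps=np.asarray(sweeps), fs=p.fs, stim_times=stim, conditions=labels),
        truth,
    )


def simulate_step_protocol(cfg: SimConfig) -> tuple[StepProtocol, dict[str, Any]]:
    """Leaky-integrator current-step responses with a threshold current.

    Below ``threshold_current`` the response is a passive charging curve; at
    and above it, ``1 + spikes_per_increment * (I - threshold)/increment``
    spikes are emitted, evenly spaced through the step."""
    p = cfg.steps
    rng = cfg.rng("steps")
    currents = p.start_current + p.increment * np.arange(p.n_steps)
    n_pre = int(round(p.pre * p.fs))
    n_step = int(round(p.step_duration * p.fs))
    n_post = int(round(p.post * p.fs))
    t_step = np.arange(n_step) / p.fs
    responses = []
    counts = []
    for current in currents:
        v = np.full(n_pre + n_step + n_post, p.rest)
        charge = p.input_resistance * current * (1.0 - np.exp(-t_step / p.tau_m))
        v[n_pre : n_pre + n_step] += charge
        v[n_pre + n_step :] = p.rest + charge[-1] * np.exp(
            -np.arange(n_post) / p.fs / p.tau_m
        )
        if current >= p.threshold_current - 1e-9:
            n_sp = 1 + int(round(p.spikes_per_increment * (current - p.threshold_current) / p.increment))
            sp_t = p.pre + (np.arange(n_sp) + 0.5) * p.step_duration / n_sp
            half = max(int(round(0.0005 * p.fs)), 1)
            for t in sp_t:
                i = int(round(t * p.fs))
                lo, hi = max(i - half, 0), min(i + half + 1, v.size)
                shape = 1.0 - np.abs(np.arange(lo - i, hi - i)) / (half + 1)
                v[lo:hi] += np.maximum((p.spike_peak - v[i]) * shape, 0.0)
        else:
            n_sp = 0
        if p.noise_sd > 0:
            v = v + rng.normal(0.0, p.noise_sd, size=v.size)
        responses.append(Trace(samples=v, fs=p.fs, t_start=0.0))
        counts.append(n_sp)
    truth = {
        "threshold_current": p.threshold_current,
        "true_counts": counts,
        "currents": currents.tolist(),
    }
    protocol = StepProtocol(
        currents=currents,
        responses=responses,
        step_duration=p.step_duration,
        step_onset=p.pre,
    )
    return protocol, truth
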