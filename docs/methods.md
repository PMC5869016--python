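# Methods

`pause_ephys` implements the analysis chain used to ask whether a pause in
the tonic firing of striatal cholinergic interneurons (CINs) inhibits spiny
projection neurons (SPNs): event-aligned spike-train statistics with CUSUM
change-point dating, UP/DOWN membrane-state segmentation and statistics,
EPSP-train facilitation metrics, unit classification, and seeded synthetic
generators that stand in for the original recordings (which are not
deposited). This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## PSTH and CUSUM significance

Spikes are binned into peristimulus time histograms (PSTHs) on half-open,
uniform bins aligned to light onset (defaults: 10 ms bins for CIN units,
100 ms for SPN units; both configurable). All statistics operate on the
across-trial (or, for group analyses, across-cell) mean spike count per bin,
`x_i`.

Baseline statistics `mu` and `sigma` are the mean and sample SD (denominator
`n1 - 1`) of `x_i` over a reference window of `n1` whole bins ending at the
alignment event (default 1 s). The cumulative sum of residuals

    S_r = sum_{i=1..r} (x_i - mu),   r = 1, 2, ...

over the analysis bins is compared with the critical boundary
`z * sigma * sqrt(r)`, with `z = 2.33` at alpha = 0.01 (group analyses) and
`z = 1.65` at alpha = 0.05 (single cells); a general mode replaces these
printed constants with the exact upper-tail normal quantile. Decrease and
increase are tested as independent one-sided boundaries, and exact touching
of the boundary counts as a crossing (a deterministic tie-break).

A bin is declared significantly below baseline only when both conditions
hold: its mean count is more than 2 SD below `mu`, and it lies at or after
the first downward boundary crossing. The onset latency is the left edge of
the first such bin. Recovery after light offset re-references the baseline
to the final 0.5 s of the light-on period and applies the same machinery to
the post-offset bins; rebound duration is the first contiguous run of
post-offset bins exceeding the *original* baseline mean by 2 SD.

Calibration: on 1000 simulated unmodulated cells (homogeneous Poisson at
1.5 Hz, 10 trials, 100 ms bins, 1 s baseline and analysis windows,
alpha = 0.05) the full procedure flags a spurious decrease in roughly 3–5%
of cells. With 10 reference bins the SD estimate is noisy; underestimates
shrink the boundary and the 2 SD gate together, which is why the group
onset-latency experiment occasionally (≈4–5% of replicates) dates an onset
before the true 0.4 s delay.

## UP/DOWN state analysis

Whole-cell traces are despiked before any state analysis: samples within
(−1 ms, +4 ms) of each spike are replaced by linear interpolation between
the window edges; overlapping windows merge.

The all-points amplitude distribution is fitted with a two-component
Gaussian mixture by EM (scikit-learn backend). Initialization is
deterministic — component means start at the 25th/75th percentiles, equal
weights, pooled variance — so the fit is a pure function of the data.
Components are ordered `m_down < m_up`; a fit whose mean separation is
smaller than the sum of the component SDs is flagged as effectively
unimodal. On a 50 000-sample mixture at realistic parameters
(−72/−56 mV, SDs 2/3 mV) the means are recovered well within ±0.3 mV.

Segmentation uses a crossover of moving averages: a sample is provisionally
UP when a fast moving average (default 5 ms) exceeds a slow one. The slow
window must span at least a full UP/DOWN cycle so that it settles *between*
the two potential levels and acts as an adaptive threshold; we default to
1.5 s (mean cycle ≈ 0.9 s). A short slow window (e.g. 100 ms) cannot work
here: inside any steady state the two averages coincide up to noise, the
UP/DOWN indicator chatters at the noise timescale, and no excursion survives
the duration filter. UP excursions shorter than 0.2 s are merged into the
flanking DOWN state (the standard filter in the membrane-state literature);
we apply the same 0.2 s filter symmetrically to interior DOWN gaps to
suppress residual chatter. The result alternates and tiles the trace
exactly. On noiseless two-level traces the boundary error is far below the
slow_window/2 bound (sample-accurate on square waves; within half a
transition ramp on ramped transitions).

Condition windows per light epoch follow the 5 s protocol: before =
[onset − 5 s, onset), during = [onset, onset + 5 s), after = [offset + 10 s,
offset + 15 s). The protocol's "10 s after" phrasing is ambiguous (a window
starting at +10 s versus covering 0–10 s); we start the after-window 10 s
after the offset. Segments belong to a window by their onset. Per window we
report: mean UP/DOWN dwell durations, UP frequency (onsets per second),
state potentials and UP amplitude (`m_up − m_down`) from a mixture fit
restricted to the window, the UP-component weight, the firing rate within
UP states (spikes per second of UP time — the per-UP-state figure is a rate,
matching its reported units), and the mean 10–90% rising slope.

UP-state averaging centers each event on its midpoint and offsets it so the
mean of the 50 ms before onset maps to 0 mV, then averages point-wise on a
fixed ±0.5 s grid. The transition slope is the least-squares slope of the
samples between the last 10% point preceding the first 90% point of the
event's peak amplitude (the standard rise-time convention; taking instead
*all* rising-phase samples inside the 10–90% band would sweep in noisy
plateau samples and bias the slope down). The peak potential is the mean of
the central 50% of the event's span. Both are exact on piecewise-linear
constructions.

## EPSP trains

Sweeps are averaged per condition; the amplitude of the k-th EPSP is the
maximum of the averaged trace in (stim_k + 1 ms, stim_k + 35 ms] minus the
mean over the 4 ms preceding the stimulus. The 1 ms blank skips the
stimulation artifact; the per-stimulus local baseline makes each amplitude
the increment above the summated envelope, which is the convention that
keeps the measurement exact (≤0.5% error) on noiseless alpha-function trains
at 25 Hz with a 4 ms kinetic time constant. Amplitudes are normalized to the
first EPSP; facilitation is summarized by the last/first ratio. Paired
per-cell contrasts (pause − before) are emitted as tidy tables; group
inference beyond mean ± SEM is left to standard statistical software.

## Unit classification

Features per unit: firing rate, ISI coefficient of variation (absent with
fewer than two intervals), and the half-width of the mean spike waveform —
full width at half the baseline-to-peak amplitude, with the baseline taken
as the mean of the 1 ms window at the snippet start (the half-amplitude
reference is configurable; baseline-to-peak is the default). Spike times are
assigned to the waveform extremum within one refractory period of the
threshold crossing, which makes them stable under the threshold choice.

The default rule labels a unit CIN when half-width ≥ 0.6 ms, rate ≥ 1 Hz and
CV ≤ 1, and SPN when half-width < 0.6 ms or (rate < 1 Hz and CV > 1); the
two rules are mutually exclusive, and units matching neither (e.g. broad,
tonic but irregular) stay unclassified. All thresholds are configurable, and
an exploratory fixed-seed 2-cluster k-means on standardized features is
provided. On synthetic populations drawn from the two well-separated feature
clusters the default rule recovers 100% of generating labels.

## Synthetic generators

Every generator is a pure function of (config, epochs) — a fixed seed gives
byte-identical output — and returns ground truth sufficient to score the
downstream estimators. Defaults encode the study conditions:

* **CIN trains**: gamma renewal (shape 4, rate 4 Hz), giving the low-CV
  tonic firing the classifier expects (a Poisson model at CV = 1 would blur
  the clusters) with ISIs concentrated in ≈0.14–0.9 s. Complete silencing
  inside light epochs; rebound burst at 5× the baseline rate starting
  ≈70 ms (±10 ms jitter) after offset and lasting 140 ms.
* **SPN trains**: inhomogeneous Poisson, baseline 1.5 Hz, rate stepped down
  by depth 0.437 from 0.4 s after light onset to light offset. The step
  (rather than a ramp) makes onset-latency recovery a sharp target.
* **Two-state membrane traces**: semi-Markov alternation with exponential
  dwells (UP 0.42 s, DOWN 0.51 s; UP mean 0.39 s during light), state
  potentials −71.6/−56.4 mV with pause shifts of −1.2/−1.4 mV,
  state-dependent white noise (SD 2/3 mV), linear transition ramps with
  10–90% rise times of 104 ms (129 ms during light) so the rising slope is
  ≈146 (≈128) mV/s, and Poisson spikes within UP states at 1.94 Hz
  (0.86 Hz during light) rendered as brief triangular transients.
* **Juxtacellular traces**: white noise plus a stereotyped biphasic
  waveform per spike; overlapping waveforms sum.
* **EPSP sweeps**: sums of alpha functions at 10 stimuli, 25 Hz; the k-th
  amplitude is `a1 * f^(k-1)` with `f` tuned so the last/first ratio equals
  the condition target (before: 4.3 mV, ratio 1.59; pause: 5.16 mV, ratio
  1.29), plus Gaussian sweep noise.
* **Current steps**: leaky-integrator charging curves for 500 ms steps at
  20 pA increments from 260 pA; at and above a 320 pA threshold current the
  spike count rises by one per increment.

What the generators do **not** emulate: correlated (synaptically filtered)
membrane noise, non-exponential dwell distributions, electrode artifacts,
drift and non-stationarity, bursty or history-dependent SPN firing, and the
awake (non-bimodal) membrane regime. Passing benchmarks therefore show the
estimators are correct and calibrated under the stated stochastic models,
not that they are robust to every pathology of real recordings.

## Benchmark experiment sizes

The pause-effect recovery experiment simulates, per seed, one long
whole-cell recording with 5 s light epochs at the standard 30 s cadence and
pools the before/during condition windows. The number of epochs (500) was
set by a power analysis of the UP-duration effect: a −0.03 s shift of an
exponential dwell with mean (and SD) 0.42 s, further attenuated by the
detector (the slower pause transitions lengthen crossover-detected UP states
by a few tens of milliseconds, opposing the dwell shortening), needs on the
order of 2500 measured UP states per condition before its sign is recovered
reliably within a single seed. The potential and firing-rate effects are
recovered with large margins at a small fraction of that length. Simulation
uses a 500 Hz sampling rate, ample for states and dwell statistics (the
mixture fits thin to ≤60 000 samples deterministically).

The false-positive benchmark uses 1000 cells; group onset recovery uses
20 replicates of 200 cells × 10 trials; all spike-train experiments run in
seconds.

## Known limitations

* The CUSUM boundary uses the printed normal-approximation constants; no
  exact Poisson tail is recomputed in paper-exact mode.
* Group PSTHs average across-cell mean rates (pooled spike counts are not
  implemented); per-bin trial counts are unavailable for group objects.
* Measured dwell durations are conditioned on the 0.2 s filters and on
  chain-merging of short gaps, so they over-estimate raw dwell means for
  strongly skewed dwell distributions; condition *contrasts* are the robust
  readout.
* `condition_windows` assumes the during-window width fits inside each
  epoch and skips (with a warning) epochs whose windows leave the recording.
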