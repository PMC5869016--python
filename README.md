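# pause-ephys

Analysis tools for a classic question in striatal physiology: what does a
**pause** in the tonic firing of cholinergic interneurons (CINs) do to the
spiny projection neurons (SPNs) that carry the striatum's output? The
package implements, as a tested and reusable pipeline, the analyses used to
show that optogenetically induced pauses *inhibit* SPNs in vivo:

* **PSTH + CUSUM change-point statistics** for spike trains. With baseline
  mean `µ` and SD `σ` over `n1` reference bins before light onset, the
  cumulative sum of residuals `S_r = Σ_{i=1..r}(x_i − µ)` is compared with
  the Poisson-derived boundary `z·σ·√r` (`z = 2.33` at α = 0.01, `1.65` at
  α = 0.05). Bins more than 2 SD below `µ` at/after the first crossing are
  significant; the onset latency is the first such bin's left edge. Includes
  rebound/recovery analysis against a re-referenced baseline.
* **UP/DOWN membrane-state analysis**: despiking, two-Gaussian fits of the
  all-points histogram, fast/slow moving-average crossover segmentation with
  a 0.2 s duration filter, and before/during/after condition statistics
  (state potentials, dwell durations, UP frequency and amplitude, firing
  within UP states, 10–90% transition slopes, center-aligned UP averages).
* **EPSP-train facilitation**: sweep averaging, per-stimulus amplitudes
  above a local baseline, normalization to the first EPSP, and the
  last/first facilitation ratio with paired condition contrasts.
* **Unit analysis**: spike detection on filtered juxtacellular traces,
  waveform half-width / rate / ISI-CV features, CIN-vs-SPN classification,
  and rheobase / F–I extraction from current-step protocols.
* **Synthetic generators with ground truth** for every input above (the
  original recordings are not deposited), plus a config-driven pipeline and
  CLI. The immunostaining worked example (903 counted neurons) is included
  as count arithmetic.

Who it is for: electrophysiologists analysing event-aligned silencing
experiments, and anyone needing a calibrated, seedable CUSUM/PSTH or
UP/DOWN-state toolchain with known-truth benchmarks.

## Worked example

Simulate the juxtacellular SPN experiment (22 cells, ten 1 s light pulses,
44% inhibition starting 0.4 s after light onset) and date the group-level
onset of inhibition:

```python
import numpy as np
from pause_ephys import synth, psth

cfg = synth.SimConfig(seed=7)
light = synth.default_light_epochs(n=10, duration=1.0, interval=50.0)

rng = cfg.rng("spn")
cells = []
for _ in range(22):
    train, _ = synth.simulate_spn_train(cfg, light, duration=520.0, rng=rng)
    cells.append(psth.build_psth(train, light, window=(-1.0, 2.0), bin_width=0.1))

group = psth.group_psth(cells)
base = psth.baseline_stats(group, reference=(-1.0, 0.0))
cus = psth.cusum(group, base, alpha=0.01)
flags, onset = psth.significant_bins(group, base, cus, "decrease")

print(f"baseline: mu = {base.mu:.3f} spikes/bin, sigma = {base.sigma:.3f} (n1 = {base.n1})")
print(f"boundary coefficient z = {cus.z} (alpha = {cus.alpha})")
print(f"first downward crossing at analysis bin {cus.first_crossing_decrease}")
print(f"significant inhibition onset: {onset:.1f} s after light onset")
inhib = 100 * (1 - group.mean_counts[group.bins_in(0.4, 1.0)].mean() / base.mu)
print(f"firing inhibition during the pause: {inhib:.1f} %")
```

Output:

```
baseline: mu = 0.163 spikes/bin, sigma = 0.025 (n1 = 10)
boundary coefficient z = 2.33 (alpha = 0.01)
first downward crossing at analysis bin 5
significant inhibition onset: 0.5 s after light onset
firing inhibition during the pause: 41.3 %
```

The group PSTH runs at ~0.163 spikes per 100 ms bin (≈1.6 Hz) before the
light; the CUSUM crosses its downward boundary in the sixth analysis bin, so
with the 2 SD bin criterion the inhibition is dated 0.5 s after light onset
(one bin after the true 0.4 s delay of this simulation — see
`docs/methods.md` for the calibration of this estimator), and firing during
the inhibited part of the pause drops by ~41%, close to the generating 43.7%
depth.

The same stages are available from the shell:

```bash
pause-ephys simulate spn --seed 7 --out spn --duration 520
pause-ephys psth --spikes spn/spikes.csv --epochs spn/epochs.csv \
    --bin 0.1 --window -1 2 --out psth.csv
pause-ephys counts --chat-only 387 --eyfp-only 5 --double-positive 511
pause-ephys run --config config.yaml     # full simulate-and-analyze pipeline
```

## Layout

```
src/pause_ephys/
  core.py         domain types (SpikeTrain, Trace, EpochSet, SweepSet) + I/O
  psth.py         PSTH, baseline stats, CUSUM, significance, rebound, groups
  updown.py       despiking, Gaussian fits, state segmentation, statistics
  epsp.py         sweep averaging, amplitudes, facilitation, contrasts
  spikes.py       detection, waveform features, classification, rheobase/F-I
  synth.py        seeded generators with ground truth
  experiments.py  end-to-end benchmark experiments
  pipeline.py     config-driven orchestration, summaries, count arithmetic
  cli.py          `pause-ephys` command-line interface
docs/methods.md   models, parameters, numerical choices, limitations
```
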