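# Full-pipeline configuration for `pause-ephys run --config examples/config.yaml`.
# Any omitted key keeps its default.
seed: 7
outdir: results/run7
n_spn_cells: 22          # juxtacellular SPN units in the group analysis
n_trials: 10             # light pulses per unit
light_duration: 1.0      # s
light_interval: 50.0     # s
bin_width: 0.1           # s, SPN PSTH bins
psth_window: [-1.0, 2.0] # s relative to light onset
alpha_group: 0.01
alpha_single: 0.05
updown_epochs: 5         # 5 s whole-cell light epochs at 30 s cadence
counts: [387, 5, 511]    # ChAT+/eYFP-, ChAT-/eYFP+, double-positive
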