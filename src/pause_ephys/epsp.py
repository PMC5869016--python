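"""EPSP-train quantification for repetitive corticostriatal stimulation.

A train of 10 electrical stimuli at 25 Hz evokes facilitating, summating
EPSPs.  Sweeps are averaged per condition, per-stimulus amplitudes are
measured as the peak of the response above a local pre-stimulus baseline
(so that each amplitude is the increment above the summated envelope), the
sequence is normalized to the first EPSP, and short-term facilitation is
summarized by the last/first amplitude ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SweepSet, Trace, ValidationError

__all__ = [
    "EpspTrainResult",
    "average_sweeps",
    "epsp_amplitudes",
    "facilitation_metrics",
    "condition_contrast",
]


@dataclass(frozen=True)
class EpspTrainResult:
    """Per-stimulus amplitudes with first-EPSP normalization."""

    amplitudes: np.ndarray  # mV
    condition: str = ""

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        if amps.size < 2:
            raise ValidationError("at least two amplitudes required")
        if amps[0] <= 0:
            raise ValidationError("first amplitude must be positive")

    @property
    def normalized(self) -> np.ndarray:
        return self.amplitudes / self.amplitudes[0]

    @property
    def ratio_last_first(self) -> float:
        return float(self.amplitudes[-1] / self.amplitudes[0])


def average_sweeps(sweeps: SweepSet, condition: str | None = None) -> Trace:
    """Point-wise mean of the sweeps carrying ``condition`` (all sweeps if None)."""
    if condition is None:
        sel = np.ones(sweeps.n_sweeps, dtype=bool)
    else:
        sel = np.asarray([c == condition for c in sweeps.conditions])
    if not np.any(sel):
        raise ValidationError(f"no sweeps with condition {condition!r}")
    return Trace(samples=sweeps.sweeps[sel].mean(axis=0), fs=sweeps.fs)


def epsp_amplitudes(
    mean_trace: Trace,
    stim_times: Sequence[float],
    search: float = 0.035,
    local_baseline: float = 0.004,
    artifact_blank: float = 0.001,
) -> np.ndarray:
    """Per-stimulus EPSP amplitudes from an averaged trace.

    ``amplitude[k]`` = max of the trace in ``(stim_k + artifact_blank,
    stim_k + search]`` minus the mean over ``[stim_k - local_baseline,
    stim_k)``.  The first ``artifact_blank`` seconds after each stimulus are
    excluded to skip the electrical stimulation artifact.
    """
    stim = np.asarray(stim_times, dtype=float)
    if stim.size == 0:
        raise ValidationError("at least one stimulus time required")
    isi = np.diff(stim)
    if isi.size and search > np.min(isi) + 1e-12:
        raise ValidationError("search window overlaps the next stimulus")
    t_rel = stim - mean_trace.t_start
    if np.any(t_rel < 0) or np.any(t_rel >= mean_trace.duration):
        raise ValidationError("stimulus times must fall within the trace")
    amps = np.empty(stim.size)
    for k, t in enumerate(stim):
        seg = mean_trace.slice(t + artifact_blank, t + search)
        base_seg = mean_trace.slice(max(t - local_baseline, mean_trace.t_start), t)
        if seg.size == 0 or base_seg.size == 0:
            raise ValidationError("search or baseline window contains no samples")
        amps[k] = float(np.max(seg)) - float(np.mean(base_seg))
    return amps


def facilitation_metrics(
    amplitudes: Sequence[float], condition: str = ""
) -> EpspTrainResult:
    """Normalize a train of amplitudes to the first EPSP and form the last/first ratio."""
    return EpspTrainResult(amplitudes=np.asarray(amplitudes, dtype=float), condition=condition)


def condition_contrast(
    before: Mapping[str, EpspTrainResult],
    pause: Mapping[str, EpspTrainResult],
) -> pd.DataFrame:
    """Per-cell paired contrast between the before and pause conditions.

    Inputs map cell identifiers to train results; the cell sets must match.
    Returns one row per cell with the first-EPSP amplitudes, facilitation
    ratios and their paired differences (pause - before).
    """
    if set(before) != set(pause):
        raise ValidationError("unmatched cells between conditions")
    if not before:
        raise ValidationError("at least one cell required")
    rows = []
    for cell in sorted(before):
        b, p = before[cell], pause[cell]
        rows.append(
            {
                "cell_id": cell,
                "first_before_mV": float(b.amplitudes[0]),
                "first_pause_mV": float(p.amplitudes[0]),
                "d_first_mV": float(p.amplitudes[0] - b.amplitudes[0]),
                "ratio_before": b.ratio_last_first,
                "ratio_pause": p.ratio_last_first,
                "d_ratio": p.ratio_last_first - b.ratio_last_first,
            }
        )
    return pd.DataFrame(rows)
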