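"""End-to-end orchestration, descriptive summaries, and the
immunohistochemistry co-expression arithmetic.

Inferential group statistics (ANOVA families, paired t-tests, post-hoc
corrections) are deliberately not re-implemented here: the pipeline emits
tidy per-cell tables for direct consumption by standard statistical software
and reports descriptive mean +- SEM only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import epsp as epsp_mod
from . import psth as psth_mod
from . import synth, updown
from .core import ValidationError, write_table

__all__ = [
    "CountTable",
    "PipelineConfig",
    "summarize",
    "coexpression_summary",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("pause_ephys")


def summarize(values: Sequence[float]) -> tuple[float, float | None, int]:
    """Descriptive mean, SEM (sample SD / sqrt(n); ``None`` for n = 1) and n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty sequence")
    mean = float(np.mean(arr))
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    return mean, sem, int(arr.size)


@dataclass(frozen=True)
class CountTable:
    """Immunostaining counts: ChAT+/eYFP-, ChAT-/eYFP+, and double-positive.

    Scalars give pooled counts; equal-length sequences give per-animal rows.
    """

    chat_only: Any
    eyfp_only: Any
    double_positive: Any

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chat_only": np.atleast_1d(self.chat_only),
                "eyfp_only": np.atleast_1d(self.eyfp_only),
                "double_positive": np.atleast_1d(self.double_positive),
            }
        )
        if (df < 0).any().any() or not all(
            np.issubdtype(t, np.integer) for t in df.dtypes
        ):
            raise ValidationError("counts must be non-negative integers")
        return df


def coexpression_summary(counts: CountTable) -> pd.DataFrame:
    """Specificity and transduction percentages from cell counts.

    Pooled specificity = 100 * double / (double + eyfp_only): the share of
    silencer-expressing cells that are cholinergic.  Pooled transduction =
    100 * double / (double + chat_only): the share of cholinergic cells that
    express the silencer.  With per-animal rows, per-animal mean +- SEM of
    both percentages is appended.
    """
    df = counts.as_frame()
    if int(df.values.sum()) == 0:
        raise ValidationError("all-zero count table")
    double = int(df["double_positive"].sum())
    eyfp = int(df["eyfp_only"].sum())
    chat = int(df["chat_only"].sum())
    if double + eyfp == 0 or double + chat == 0:
        raise ValidationError("insufficient counts for the percentages")
    out = {
        "specificity_pct": 100.0 * double / (double + eyfp),
        "transduction_pct": 100.0 * double / (double + chat),
        "total": int(df.values.sum()),
    }
    rows = [dict(out, level="pooled")]
    if len(df) > 1:
        spec = 100.0 * df["double_positive"] / (df["double_positive"] + df["eyfp_only"])
        trans = 100.0 * df["double_positive"] / (df["double_positive"] + df["chat_only"])
        s_mean, s_sem, n = summarize(spec)
        t_mean, t_sem, _ = summarize(trans)
        rows.append(
            {
                "level": "per_animal_mean",
                "specificity_pct": s_mean,
                "transduction_pct": t_mean,
                "total": n,
            }
        )
        rows.append(
            {
                "level": "per_animal_sem",
                "specificity_pct": s_sem,
                "transduction_pct": t_sem,
                "total": n,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# config-driven pipeline
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a simulate-and-analyze run."""

    seed: int = 0
    outdir: str = "results"
    n_spn_cells: int = 22
    n_trials: int = 10
    light_duration: float = 1.0
    light_interval: float = 50.0
    bin_width: float = 0.1
    psth_window: tuple[float, float] = (-1.0, 2.0)
    alpha_group: float = 0.01
    alpha_single: float = 0.05
    updown_epochs: int = 5
    counts: tuple[int, int, int] = (387, 5, 511)
    log_level: str = "INFO"

    def canonical(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "psth_window" in data:
        data["psth_window"] = tuple(data["psth_window"])
    if "counts" in data:
        data["counts"] = tuple(data["counts"])
    return PipelineConfig(**data)


def _spn_stage(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    epochs = synth.default_light_epochs(
        n=cfg.n_trials, duration=cfg.light_duration, interval=cfg.light_interval
    )
    duration = float(epochs.offsets[-1] + 10.0)
    sim = synth.SimConfig(seed=cfg.seed)
    rng = sim.rng("spn")
    rows = []
    psths = []
    for c in range(cfg.n_spn_cells):
        train, _ = synth.simulate_spn_train(
            sim, epochs, duration=duration, unit_id=f"spn{c}", rng=rng
        )
        p = psth_mod.build_psth(train, epochs, window=cfg.psth_window, bin_width=cfg.bin_width)
        psths.append(p)
        base = psth_mod.baseline_stats(p, (-1.0, 0.0))
        flagged = False
        latency = None
        if base.sigma > 0:
            cus = psth_mod.cusum(p, base, alpha=cfg.alpha_single)
            _, latency = psth_mod.significant_bins(p, base, cus, "decrease")
            flagged = latency is not None
        rows.append(
            {
                "unit_id": train.unit_id,
                "firing_rate_hz": train.firing_rate,
                "baseline_mu": base.mu,
                "baseline_sigma": base.sigma,
                "decrease_flagged": flagged,
                "onset_latency_s": latency,
            }
        )
    per_cell = pd.DataFrame(rows)
    write_table(per_cell, outdir / "spn_cells.csv")
    group = psth_mod.group_psth(psths)
    gbase = psth_mod.baseline_stats(group, (-1.0, 0.0))
    gcus = psth_mod.cusum(group, gbase, alpha=cfg.alpha_group)
    _, g_latency = psth_mod.significant_bins(group, gbase, gcus, "decrease")
    write_table(
        pd.DataFrame(
            {
                "bin_left_s": group.bin_edges[:-1],
                "mean_counts": group.mean_counts,
                "rate_hz": group.rate,
            }
        ),
        outdir / "group_psth.csv",
    )
    return {
        "n_cells": cfg.n_spn_cells,
        "group_onset_latency_s": g_latency,
        "single_cell_flag_fraction": float(per_cell["decrease_flagged"].mean()),
    }


def _updown_stage(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    epochs = synth.default_light_epochs(
        n=cfg.updown_epochs, duration=5.0, interval=30.0, first_onset=10.0
    )
    params = replace(
        synth.SimConfig(seed=cfg.seed).updown,
        duration=float(epochs.offsets[-1] + 20.0),
    )
    sim = replace(synth.SimConfig(seed=cfg.seed), updown=params)
    bundle = synth.simulate_updown_trace(sim, epochs)
    clean = updown.remove_spikes(bundle.trace, bundle.spikes)
    seg = updown.segment_states(clean)
    windows = updown.condition_windows(
        epochs, width=5.0, post_gap=10.0, t_start=clean.t_start, t_stop=clean.t_stop
    )
    rows = []
    for i, w in enumerate(windows):
        for cond, win in [("before", w.before), ("during", w.during), ("after", w.after)]:
            st = updown.state_statistics(seg, clean, bundle.spikes, win)
            rows.append({"epoch": i, "condition": cond, **asdict(st)})
    table = pd.DataFrame(rows)
    write_table(table, outdir / "updown_states.csv")
    deltas = {}
    for col in ("down_potential", "up_potential", "up_duration", "ap_rate_in_up"):
        b = table.loc[table.condition == "before", col].dropna()
        d = table.loc[table.condition == "during", col].dropna()
        if len(b) and len(d):
            deltas[f"d_{col}"] = float(d.mean() - b.mean())
    return {"n_epochs": len(windows), **deltas}


def _epsp_stage(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    sim = synth.SimConfig(seed=cfg.seed)
    sweeps, _ = synth.simulate_epsp_sweeps(sim)
    results = {}
    for condition in ("before", "pause"):
        mean_trace = epsp_mod.average_sweeps(sweeps, condition)
        amps = epsp_mod.epsp_amplitudes(mean_trace, sweeps.stim_times)
        results[condition] = epsp_mod.facilitation_metrics(amps, condition)
    table = pd.DataFrame(
        {
            "stimulus": np.arange(1, results["before"].amplitudes.size + 1),
            "before_mV": results["before"].amplitudes,
            "pause_mV": results["pause"].amplitudes,
            "before_norm": results["before"].normalized,
            "pause_norm": results["pause"].normalized,
        }
    )
    write_table(table, outdir / "epsp_trains.csv")
    return {
        "ratio_before": results["before"].ratio_last_first,
        "ratio_pause": results["pause"].ratio_last_first,
        "first_before_mV": float(results["before"].amplitudes[0]),
        "first_pause_mV": float(results["pause"].amplitudes[0]),
    }


def _counts_stage(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    chat, eyfp, double = cfg.counts
    table = coexpression_summary(CountTable(chat, eyfp, double))
    write_table(table, outdir / "coexpression.csv")
    pooled = table[table.level == "pooled"].iloc[0]
    return {
        "specificity_pct": float(pooled.specificity_pct),
        "transduction_pct": float(pooled.transduction_pct),
        "total": int(pooled.total),
    }


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run simulate-and-analyze stages and write tables, a JSON summary and a log.

    Deterministic: re-running with the same config (including seed) reproduces
    identical tables; every output carries the config hash.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    digest = cfg.digest()
    summary: dict[str, Any] = {"config_hash": digest, "seed": cfg.seed}
    try:
        for name, stage in [
            ("spn_firing", _spn_stage),
            ("updown_states", _updown_stage),
            ("epsp_trains", _epsp_stage),
            ("coexpression", _counts_stage),
        ]:
            log.info("stage %s starting", name)
            try:
                summary[name] = stage(cfg, outdir)
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                summary["failed_stage"] = name
                (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done", name)
        (outdir / "config.yaml").write_text(f"# hash={digest}\n" + cfg.canonical())
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
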