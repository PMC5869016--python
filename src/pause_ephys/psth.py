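"""Event-aligned PSTHs and CUSUM change-point significance testing.

The procedure dates the onset of a firing-rate change in a peristimulus time
histogram (PSTH).  Let ``x_i`` be the across-trial mean spike count in the
``i``-th analysis bin (bins start at the alignment event), and let ``mu`` and
``sigma`` be the mean and sample SD of the same quantity over ``n1`` reference
bins immediately before the event.  The cumulative sum of residuals

    S_r = sum_{i=1..r} (x_i - mu)

is compared with a critical boundary ``z * sigma * sqrt(r)`` derived from a
Poisson/normal approximation, with ``z = 2.33`` at alpha = 0.01 and
``z = 1.65`` at alpha = 0.05.  A bin is declared significantly below baseline
only if its mean count falls more than 2 SD under ``mu`` *and* it occurs at or
after the first boundary crossing in that direction; the onset latency is the
left edge of the first such bin.  Decreases and increases are evaluated as
independent one-sided tests, and touching the boundary counts as a crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import EpochSet, SpikeTrain, ValidationError

__all__ = [
    "Psth",
    "BaselineStats",
    "CusumResult",
    "ReboundResult",
    "build_psth",
    "baseline_stats",
    "critical_coefficient",
    "cusum",
    "significant_bins",
    "rebound_analysis",
    "group_psth",
]

_TOL = 1e-9

#: the critical coefficients as printed for the Poisson-derived boundary
PAPER_Z = {0.01: 2.33, 0.05: 1.65}


@dataclass(frozen=True)
class Psth:
    """Peristimulus time histogram on a uniform half-open bin grid.

    ``bin_edges`` are relative to the alignment event; ``counts`` is the
    per-trial count matrix (absent for group averages); ``mean_counts`` is the
    across-trial (or across-cell) mean count per bin.
    """

    bin_edges: np.ndarray
    mean_counts: np.ndarray
    n_trials: int
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        mc = np.asarray(self.mean_counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "mean_counts", mc)
        widths = np.diff(edges)
        if np.any(widths <= 0) or np.max(np.abs(widths - widths[0])) > _TOL:
            raise ValidationError("bin edges must be strictly increasing and uniform")
        if mc.size != edges.size - 1:
            raise ValidationError("one mean count per bin required")
        if self.counts is not None:
            counts = np.asarray(self.counts)
            object.__setattr__(self, "counts", counts)
            if counts.shape != (self.n_trials, mc.size):
                raise ValidationError("counts must be (n_trials, n_bins)")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_bins(self) -> int:
        return int(self.mean_counts.size)

    @property
    def rate(self) -> np.ndarray:
        """Mean firing rate per bin in spikes/s."""
        return self.mean_counts / self.bin_width

    def bins_in(self, t0: float, t1: float) -> np.ndarray:
        """Indices of bins wholly contained in ``[t0, t1]``."""
        left, right = self.bin_edges[:-1], self.bin_edges[1:]
        return np.nonzero((left >= t0 - _TOL) & (right <= t1 + _TOL))[0]


@dataclass(frozen=True)
class BaselineStats:
    """Reference-window firing statistics in spikes/bin."""

    mu: float
    sigma: float
    n1: int
    window: tuple[float, float]


@dataclass(frozen=True)
class CusumResult:
    """Cumulative sums, boundary and crossings over the analysis bins.

    ``first_crossing_decrease``/``_increase`` are 0-based indices into the
    analysis bins (``None`` when the boundary is never reached).
    """

    s: np.ndarray
    boundary: np.ndarray
    z: float
    alpha: float
    mu: float
    sigma: float
    analysis_edges: np.ndarray
    first_crossing_decrease: int | None
    first_crossing_increase: int | None


def build_psth(
    train: SpikeTrain,
    events: EpochSet,
    window: tuple[float, float] = (-1.0, 2.0),
    bin_width: float = 0.1,
) -> Psth:
    """Bin spikes around each event onset into half-open bins.

    ``window`` is relative to the onset and must span a whole number of bins.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    span = window[1] - window[0]
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-6 or round(n_bins) < 1:
        raise ValidationError("window must span a whole, positive number of bins")
    n_bins = int(round(n_bins))
    if len(events) == 0:
        raise ValidationError("at least one alignment event required")
    edges = window[0] + np.arange(n_bins + 1) * bin_width
    counts = np.empty((len(events), n_bins), dtype=int)
    for t_idx, onset in enumerate(events.onsets):
        # searchsorted keeps every bin half-open [e_i, e_{i+1})
        pos = np.searchsorted(train.times, onset + edges, side="left")
        counts[t_idx] = np.diff(pos)
    return Psth(
        bin_edges=edges,
        mean_counts=counts.mean(axis=0),
        n_trials=len(events),
        counts=counts,
    )


def baseline_stats(psth: Psth, reference: tuple[float, float] = (-1.0, 0.0)) -> BaselineStats:
    """Mean and sample SD (denominator ``n1 - 1``) of the PSTH over reference bins.

    The reference window must consist of whole bins ending at or before the
    alignment event.
    """
    if reference[1] > _TOL:
        raise ValidationError("reference window must end at or before the event")
    idx = psth.bins_in(reference[0], reference[1])
    if idx.size < 2:
        raise ValidationError("reference window must cover at least 2 whole bins")
    x = psth.mean_counts[idx]
    return BaselineStats(
        mu=float(np.mean(x)),
        sigma=float(np.std(x, ddof=1)),
        n1=int(idx.size),
        window=(float(psth.bin_edges[idx[0]]), float(psth.bin_edges[idx[-1] + 1])),
    )


def critical_coefficient(alpha: float, paper_exact: bool = True) -> float:
    """Critical coefficient ``z`` for the CUSUM boundary.

    In paper-exact mode the printed constants are returned (2.33 at 0.01,
    1.65 at 0.05); in general mode the upper-tail standard-normal quantile.
    """
    if not 0.0 < alpha < 0.5:
        raise ValidationError("alpha must lie in (0, 0.5)")
    if paper_exact:
        if alpha not in PAPER_Z:
            raise ValidationError("paper-exact mode supports alpha in {0.01, 0.05}")
        return PAPER_Z[alpha]
    return float(stats.norm.isf(alpha))


def cusum(
    psth: Psth,
    baseline: BaselineStats,
    alpha: float = 0.05,
    paper_exact: bool = True,
    analysis_start: float = 0.0,
) -> CusumResult:
    """CUSUM of residuals over the analysis bins (those at/after the event).

    ``s[r-1] = sum_{i=1..r}(x_i - mu)``; the boundary for the ``r``-th bin is
    ``z * sigma * sqrt(r)``.  Touching the boundary counts as a crossing.
    """
    if baseline.sigma <= 0:
        raise ValidationError("degenerate baseline: sigma must be positive")
    idx = np.nonzero(psth.bin_edges[:-1] >= analysis_start - _TOL)[0]
    if idx.size == 0:
        raise ValidationError("no analysis bins at or after the alignment event")
    x = psth.mean_counts[idx]
    s = np.cumsum(x - baseline.mu)
    r = np.arange(1, s.size + 1)
    z = critical_coefficient(alpha, paper_exact=paper_exact)
    boundary = z * baseline.sigma * np.sqrt(r)
    dec = np.nonzero(s <= -boundary)[0]
    inc = np.nonzero(s >= boundary)[0]
    return CusumResult(
        s=s,
        boundary=boundary,
        z=z,
        alpha=alpha,
        mu=baseline.mu,
        sigma=baseline.sigma,
        analysis_edges=psth.bin_edges[idx[0] : idx[-1] + 2],
        first_crossing_decrease=int(dec[0]) if dec.size else None,
        first_crossing_increase=int(inc[0]) if inc.size else None,
    )


def significant_bins(
    psth: Psth,
    baseline: BaselineStats,
    cus: CusumResult,
    direction: str = "decrease",
) -> tuple[np.ndarray, float | None]:
    """Per-analysis-bin significance flags plus onset latency.

    A bin is flagged iff its mean count deviates from ``mu`` by more than
    2 SD in ``direction`` *and* it lies at/after the first CUSUM crossing in
    that direction.  The latency is the left edge of the first flagged bin
    (``None`` when nothing is flagged).
    """
    if direction not in {"decrease", "increase"}:
        raise ValidationError("direction must be 'decrease' or 'increase'")
    left = cus.analysis_edges[:-1]
    i0 = int(np.searchsorted(psth.bin_edges[:-1], left[0] - _TOL))
    x = psth.mean_counts[i0 : i0 + left.size]
    if direction == "decrease":
        exceed = x < baseline.mu - 2.0 * baseline.sigma
        crossing = cus.first_crossing_decrease
    else:
        exceed = x > baseline.mu + 2.0 * baseline.sigma
        crossing = cus.first_crossing_increase
    flags = np.zeros(x.size, dtype=bool)
    if crossing is not None:
        flags[crossing:] = exceed[crossing:]
    hit = np.nonzero(flags)[0]
    latency = float(left[hit[0]]) if hit.size else None
    return flags, latency


@dataclass(frozen=True)
class ReboundResult:
    """Post-offset recovery statistics relative to a re-referenced baseline."""

    recovery_latency: float | None  # s after light offset
    rebound_duration: float  # s above mu_orig + 2*sigma_orig
    new_baseline: BaselineStats
    cusum: CusumResult


def rebound_analysis(
    psth: Psth,
    light_offset: float,
    new_reference: tuple[float, float],
    original: BaselineStats,
    alpha: float = 0.01,
    paper_exact: bool = True,
) -> ReboundResult:
    """Analyse the recovery after the light is turned off.

    The baseline is re-referenced to ``new_reference`` (bins inside the light-on
    period ending at ``light_offset``); recovery latency is the onset of the
    first significant increase after the offset relative to that baseline.
    Rebound duration is the first contiguous run of post-offset bins whose mean
    count exceeds the *original* baseline mean by more than 2 SD.
    """
    if new_reference[1] > light_offset + _TOL:
        raise ValidationError("new reference window must end at the light offset")
    ref_idx = psth.bins_in(new_reference[0], new_reference[1])
    if ref_idx.size < 2:
        raise ValidationError("new reference window must cover at least 2 bins")
    x_ref = psth.mean_counts[ref_idx]
    new_base = BaselineStats(
        mu=float(np.mean(x_ref)),
        sigma=float(np.std(x_ref, ddof=1)),
        n1=int(ref_idx.size),
        window=(float(psth.bin_edges[ref_idx[0]]), float(psth.bin_edges[ref_idx[-1] + 1])),
    )
    cus = cusum(psth, new_base, alpha=alpha, paper_exact=paper_exact, analysis_start=light_offset)
    flags, latency = significant_bins(psth, new_base, cus, direction="increase")
    recovery = None if latency is None else latency - light_offset
    # rebound duration against the original pre-light baseline
    post = np.nonzero(psth.bin_edges[:-1] >= light_offset - _TOL)[0]
    above = psth.mean_counts[post] > original.mu + 2.0 * original.sigma
    hit = np.nonzero(above)[0]
    duration = 0.0
    if hit.size:
        run_end = hit[0]
        while run_end < above.size and above[run_end]:
            run_end += 1
        duration = (run_end - hit[0]) * psth.bin_width
    return ReboundResult(
        recovery_latency=recovery,
        rebound_duration=float(duration),
        new_baseline=new_base,
        cusum=cus,
    )


def group_psth(psths: Sequence[Psth] | Iterable[Psth]) -> Psth:
    """Across-cell mean PSTH; inputs must share an identical bin grid."""
    psths = list(psths)
    if not psths:
        raise ValidationError("at least one PSTH required")
    edges = psths[0].bin_edges
    for p in psths[1:]:
        if p.bin_edges.size != edges.size or np.max(np.abs(p.bin_edges - edges)) > _TOL:
            raise ValidationError("mismatched binning across PSTHs")
    mean = np.mean([p.mean_counts for p in psths], axis=0)
    return Psth(bin_edges=edges, mean_counts=mean, n_trials=len(psths), counts=None)
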