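"""Global duration statistics: duration-based multiple-comparison control.

A pointwise permutation test yields a p-value series across the epoch;
isolated sub-threshold p-values are expected by chance, so only
sufficiently long runs of consecutive significant timepoints are treated
as reliable.  The duration threshold is calibrated from the permutations
themselves: each permutation's statistic series is converted to its own
p-value series against the full permutation distribution, the maximal
sub-alpha run length per permutation forms the null duration
distribution, and an observed run survives only if it is strictly longer
than the chosen percentile (default 95th) of that distribution.  This
controls the family-wise error rate over the whole analysed epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TanovaResult

__all__ = ["Run", "GdsResult", "runs_below_alpha", "permutation_p_series", "apply_gds"]


@dataclass(frozen=True)
class Run:
    """A maximal run of consecutive timepoints with p < alpha."""

    onset_idx: int
    offset_idx: int  # inclusive
    onset_ms: float
    offset_ms: float
    duration_samples: int
    duration_ms: float
    surviving: bool = False


@dataclass
class GdsResult:
    """Duration threshold and the runs that survive it."""

    effect: str
    alpha: float
    percentile: float
    duration_threshold_samples: int
    duration_threshold_ms: float
    observed_runs: list[Run]
    perm_max_run_distribution: np.ndarray = field(repr=False, default=None)

    @property
    def surviving_runs(self) -> list[Run]:
        return [r for r in self.observed_runs if r.surviving]

    def to_frame(self) -> pd.DataFrame:
        cols = ["onset_ms", "offset_ms", "duration_ms", "duration_samples", "surviving"]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.observed_runs])


def runs_below_alpha(
    p_series: np.ndarray, alpha: float, times_ms: np.ndarray | None = None
) -> list[Run]:
    """Maximal runs of strictly consecutive samples with p < alpha.

    A single sample at p >= alpha breaks a run (no gap bridging).
    Durations in ms span onset to offset sample times; a one-sample run at
    sampling step dt has duration dt.
    """
    p = np.asarray(p_series, float)
    if p.size == 0:
        raise ValueError("empty p-value series")
    if times_ms is None:
        times_ms = np.arange(p.size, dtype=float)
    times_ms = np.asarray(times_ms, float)
    dt = float(np.median(np.diff(times_ms))) if p.size > 1 else 1.0
    sig = p < alpha
    edges = np.diff(np.concatenate([[0], sig.astype(int), [0]]))
    onsets = np.flatnonzero(edges == 1)
    offsets = np.flatnonzero(edges == -1) - 1
    return [
        Run(
            onset_idx=int(a),
            offset_idx=int(b),
            onset_ms=float(times_ms[a]),
            offset_ms=float(times_ms[b]),
            duration_samples=int(b - a + 1),
            duration_ms=float(b - a + 1) * dt,
        )
        for a, b in zip(onsets, offsets)
    ]


def permutation_p_series(result: TanovaResult) -> np.ndarray:
    """Per-permutation p-value series against the permutation distribution.

    For permutation k at timepoint t, its statistic is treated as the
    observed value and ranked within the full permutation distribution at
    t with the same add-one estimator used for the observed data:
    p_k(t) = (1 + #{j : perm[j, t] >= perm[k, t]}) / (1 + n_perm), where
    the count includes j = k.  A column of total ties therefore maps to
    p = 1 everywhere, and a strict maximum attains the smallest reachable
    value 2 / (1 + n_perm).
    """
    perm = result.perm_stats
    if perm is None or perm.size == 0:
        raise ValueError("perm_stats were not retained on this result")
    n = perm.shape[0]
    # count of >= including self: n - (ascending min-rank) + 1; min-rank via
    # double argsort handles ties exactly.
    order = np.argsort(perm, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n)[:, None], axis=0)
    # convert ordinal ranks to min-ranks under ties
    sorted_vals = np.take_along_axis(perm, order, axis=0)
    is_new = np.ones_like(sorted_vals, dtype=bool)
    is_new[1:] = sorted_vals[1:] != sorted_vals[:-1]
    group_start = np.maximum.accumulate(
        np.where(is_new, np.arange(n)[:, None], 0), axis=0
    )
    min_rank_sorted = group_start  # 0-based min rank per sorted slot
    min_ranks = np.empty_like(order)
    np.put_along_axis(min_ranks, order, min_rank_sorted, axis=0)
    count_geq = n - min_ranks  # includes self
    return (1.0 + count_geq) / (1.0 + n)


def _max_run_lengths(sig: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a boolean (n, t) array."""
    n, t = sig.shape
    padded = np.zeros((n, t + 2), dtype=int)
    padded[:, 1:-1] = sig
    # cumulative length resets at False: classic cumsum-of-runs trick
    out = np.zeros(n, dtype=int)
    run = np.zeros(n, dtype=int)
    for j in range(1, t + 1):
        run = (run + 1) * padded[:, j]
        out = np.maximum(out, run)
    return out


def apply_gds(
    result: TanovaResult, alpha: float = 0.05, percentile: float = 95.0
) -> GdsResult:
    """Duration-correct a pointwise TANOVA result.

    The duration threshold is the ceiling-rank ``percentile`` of the
    per-permutation maximal sub-alpha run lengths; an observed run
    survives iff its length in samples is strictly greater than the
    threshold ("exceeds the percentile").  Fully deterministic given the
    TANOVA result: the same permutation set is reused, no new resampling.
    """
    perm_p = permutation_p_series(result)
    max_runs = _max_run_lengths(perm_p < alpha)
    k = int(np.ceil(percentile / 100.0 * max_runs.size))
    k = min(max(k, 1), max_runs.size)
    threshold = int(np.sort(max_runs)[k - 1])

    dt = 1000.0 / result.sampling_rate if result.sampling_rate else 1.0
    observed = runs_below_alpha(result.p_values, alpha, result.times_ms)
    observed = [
        Run(
            r.onset_idx, r.offset_idx, r.onset_ms, r.offset_ms,
            r.duration_samples, r.duration_ms,
            surviving=r.duration_samples > threshold,
        )
        for r in observed
    ]
    return GdsResult(
        effect=result.effect,
        alpha=alpha,
        percentile=percentile,
        duration_threshold_samples=threshold,
        duration_threshold_ms=threshold * dt,
        observed_runs=observed,
        perm_max_run_distribution=max_runs,
    )
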