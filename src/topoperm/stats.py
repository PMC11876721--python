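"""Topographic permutation statistics: GFP, GDI, TANOVA, effect sizes.

The unit of analysis is the subject x condition averaged scalp map series.
Global field power (GFP) is the standard deviation of voltage across
electrodes at one timepoint; the global dissimilarity index (GDI) between
two maps is the root-mean-square of their electrode-wise difference, which
for average-referenced maps equals the GFP of the difference map.

TANOVA tests, at each timepoint, whether the grand-mean maps of the levels
of an experimental factor differ in topography: the observed GDI (or, for
the 2x2 interaction, the RMS of the double-difference map) is compared to
a permutation null built by reassigning each participant's condition maps
to conditions within that participant.  p-values use the add-one
estimator (1 + exceedances) / (1 + n_perm), with ties counted as
exceedances, so they are never zero.

Effect sizes: partial eta squared is the share of the windowed contrast
field's sum of squares explained by the group-mean contrast; Cohen's d is
reported both through the deterministic conversion d = 2*sqrt(eta2 /
(1 - eta2)) and through a permutation z-score normalised by
sqrt(p1 * p2 * N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import CELL_LABELS
from .preprocess import ConditionERP

__all__ = [
    "ErpStack",
    "TanovaResult",
    "EffectSizeReport",
    "gfp",
    "gdi",
    "normalize_by_gfp",
    "tanova_pointwise",
    "tanova_window",
    "tanova_dispersion",
    "effect_size_eta2",
    "eta2_to_cohens_d",
    "cohens_d_permutation",
]

EFFECTS = ("repetition_main", "expectation_main", "interaction", "between_sets")


def gfp(map_or_series: np.ndarray, axis: int = -2) -> np.ndarray | float:
    """Global field power: SD of voltage across channels.

    For a 1-D map returns a scalar; for (..., channels, time) arrays the
    channel axis defaults to the second-to-last.
    """
    v = np.asarray(map_or_series, float)
    if v.ndim == 1:
        return float(np.sqrt(np.mean((v - v.mean()) ** 2)))
    return np.sqrt(np.mean((v - v.mean(axis=axis, keepdims=True)) ** 2, axis=axis))


def gdi(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Global dissimilarity index: RMS electrode-wise map difference.

    sqrt((1/N) * sum_i (a_i - b_i)^2); symmetric and nonnegative.  Equals
    gfp(a - b) when both maps are average-referenced.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ValueError(f"channel mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def normalize_by_gfp(map_series: np.ndarray) -> np.ndarray:
    """Divide each timepoint's map by its GFP (McCarthy-Wood scaling).

    Accepts (channels,) or (..., channels, time); raises if any normalised
    timepoint has zero GFP, identifying the first offending timepoint.
    """
    v = np.asarray(map_series, float)
    if v.ndim == 1:
        g = gfp(v)
        if g < 1e-15:
            raise ValueError("cannot GFP-normalise a flat map (GFP == 0)")
        return v / g
    g = gfp(v)  # (..., time)
    if np.any(g < 1e-15):
        t_bad = int(np.argwhere(g < 1e-15)[0][-1])
        raise ValueError(f"GFP is zero at timepoint index {t_bad}; cannot normalise")
    return v / g[..., None, :]


@dataclass
class ErpStack:
    """Subject x condition ERP maps stacked into one array.

    ``data`` has shape (subjects, cells, channels, time); every subject
    must contribute every cell.
    """

    data: np.ndarray
    subjects: tuple[str, ...]
    cells: tuple[str, ...]
    times_ms: np.ndarray
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise ValueError("data must be (subjects, cells, channels, time)")
        s, c, ch, t = self.data.shape
        if s != len(self.subjects) or c != len(self.cells) or t != len(self.times_ms):
            raise ValueError("data shape inconsistent with labels/times")
        if self.channel_labels is not None and len(self.channel_labels) != ch:
            raise ValueError("channel_labels inconsistent with data")

    @classmethod
    def from_condition_erps(cls, per_subject: Sequence[Sequence[ConditionERP]],
                            cells: Sequence[str] = CELL_LABELS) -> "ErpStack":
        """Stack per-subject lists of :class:`ConditionERP` (any cell order)."""
        subjects, rows = [], []
        times = None
        for erps in per_subject:
            by_cell = {e.cell: e for e in erps}
            missing = [c for c in cells if c not in by_cell]
            if missing:
                raise ValueError(f"subject {erps[0].subject_id!r} missing cells {missing}")
            subjects.append(erps[0].subject_id)
            rows.append(np.stack([by_cell[c].map_series for c in cells]))
            times = by_cell[cells[0]].times_ms
        return cls(np.stack(rows), tuple(subjects), tuple(cells), np.asarray(times))

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        mask = (self.times_ms >= window_ms[0]) & (self.times_ms <= window_ms[1])
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
        return mask


@dataclass
class TanovaResult:
    """Pointwise TANOVA output for one effect."""

    effect: str
    times_ms: np.ndarray
    observed_stat: np.ndarray  # (time,), uV
    p_values: np.ndarray  # (time,), in (0, 1]
    perm_stats: np.ndarray  # (n_perm, time)
    n_perm: int
    seed: int
    alpha: float = 0.05
    sampling_rate: float | None = None
    normalized: bool = False


@dataclass
class EffectSizeReport:
    """Effect sizes for one GDS-surviving window."""

    effect: str
    window_ms: tuple[float, float]
    partial_eta2: float
    cohen_d: float  # from the eta2 conversion
    z_score: float
    cohen_d_permutation: float
    p1: float
    p2: float
    n_subjects: int


def _cell_factor_levels(cells: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Parse repetition/expectation levels from standard cell labels."""
    rep = np.array([c.endswith("Rep") for c in cells])
    exp = np.array([c.startswith("Exp") for c in cells])
    return rep, exp


def _contrast_weights(cells: Sequence[str], effect: str) -> np.ndarray:
    """Cell weights whose grand-mean combination is the tested contrast map."""
    c = len(cells)
    if effect == "between_sets":
        if c != 2:
            raise ValueError("between_sets requires exactly 2 cells")
        return np.array([1.0, -1.0])
    rep, exp = _cell_factor_levels(cells)
    if effect == "repetition_main":
        pos, neg = rep, ~rep
    elif effect == "expectation_main":
        pos, neg = exp, ~exp
    elif effect == "interaction":
        if c != 4:
            raise ValueError("interaction requires the four 2x2 cells")
        sign = np.where(rep, 1.0, -1.0) * np.where(exp, 1.0, -1.0)
        return sign  # RMS of the double-difference map
    else:
        raise ValueError(f"unknown effect {effect!r}")
    if c == 2 and (pos.sum() != 1 or neg.sum() != 1):
        raise ValueError(f"cells {cells} do not span the {effect} factor")
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError(f"cells {cells} do not span the {effect} factor")
    w = np.zeros(c)
    w[pos] = 1.0 / pos.sum()
    w[neg] = -1.0 / neg.sum()
    return w


def _permutation_indices(
    rng: np.random.Generator,
    n_perm: int,
    n_subjects: int,
    cells: Sequence[str],
    effect: str,
    scheme: str,
) -> np.ndarray:
    """(n_perm, subjects, cells) permuted cell indices, one per subject.

    ``full_cell`` draws a uniform permutation of all condition maps within
    each subject; ``restricted`` permutes only the tested factor's levels
    within each level of the other factor (main effects of a 2x2 design).
    """
    c = len(cells)
    if scheme == "full_cell":
        idx = np.tile(np.arange(c), (n_perm, n_subjects, 1))
        return rng.permuted(idx, axis=2)
    if scheme != "restricted":
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if effect not in ("repetition_main", "expectation_main") or c != 4:
        raise ValueError("restricted scheme applies to 2x2 main effects only")
    rep, exp = _cell_factor_levels(cells)
    other = exp if effect == "repetition_main" else rep
    idx = np.tile(np.arange(c), (n_perm, n_subjects, 1))
    for level in (True, False):
        pair = np.flatnonzero(other == level)
        swap = rng.random((n_perm, n_subjects)) < 0.5
        idx[..., pair[0]] = np.where(swap, pair[1], pair[0])
        idx[..., pair[1]] = np.where(swap, pair[0], pair[1])
    return idx


def _normalize_stack(data: np.ndarray) -> np.ndarray:
    g = gfp(data)  # (s, c, t)
    if np.any(g < 1e-15):
        s, c, t = np.argwhere(g < 1e-15)[0]
        raise ValueError(
            f"GFP is zero for subject {s}, cell {c}, timepoint {t}; cannot normalise"
        )
    return data / g[:, :, None, :]


def tanova_pointwise(
    stack: ErpStack,
    effect: str,
    n_perm: int = 5000,
    seed: int = 0,
    normalized: bool = False,
    alpha: float = 0.05,
    scheme: str = "full_cell",
) -> TanovaResult:
    """Point-by-point topographic permutation test of one effect.

    The observed statistic at each timepoint is the GDI between the
    grand-mean maps of the tested factor's levels (for ``interaction``, the
    RMS across channels of the grand-mean double-difference map;
    ``between_sets`` compares two paired map sets, e.g. per-subject
    repetition-effect difference maps of two stimulus categories).  The
    null is built by reassigning each subject's maps to conditions within
    that subject, and p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if stack.data.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    data = _normalize_stack(stack.data) if normalized else stack.data
    n_subj, n_cells, _, _ = data.shape
    w = _contrast_weights(stack.cells, effect)

    observed = _rms_of_weighted_mean(data, np.tile(w, (1, n_subj, 1)))[0]
    rng = np.random.default_rng(seed)
    idx = _permutation_indices(rng, n_perm, n_subj, stack.cells, effect, scheme)
    perm_stats = np.empty((n_perm, data.shape[-1]))
    # chunk so the (k, channels, time) einsum intermediate stays ~100 MB
    chunk = max(1, int(1.2e7 // (data.shape[2] * data.shape[3])))
    for k0 in range(0, n_perm, chunk):
        weights = w[idx[k0 : k0 + chunk]]  # (k, s, c)
        perm_stats[k0 : k0 + chunk] = _rms_of_weighted_mean(data, weights)
    exceed = (perm_stats >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)

    rate = None
    if len(stack.times_ms) > 1:
        rate = 1000.0 / float(np.median(np.diff(stack.times_ms)))
    return TanovaResult(
        effect=effect,
        times_ms=np.asarray(stack.times_ms, float),
        observed_stat=observed,
        p_values=p,
        perm_stats=perm_stats,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        sampling_rate=rate,
        normalized=normalized,
    )


def _rms_of_weighted_mean(data: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """RMS over channels of the subject-mean weighted cell combination.

    data: (s, c, ch, t); weights: (k, s, c) -> returns (k, t).
    """
    contrast = np.einsum("ksc,scht->kht", weights, data) / data.shape[0]
    return np.sqrt(np.mean(contrast**2, axis=1))


def tanova_window(
    stack: ErpStack,
    effect: str,
    window_ms: tuple[float, float],
    n_perm: int = 5000,
    seed: int = 0,
    normalized: bool = False,
    alpha: float = 0.05,
    scheme: str = "full_cell",
) -> TanovaResult:
    """Single TANOVA on window-averaged maps (e.g. N250r topography tests).

    Maps are averaged over the window per subject and condition first; if
    ``normalized``, the window-mean maps are GFP-scaled before testing, so
    the comparison is purely topographic.  A one-sample window reduces
    exactly to the pointwise test at that sample.
    """
    mask = stack.window_mask(window_ms)
    win = stack.data[..., mask].mean(axis=-1, keepdims=True)
    sub = ErpStack(
        win,
        stack.subjects,
        stack.cells,
        np.array([np.mean(window_ms)]),
        stack.channel_labels,
    )
    res = tanova_pointwise(sub, effect, n_perm, seed, normalized, alpha, scheme)
    res.effect = f"{res.effect}[{window_ms[0]:g}-{window_ms[1]:g}ms]"
    return res


def tanova_dispersion(
    stack: ErpStack,
    n_perm: int = 5000,
    seed: int = 0,
    normalized: bool = False,
    alpha: float = 0.05,
) -> TanovaResult:
    """Pointwise dissimilarity test across k >= 2 paired map sets.

    Generalises the two-set GDI comparison to several sets (e.g. the
    repetition-effect difference maps of three stimulus categories, whose
    heterogeneity is the repetition x category interaction): the statistic
    is the RMS, across sets and channels, of the grand-mean maps around
    their common mean.  For two sets it is proportional to their GDI, so
    p-values coincide.  The null permutes set labels within each subject.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_subj, n_cells = stack.data.shape[:2]
    if n_subj < 2 or n_cells < 2:
        raise ValueError("need at least 2 subjects and 2 map sets")
    data = _normalize_stack(stack.data) if normalized else stack.data

    def dispersion(grand: np.ndarray) -> np.ndarray:  # grand: (c, ch, t)
        centred = grand - grand.mean(axis=0, keepdims=True)
        return np.sqrt(np.mean(centred**2, axis=(0, 1)))

    observed = dispersion(data.mean(axis=0))
    rng = np.random.default_rng(seed)
    idx = _permutation_indices(rng, n_perm, n_subj, stack.cells, "", "full_cell")
    perm_stats = np.empty((n_perm, data.shape[-1]))
    rows = np.arange(n_subj)[:, None]
    for k in range(n_perm):
        perm_stats[k] = dispersion(data[rows, idx[k]].mean(axis=0))
    exceed = (perm_stats >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    rate = None
    if len(stack.times_ms) > 1:
        rate = 1000.0 / float(np.median(np.diff(stack.times_ms)))
    return TanovaResult(
        effect="dispersion",
        times_ms=np.asarray(stack.times_ms, float),
        observed_stat=observed,
        p_values=p,
        perm_stats=perm_stats,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        sampling_rate=rate,
        normalized=normalized,
    )


def effect_size_eta2(
    stack: ErpStack,
    effect: str,
    window_ms: tuple[float, float],
    normalized: bool = False,
) -> float:
    """Partial eta squared of an effect over a time window.

    The per-subject contrast map (weighted cell combination, averaged over
    the window) is partitioned as grand mean + residual:
    SS_effect = N * sum_ch(grand_mean^2), SS_error = sum_subj sum_ch
    (residual^2), eta2 = SS_effect / (SS_effect + SS_error) — the share of
    the contrast field's variance explained by the design.
    """
    data = _normalize_stack(stack.data) if normalized else stack.data
    mask = stack.window_mask(window_ms)
    w = _contrast_weights(stack.cells, effect)
    contrasts = np.einsum("c,scht->sht", w, data[..., mask]).mean(axis=-1)  # (s, ch)
    grand = contrasts.mean(axis=0)
    ss_effect = contrasts.shape[0] * float((grand**2).sum())
    ss_error = float(((contrasts - grand) ** 2).sum())
    total = ss_effect + ss_error
    if total < 1e-30:
        raise ValueError("zero total variance in the contrast field")
    return ss_effect / total


def eta2_to_cohens_d(partial_eta2: float) -> float:
    """Deterministic conversion d = 2 * sqrt(eta2 / (1 - eta2)).

    The standard F-family relation between partial eta squared and Cohen's
    d for a two-level contrast; report rounded to 2 decimals.
    """
    if not 0.0 <= partial_eta2 < 1.0:
        raise ValueError("partial eta squared must be in [0, 1)")
    return 2.0 * float(np.sqrt(partial_eta2 / (1.0 - partial_eta2)))


def cohens_d_permutation(
    result: TanovaResult,
    window_ms: tuple[float, float],
    p1: float,
    p2: float,
    n_subjects: int,
) -> tuple[float, float]:
    """Permutation-based effect size over a window.

    z is the observed window-mean statistic standardised against the
    permutation distribution of window-mean statistics; d = z /
    sqrt(p1 * p2 * N) with p1, p2 the condition proportions and N the
    number of subjects.
    """
    mask = (result.times_ms >= window_ms[0]) & (result.times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    obs = float(result.observed_stat[mask].mean())
    perm = result.perm_stats[:, mask].mean(axis=1)
    sd = float(perm.std(ddof=1))
    if sd < 1e-15:
        raise ValueError("permutation distribution has zero variance")
    z = (obs - float(perm.mean())) / sd
    return z, z / float(np.sqrt(p1 * p2 * n_subjects))
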