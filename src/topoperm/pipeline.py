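"""Orchestration of the full topographic analysis.

Mirrors the published analysis structure: per-category 2x2 (repetition x
expectation) pointwise TANOVAs with duration correction and effect sizes;
a cross-category analysis of the repetition effect (repetition x category
heterogeneity test, pairwise non-normalised contrasts of the per-subject
repetition difference maps); and normalised window-mean topography
comparisons of the shared N250r-range repetition effects, including an
early/late split of a broad window.

TANOVA handles two within-subject factors at a time, so category enters
either as the block over which 2x2 analyses repeat or as one factor of
the repetition x category analysis — never as a third crossed factor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .gds import GdsResult, apply_gds
from .stats import (
    EffectSizeReport,
    ErpStack,
    TanovaResult,
    cohens_d_permutation,
    effect_size_eta2,
    eta2_to_cohens_d,
    tanova_dispersion,
    tanova_pointwise,
)

__all__ = [
    "AnalysisConfig",
    "FactorialAnalysis",
    "CrossCategoryAnalysis",
    "run_factorial_analysis",
    "run_cross_category_analysis",
]

logger = logging.getLogger("topoperm")

FACTORIAL_EFFECTS = ("repetition_main", "expectation_main", "interaction")

#: Condition proportions of the tested two-level factors.  Cues are
#: equiprobable and repetition/alternation marginals are balanced, so both
#: factor levels carry half the trials.
CONDITION_PROPORTIONS = (0.5, 0.5)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of a calibrated analysis run."""

    n_perm: int = 5000
    alpha: float = 0.05
    gds_percentile: float = 95.0
    analysis_interval_ms: tuple[float, float] = (-150.0, 850.0)
    normalized_factorial: bool = False  # factorial TANOVAs on raw maps
    normalized_topography: bool = True  # window topography tests GFP-scaled
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm < 100 gives uncalibrated p-values")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.gds_percentile <= 100:
            raise ValueError("gds_percentile must be in (0, 100]")


@dataclass
class FactorialAnalysis:
    """Results of one per-category 2x2 analysis."""

    category: str
    tanovas: dict[str, TanovaResult]
    gds: dict[str, GdsResult]
    effect_sizes: list[EffectSizeReport]

    def surviving_windows(self, effect: str) -> list[tuple[float, float]]:
        return [(r.onset_ms, r.offset_ms) for r in self.gds[effect].surviving_runs]


@dataclass
class CrossCategoryAnalysis:
    """Results of the repetition x category analysis."""

    categories: tuple[str, ...]
    interaction: TanovaResult
    interaction_gds: GdsResult
    pairwise: dict[tuple[str, str], TanovaResult]
    pairwise_gds: dict[tuple[str, str], GdsResult]
    topography_tests: dict[tuple[str, str], TanovaResult]
    early_late_test: TanovaResult | None
    effect_sizes: list[EffectSizeReport] = field(default_factory=list)


def _restrict(stack: ErpStack, interval_ms: tuple[float, float]) -> ErpStack:
    mask = stack.window_mask(interval_ms)
    return ErpStack(stack.data[..., mask], stack.subjects, stack.cells,
                    stack.times_ms[mask], stack.channel_labels)


def _window_effect_sizes(
    stack: ErpStack,
    effect: str,
    res: TanovaResult,
    gds_res: GdsResult,
    normalized: bool,
) -> list[EffectSizeReport]:
    """Both effect-size routes for every GDS-surviving window."""
    out = []
    p1, p2 = CONDITION_PROPORTIONS
    n = len(stack.subjects)
    for run in gds_res.surviving_runs:
        window = (run.onset_ms, run.offset_ms)
        eta2 = effect_size_eta2(stack, effect, window, normalized=normalized)
        z, d_perm = cohens_d_permutation(res, window, p1, p2, n)
        out.append(
            EffectSizeReport(
                effect=effect,
                window_ms=window,
                partial_eta2=eta2,
                cohen_d=eta2_to_cohens_d(eta2),
                z_score=z,
                cohen_d_permutation=d_perm,
                p1=p1,
                p2=p2,
                n_subjects=n,
            )
        )
    return out


def run_factorial_analysis(
    stack: ErpStack, category: str, config: AnalysisConfig = AnalysisConfig()
) -> FactorialAnalysis:
    """Per-category 2x2 analysis: 3 pointwise TANOVAs, GDS, effect sizes."""
    stack = _restrict(stack, config.analysis_interval_ms)
    tanovas: dict[str, TanovaResult] = {}
    gds: dict[str, GdsResult] = {}
    sizes: list[EffectSizeReport] = []
    for i, effect in enumerate(FACTORIAL_EFFECTS):
        res = tanova_pointwise(
            stack,
            effect,
            n_perm=config.n_perm,
            seed=config.seed + i,
            normalized=config.normalized_factorial,
            alpha=config.alpha,
        )
        g = apply_gds(res, config.alpha, config.gds_percentile)
        tanovas[effect] = res
        gds[effect] = g
        sizes.extend(
            _window_effect_sizes(stack, effect, res, g, config.normalized_factorial)
        )
        for run in g.surviving_runs:
            logger.info(
                "%s/%s: surviving window %.0f-%.0f ms", category, effect,
                run.onset_ms, run.offset_ms,
            )
    return FactorialAnalysis(category, tanovas, gds, sizes)


def repetition_difference_stack(stacks: dict[str, ErpStack]) -> ErpStack:
    """Per-subject repetition - alternation difference maps, one cell per
    category (the paired map sets compared across categories)."""
    cats = tuple(stacks)
    first = stacks[cats[0]]
    diffs = []
    for cat in cats:
        s = stacks[cat]
        if s.subjects != first.subjects:
            raise ValueError("all categories must share the same subjects (paired)")
        rep = np.array([c.endswith("Rep") for c in s.cells])
        diff = s.data[:, rep].mean(axis=1) - s.data[:, ~rep].mean(axis=1)
        diffs.append(diff)
    return ErpStack(
        np.stack(diffs, axis=1), first.subjects, cats, first.times_ms,
        first.channel_labels,
    )


def run_cross_category_analysis(
    stacks: dict[str, ErpStack],
    config: AnalysisConfig = AnalysisConfig(),
    n250r_windows: dict[str, tuple[float, float]] | None = None,
    early_late_split: tuple[tuple[float, float], tuple[float, float]] | None = None,
    early_late_category: str | None = None,
) -> CrossCategoryAnalysis:
    """Cross-category repetition-effect analysis.

    Stages: (1) pointwise heterogeneity test of the per-subject repetition
    difference maps across categories (the repetition x category
    interaction), GDS-corrected; (2) pairwise non-normalised contrasts
    between the categories' difference maps, GDS-corrected; (3) if
    ``n250r_windows`` gives one window per category, pairwise GFP-normalised
    topography tests of the window-mean difference maps; (4) optionally an
    early/late split comparison of one category's difference topography.
    """
    if len(stacks) < 2:
        raise ValueError("cross-category analysis needs at least 2 categories")
    diff = _restrict(repetition_difference_stack(stacks), config.analysis_interval_ms)
    cats = diff.cells

    interaction = tanova_dispersion(
        diff, n_perm=config.n_perm, seed=config.seed, alpha=config.alpha
    )
    interaction.effect = "repetition_x_category"
    interaction_gds = apply_gds(interaction, config.alpha, config.gds_percentile)

    pairwise: dict[tuple[str, str], TanovaResult] = {}
    pairwise_gds: dict[tuple[str, str], GdsResult] = {}
    for i, (a, b) in enumerate(itertools.combinations(cats, 2)):
        sub = ErpStack(
            diff.data[:, [cats.index(a), cats.index(b)]],
            diff.subjects, (a, b), diff.times_ms, diff.channel_labels,
        )
        res = tanova_pointwise(
            sub, "between_sets", n_perm=config.n_perm, seed=config.seed + 10 + i,
            alpha=config.alpha,
        )
        res.effect = f"repetition:{a}_vs_{b}"
        pairwise[(a, b)] = res
        pairwise_gds[(a, b)] = apply_gds(res, config.alpha, config.gds_percentile)

    topo_tests: dict[tuple[str, str], TanovaResult] = {}
    sizes: list[EffectSizeReport] = []
    if n250r_windows is not None:
        missing = [c for c in cats if c not in n250r_windows]
        if missing:
            raise ValueError(f"n250r_windows missing categories {missing}")
        win_means = {
            cat: diff.data[:, cats.index(cat)][
                ..., diff.window_mask(n250r_windows[cat])
            ].mean(axis=-1)
            for cat in cats
        }
        for i, (a, b) in enumerate(itertools.combinations(cats, 2)):
            pair = ErpStack(
                np.stack([win_means[a], win_means[b]], axis=1)[..., None],
                diff.subjects, (a, b), np.array([0.0]), diff.channel_labels,
            )
            res = tanova_pointwise(
                pair, "between_sets", n_perm=config.n_perm,
                seed=config.seed + 20 + i,
                normalized=config.normalized_topography, alpha=config.alpha,
            )
            res.effect = f"n250r_topography:{a}_vs_{b}"
            topo_tests[(a, b)] = res

    early_late = None
    if early_late_split is not None:
        cat = early_late_category or cats[0]
        (w_early, w_late) = early_late_split
        cat_maps = diff.data[:, cats.index(cat)]
        means = np.stack(
            [
                cat_maps[..., diff.window_mask(w_early)].mean(-1),
                cat_maps[..., diff.window_mask(w_late)].mean(-1),
            ],
            axis=1,
        )[..., None]
        pair = ErpStack(means, diff.subjects, ("early", "late"),
                        np.array([0.0]), diff.channel_labels)
        early_late = tanova_pointwise(
            pair, "between_sets", n_perm=config.n_perm, seed=config.seed + 30,
            normalized=config.normalized_topography, alpha=config.alpha,
        )
        early_late.effect = f"{cat}:early_vs_late_topography"

    return CrossCategoryAnalysis(
        categories=cats,
        interaction=interaction,
        interaction_gds=interaction_gds,
        pairwise=pairwise,
        pairwise_gds=pairwise_gds,
        topography_tests=topo_tests,
        early_late_test=early_late,
        effect_sizes=sizes,
    )
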