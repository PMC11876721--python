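"""Calibration studies for the permutation machinery.

Desk-scale simulation harnesses that check the statistical guarantees the
pipeline relies on: family-wise error control of the duration-corrected
TANOVA under a global null, and recovery of an injected effect window at
a known signal-to-noise ratio.  Both operate on subject-level condition
ERPs (the group-level generator), which is the resolution at which the
permutation statistics act.

Default conditions: 20 subjects, 32 channels, 250 timepoints at 250 Hz,
spatially correlated AR(1) noise of 1 uV at the subject-ERP level, 1000
permutations, alpha 0.05 and the 95th duration percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CELL_LABELS
from .gds import apply_gds
from .montage import Montage, ring_montage
from .simulate import EffectSpec, NoiseSpec, make_topography, simulate_condition_erps
from .stats import ErpStack, tanova_pointwise

__all__ = [
    "CalibrationConditions",
    "fwer_replicate",
    "fwer_study",
    "recovery_replicate",
    "recovery_study",
]


@dataclass(frozen=True)
class CalibrationConditions:
    """Simulation conditions for one calibration replicate."""

    n_subjects: int = 20
    n_channels: int = 32
    sampling_rate: float = 250.0
    epoch_window_ms: tuple[float, float] = (-150.0, 846.0)  # 250 samples
    erp_noise_sd: float = 1.0
    spatial_smoothing_sigma: float = 0.4
    ar1_coefficient: float = 0.5
    subject_amplitude_sd: float = 0.3
    n_perm: int = 1000
    alpha: float = 0.05
    gds_percentile: float = 95.0

    def montage(self) -> Montage:
        return ring_montage(self.n_channels)

    def noise(self) -> NoiseSpec:
        return NoiseSpec(
            trial_noise_sd=self.erp_noise_sd,
            spatial_smoothing_sigma=self.spatial_smoothing_sigma,
            ar1_coefficient=self.ar1_coefficient,
            subject_amplitude_sd=self.subject_amplitude_sd,
        )


def _simulate_stack(
    cond: CalibrationConditions, effects: list[EffectSpec], seed: int,
    montage: Montage | None = None,
) -> ErpStack:
    montage = montage or cond.montage()
    data, times = simulate_condition_erps(
        cond.n_subjects, effects, cond.noise(), montage,
        sampling_rate=cond.sampling_rate, epoch_window_ms=cond.epoch_window_ms,
        seed=seed,
    )
    return ErpStack(
        data, tuple(f"S{i:02d}" for i in range(cond.n_subjects)), CELL_LABELS,
        times, montage.channel_labels,
    )


def fwer_replicate(
    seed: int, cond: CalibrationConditions = CalibrationConditions(),
    montage: Montage | None = None,
) -> bool:
    """One global-null replicate; True if any GDS-surviving window appears.

    No effects are injected, so any surviving window of the duration-
    corrected repetition TANOVA is a family-wise false positive.
    """
    stack = _simulate_stack(cond, [], seed, montage)
    res = tanova_pointwise(
        stack, "repetition_main", n_perm=cond.n_perm, seed=seed,
        alpha=cond.alpha,
    )
    gds = apply_gds(res, cond.alpha, cond.gds_percentile)
    return bool(gds.surviving_runs)


def fwer_study(
    seeds: list[int], cond: CalibrationConditions = CalibrationConditions()
) -> float:
    """Empirical FWER: fraction of null replicates with a surviving window."""
    montage = cond.montage()
    hits = sum(fwer_replicate(s, cond, montage) for s in seeds)
    return hits / len(seeds)


def recovery_replicate(
    seed: int,
    cond: CalibrationConditions = CalibrationConditions(),
    window_ms: tuple[float, float] = (200.0, 300.0),
    amplitude: float = 3.0,
    montage: Montage | None = None,
) -> float:
    """One effect-recovery replicate; returns the Jaccard overlap.

    A repetition effect of the given grand-average amplitude (in units of
    the ERP noise SD when the noise SD is 1 uV) is injected in
    ``window_ms``; the overlap is computed between the timepoints inside
    the injected window and the union of GDS-surviving significant
    timepoints.
    """
    montage = montage or cond.montage()
    rng = np.random.default_rng(np.random.SeedSequence([97, seed]))
    focus = list(rng.choice(montage.channel_labels, size=2, replace=False))
    topo = make_topography(montage, focus, 0.3)
    eff = EffectSpec("injected", "repetition_main", topo, window_ms, amplitude)
    stack = _simulate_stack(cond, [eff], seed, montage)
    res = tanova_pointwise(
        stack, "repetition_main", n_perm=cond.n_perm, seed=seed, alpha=cond.alpha
    )
    gds = apply_gds(res, cond.alpha, cond.gds_percentile)

    injected = set(
        np.flatnonzero((stack.times_ms >= window_ms[0]) &
                       (stack.times_ms <= window_ms[1]))
    )
    detected: set[int] = set()
    for run in gds.surviving_runs:
        detected.update(range(run.onset_idx, run.offset_idx + 1))
    union = injected | detected
    return len(injected & detected) / len(union) if union else 1.0


def recovery_study(
    seeds: list[int],
    cond: CalibrationConditions = CalibrationConditions(),
    window_ms: tuple[float, float] = (200.0, 300.0),
    amplitude: float = 3.0,
    jaccard_threshold: float = 0.5,
) -> float:
    """Fraction of replicates whose Jaccard overlap reaches the threshold."""
    montage = cond.montage()
    hits = sum(
        recovery_replicate(s, cond, window_ms, amplitude, montage) >= jaccard_threshold
        for s in seeds
    )
    return hits / len(seeds)
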