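"""Synthetic multi-subject ERP data with injectable topographic effects.

The generator is a forward model for the cued repetition-probability
design: every trial's signal is a sum of condition-contrast effects, each
an amplitude times a fixed zero-mean unit-GFP scalp topography times a
temporal envelope, to which spatially correlated, temporally autocorrelated
Gaussian noise is added.  Because the injected contrast maps are known
exactly, every statistical stage downstream can be validated against
ground truth.

Noise model: independent white Gaussian samples are first filtered to an
AR(1) process along time (stationary initialisation), then mixed across
channels by the symmetric square root of a distance-based Gaussian kernel,
rescaled so every channel keeps the requested marginal standard deviation.
This captures the two correlations that matter for the validity of
permutation inference on scalp maps — temporal smoothness and spatial
covariance — without modelling cortical sources.

Between-subject variability enters as a per-subject multiplicative effect
scale drawn from a lognormal distribution with median 1, so effect signs
are consistent across subjects as group-level topographic tests assume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .design import CELL_LABELS, DesignSpec, build_category_trials
from .montage import Montage

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "EpochedData",
    "make_topography",
    "simulate_subject_epochs",
    "simulate_study",
    "simulate_condition_erps",
]

CONTRASTS = ("repetition_main", "expectation_main", "interaction")


def _gfp(v: np.ndarray) -> float:
    v = np.asarray(v, float)
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


@dataclass(frozen=True)
class EffectSpec:
    """A condition-contrast effect to inject into simulated trials.

    ``contrast`` is one of ``repetition_main``, ``expectation_main``,
    ``interaction`` or ``category_specific:<label>`` (a repetition contrast
    restricted to one stimulus category).  ``amplitude`` is the peak
    condition-difference in microvolts: with a unit-GFP topography, a
    repetition_main amplitude of *a* makes the noise-free repetition minus
    alternation difference map equal ``a * topography`` at the envelope
    peak, and likewise the double-difference map for ``interaction``.
    """

    name: str
    contrast: str
    topography: np.ndarray
    window_ms: tuple[float, float]
    amplitude: float
    envelope: str | Callable[[np.ndarray], np.ndarray] = "raised_cosine"

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, float)
        object.__setattr__(self, "topography", topo)
        if topo.ndim != 1 or topo.size < 2:
            raise ValueError("topography must be a 1-D map over channels")
        if abs(topo.mean()) > 1e-8:
            raise ValueError("topography must have zero mean across channels")
        if abs(_gfp(topo) - 1.0) > 1e-6:
            raise ValueError("topography must have unit GFP")
        base = self.contrast.split(":", 1)[0]
        if base not in CONTRASTS and base != "category_specific":
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.window_ms[1] <= self.window_ms[0]:
            raise ValueError("window_ms must satisfy onset < offset")

    def trial_signs(self, table: pd.DataFrame) -> np.ndarray:
        """Signed per-trial weight so condition differences equal amplitude.

        Repetition/expectation main effects use +-1/2 coding (difference of
        the two marginal means equals 1); the interaction uses +-1/4 so the
        double difference equals 1.
        """
        rep = np.where(table["is_repetition"].to_numpy(), 1.0, -1.0)
        exp = np.where(table["is_expected"].to_numpy(), 1.0, -1.0)
        base, _, arg = self.contrast.partition(":")
        if base == "repetition_main":
            return 0.5 * rep
        if base == "expectation_main":
            return 0.5 * exp
        if base == "interaction":
            return 0.25 * rep * exp
        # category_specific: repetition contrast only within the category
        mask = (table["category"] == arg).to_numpy(float)
        return 0.5 * rep * mask

    def cell_signs(self, cells: Sequence[str] = CELL_LABELS) -> np.ndarray:
        """Per-condition-cell weight for ERP-level simulation."""
        rep = np.array([1.0 if c.endswith("Rep") else -1.0 for c in cells])
        exp = np.array([1.0 if c.startswith("Exp") else -1.0 for c in cells])
        base = self.contrast.split(":", 1)[0]
        if base == "repetition_main":
            return 0.5 * rep
        if base == "expectation_main":
            return 0.5 * exp
        if base == "interaction":
            return 0.25 * rep * exp
        raise ValueError(
            "category_specific effects need a trial table, not cell labels"
        )

    def envelope_values(self, times_ms: np.ndarray) -> np.ndarray:
        """Temporal envelope sampled at ``times_ms`` (peak value 1)."""
        on, off = self.window_ms
        if callable(self.envelope):
            return np.asarray(self.envelope(times_ms), float)
        if self.envelope == "raised_cosine":
            phase = (times_ms - on) / (off - on)
            env = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
            return np.where((phase >= 0) & (phase <= 1), env, 0.0)
        if self.envelope == "boxcar":
            return ((times_ms >= on) & (times_ms <= off)).astype(float)
        raise ValueError(f"unknown envelope {self.envelope!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise parameters: trial-level SD (uV), spatial kernel width (montage
    distance units), temporal AR(1) coefficient, and the lognormal sigma of
    the per-subject multiplicative effect scale."""

    trial_noise_sd: float = 5.0
    spatial_smoothing_sigma: float = 0.4
    ar1_coefficient: float = 0.5
    subject_amplitude_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.trial_noise_sd < 0:
            raise ValueError("trial_noise_sd must be >= 0")
        if not -1.0 < self.ar1_coefficient < 1.0:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.subject_amplitude_sd < 0:
            raise ValueError("subject_amplitude_sd must be >= 0")


@dataclass
class EpochedData:
    """Single-subject epoched data: trials x channels x time, in uV."""

    data: np.ndarray
    times_ms: np.ndarray
    sampling_rate: float
    trial_table: pd.DataFrame
    montage: Montage
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        n_trials, n_channels, n_times = self.data.shape
        if n_trials != len(self.trial_table):
            raise ValueError("data and trial table disagree on trial count")
        if n_channels != self.montage.n_channels:
            raise ValueError("data and montage disagree on channel count")
        if n_times != len(self.times_ms):
            raise ValueError("data and times_ms disagree on sample count")

    @property
    def epoch_window_ms(self) -> tuple[float, float]:
        return float(self.times_ms[0]), float(self.times_ms[-1])


def epoch_times(
    epoch_window_ms: tuple[float, float] = (-150.0, 850.0),
    sampling_rate: float = 250.0,
) -> np.ndarray:
    """Sample times in ms covering the epoch window at the given rate."""
    start, stop = epoch_window_ms
    step = 1000.0 / sampling_rate
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def make_topography(
    montage: Montage,
    focus_channels: Sequence[str] | Mapping[str, float],
    spatial_sigma: float,
) -> np.ndarray:
    """Smooth scalp map peaking at the focus channels (zero mean, unit GFP).

    Each focus channel contributes a Gaussian bump of width ``spatial_sigma``
    (in montage distance units) scaled by its weight (+1 for plain label
    lists); the summed map is re-centred to zero mean across channels —
    i.e. expressed against the average reference — and normalised to unit
    global field power.  ``spatial_sigma = 0`` gives point sources.
    """
    if isinstance(focus_channels, Mapping):
        weights = dict(focus_channels)
    else:
        weights = {label: 1.0 for label in focus_channels}
    if not weights:
        raise ValueError("need at least one focus channel")
    topo = np.zeros(montage.n_channels)
    for label, w in weights.items():
        i = montage.index_of(label)
        if spatial_sigma <= 0:
            topo[i] += w
        else:
            d = np.linalg.norm(montage.positions - montage.positions[i], axis=1)
            topo += w * np.exp(-0.5 * (d / spatial_sigma) ** 2)
    topo -= topo.mean()
    norm = _gfp(topo)
    if norm < 1e-12:
        raise ValueError(
            "topography is flat after average-reference centring "
            "(degenerate sigma or cancelling weights)"
        )
    return topo / norm


def spatial_mixing_matrix(montage: Montage, sigma: float) -> np.ndarray:
    """Square root of the Gaussian distance kernel, row-normalised so mixed
    white noise keeps unit variance per channel."""
    if sigma <= 0:
        return np.eye(montage.n_channels)
    d = montage.distances()
    kernel = np.exp(-0.5 * (d / sigma) ** 2)
    eigval, eigvec = np.linalg.eigh(kernel)
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None))) @ eigvec.T
    row_power = np.sqrt((root**2).sum(axis=1, keepdims=True))
    return root / row_power


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], phi: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov = rng.standard_normal(shape) * (sd * np.sqrt(1.0 - phi**2))
    # Replace the first sample by a draw from the stationary distribution,
    # then run the recursion with lfilter.
    innov[..., 0] = rng.standard_normal(shape[:-1]) * sd
    return signal.lfilter([1.0], [1.0, -phi], innov, axis=-1)


def simulate_noise(
    rng: np.random.Generator,
    n_maps: int,
    montage: Montage,
    times_ms: np.ndarray,
    noise: NoiseSpec,
    sd: float | None = None,
) -> np.ndarray:
    """(n_maps, channels, time) noise: AR(1) in time, correlated in space."""
    sd = noise.trial_noise_sd if sd is None else sd
    white = _ar1_noise(
        rng, (n_maps, montage.n_channels, len(times_ms)), noise.ar1_coefficient, sd
    )
    mix = spatial_mixing_matrix(montage, noise.spatial_smoothing_sigma)
    return np.einsum("ij,njt->nit", mix, white)


def simulate_subject_epochs(
    table: pd.DataFrame,
    effects: Sequence[EffectSpec],
    noise: NoiseSpec,
    montage: Montage,
    sampling_rate: float = 250.0,
    epoch_window_ms: tuple[float, float] = (-150.0, 850.0),
    seed: int | np.random.SeedSequence = 0,
    effect_scale: float = 1.0,
    subject_id: str = "S00",
) -> EpochedData:
    """Simulate one subject's epochs for a given trial table.

    Each trial's signal is the sum over effects of ``amplitude *
    effect_scale * sign(trial) * envelope(t) * topography`` plus one draw
    of AR(1)-in-time, spatially correlated noise.
    """
    times = epoch_times(epoch_window_ms, sampling_rate)
    for eff in effects:
        if eff.topography.size != montage.n_channels:
            raise ValueError(f"effect {eff.name!r} topography does not match montage")
        if eff.window_ms[0] < times[0] or eff.window_ms[1] > times[-1]:
            raise ValueError(f"effect {eff.name!r} window outside the epoch")
    rng = np.random.default_rng(seed)
    n_trials = len(table)
    data = simulate_noise(rng, n_trials, montage, times, noise)
    for eff in effects:
        env = eff.envelope_values(times)
        signs = eff.trial_signs(table)
        # (trials,) x (channels,) x (time,) outer product
        data += (
            eff.amplitude
            * effect_scale
            * signs[:, None, None]
            * eff.topography[None, :, None]
            * env[None, None, :]
        )
    return EpochedData(data, times, sampling_rate, table.reset_index(drop=True),
                       montage, subject_id)


def simulate_study(
    n_subjects: int,
    spec: DesignSpec,
    effects: Sequence[EffectSpec],
    noise: NoiseSpec,
    montage: Montage,
    category: str | None = None,
    sampling_rate: float = 250.0,
    epoch_window_ms: tuple[float, float] = (-150.0, 850.0),
    seed: int = 0,
) -> list[EpochedData]:
    """Simulate a multi-subject study (one category block per subject).

    Subject seeds are spawned deterministically from the master seed; the
    per-subject effect scale is drawn once per subject from a lognormal
    with median 1 and log-SD ``noise.subject_amplitude_sd``.  ``category``
    defaults to the first category in the design spec.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    category = category or spec.categories[0]
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)
    scale_rng = np.random.default_rng(master.spawn(1)[0])
    datasets = []
    for s, sub_seed in enumerate(subject_seeds):
        design_seed, noise_seed = sub_seed.spawn(2)
        sub_spec = spec.with_seed(int(design_seed.generate_state(1)[0] % (2**31)))
        table = build_category_trials(sub_spec, category)
        scale = float(
            np.exp(scale_rng.normal(0.0, noise.subject_amplitude_sd))
        )
        datasets.append(
            simulate_subject_epochs(
                table, effects, noise, montage, sampling_rate, epoch_window_ms,
                seed=noise_seed, effect_scale=scale, subject_id=f"S{s:02d}",
            )
        )
    return datasets


def simulate_condition_erps(
    n_subjects: int,
    effects: Sequence[EffectSpec],
    noise: NoiseSpec,
    montage: Montage,
    cells: Sequence[str] = CELL_LABELS,
    sampling_rate: float = 250.0,
    epoch_window_ms: tuple[float, float] = (-150.0, 850.0),
    erp_noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate subject x condition ERP maps directly (no single trials).

    The group-level fast path for calibration studies: residual noise is
    drawn per subject-condition ERP (``erp_noise_sd``, defaulting to
    ``trial_noise_sd`` — interpret it as the standard error left after
    trial averaging), with the same AR(1)-in-time / spatially correlated
    structure as trial noise.  Returns ``(data, times_ms)`` with ``data``
    shaped (subjects, cells, channels, time).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    times = epoch_times(epoch_window_ms, sampling_rate)
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master)
    sd = noise.trial_noise_sd if erp_noise_sd is None else erp_noise_sd
    n_cells = len(cells)
    flat = simulate_noise(rng, n_subjects * n_cells, montage, times, noise, sd=sd)
    data = flat.reshape(n_subjects, n_cells, montage.n_channels, len(times))
    scales = np.exp(rng.normal(0.0, noise.subject_amplitude_sd, size=n_subjects))
    for eff in effects:
        env = eff.envelope_values(times)
        signs = eff.cell_signs(cells)
        data += (
            eff.amplitude
            * scales[:, None, None, None]
            * signs[None, :, None, None]
            * eff.topography[None, None, :, None]
            * env[None, None, None, :]
        )
    return data, times
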