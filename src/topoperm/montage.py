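"""Electrode montages as 2-D layouts on the unit disc.

Scalp statistics here only need channel identities and relative distances,
so a montage is a list of labels plus planar coordinates obtained by
azimuthal projection of the standard 10-10 positions (or generated
synthetically for small test layouts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "standard_64_montage", "ring_montage"]


@dataclass(frozen=True)
class Montage:
    """Channel labels and 2-D positions on the unit disc."""

    channel_labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("channel labels must be unique")
        if len(self.channel_labels) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if pos.shape != (len(self.channel_labels), 2) or not np.all(np.isfinite(pos)):
            raise ValueError("positions must be a finite (n_channels, 2) array")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index_of(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between channel positions."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(-1))


def standard_64_montage() -> Montage:
    """64-channel 10-10 scalp montage projected onto the unit disc.

    Uses the BioSemi 64-electrode layout (standard 10-10 positions) shipped
    with MNE-Python; 3-D head coordinates are flattened with an azimuthal
    equidistant projection so that the vertex maps to the origin and the
    head circumference to the unit circle.
    """
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    ch_pos = std.get_positions()["ch_pos"]
    labels = tuple(ch_pos)
    xyz = np.array([ch_pos[c] for c in labels])
    xyz = xyz - xyz.mean(axis=0) * [1.0, 1.0, 0.0]  # centre in the x/y plane
    r = np.linalg.norm(xyz, axis=1)
    polar = np.arccos(np.clip(xyz[:, 2] / r, -1.0, 1.0))  # angle from vertex
    azimuth = np.arctan2(xyz[:, 1], xyz[:, 0])
    rho = polar / (np.pi / 2.0)  # equator -> radius 1
    pos = np.column_stack([rho * np.cos(azimuth), rho * np.sin(azimuth)])
    pos /= max(1.0, np.abs(pos).max())
    return Montage(labels, pos)


def ring_montage(n_channels: int, label_prefix: str = "ch") -> Montage:
    """Synthetic montage: channels on concentric rings of the unit disc.

    Used for desk-scale simulations where only distances matter (e.g. the
    32-channel calibration layouts).
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    # One centre electrode, remaining spread over rings of ~8, 12, 16, ...
    pos = [(0.0, 0.0)]
    ring, remaining = 1, n_channels - 1
    while remaining > 0:
        k = min(remaining, 4 + 4 * ring)
        radius = ring / np.ceil((n_channels - 1) / 12 + 1)
        radius = min(radius, 1.0)
        angles = 2 * np.pi * np.arange(k) / k + 0.1 * ring
        pos.extend((radius * np.cos(a), radius * np.sin(a)) for a in angles)
        remaining -= k
        ring += 1
    pos = np.array(pos[:n_channels])
    if pos[1:].size:  # rescale so the outermost ring sits on the unit circle
        pos /= np.linalg.norm(pos, axis=1).max()
    labels = tuple(f"{label_prefix}{i:02d}" for i in range(n_channels))
    return Montage(labels, pos)
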