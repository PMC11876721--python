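"""Plain-text persistence for datasets, ERP stacks and analysis results.

Everything is stored as delimited text plus JSON sidecars so datasets can
be inspected, versioned and regenerated byte-identically from a seed:

dataset directory
    sub-<id>_epochs.csv   long format, one row per (trial, time) with one
                          column per channel, in uV
    sub-<id>_trials.csv   the trial table
    sub-<id>_meta.json    channel labels/positions, rate, window, units
erp directory
    sub-<id>_erp.csv      one row per (cell, time), one column per channel
results directory
    tanova_<effect>.csv, windows.csv, effect_sizes.csv, report.json
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import read_trial_table, write_trial_table
from .gds import GdsResult
from .montage import Montage
from .simulate import EpochedData
from .stats import EffectSizeReport, ErpStack, TanovaResult

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_dataset",
    "load_dataset",
    "save_erp_stack",
    "load_erp_stack",
    "save_analysis_results",
]


def _montage_to_dict(m: Montage) -> dict:
    return {"channel_labels": list(m.channel_labels),
            "positions": np.asarray(m.positions).tolist()}


def _montage_from_dict(d: dict) -> Montage:
    return Montage(tuple(d["channel_labels"]), np.asarray(d["positions"]))


def save_epochs(epochs: EpochedData, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = epochs.subject_id
    n_trials, n_ch, n_t = epochs.data.shape
    frame = pd.DataFrame(
        epochs.data.transpose(0, 2, 1).reshape(n_trials * n_t, n_ch),
        columns=list(epochs.montage.channel_labels),
    )
    frame.insert(0, "trial", np.repeat(np.arange(n_trials), n_t))
    frame.insert(1, "time_ms", np.tile(epochs.times_ms, n_trials))
    frame.to_csv(directory / f"sub-{sid}_epochs.csv", index=False, float_format="%.6g")
    write_trial_table(epochs.trial_table, directory / f"sub-{sid}_trials.csv")
    meta = {
        "subject_id": sid,
        "sampling_rate_hz": epochs.sampling_rate,
        "epoch_window_ms": list(epochs.epoch_window_ms),
        "units": "uV",
        "montage": _montage_to_dict(epochs.montage),
    }
    (directory / f"sub-{sid}_meta.json").write_text(json.dumps(meta, indent=1))


def load_epochs(directory, subject_id: str) -> EpochedData:
    directory = Path(directory)
    meta = json.loads((directory / f"sub-{subject_id}_meta.json").read_text())
    montage = _montage_from_dict(meta["montage"])
    table = read_trial_table(directory / f"sub-{subject_id}_trials.csv")
    frame = pd.read_csv(directory / f"sub-{subject_id}_epochs.csv")
    times = np.unique(frame["time_ms"].to_numpy())
    n_trials = int(frame["trial"].max()) + 1
    data = (
        frame[list(montage.channel_labels)]
        .to_numpy()
        .reshape(n_trials, len(times), montage.n_channels)
        .transpose(0, 2, 1)
    )
    return EpochedData(data, times, meta["sampling_rate_hz"], table, montage,
                       subject_id=subject_id)


def save_dataset(datasets: list[EpochedData], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for epochs in datasets:
        save_epochs(epochs, directory)
    manifest = {"subjects": [e.subject_id for e in datasets]}
    (directory / "dataset.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(directory) -> list[EpochedData]:
    directory = Path(directory)
    manifest = json.loads((directory / "dataset.json").read_text())
    return [load_epochs(directory, sid) for sid in manifest["subjects"]]


def save_erp_stack(stack: ErpStack, directory) -> None:
    """Persist subject x condition ERP maps, one CSV per subject."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = list(stack.channel_labels or
                    [f"ch{i:02d}" for i in range(stack.data.shape[2])])
    for s, sid in enumerate(stack.subjects):
        n_cells, n_ch, n_t = stack.data.shape[1:]
        frame = pd.DataFrame(
            stack.data[s].transpose(0, 2, 1).reshape(n_cells * n_t, n_ch),
            columns=channels,
        )
        frame.insert(0, "cell", np.repeat(list(stack.cells), n_t))
        frame.insert(1, "time_ms", np.tile(stack.times_ms, n_cells))
        frame.to_csv(directory / f"sub-{sid}_erp.csv", index=False,
                     float_format="%.8g")
    meta = {
        "subjects": list(stack.subjects),
        "cells": list(stack.cells),
        "times_ms": np.asarray(stack.times_ms).tolist(),
        "channel_labels": channels,
        "units": "uV",
    }
    (directory / "erp_meta.json").write_text(json.dumps(meta, indent=1))


def load_erp_stack(directory) -> ErpStack:
    """Load pre-averaged ERPs (the entry point for non-simulated data)."""
    directory = Path(directory)
    meta = json.loads((directory / "erp_meta.json").read_text())
    times = np.asarray(meta["times_ms"], float)
    channels = meta["channel_labels"]
    rows = []
    for sid in meta["subjects"]:
        frame = pd.read_csv(directory / f"sub-{sid}_erp.csv")
        maps = []
        for cell in meta["cells"]:
            block = frame[frame["cell"] == cell]
            maps.append(block[channels].to_numpy().T)  # (ch, time)
        rows.append(np.stack(maps))
    return ErpStack(np.stack(rows), tuple(meta["subjects"]), tuple(meta["cells"]),
                    times, tuple(channels))


def _tanova_frame(res: TanovaResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_ms": res.times_ms, "gdi_uv": res.observed_stat, "p": res.p_values}
    )


def save_analysis_results(
    directory,
    tanovas: dict[str, TanovaResult],
    gds_results: dict[str, GdsResult],
    effect_sizes: list[EffectSizeReport],
    extra: dict | None = None,
) -> None:
    """Write the standard result files for one analysis."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    windows_rows = []
    for name, res in tanovas.items():
        _tanova_frame(res).to_csv(directory / f"tanova_{name}.csv", index=False,
                                  float_format="%.8g")
        g = gds_results.get(name)
        if g is None:
            continue
        for r in g.observed_runs:
            windows_rows.append(
                {
                    "effect": name,
                    "onset_ms": r.onset_ms,
                    "offset_ms": r.offset_ms,
                    "duration_ms": r.duration_ms,
                    "duration_samples": r.duration_samples,
                    "threshold_samples": g.duration_threshold_samples,
                    "surviving": r.surviving,
                }
            )
    pd.DataFrame(
        windows_rows,
        columns=["effect", "onset_ms", "offset_ms", "duration_ms",
                 "duration_samples", "threshold_samples", "surviving"],
    ).to_csv(directory / "windows.csv", index=False)
    pd.DataFrame(
        [
            {
                "effect": e.effect,
                "onset_ms": e.window_ms[0],
                "offset_ms": e.window_ms[1],
                "partial_eta2": round(e.partial_eta2, 4),
                "cohen_d": round(e.cohen_d, 2),
                "z_score": round(e.z_score, 3),
                "cohen_d_permutation": round(e.cohen_d_permutation, 2),
                "n_subjects": e.n_subjects,
            }
            for e in effect_sizes
        ],
        columns=["effect", "onset_ms", "offset_ms", "partial_eta2", "cohen_d",
                 "z_score", "cohen_d_permutation", "n_subjects"],
    ).to_csv(directory / "effect_sizes.csv", index=False)

    report = {
        "effects": {
            name: {
                "n_perm": res.n_perm,
                "seed": res.seed,
                "alpha": res.alpha,
                "normalized": res.normalized,
                "surviving_windows": [
                    [r.onset_ms, r.offset_ms]
                    for r in gds_results[name].surviving_runs
                ]
                if name in gds_results
                else [],
            }
            for name, res in tanovas.items()
        },
    }
    if extra:
        report.update(extra)
    (directory / "report.json").write_text(json.dumps(report, indent=1))
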