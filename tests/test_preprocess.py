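"""Preprocessing chain: filtering, referencing, baseline, rejection, averaging."""

import numpy as np
import pandas as pd
import pytest

import topoperm as tp
from topoperm.simulate import epoch_times


def sine_epochs(montage, freq_hz, fs=250.0, duration_s=8.0, amp=1.0):
    """One long 'epoch' holding a pure sinusoid on every channel."""
    t = np.arange(int(duration_s * fs)) / fs
    data = amp * np.sin(2 * np.pi * freq_hz * t)[None, None, :].repeat(
        montage.n_channels, axis=1
    )
    table = pd.DataFrame(
        {
            "trial_index": [0], "block": [0], "category": ["words"],
            "cue_level": ["high_rep"], "cue_label": ["animate"],
            "s1_id": ["a"], "s2_id": ["a"], "is_repetition": [True],
            "is_expected": [True], "is_target": [False], "size_reduced": ["s1"],
        }
    )
    return tp.EpochedData(data, t * 1000.0, fs, table, montage)


def random_epochs(montage, seed=0, n_trials=12, fs=250.0, target_every=4):
    rng = np.random.default_rng(seed)
    times = epoch_times((-150, 850), fs)
    data = rng.normal(0, 5, size=(n_trials, montage.n_channels, times.size))
    cues = rng.choice(["high_rep", "low_rep"], n_trials)
    reps = rng.random(n_trials) < 0.5
    table = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "block": 0,
            "category": "words",
            "cue_level": cues,
            "cue_label": np.where(cues == "high_rep", "animate", "inanimate"),
            "s1_id": "a",
            "s2_id": np.where(reps, "a", "b"),
            "is_repetition": reps,
            "is_expected": (cues == "high_rep") == reps,
            "is_target": np.arange(n_trials) % target_every == 0,
            "size_reduced": "s1",
        }
    )
    # guarantee every cell is populated
    forced = [("high_rep", True), ("high_rep", False), ("low_rep", True),
              ("low_rep", False)]
    for i, (cue, rep) in enumerate(forced[: min(4, n_trials)]):
        table.loc[i, ["cue_level", "is_repetition"]] = cue, rep
        table.loc[i, "cue_label"] = "animate" if cue == "high_rep" else "inanimate"
        table.loc[i, "is_expected"] = (cue == "high_rep") == rep
        table.loc[i, "is_target"] = False
    return tp.EpochedData(data, times, fs, table, montage)


class TestBandpassFilter:
    def test_in_band_sinusoid_passes(self, two_channel):
        # long signal so the 0.3 Hz high-pass transient dies out before the
        # measured centre section
        epochs = sine_epochs(two_channel, 10.0, duration_s=30.0)
        out = tp.bandpass_filter(epochs)
        centre = out.data[0, 0, 2500:-2500]
        assert np.abs(centre).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self, two_channel):
        epochs = sine_epochs(two_channel, 10.0, amp=0.0)
        epochs.data[:] = 5.0
        out = tp.bandpass_filter(epochs)
        assert np.abs(out.data[0, 0, 500:-500]).max() < 0.05

    def test_stopband_attenuation_matches_butterworth_response(self, two_channel):
        """50 Hz attenuation equals the squared (forward-backward) 4th-order
        Butterworth low-pass magnitude at 50 Hz, computed in closed form
        (bilinear-transform design, so frequencies are prewarped)."""
        epochs = sine_epochs(two_channel, 50.0, duration_s=30.0)
        out = tp.bandpass_filter(epochs)
        measured = np.abs(out.data[0, 0, 2500:-2500]).max()
        fs = 250.0
        warp = lambda f: np.tan(np.pi * f / fs)
        expected = 1.0 / (1.0 + (warp(50.0) / warp(30.0)) ** (2 * 4))
        assert measured == pytest.approx(expected, rel=0.10)

    def test_invalid_band_raises(self, two_channel):
        epochs = sine_epochs(two_channel, 10.0)
        with pytest.raises(ValueError, match="band"):
            tp.bandpass_filter(epochs, low_hz=30.0, high_hz=0.3)


class TestAverageReference:
    def test_two_channel_arithmetic(self, two_channel):
        epochs = sine_epochs(two_channel, 10.0, amp=0.0)
        epochs.data[0, :, 0] = [3.0, 1.0]
        out = tp.average_reference(epochs)
        np.testing.assert_allclose(out.data[0, :, 0], [1.0, -1.0])

    def test_idempotent(self, ring32):
        epochs = random_epochs(ring32, seed=1)
        once = tp.average_reference(epochs)
        twice = tp.average_reference(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_gfp_invariant_under_rereferencing(self, ring32):
        epochs = random_epochs(ring32, seed=2)
        referenced = tp.average_reference(epochs)
        np.testing.assert_allclose(
            tp.gfp(epochs.data), tp.gfp(referenced.data), atol=1e-12
        )


class TestBaselineCorrect:
    def test_constant_trial_becomes_zero(self, two_channel):
        epochs = random_epochs(two_channel, seed=3)
        epochs.data[:] = 5.0
        out = tp.baseline_correct(epochs)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_idempotent_and_baseline_zeroed(self, ring32):
        epochs = random_epochs(ring32, seed=4)
        once = tp.baseline_correct(epochs)
        mask = (once.times_ms >= -150) & (once.times_ms <= 0)
        assert np.abs(once.data[:, :, mask].mean(axis=-1)).max() < 1e-12
        twice = tp.baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_empty_window_raises(self, ring32):
        epochs = random_epochs(ring32, seed=5)
        with pytest.raises(ValueError, match="baseline"):
            tp.baseline_correct(epochs, window_ms=(-500.0, -400.0))


class TestRejectArtifacts:
    def test_threshold_is_strict(self, two_channel):
        epochs = random_epochs(two_channel, seed=6, n_trials=3)
        epochs.data[:] = 0.0
        epochs.data[0, 0, 10] = 81.0   # rejected
        epochs.data[1, 1, 20] = 80.0   # kept: exactly at the boundary
        epochs.data[2, 0, 30] = -80.5  # rejected (negative excursion)
        out, log = tp.reject_artifacts(epochs)
        assert list(log.rejected) == [True, False, True]
        assert out.data.shape[0] == 1

    def test_surviving_count_matches_brute_force(self, ring32):
        epochs = random_epochs(ring32, seed=7, n_trials=10)
        rng = np.random.default_rng(8)
        peaks = rng.uniform(50, 110, size=10)
        for i, p in enumerate(peaks):
            epochs.data[i] *= 0.01
            epochs.data[i, rng.integers(32), rng.integers(epochs.data.shape[2])] = p
        out, log = tp.reject_artifacts(epochs, threshold_uv=80.0)
        expected_kept = [np.abs(epochs.data[i]).max() <= 80.0 for i in range(10)]
        assert out.data.shape[0] == sum(expected_kept)
        assert list(~log.rejected) == expected_kept


class TestAverageConditions:
    def test_cell_means_match_brute_force(self, ring32):
        epochs = random_epochs(ring32, seed=9, n_trials=16)
        erps = tp.average_conditions(epochs, nontarget_only=True)
        table = epochs.trial_table
        for erp in erps:
            cells = table.apply(tp.condition_of, axis=1)
            mask = (cells == erp.cell) & ~table.is_target
            brute = epochs.data[mask.to_numpy()].mean(axis=0)
            np.testing.assert_allclose(erp.map_series, brute, atol=1e-12)
            assert erp.n_trials_averaged == int(mask.sum())

    def test_target_trials_excluded(self, ring32):
        epochs = random_epochs(ring32, seed=10, n_trials=16)
        with_targets = tp.average_conditions(epochs, nontarget_only=False)
        without = tp.average_conditions(epochs, nontarget_only=True)
        totals_with = sum(e.n_trials_averaged for e in with_targets)
        totals_without = sum(e.n_trials_averaged for e in without)
        assert totals_with == 16
        assert totals_without == 16 - int(epochs.trial_table.is_target.sum())

    def test_empty_cell_raises_with_name(self, ring32):
        epochs = random_epochs(ring32, seed=11, n_trials=8)
        drop = epochs.trial_table.apply(tp.condition_of, axis=1) != "Unexp_Rep"
        trimmed = tp.EpochedData(
            epochs.data[drop.to_numpy()], epochs.times_ms, epochs.sampling_rate,
            epochs.trial_table[drop].reset_index(drop=True), epochs.montage,
        )
        with pytest.raises(ValueError, match="Unexp_Rep"):
            tp.average_conditions(trimmed)

    def test_reference_commutes_with_averaging(self, ring32):
        """Average reference and condition averaging are both linear, so
        their order must not matter."""
        epochs = random_epochs(ring32, seed=12, n_trials=16)
        ref_first = tp.average_conditions(tp.average_reference(epochs))
        avg_first = tp.average_conditions(epochs)
        for a, b in zip(ref_first, avg_first):
            np.testing.assert_allclose(
                a.map_series, b.map_series - b.map_series.mean(axis=0), atol=1e-10
            )


def test_full_chain_is_deterministic(ring32):
    epochs = random_epochs(ring32, seed=13, n_trials=16)
    erps_a, log_a = tp.preprocess(epochs)
    erps_b, log_b = tp.preprocess(epochs)
    for a, b in zip(erps_a, erps_b):
        np.testing.assert_array_equal(a.map_series, b.map_series)
    pd.testing.assert_frame_equal(log_a, log_b)
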