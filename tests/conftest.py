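import numpy as np
import pytest

import topoperm as tp


@pytest.fixture(scope="session")
def ring32() -> tp.Montage:
    return tp.ring_montage(32)


@pytest.fixture(scope="session")
def two_channel() -> tp.Montage:
    return tp.Montage(("left", "right"), np.array([[-0.5, 0.0], [0.5, 0.0]]))


@pytest.fixture(scope="session")
def standard64() -> tp.Montage:
    return tp.standard_64_montage()


def make_stack(
    montage: tp.Montage,
    n_subjects: int = 12,
    effects: tuple = (),
    noise_sd: float = 1.0,
    subject_sd: float = 0.3,
    seed: int = 0,
    sampling_rate: float = 250.0,
    epoch_window_ms: tuple = (-150.0, 846.0),
) -> tp.ErpStack:
    """Subject x cell ERP stack from the group-level generator."""
    noise = tp.NoiseSpec(trial_noise_sd=noise_sd, subject_amplitude_sd=subject_sd)
    data, times = tp.simulate_condition_erps(
        n_subjects, list(effects), noise, montage,
        sampling_rate=sampling_rate, epoch_window_ms=epoch_window_ms, seed=seed,
    )
    return tp.ErpStack(
        data,
        tuple(f"S{i:02d}" for i in range(n_subjects)),
        tp.CELL_LABELS,
        times,
        montage.channel_labels,
    )


@pytest.fixture()
def stack_factory():
    return make_stack
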