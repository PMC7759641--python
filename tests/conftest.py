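import numpy as np
import pytest

from btnd import (
    BTNDConfig,
    FusedLassoParams,
    SeizureRecording,
    generate_planted_dataset,
)


@pytest.fixture(scope="session")
def planted_small():
    """Small planted instance: 8 nodes (28 edges), K=2, two seizures."""
    X, truth = generate_planted_dataset(
        n_nodes=8, K=2, durations=[30, 40], edge_sparsity=0.2,
        noise_sigma=0.0, seed=7,
    )
    return X, truth


@pytest.fixture(scope="session")
def planted_benchmark():
    """The reference planted family: 20 nodes (190 edges), K=4, S=3."""
    X, truth = generate_planted_dataset(
        n_nodes=20, K=4, durations=[60, 80, 100], edge_sparsity=0.1,
        noise_sigma=0.05, seed=1,
    )
    return X, truth


@pytest.fixture()
def small_config():
    return BTNDConfig(
        K=2,
        lam=0.001,
        base_fused=FusedLassoParams(gamma=0.001, eta=0.2),
        n_restarts=3,
        seed=0,
    )


@pytest.fixture()
def sine_recording():
    """Two-channel recording: 32 Hz cosine and its quadrature at 256 Hz."""
    fs = 256.0
    t = np.arange(int(8 * fs)) / fs
    return SeizureRecording(
        samples=np.vstack([np.cos(2 * np.pi * 32 * t),
                           np.sin(2 * np.pi * 32 * t)]),
        sampling_rate_hz=fs,
        channel_labels=["A1", "A2"],
        seizure_id="sine",
    )
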