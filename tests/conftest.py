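import numpy as np
import pytest

from convsel.net import (
    ArchitectureSpec,
    InitConfig,
    LayerSpec,
    NetworkModel,
    build_network,
)
from convsel.stimuli import StimulusSpec, generate_stimulus_set


@pytest.fixture(scope="session")
def tiny_arch() -> ArchitectureSpec:
    """Two-conv stack on a 64 px canvas; fast enough for per-test builds."""
    return ArchitectureSpec(
        layers=(
            LayerSpec("conv", "conv1", kernel=7, stride=2, out_channels=8),
            LayerSpec("relu", "relu1"),
            LayerSpec("pool", "pool1", kernel=3, stride=2),
            LayerSpec("conv", "conv2", kernel=3, pad=1, out_channels=16),
            LayerSpec("relu", "relu2"),
        ),
        input_shape=(64, 64, 3),
    )


@pytest.fixture(scope="session")
def tiny_net(tiny_arch) -> NetworkModel:
    return build_network(tiny_arch, InitConfig(seed=7))


@pytest.fixture(scope="session")
def small_stim():
    """Six classes x 13 images at 64 px (10 selection / 2 train / 1 test)."""
    return generate_stimulus_set(StimulusSpec(n_per_class=13, image_size=64, seed=5))


def gaussian_template_net(size: int = 21, k: int = 15, sigma: float = 4.0):
    """Single-conv toy whose only filter is a known zero-mean Gaussian blob."""
    spec = ArchitectureSpec(
        layers=(
            LayerSpec("conv", "conv1", kernel=k, stride=1, out_channels=1),
            LayerSpec("relu", "relu1"),
        ),
        input_shape=(size, size, 1),
    )
    g = np.arange(k) - (k - 1) / 2
    t = np.exp(-0.5 * (g[:, None] ** 2 + g[None, :] ** 2) / sigma**2)
    t = (t - t.mean()).astype(np.float32)
    net = NetworkModel(
        spec=spec,
        init=InitConfig(seed=0),
        weights={"conv1": t[None, None]},
        biases={"conv1": np.zeros(1, dtype=np.float32)},
    )
    return net, t
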