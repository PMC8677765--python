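"""Untrained convolutional feature hierarchies.

The model is an AlexNet-style feature stack (five convolutions with ReLU,
interleaved max-pooling, optional local response normalization) whose weights
are never trained: they are drawn once from a zero-mean distribution whose
standard deviation is sqrt(1 / fan_in), the "efficient backprop" scaling that
balances signal strength across layers.  Unit responses are recorded
post-ReLU, pre-pool, so the default final layer (conv5) exposes the familiar
13 x 13 x 256 = 43,264 unit geometry.

The forward pass is pure numpy (im2col + BLAS matmul, float32); there is no
training code and no classification head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "InitConfig",
    "NetworkModel",
    "UnitIndex",
    "ResponseTable",
    "conv_output_size",
    "default_architecture",
    "desk_architecture",
    "build_network",
    "sample_weights",
    "extract_responses",
    "rescale_weights",
    "unit_responses",
]


class ConfigurationError(ValueError):
    """Raised when an architecture or init description is invalid."""


def conv_output_size(n: int, kernel: int, stride: int, pad: int) -> int:
    """Spatial output size of a convolution/pool: floor((n + 2p - k)/s) + 1."""
    out = (n + 2 * pad - kernel) // stride + 1
    if out <= 0:
        raise ConfigurationError(
            f"kernel {kernel} with stride {stride}, pad {pad} does not fit input size {n}"
        )
    return out


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor.

    kind is one of ``conv``, ``relu``, ``lrn`` (local response normalization)
    or ``pool`` (max-pooling).  kernel/stride/pad are in pixels;
    out_channels/groups apply to convolutions only.
    """

    kind: str
    name: str
    kernel: int = 0
    stride: int = 1
    pad: int = 0
    out_channels: int = 0
    groups: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "relu", "lrn", "pool"):
            raise ConfigurationError(f"layer {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "conv":
            if self.kernel < 1 or self.out_channels < 1 or self.stride < 1:
                raise ConfigurationError(f"layer {self.name!r}: invalid conv geometry")
            if self.out_channels % self.groups:
                raise ConfigurationError(
                    f"layer {self.name!r}: out_channels not divisible by groups"
                )
        if self.kind == "pool" and (self.kernel < 1 or self.stride < 1):
            raise ConfigurationError(f"layer {self.name!r}: invalid pool geometry")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer stack plus the input geometry (height, width, channels)."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (227, 227, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate layer names")

    def conv_layers(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.kind == "conv"]

    def shapes(self) -> dict[str, tuple[int, int, int]]:
        """Output shape (channels, height, width) after every layer."""
        h, w, c = self.input_shape
        out: dict[str, tuple[int, int, int]] = {}
        for layer in self.layers:
            if layer.kind == "conv":
                if c % layer.groups:
                    raise ConfigurationError(
                        f"layer {layer.name!r}: input channels {c} not divisible by "
                        f"groups {layer.groups}"
                    )
                h = conv_output_size(h, layer.kernel, layer.stride, layer.pad)
                w = conv_output_size(w, layer.kernel, layer.stride, layer.pad)
                c = layer.out_channels
            elif layer.kind == "pool":
                h = conv_output_size(h, layer.kernel, layer.stride, layer.pad)
                w = conv_output_size(w, layer.kernel, layer.stride, layer.pad)
            out[layer.name] = (c, h, w)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"input_shape": list(self.input_shape), "layers": [asdict(l) for l in self.layers]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        return cls(
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
            input_shape=tuple(d["input_shape"]),
        )


def default_architecture(
    lrn: bool = False, input_size: int = 227, channel_scale: float = 1.0
) -> ArchitectureSpec:
    """The AlexNet feature stack.

    conv1 96x11x11 s4; conv2 256x5x5 p2 g2; conv3 384x3x3 p1;
    conv4 384x3x3 p1 g2; conv5 256x3x3 p1 g2; ReLU after every conv;
    3x3 stride-2 max-pool after conv1, conv2 and conv5.  ``lrn`` inserts the
    original local response normalization after conv1/conv2 (off by default).
    ``channel_scale`` shrinks every channel count (desk-scale presets).
    """

    def ch(n: int) -> int:
        # keep divisibility by 2 for the grouped convolutions
        return max(2, 2 * round(n * channel_scale / 2))

    layers: list[LayerSpec] = [
        LayerSpec("conv", "conv1", kernel=11, stride=4, out_channels=ch(96)),
        LayerSpec("relu", "relu1"),
    ]
    if lrn:
        layers.append(LayerSpec("lrn", "norm1"))
    layers += [
        LayerSpec("pool", "pool1", kernel=3, stride=2),
        LayerSpec("conv", "conv2", kernel=5, pad=2, out_channels=ch(256), groups=2),
        LayerSpec("relu", "relu2"),
    ]
    if lrn:
        layers.append(LayerSpec("lrn", "norm2"))
    layers += [
        LayerSpec("pool", "pool2", kernel=3, stride=2),
        LayerSpec("conv", "conv3", kernel=3, pad=1, out_channels=ch(384)),
        LayerSpec("relu", "relu3"),
        LayerSpec("conv", "conv4", kernel=3, pad=1, out_channels=ch(384), groups=2),
        LayerSpec("relu", "relu4"),
        LayerSpec("conv", "conv5", kernel=3, pad=1, out_channels=ch(256), groups=2),
        LayerSpec("relu", "relu5"),
        LayerSpec("pool", "pool5", kernel=3, stride=2),
    ]
    return ArchitectureSpec(layers=tuple(layers), input_shape=(input_size, input_size, 3))


def desk_architecture(input_size: int = 127) -> ArchitectureSpec:
    """Quarter-width AlexNet on a smaller canvas, for one-CPU experiments."""
    return default_architecture(input_size=input_size, channel_scale=0.25)


@dataclass(frozen=True)
class InitConfig:
    """Random-initialization recipe.

    Per conv layer the base std is sqrt(1 / fan_in) with
    fan_in = k*k*(in_channels / groups); the effective std is
    base * scale_percent / 100.  The uniform variant uses half-width
    sqrt(3) * std so its variance matches the Gaussian one.
    """

    distribution: str = "gaussian"
    scale_percent: float = 100.0
    seed: int = 0
    zero_bias: bool = False

    def __post_init__(self) -> None:
        if self.distribution not in ("gaussian", "uniform"):
            raise ConfigurationError(f"unknown distribution {self.distribution!r}")
        if not self.scale_percent > 0:
            raise ConfigurationError("scale_percent must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "InitConfig":
        return cls(**json.loads(text))


def sample_weights(
    shape: Sequence[int],
    init: InitConfig,
    fan_in: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a weight tensor with std sqrt(1/fan_in) * scale_percent/100."""
    if fan_in < 1:
        raise ValueError(f"fan_in must be >= 1, got {fan_in}")
    if rng is None:
        rng = np.random.default_rng(init.seed)
    std = np.sqrt(1.0 / fan_in) * init.scale_percent / 100.0
    if init.distribution == "gaussian":
        w = rng.normal(0.0, std, size=tuple(shape))
    else:
        half = np.sqrt(3.0) * std
        w = rng.uniform(-half, half, size=tuple(shape))
    return w.astype(np.float32)


@dataclass
class NetworkModel:
    """An untrained network: architecture + per-conv-layer weights and biases."""

    spec: ArchitectureSpec
    init: InitConfig
    weights: dict[str, np.ndarray]
    biases: dict[str, np.ndarray]

    @property
    def conv_layer_names(self) -> list[str]:
        return [l.name for l in self.spec.conv_layers()]


def build_network(spec: ArchitectureSpec, init: InitConfig) -> NetworkModel:
    """Draw all conv weights/biases per ``init``; bit-deterministic per seed."""
    spec.shapes()  # validates geometry, raises naming the offending layer
    rng = np.random.default_rng(init.seed)
    weights: dict[str, np.ndarray] = {}
    biases: dict[str, np.ndarray] = {}
    c_in = spec.input_shape[2]
    for layer in spec.layers:
        if layer.kind != "conv":
            continue
        cpg = c_in // layer.groups
        fan_in = layer.kernel * layer.kernel * cpg
        weights[layer.name] = sample_weights(
            (layer.out_channels, cpg, layer.kernel, layer.kernel), init, fan_in, rng
        )
        if init.zero_bias:
            biases[layer.name] = np.zeros(layer.out_channels, dtype=np.float32)
        else:
            biases[layer.name] = sample_weights((layer.out_channels,), init, fan_in, rng)
        c_in = layer.out_channels
    return NetworkModel(spec=spec, init=init, weights=weights, biases=biases)


def rescale_weights(net: NetworkModel, factor: float) -> NetworkModel:
    """Multiply every conv weight tensor by ``factor`` (> 0); biases untouched.

    With zero biases the post-ReLU response of the L-th conv layer scales by
    factor**L (positive homogeneity of conv + ReLU + max-pool).
    """
    if not factor > 0:
        raise ValueError("factor must be positive")
    return NetworkModel(
        spec=net.spec,
        init=net.init,
        weights={k: (v * np.float32(factor)) for k, v in net.weights.items()},
        biases={k: v.copy() for k, v in net.biases.items()},
    )


# ---------------------------------------------------------------------------
# forward pass


def _conv2d(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int, groups: int
) -> np.ndarray:
    """Grouped 2D convolution via im2col. x: (N,C,H,W); w: (O,C/g,k,k)."""
    out_c, cpg, k, _ = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, _, oh, ow = win.shape[:4]
    opg = out_c // groups
    out = np.empty((n, oh, ow, out_c), dtype=np.float32)
    for g in range(groups):
        cols = (
            win[:, g * cpg : (g + 1) * cpg]
            .transpose(0, 2, 3, 1, 4, 5)
            .reshape(n * oh * ow, cpg * k * k)
        )
        wg = w[g * opg : (g + 1) * opg].reshape(opg, cpg * k * k)
        out[..., g * opg : (g + 1) * opg] = (cols @ wg.T).reshape(n, oh, ow, opg)
    out += b.astype(np.float32)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def _maxpool2d(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride].max(axis=(4, 5))


def _lrn(x: np.ndarray, n: int = 5, k: float = 2.0, alpha: float = 1e-4, beta: float = 0.75) -> np.ndarray:
    """Across-channel local response normalization (original AlexNet constants)."""
    sq = x * x
    c = x.shape[1]
    acc = np.empty_like(x)
    half = n // 2
    csum = np.concatenate(
        [np.zeros_like(sq[:, :1]), np.cumsum(sq, axis=1)], axis=1
    )
    for i in range(c):
        lo, hi = max(0, i - half), min(c, i + half + 1)
        acc[:, i] = csum[:, hi] - csum[:, lo]
    return x / (k + (alpha / n) * acc) ** beta


def _prepare_images(images: np.ndarray, spec: ArchitectureSpec) -> np.ndarray:
    """Accept (N,H,W) grayscale or (N,H,W,C); return float32 (N,C,H,W)."""
    arr = np.asarray(images, dtype=np.float32)
    h, w, c = spec.input_shape
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = np.repeat(arr[:, None], c, axis=1)
    elif arr.ndim == 4:
        arr = arr.transpose(0, 3, 1, 2)
    else:
        raise ValueError("images must be (N,H,W) or (N,H,W,C)")
    if arr.shape[2] != h or arr.shape[3] != w:
        raise ValueError(
            f"image size mismatch: expected {h}x{w}, got {arr.shape[2]}x{arr.shape[3]}"
        )
    return arr


def _forward_batch(
    net: NetworkModel, x: np.ndarray, capture: set[str], stop_after: str | None = None
) -> dict[str, np.ndarray]:
    """Run one batch; capture post-ReLU maps of the named conv layers."""
    captured: dict[str, np.ndarray] = {}
    last_conv: str | None = None
    for layer in net.spec.layers:
        if layer.kind == "conv":
            x = _conv2d(
                x, net.weights[layer.name], net.biases[layer.name],
                layer.stride, layer.pad, layer.groups,
            )
            last_conv = layer.name
        elif layer.kind == "relu":
            x = np.maximum(x, 0.0)
            if last_conv in capture:
                captured[last_conv] = x
                if stop_after is not None and last_conv == stop_after:
                    return captured
        elif layer.kind == "pool":
            x = _maxpool2d(x, layer.kernel, layer.stride)
        elif layer.kind == "lrn":
            x = _lrn(x)
    return captured


@dataclass(frozen=True)
class UnitIndex:
    """A single unit: one spatial position of one channel of one layer (0-based)."""

    layer: str
    channel: int
    row: int
    col: int


@dataclass
class ResponseTable:
    """Post-ReLU activations of one layer, flattened to stimuli x units.

    ``unit_order`` is an (n_units, 3) integer array of (channel, row, col) in
    C order, so column j of ``values`` is the unit
    UnitIndex(layer, *unit_order[j]).
    """

    layer: str
    values: np.ndarray
    unit_order: np.ndarray
    stimulus_ids: list[str]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def unit_index(self, j: int) -> UnitIndex:
        c, r, k = (int(v) for v in self.unit_order[j])
        return UnitIndex(self.layer, c, r, k)

    def flat_index(self, unit: UnitIndex) -> int:
        if unit.layer != self.layer:
            raise ValueError(f"unit is in layer {unit.layer!r}, table holds {self.layer!r}")
        hits = np.flatnonzero(
            (self.unit_order[:, 0] == unit.channel)
            & (self.unit_order[:, 1] == unit.row)
            & (self.unit_order[:, 2] == unit.col)
        )
        if hits.size != 1:
            raise KeyError(f"unit {unit} not in table")
        return int(hits[0])

    def to_hdf5(self, path, mode: str = "w") -> None:
        import h5py

        with h5py.File(path, mode) as f:
            g = f.create_group(self.layer) if self.layer not in f else f[self.layer]
            g.create_dataset("values", data=self.values, compression="gzip")
            g.create_dataset("unit_order", data=self.unit_order)
            ids = np.asarray(self.stimulus_ids, dtype="S")
            g.create_dataset("stimulus_ids", data=ids)

    @classmethod
    def from_hdf5(cls, path, layer: str) -> "ResponseTable":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[layer]
            return cls(
                layer=layer,
                values=g["values"][...],
                unit_order=g["unit_order"][...],
                stimulus_ids=[s.decode() for s in g["stimulus_ids"][...]],
            )


def _unit_order_for(shape: tuple[int, int, int]) -> np.ndarray:
    c, h, w = shape
    ch, rr, cc = np.meshgrid(np.arange(c), np.arange(h), np.arange(w), indexing="ij")
    return np.stack([ch.ravel(), rr.ravel(), cc.ravel()], axis=1).astype(np.int32)


def extract_responses(
    net: NetworkModel,
    images,
    layers: Iterable[str] | None = None,
    stimulus_ids: Sequence[str] | None = None,
    batch_size: int = 32,
) -> list[ResponseTable]:
    """Post-ReLU, pre-pool responses of the requested conv layers.

    ``images`` may be an array (N,H,W) in [0,1] or a stimuli.StimulusSet.
    Grayscale inputs are replicated across the network's input channels.
    Batching never changes the result (pure feedforward).
    """
    if hasattr(images, "images"):  # StimulusSet duck-type
        if stimulus_ids is None:
            stimulus_ids = list(images.stimulus_ids)
        images = images.images
    conv_names = net.conv_layer_names
    if layers is None:
        layers = [conv_names[-1]]
    layers = list(layers)
    unknown = set(layers) - set(conv_names)
    if unknown:
        raise ValueError(f"unknown conv layers: {sorted(unknown)}")
    arr = _prepare_images(images, net.spec)
    n = arr.shape[0]
    if stimulus_ids is None:
        stimulus_ids = [f"s{i}" for i in range(n)]
    shapes = net.spec.shapes()
    # stop the forward pass at the deepest requested layer
    deepest = max(layers, key=conv_names.index)
    chunks: dict[str, list[np.ndarray]] = {l: [] for l in layers}
    for start in range(0, n, batch_size):
        got = _forward_batch(net, arr[start : start + batch_size], set(layers), stop_after=deepest)
        for l in layers:
            chunks[l].append(got[l].reshape(got[l].shape[0], -1))
    tables = []
    for l in layers:
        vals = np.concatenate(chunks[l], axis=0)
        tables.append(
            ResponseTable(
                layer=l,
                values=vals,
                unit_order=_unit_order_for(shapes[l]),
                stimulus_ids=list(stimulus_ids),
            )
        )
    return tables


def unit_responses(net: NetworkModel, images, unit: UnitIndex, batch_size: int = 64) -> np.ndarray:
    """Responses of a single unit to a batch of images (post-ReLU)."""
    arr = _prepare_images(np.asarray(images), net.spec)
    out = []
    for start in range(0, arr.shape[0], batch_size):
        got = _forward_batch(net, arr[start : start + batch_size], {unit.layer}, stop_after=unit.layer)
        out.append(got[unit.layer][:, unit.channel, unit.row, unit.col])
    return np.concatenate(out)
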