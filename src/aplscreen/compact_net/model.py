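"""The compact channel-attention leukocyte classifier.

Architecture: a short stack of convolution blocks, each
``maxpool(relu(batchnorm(conv3x3(.))))``, followed by a single
squeeze-and-excitation channel-attention module on the final feature map,
a flatten, and two fully-connected layers (hidden width 512, then one
logit per leukocyte class) with dropout after each. The canonical
configuration uses four blocks with 64/128/256/256 channels and conv
strides 1/1/2/1 on a 224x224x3 input, giving feature maps
112x112x64 -> 56x56x128 -> 14x14x256 -> 7x7x256 and 7.4 M parameters —
small enough to train from scratch on modest single-cell datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .layers import (
    F32,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Flatten,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    SEModule,
    _softmax,
    conv_out_size,
)

CLASS_NAMES = ("basophil", "eosinophil", "lymphocyte", "monocyte",
               "promyelocyte", "neutrophil")


@dataclass(frozen=True)
class CompactNetConfig:
    """Complete architecture description; every variant is a field change."""

    block_channels: tuple[int, ...] = (64, 128, 256, 256)
    block_strides: tuple[int, ...] = (1, 1, 2, 1)
    use_se: bool = True
    se_ratio: int = 16
    #: channel-gate nonlinearity; "sigmoid" is the standard independent
    #: per-channel excitation, "softmax" normalizes the weights across
    #: channels (attenuating the feature map by ~1/C on average, which in
    #: practice slows from-scratch convergence dramatically)
    se_gate: str = "sigmoid"
    use_dropout: bool = True
    dropout_rate: float = 0.5
    fc_hidden: int = 512
    n_classes: int = 6
    input_size: int = 224
    in_channels: int = 3

    def __post_init__(self):
        if len(self.block_channels) != len(self.block_strides):
            raise ValueError("block_channels and block_strides must have equal length")
        if self.use_se and self.block_channels[-1] % self.se_ratio != 0:
            raise ValueError(
                f"SE ratio {self.se_ratio} does not divide the final channel "
                f"count {self.block_channels[-1]}")

    def feature_geometry(self) -> list[tuple[int, int]]:
        """(spatial size, channels) after each block, conv then 3x3/2 pool."""
        size = self.input_size
        out = []
        for ch, stride in zip(self.block_channels, self.block_strides):
            size = conv_out_size(size, 3, stride, 1)
            size = conv_out_size(size, 3, 2, 1)
            out.append((size, ch))
        return out

    @property
    def flatten_width(self) -> int:
        size, ch = self.feature_geometry()[-1]
        return size * size * ch


CANONICAL_CONFIG = CompactNetConfig()

#: Ablation variants: drop the attention module, drop dropout, or keep
#: only the first two / three convolution blocks (the flatten width is
#: re-derived from the resulting feature-map geometry).
ABLATION_VARIANTS = {
    "canonical": CANONICAL_CONFIG,
    "no_se": replace(CANONICAL_CONFIG, use_se=False),
    "no_dropout": replace(CANONICAL_CONFIG, use_dropout=False),
    "2_block": replace(CANONICAL_CONFIG, block_channels=(64, 128), block_strides=(1, 1)),
    "3_block": replace(CANONICAL_CONFIG, block_channels=(64, 128, 256),
                       block_strides=(1, 1, 2)),
}


class CompactNet:
    """A built network: ordered layers plus input-normalization statistics."""

    def __init__(self, config: CompactNetConfig, layers: list[Layer],
                 input_mean: np.ndarray | None = None,
                 input_std: np.ndarray | None = None):
        self.config = config
        self.layers = layers
        self.input_mean = np.asarray(input_mean if input_mean is not None
                                     else [0.5, 0.5, 0.5], dtype=F32)
        self.input_std = np.asarray(input_std if input_std is not None
                                    else [0.25, 0.25, 0.25], dtype=F32)

    # -- core passes --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def release_buffers(self) -> None:
        """Drop per-layer scratch buffers and caches (reallocated lazily)."""
        for layer in self.layers:
            if hasattr(layer, "_buffers"):
                layer._buffers = {}
            if hasattr(layer, "_cache"):
                layer._cache = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- inference ----------------------------------------------------------
    def prepare_input(self, crops: np.ndarray) -> np.ndarray:
        """uint8 NHWC (or single HWC) crops -> normalized float32 NHWC."""
        arr = np.asarray(crops)
        if arr.ndim == 3:
            arr = arr[None]
        s = self.config.input_size
        if arr.shape[1:] != (s, s, 3):
            raise ValueError(f"expected Nx{s}x{s}x3 crops, got {arr.shape}")
        x = arr.astype(F32) / F32(255.0)
        x = (x - self.input_mean) / self.input_std
        return np.ascontiguousarray(x)

    def predict_proba(self, crops: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Softmax class probabilities for a batch of uint8 crops (eval mode)."""
        x = self.prepare_input(crops)
        probs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            probs.append(_softmax(logits.astype(np.float64), axis=1))
        return np.concatenate(probs, axis=0)

    def predict(self, crops: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(crops, batch_size=batch_size).argmax(axis=1)

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            state[f"{i:03d}:{p.name}"] = p.data
        for j, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"rm:{j}"] = layer.running_mean
                state[f"rv:{j}"] = layer.running_var
        state["input_mean"] = self.input_mean
        state["input_std"] = self.input_std
        return state

    def save(self, path: str | Path) -> None:
        path = Path(path)
        cfg = asdict(self.config)
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "CompactNet":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg_raw = json.loads(bytes(data["__config__"].tobytes()).decode())
            for key in ("block_channels", "block_strides"):
                cfg_raw[key] = tuple(cfg_raw[key])
            config = CompactNetConfig(**cfg_raw)
            model = build_model(config, rng=np.random.default_rng(0))
            for i, p in enumerate(model.params()):
                p.data[...] = data[f"{i:03d}:{p.name}"]
            for j, layer in enumerate(model.layers):
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = data[f"rm:{j}"]
                    layer.running_var[...] = data[f"rv:{j}"]
            model.input_mean = data["input_mean"].astype(F32)
            model.input_std = data["input_std"].astype(F32)
        return model


def build_model(config: CompactNetConfig = CANONICAL_CONFIG,
                rng: np.random.Generator | int | None = None) -> CompactNet:
    """Instantiate the network described by ``config`` with Kaiming init."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layers: list[Layer] = []
    cin = config.in_channels
    for b, (ch, stride) in enumerate(zip(config.block_channels, config.block_strides)):
        layers.append(Conv2d(cin, ch, kernel=3, stride=stride, padding=1,
                             rng=rng, name=f"block{b}.conv"))
        layers.append(BatchNorm2d(ch, name=f"block{b}.bn"))
        layers.append(ReLU())
        layers.append(MaxPool2d(kernel=3, stride=2, padding=1))
        cin = ch
    layers[0].needs_input_grad = False  # no trainable layer below the input conv
    if config.use_se:
        layers.append(SEModule(cin, ratio=config.se_ratio, gate=config.se_gate,
                               rng=rng, name="se"))
    layers.append(Flatten())
    layers.append(Linear(config.flatten_width, config.fc_hidden, rng=rng, name="fc0"))
    layers.append(ReLU())
    if config.use_dropout:
        layers.append(Dropout(config.dropout_rate, rng=rng))
    head = Linear(config.fc_hidden, config.n_classes, rng=rng, name="fc1")
    # small classifier-head init keeps the initial logits near zero (loss
    # starts at ln(n_classes)), which stabilizes the first SGD epochs.
    # dropout regularizes the hidden FC activations only: masking the
    # 6-way output logits would inject destructive label-independent noise
    head.weight.data *= F32(0.1)
    layers.append(head)
    return CompactNet(config, layers)
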