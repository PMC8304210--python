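"""Closed-form parameter and multiply-accumulate accounting.

Both counts are pure functions of the architecture configuration, with a
per-layer breakdown. Conventions:

* parameters: conv = k^2*Cin*Cout + Cout (bias) + 2*Cout (batch-norm
  scale/shift); SE = C*(C/r) + C/r + (C/r)*C + C; FC = in*out + out.
* MACs (one input image): conv = k^2*Cin*Cout*Hout*Wout at the conv's own
  output resolution; FC = in*out; SE = 2*C*(C/r).
* ``total_ops`` additionally counts elementwise work (batch-norm scale/
  shift, ReLU, max-pool comparisons, SE rescaling) once per activation,
  the looser convention some model-profiling tools fold into "FLOPs".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .layers import conv_out_size
from .model import CompactNetConfig, CANONICAL_CONFIG

__all__ = ["LayerAccount", "ModelAccount", "count_parameters", "count_macs", "account"]


@dataclass(frozen=True)
class LayerAccount:
    name: str
    n_parameters: int
    macs: int
    elementwise_ops: int = 0


@dataclass
class ModelAccount:
    per_layer: list[LayerAccount] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.per_layer)

    @property
    def mac_count(self) -> int:
        return sum(l.macs for l in self.per_layer)

    @property
    def total_ops(self) -> int:
        """MACs plus elementwise operations (BN/ReLU/pool/SE-rescale)."""
        return self.mac_count + sum(l.elementwise_ops for l in self.per_layer)

    @property
    def params_millions(self) -> float:
        return round(self.n_parameters / 1e6, 3)

    @property
    def macs_giga(self) -> float:
        return round(self.mac_count / 1e9, 3)

    def as_dict(self) -> dict:
        return {
            "n_parameters": self.n_parameters,
            "params_millions": self.params_millions,
            "mac_count": self.mac_count,
            "macs_giga": self.macs_giga,
            "total_ops": self.total_ops,
            "per_layer": [
                {"name": l.name, "params": l.n_parameters, "macs": l.macs,
                 "elementwise_ops": l.elementwise_ops}
                for l in self.per_layer
            ],
        }

    def table(self) -> str:
        lines = [f"{'layer':<14}{'params':>12}{'MACs':>16}"]
        for l in self.per_layer:
            lines.append(f"{l.name:<14}{l.n_parameters:>12,}{l.macs:>16,}")
        lines.append(f"{'total':<14}{self.n_parameters:>12,}{self.mac_count:>16,}")
        lines.append(f"params {self.params_millions} M;  MACs {self.macs_giga} G;  "
                     f"MACs+elementwise {round(self.total_ops / 1e9, 3)} G")
        return "\n".join(lines)


def account(config: CompactNetConfig = CANONICAL_CONFIG) -> ModelAccount:
    """Per-layer parameter and MAC breakdown for one input image."""
    acc = ModelAccount()
    size = config.input_size
    cin = config.in_channels
    for b, (ch, stride) in enumerate(zip(config.block_channels, config.block_strides)):
        conv_size = conv_out_size(size, 3, stride, 1)
        pool_size = conv_out_size(conv_size, 3, 2, 1)
        params = 9 * cin * ch + ch + 2 * ch
        macs = 9 * cin * ch * conv_size * conv_size
        conv_act = ch * conv_size * conv_size
        # BN scale+shift (2/act) + ReLU (1/act) + pool window comparisons
        elementwise = 3 * conv_act + 9 * ch * pool_size * pool_size
        acc.per_layer.append(LayerAccount(f"block{b}", params, macs, elementwise))
        size, cin = pool_size, ch
    if config.use_se:
        c, r = cin, config.se_ratio
        params = c * (c // r) + c // r + (c // r) * c + c
        macs = 2 * c * (c // r)
        elementwise = c * size * size + c * size * size  # squeeze sum + rescale
        acc.per_layer.append(LayerAccount("se", params, macs, elementwise))
    flat = size * size * cin
    acc.per_layer.append(LayerAccount(
        "fc0", flat * config.fc_hidden + config.fc_hidden,
        flat * config.fc_hidden, config.fc_hidden))
    acc.per_layer.append(LayerAccount(
        "fc1", config.fc_hidden * config.n_classes + config.n_classes,
        config.fc_hidden * config.n_classes, config.n_classes))
    return acc


def count_parameters(config: CompactNetConfig = CANONICAL_CONFIG) -> ModelAccount:
    return account(config)


def count_macs(config: CompactNetConfig = CANONICAL_CONFIG) -> ModelAccount:
    return account(config)
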