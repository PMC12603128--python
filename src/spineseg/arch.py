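"""Architecture of the Inception-enhanced dual-output U-Net.

The network is a U-Net whose first encoder block is an Inception module
(four parallel branches concatenated to 256 channels) and which carries an
auxiliary 1x1-conv + softmax head on the bottleneck ("dual output") in
addition to the usual full-resolution head.  This module provides

* declarative configuration (:class:`ModelConfig`, :class:`InceptionConfig`),
* :func:`build_model`, which realizes the configuration as a runnable
  :class:`LayerGraph` of numpy layers, and
* two independent parameter accountants — :func:`count_parameters_analytic`
  (closed-form arithmetic over the layer plan, never touching an array) and
  :func:`count_parameters_built` (read off a realized network).

Conventions pinned for exact parameter accounting: every convolution has a
bias; batch normalization follows every convolution, including all six
Inception-branch convolutions, but neither 1x1 output head; upsampling is a
2x2 transposed convolution (stride 2, bias, ReLU, no batch-norm); the last
decoder stage uses 64 filters and concatenates the first-block output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn


class ConfigurationError(ValueError):
    """Raised when a model configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    """One convolutional layer in the analytic layer plan."""

    kernel_size: int
    in_channels: int
    out_channels: int
    has_bias: bool = True
    has_batchnorm: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd and positive")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")

    @property
    def weight_params(self) -> int:
        n = self.kernel_size ** 2 * self.in_channels * self.out_channels
        return n + (self.out_channels if self.has_bias else 0)

    @property
    def bn_trainable(self) -> int:
        return 2 * self.out_channels if self.has_batchnorm else 0

    @property
    def bn_non_trainable(self) -> int:
        return 2 * self.out_channels if self.has_batchnorm else 0


@dataclass(frozen=True)
class InceptionConfig:
    """Filter plan of the four-branch Inception first block.

    Branch 1: 1x1 conv; branch 2: 1x1 reduce then 3x3; branch 3: 1x1 reduce
    then 5x5; branch 4: 3x3 max-pool (stride 1) then 1x1.  Defaults give a
    256-channel concatenated output.
    """

    branch1_filters: int = 64
    branch2_reduce: int = 96
    branch2_filters: int = 128
    branch3_reduce: int = 16
    branch3_filters: int = 32
    branch4_filters: int = 32

    @property
    def out_channels(self) -> int:
        return (self.branch1_filters + self.branch2_filters
                + self.branch3_filters + self.branch4_filters)

    def scaled(self, factor: float) -> "InceptionConfig":
        """Uniformly scaled variant for reduced-size models."""
        s = lambda v: max(1, int(round(v * factor)))
        return InceptionConfig(
            branch1_filters=s(self.branch1_filters),
            branch2_reduce=s(self.branch2_reduce),
            branch2_filters=s(self.branch2_filters),
            branch3_reduce=s(self.branch3_reduce),
            branch3_filters=s(self.branch3_filters),
            branch4_filters=s(self.branch4_filters),
        )


@dataclass(frozen=True)
class ModelConfig:
    """Full declarative description of the network and its ablations."""

    input_size: int = 128
    input_channels: int = 1
    n_classes: int = 2
    encoder_filters: tuple[int, ...] = (128, 256, 512)
    bottleneck_filters: int = 1024
    decoder_filters: tuple[int, ...] = (512, 256, 128, 64)
    upsampling: str = "transposed_conv_2x2"
    dropout_rate: float = 0.5
    use_inception: bool = True
    use_dual_output: bool = True
    inception: InceptionConfig = field(default_factory=InceptionConfig)
    # filters of the plain (non-Inception) first block used in ablations
    plain_first_filters: int = 64

    def __post_init__(self):
        object.__setattr__(self, "encoder_filters", tuple(self.encoder_filters))
        object.__setattr__(self, "decoder_filters", tuple(self.decoder_filters))
        self.validate()

    def validate(self) -> None:
        if self.input_size % 16 != 0:
            raise ConfigurationError(
                f"input_size={self.input_size} must be divisible by 16 "
                "(four 2x2 pooling stages)")
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes={self.n_classes} must be >= 2")
        if len(self.decoder_filters) != len(self.encoder_filters) + 1:
            raise ConfigurationError(
                "decoder_filters must have one more stage than encoder_filters")
        if self.upsampling != "transposed_conv_2x2":
            raise ConfigurationError(f"unknown upsampling {self.upsampling!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // 16

    @property
    def first_block_channels(self) -> int:
        return (self.inception.out_channels if self.use_inception
                else self.plain_first_filters)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_filters"] = list(self.encoder_filters)
        d["decoder_filters"] = list(self.decoder_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "inception" in d and isinstance(d["inception"], dict):
            d["inception"] = InceptionConfig(**d["inception"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls.from_dict(json.loads(s))

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


def reduced_config(**overrides) -> ModelConfig:
    """A small configuration (64x64 input) trainable on a CPU in minutes.

    Filters are a quarter of the full model's; the Inception block is scaled
    accordingly so its 64-channel output keeps the 2:1 ratio to the next
    encoder stage that the full model has.
    """
    cfg = ModelConfig(
        input_size=64,
        encoder_filters=(32, 64, 128),
        bottleneck_filters=256,
        decoder_filters=(128, 64, 32, 16),
        inception=InceptionConfig().scaled(0.25),
        plain_first_filters=16,
    )
    return cfg.with_(**overrides) if overrides else cfg


@dataclass(frozen=True)
class ParameterCount:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self):
        if self.total != self.trainable + self.non_trainable:
            raise ValueError("total must equal trainable + non_trainable")
        if min(self.total, self.trainable, self.non_trainable) < 0:
            raise ValueError("parameter counts must be non-negative")


# ---------------------------------------------------------------------------
# the analytic layer plan
# ---------------------------------------------------------------------------

def _conv_plan(config: ModelConfig) -> list[tuple[str, ConvSpec]]:
    """Ordered (name, ConvSpec) list of every parameterized layer.

    Transposed convolutions are represented as ConvSpecs with
    has_batchnorm=False and kernel_size treated as 2 via a dedicated entry
    (kernel 2 is even, so they are emitted as explicit tuples below).
    """
    plan: list[tuple[str, ConvSpec]] = []
    cin = config.input_channels
    if config.use_inception:
        inc = config.inception
        plan += [
            ("inc_b1", ConvSpec(1, cin, inc.branch1_filters)),
            ("inc_b2_reduce", ConvSpec(1, cin, inc.branch2_reduce)),
            ("inc_b2", ConvSpec(3, inc.branch2_reduce, inc.branch2_filters)),
            ("inc_b3_reduce", ConvSpec(1, cin, inc.branch3_reduce)),
            ("inc_b3", ConvSpec(5, inc.branch3_reduce, inc.branch3_filters)),
            ("inc_b4", ConvSpec(1, cin, inc.branch4_filters)),
        ]
    else:
        f = config.plain_first_filters
        plan += [
            ("enc1a", ConvSpec(3, cin, f)),
            ("enc1b", ConvSpec(3, f, f)),
        ]
    c = config.first_block_channels
    for i, f in enumerate(config.encoder_filters, start=2):
        plan += [(f"enc{i}a", ConvSpec(3, c, f)), (f"enc{i}b", ConvSpec(3, f, f))]
        c = f
    bf = config.bottleneck_filters
    plan += [("bott_a", ConvSpec(3, c, bf)), ("bott_b", ConvSpec(3, bf, bf))]
    if config.use_dual_output:
        plan.append(("bottleneck_head",
                     ConvSpec(1, bf, config.n_classes, has_batchnorm=False,
                              activation="linear")))
    skips = [config.first_block_channels] + list(config.encoder_filters)
    c = bf
    for i, f in enumerate(config.decoder_filters, start=1):
        # 2x2 transposed conv: k=2 is even so ConvSpec cannot express it;
        # emit a 1x1 spec scaled by 4 to keep the arithmetic k^2*cin*cout+cout.
        plan.append((f"dec{i}_up",
                     ConvSpec(1, 4 * c, f, has_batchnorm=False)))
        skip = skips[-i]
        plan += [(f"dec{i}a", ConvSpec(3, f + skip, f)),
                 (f"dec{i}b", ConvSpec(3, f, f))]
        c = f
    plan.append(("final_head",
                 ConvSpec(1, c, config.n_classes, has_batchnorm=False,
                          activation="linear")))
    return plan


def count_parameters_analytic(config: ModelConfig) -> ParameterCount:
    """Closed-form parameter count over the layer plan (no arrays built)."""
    config.validate()
    trainable = 0
    non_trainable = 0
    for _, spec in _conv_plan(config):
        trainable += spec.weight_params + spec.bn_trainable
        non_trainable += spec.bn_non_trainable
    return ParameterCount(trainable + non_trainable, trainable, non_trainable)


def dual_output_head_params(config: ModelConfig) -> int:
    """Parameters added by the bottleneck head (1x1 conv, no batch-norm)."""
    return config.bottleneck_filters * config.n_classes + config.n_classes


# ---------------------------------------------------------------------------
# building the runnable network
# ---------------------------------------------------------------------------

class LayerGraph(nn.Graph):
    """A realized network: the node DAG plus its configuration echo."""

    def __init__(self, config: ModelConfig):
        super().__init__((config.input_size, config.input_size,
                          config.input_channels))
        self.config = config

    def predict(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """Inference forward pass.

        ``images`` is (N, H, W) or (N, H, W, C); returns the softmax maps
        of the declared outputs.
        """
        x = np.asarray(images, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        return self.forward(x, training=False)

    def layer_table(self) -> list[tuple[str, str, tuple, int]]:
        """(name, layer type, output shape, parameter count) per node."""
        rows = []
        for node in self.nodes.values():
            if node.layer is None:
                rows.append((node.name, "Input", node.shape, 0))
            else:
                n_par = sum(p.size for p in node.layer.params())
                rows.append((node.name, type(node.layer).__name__,
                             node.shape, n_par))
        return rows

    def summary(self) -> str:
        lines = [f"{'layer':<22}{'type':<20}{'output shape':<18}{'params':>12}"]
        lines.append("-" * len(lines[0]))
        for name, kind, shape, n_par in self.layer_table():
            lines.append(f"{name:<22}{kind:<20}{str(shape):<18}{n_par:>12,}")
        c = count_parameters_built(self)
        lines.append("-" * len(lines[0]))
        lines.append(f"total {c.total:,}  trainable {c.trainable:,}  "
                     f"non-trainable {c.non_trainable:,}")
        return "\n".join(lines)


def _conv_bn(graph: LayerGraph, name: str, src: str, k: int, cin: int,
             cout: int, rng: np.random.Generator) -> str:
    graph.add(f"{name}_conv", nn.Conv2D(k, cin, cout, "linear", rng), src)
    graph.add(f"{name}_bn", nn.BatchNorm(cout, activation="relu"), f"{name}_conv")
    return f"{name}_bn"


def build_model(config: ModelConfig, seed: int = 0) -> LayerGraph:
    """Construct the runnable network a :class:`ModelConfig` denotes.

    Layout: Inception (or plain) first block -> 2x2 pool -> three encoder
    blocks of paired 3x3 conv+BN+ReLU with pooling -> bottleneck (two 3x3
    convs, dropout) with optional auxiliary softmax head -> four decoder
    stages of 2x2 transposed conv, skip concatenation and paired convs ->
    1x1 conv + softmax final head.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    g = LayerGraph(config)
    cin = config.input_channels
    drop = config.dropout_rate

    if config.use_inception:
        inc = config.inception
        b1 = _conv_bn(g, "inc_b1", "input", 1, cin, inc.branch1_filters, rng)
        b2r = _conv_bn(g, "inc_b2_reduce", "input", 1, cin, inc.branch2_reduce, rng)
        b2 = _conv_bn(g, "inc_b2", b2r, 3, inc.branch2_reduce, inc.branch2_filters, rng)
        b3r = _conv_bn(g, "inc_b3_reduce", "input", 1, cin, inc.branch3_reduce, rng)
        b3 = _conv_bn(g, "inc_b3", b3r, 5, inc.branch3_reduce, inc.branch3_filters, rng)
        g.add("inc_b4_pool", nn.MaxPool3x3Same(), "input")
        b4 = _conv_bn(g, "inc_b4", "inc_b4_pool", 1, cin, inc.branch4_filters, rng)
        block1 = g.add("block1_out", nn.Concat(), [b1, b2, b3, b4])
    else:
        f = config.plain_first_filters
        a = _conv_bn(g, "enc1a", "input", 3, cin, f, rng)
        block1 = _conv_bn(g, "enc1b", a, 3, f, f, rng)
    c = config.first_block_channels

    skips = [block1]
    x = g.add("pool1", nn.MaxPool2x2(), block1)
    n_enc = len(config.encoder_filters)
    for i, f in enumerate(config.encoder_filters, start=2):
        a = _conv_bn(g, f"enc{i}a", x, 3, c, f, rng)
        x = _conv_bn(g, f"enc{i}b", a, 3, f, f, rng)
        # dropout in the deeper half of the encoder
        if i > 1 + n_enc // 2 and drop > 0:
            x = g.add(f"enc{i}_drop", nn.Dropout(drop), x)
        skips.append(x)
        x = g.add(f"pool{i}", nn.MaxPool2x2(), x)
        c = f

    bf = config.bottleneck_filters
    x = _conv_bn(g, "bott_a", x, 3, c, bf, rng)
    if drop > 0:
        x = g.add("bott_a_drop", nn.Dropout(drop), x)
    x = _conv_bn(g, "bott_b", x, 3, bf, bf, rng)
    if drop > 0:
        x = g.add("bott_b_drop", nn.Dropout(drop), x)

    if config.use_dual_output:
        g.add("bottleneck_head", nn.Conv2D(1, bf, config.n_classes, "linear", rng), x)
        g.add("bottleneck_softmax", nn.Softmax(), "bottleneck_head")
        g.outputs["bottleneck"] = "bottleneck_softmax"

    c = bf
    for i, f in enumerate(config.decoder_filters, start=1):
        up = g.add(f"dec{i}_up", nn.TransposedConv2x2(c, f, "relu", rng), x)
        cat = g.add(f"dec{i}_cat", nn.Concat(), [up, skips[-i]])
        skip_c = g.nodes[skips[-i]].shape[2]
        a = _conv_bn(g, f"dec{i}a", cat, 3, f + skip_c, f, rng)
        x = _conv_bn(g, f"dec{i}b", a, 3, f, f, rng)
        c = f

    g.add("final_head", nn.Conv2D(1, c, config.n_classes, "linear", rng), x)
    g.add("final_softmax", nn.Softmax(), "final_head")
    g.outputs["final"] = "final_softmax"
    return g


def count_parameters_built(graph: LayerGraph) -> ParameterCount:
    """Parameter count read off a realized network's arrays."""
    trainable = sum(p.size for p in graph.params() if p.trainable)
    non_trainable = sum(p.size for p in graph.params() if not p.trainable)
    return ParameterCount(trainable + non_trainable, trainable, non_trainable)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(graph: LayerGraph, path) -> None:
    """Save config + weights to an .npz file."""
    weights = {k.replace("/", "__"): v for k, v in graph.get_weights().items()}
    np.savez(path, __config__=np.frombuffer(
        graph.config.to_json().encode(), dtype=np.uint8), **weights)


def load_model(path) -> LayerGraph:
    with np.load(path) as data:
        cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
        graph = build_model(cfg)
        weights = {k.replace("__", "/"): data[k] for k in data.files
                   if k != "__config__"}
    graph.set_weights(weights)
    return graph
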