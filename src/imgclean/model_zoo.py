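"""Declarative network architectures and an analytic parameter-budget oracle.

The screening network ("VGG_NIN") keeps the 13-convolution VGG16 trunk with
batch normalisation but replaces the ~120M-parameter fully connected head
with a network-in-network head: two 1x1 convolutions (512->2048->2048, each
with bias, batch norm and ReLU), global average pooling, and a single linear
layer to the class logits.  This drops the budget from 134,277,186 to
19,982,402 parameters for two classes while preserving the trunk's feature
extractor.

Architectures are plain data (:class:`ArchitectureSpec`); models are built
from them by :func:`build_model`, and :func:`parameter_budget` computes the
trainable-parameter count analytically so built models can be verified
against a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import nn

#: VGG16 convolutional trunk: channel widths, 'M' = 2x2 max pool.
VGG16_TRUNK = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
               512, 512, 512, "M", 512, 512, 512, "M")

LAYER_KINDS = ("conv", "batch_norm", "activation", "max_pool",
               "global_avg_pool", "fully_connected")


@dataclass(frozen=True)
class LayerSpec:
    """One layer: kind, channel fan-in/out, kernel edge, bias flag.

    ``kernel`` is 0 for non-convolutional kinds; pooling and activation
    layers carry no learnable parameters.
    """

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 0
    has_bias: bool = False

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "fully_connected"):
            if self.in_channels <= 0 or self.out_channels <= 0:
                raise ValueError(f"{self.kind} needs positive in/out channels")
        if self.kind == "conv" and self.kernel <= 0:
            raise ValueError("conv needs a positive kernel size")

    @property
    def param_count(self) -> int:
        if self.kind == "conv":
            n = self.in_channels * self.out_channels * self.kernel ** 2
            return n + (self.out_channels if self.has_bias else 0)
        if self.kind == "fully_connected":
            n = self.in_channels * self.out_channels
            return n + (self.out_channels if self.has_bias else 0)
        if self.kind == "batch_norm":
            return 2 * self.out_channels
        return 0


@dataclass(frozen=True)
class ArchitectureSpec:
    """Named ordered layer list with the expected input size and class count."""

    name: str
    layers: tuple[LayerSpec, ...]
    num_classes: int
    input_size: int

    def validate(self) -> None:
        """Check channel compatibility and the pooling cascade by simulating
        shapes through the stack."""
        ch, size = 3, self.input_size
        for i, ls in enumerate(self.layers):
            where = f"{self.name} layer {i} ({ls.kind})"
            if ls.kind == "conv":
                if ls.in_channels != ch:
                    raise ValueError(f"{where}: expects {ls.in_channels} "
                                     f"input channels, gets {ch}")
                if ls.kernel % 2 == 0:
                    raise ValueError(f"{where}: only odd kernels supported")
                ch = ls.out_channels
            elif ls.kind == "batch_norm":
                if ls.out_channels != ch:
                    raise ValueError(f"{where}: channel mismatch")
            elif ls.kind == "max_pool":
                if size < 2 or size % 2:
                    raise ValueError(
                        f"{where}: spatial size {size} cannot be pooled")
                size //= 2
            elif ls.kind == "global_avg_pool":
                size = 1
            elif ls.kind == "fully_connected":
                if ls.in_channels != ch * size * size:
                    raise ValueError(
                        f"{where}: expects {ls.in_channels} features, "
                        f"gets {ch}*{size}*{size}={ch * size * size}")
                ch, size = ls.out_channels, 1
        if ch != self.num_classes:
            raise ValueError(f"{self.name}: final layer emits {ch} outputs, "
                             f"expected {self.num_classes}")


def _conv_bn_relu(in_ch: int, out_ch: int, kernel: int) -> list[LayerSpec]:
    return [
        LayerSpec("conv", in_ch, out_ch, kernel, has_bias=True),
        LayerSpec("batch_norm", out_ch, out_ch),
        LayerSpec("activation", out_ch, out_ch),
    ]


def _trunk_layers() -> list[LayerSpec]:
    layers: list[LayerSpec] = []
    ch = 3
    for item in VGG16_TRUNK:
        if item == "M":
            layers.append(LayerSpec("max_pool", kernel=2))
        else:
            layers.extend(_conv_bn_relu(ch, int(item), 3))
            ch = int(item)
    return layers


def vgg_nin_spec(num_classes: int = 2, input_size: int = 224,
                 head_width: int = 2048) -> ArchitectureSpec:
    """The screening network: VGG16-bn trunk + 1x1-conv (NIN) head.

    Head: 1x1 conv 512->``head_width`` and ``head_width``->``head_width``
    (bias + batch norm + ReLU each), global average pooling, then a linear
    layer to ``num_classes``.  At the default width of 2048 the two-class
    budget is 19,982,402 parameters.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be at least 2")
    layers = _trunk_layers()
    layers += _conv_bn_relu(512, head_width, 1)
    layers += _conv_bn_relu(head_width, head_width, 1)
    layers.append(LayerSpec("global_avg_pool"))
    layers.append(LayerSpec("fully_connected", head_width, num_classes,
                            has_bias=True))
    spec = ArchitectureSpec("vgg_nin", tuple(layers), num_classes, input_size)
    spec.validate()
    return spec


def vgg16_bn_spec(num_classes: int = 2, input_size: int = 224
                  ) -> ArchitectureSpec:
    """Standard VGG16 with batch norm: trunk + 25088->4096->4096->classes head."""
    if num_classes < 2:
        raise ValueError("num_classes must be at least 2")
    if input_size % 32:
        raise ValueError("input_size must be a multiple of 32")
    layers = _trunk_layers()
    feat = 512 * (input_size // 32) ** 2
    layers.append(LayerSpec("fully_connected", feat, 4096, has_bias=True))
    layers.append(LayerSpec("activation", 4096, 4096))
    layers.append(LayerSpec("fully_connected", 4096, 4096, has_bias=True))
    layers.append(LayerSpec("activation", 4096, 4096))
    layers.append(LayerSpec("fully_connected", 4096, num_classes, has_bias=True))
    spec = ArchitectureSpec("vgg16_bn", tuple(layers), num_classes, input_size)
    spec.validate()
    return spec


def small_reference_spec(input_size: int = 32, num_classes: int = 2
                         ) -> ArchitectureSpec:
    """Desk-scale surrogate in the same topology family as the screening net:
    three conv/pool stages, two 1x1 convolutions, global average pooling, and
    a linear head.  Under 200k parameters; trains on one CPU in minutes.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be at least 2")
    if input_size < 16:
        raise ValueError("input_size must be at least 16")
    if input_size % 8:
        raise ValueError("input_size must be divisible by 8 "
                         "(three halving pools)")
    layers: list[LayerSpec] = []
    ch = 3
    for out_ch in (16, 32, 64):
        layers.extend(_conv_bn_relu(ch, out_ch, 3))
        layers.append(LayerSpec("max_pool", kernel=2))
        ch = out_ch
    layers += _conv_bn_relu(64, 96, 1)
    layers += _conv_bn_relu(96, 96, 1)
    layers.append(LayerSpec("global_avg_pool"))
    layers.append(LayerSpec("fully_connected", 96, num_classes, has_bias=True))
    spec = ArchitectureSpec("small_reference", tuple(layers), num_classes,
                            input_size)
    spec.validate()
    return spec


def parameter_budget(spec: ArchitectureSpec) -> int:
    """Analytic trainable-parameter count: conv = in*out*k^2 (+out if bias),
    batch norm = 2*channels, fully connected = in*out (+out if bias),
    pooling/activation = 0."""
    spec.validate()
    return sum(ls.param_count for ls in spec.layers)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate a trainable classifier from a spec.

    Weight initialisation is deterministic given ``seed``; the built model's
    ``trainable_count`` equals :func:`parameter_budget` of the spec.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    for ls in spec.layers:
        if ls.kind == "conv":
            layers.append(nn.Conv2d(ls.in_channels, ls.out_channels,
                                    ls.kernel, ls.has_bias, rng))
        elif ls.kind == "batch_norm":
            layers.append(nn.BatchNorm2d(ls.out_channels))
        elif ls.kind == "activation":
            layers.append(nn.ReLU())
        elif ls.kind == "max_pool":
            layers.append(nn.MaxPool2d())
        elif ls.kind == "global_avg_pool":
            layers.append(nn.GlobalAvgPool())
        elif ls.kind == "fully_connected":
            layers.append(nn.Linear(ls.in_channels, ls.out_channels,
                                    ls.has_bias, rng))
        else:  # pragma: no cover - LayerSpec already rejects unknown kinds
            raise ValueError(f"cannot build layer kind {ls.kind!r}")
    return nn.Sequential(layers)


def spec_to_table(spec: ArchitectureSpec) -> str:
    """Plain-text layer table: one line per layer
    (kind in out kernel bias params), plus name/meta and total lines."""
    lines = [f"# {spec.name} classes={spec.num_classes} "
             f"input={spec.input_size}"]
    lines.append("kind\tin\tout\tkernel\tbias\tparams")
    for ls in spec.layers:
        lines.append(f"{ls.kind}\t{ls.in_channels}\t{ls.out_channels}\t"
                     f"{ls.kernel}\t{int(ls.has_bias)}\t{ls.param_count}")
    lines.append(f"# total\t{parameter_budget(spec)}")
    return "\n".join(lines) + "\n"


def spec_from_table(text: str) -> ArchitectureSpec:
    """Inverse of :func:`spec_to_table` (the params column is re-derived)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    head = lines[0].lstrip("# ").split()
    name = head[0]
    meta = dict(kv.split("=") for kv in head[1:])
    layers = []
    for ln in lines[2:]:
        if ln.startswith("#"):
            continue
        kind, cin, cout, kernel, bias, _params = ln.split("\t")
        layers.append(LayerSpec(kind, int(cin), int(cout), int(kernel),
                                bool(int(bias))))
    spec = ArchitectureSpec(name, tuple(layers), int(meta["classes"]),
                            int(meta["input"]))
    spec.validate()
    return spec
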