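"""Declarative CNN architectures for volumetric FLAIR classification.

The core model is a custom 3D convolutional network: eight 3x3x3 convolutions
with channel width growing from 32 to 512, batch normalization before every
activation, a 2x2x2 max-pool (stride 2) after every second convolution, two
linearly-activated fully connected layers and a softmax output over the four
diagnostic classes (HC, NCI, VaMCI, VaD).  A VGG-16-topology 2D network is
provided as the slice-based baseline.

Architectures are described declaratively (`ArchitectureSpec`, a sequence of
`LayerSpec`) so that they can be serialized, shape-traced symbolically and
instantiated by the numpy engine in :mod:`flairvol.nn`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from math import prod
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

LAYER_KINDS = frozenset(
    {"conv3d", "conv2d", "batchnorm", "relu", "maxpool", "flatten", "dense", "softmax"}
)


def relu(x):
    """Rectified linear unit, R(x) = max(x, 0). Works on scalars and arrays."""
    return np.maximum(x, 0)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network: kind plus the parameters that kind needs."""

    kind: str
    out_channels: int | None = None
    units: int | None = None
    filter_size: tuple[int, ...] | None = None
    stride: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        for key in ("filter_size", "stride"):
            if key in d:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        d = dict(d)
        for key in ("filter_size", "stride"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ArchitectureSpec:
    """An ordered stack of layers plus the input geometry it expects."""

    layers: tuple[LayerSpec, ...]
    input_extents: tuple[int, ...]
    n_classes: int
    name: str = "model"
    in_channels: int = 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "input_extents": list(self.input_extents),
                "n_classes": self.n_classes,
                "in_channels": self.in_channels,
                "layers": [l.to_dict() for l in self.layers],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        return cls(
            layers=tuple(LayerSpec.from_dict(l) for l in d["layers"]),
            input_extents=tuple(d["input_extents"]),
            n_classes=d["n_classes"],
            name=d.get("name", "model"),
            in_channels=d.get("in_channels", 1),
        )

    @property
    def conv_channels(self) -> list[int]:
        return [l.out_channels for l in self.layers if l.kind in ("conv3d", "conv2d")]


def build_3d_cnn(
    input_extents: Sequence[int],
    n_classes: int = 4,
    base_channels: int = 32,
    fc_units: tuple[int, int] = (256, 64),
    bn_on_fc: bool = True,
) -> ArchitectureSpec:
    """The custom 3D network: 8 convs (channels base..16*base), 4 pools.

    ``base_channels=32`` gives the full-size channel schedule
    32, 64, 64, 128, 128, 256, 256, 512; smaller values scale every width
    proportionally for desk-scale experiments while preserving the topology.

    Parameters
    ----------
    input_extents
        Spatial extents (rows, cols, slices).  Each must be at least 16 so
        the volume survives the four halving pools.
    """
    input_extents = tuple(int(e) for e in input_extents)
    if len(input_extents) != 3:
        raise ValueError(f"3D model needs 3 input extents, got {input_extents}")
    for ax, e in enumerate(input_extents):
        if e < 16:
            raise ValueError(
                f"input extent {e} on axis {ax} too small to survive 4 pooling halvings (need >= 16)"
            )
    mults = [1, 2, 2, 4, 4, 8, 8, 16]
    layers: list[LayerSpec] = []
    for i, m in enumerate(mults):
        layers.append(
            LayerSpec("conv3d", out_channels=base_channels * m, filter_size=(3, 3, 3), stride=(1, 1, 1))
        )
        layers.append(LayerSpec("batchnorm"))
        layers.append(LayerSpec("relu"))
        if i % 2 == 1:
            layers.append(LayerSpec("maxpool", filter_size=(2, 2, 2), stride=(2, 2, 2)))
    layers.append(LayerSpec("flatten"))
    for u in fc_units:
        layers.append(LayerSpec("dense", units=u))
        if bn_on_fc:
            layers.append(LayerSpec("batchnorm"))
        # linear activation: no nonlinearity after the two hidden FC layers
    layers.append(LayerSpec("dense", units=n_classes))
    layers.append(LayerSpec("softmax"))
    return ArchitectureSpec(tuple(layers), input_extents, n_classes, name="cnn3d")


def build_2d_baseline(
    input_extents: Sequence[int],
    n_classes: int = 4,
    base_channels: int = 64,
    fc_units: tuple[int, int] = (256, 64),
    batch_norm: bool = True,
    pretrained: bool = False,
) -> ArchitectureSpec:
    """VGG-16-topology 2D baseline: 13 convs in 5 blocks + 3 dense layers.

    The canonical channel schedule (64,128,256,512,512 per block) corresponds
    to ``base_channels=64``.  ImageNet-pretrained weights are not bundled, so
    requesting ``pretrained=True`` falls back to random initialization with a
    logged warning rather than failing.
    """
    input_extents = tuple(int(e) for e in input_extents)
    if len(input_extents) != 2:
        raise ValueError(f"2D baseline needs 2 input extents, got {input_extents}")
    for ax, e in enumerate(input_extents):
        if e < 32:
            raise ValueError(
                f"in-plane extent {e} on axis {ax} too small for 5 pooling halvings (need >= 32)"
            )
    if pretrained:
        msg = "pretrained 2D weights requested but no local weights are available; using random initialization"
        warnings.warn(msg)
        logger.warning(msg)
    blocks = [(1, 2), (2, 2), (4, 3), (8, 3), (8, 3)]  # (channel multiplier, conv count)
    layers: list[LayerSpec] = []
    for mult, n_conv in blocks:
        for _ in range(n_conv):
            layers.append(
                LayerSpec("conv2d", out_channels=base_channels * mult, filter_size=(3, 3), stride=(1, 1))
            )
            if batch_norm:
                layers.append(LayerSpec("batchnorm"))
            layers.append(LayerSpec("relu"))
        layers.append(LayerSpec("maxpool", filter_size=(2, 2), stride=(2, 2)))
    layers.append(LayerSpec("flatten"))
    for u in fc_units:
        layers.append(LayerSpec("dense", units=u))
        layers.append(LayerSpec("relu"))
    layers.append(LayerSpec("dense", units=n_classes))
    layers.append(LayerSpec("softmax"))
    return ArchitectureSpec(tuple(layers), input_extents, n_classes, name="vgg2d")


@dataclass
class ShapeTrace:
    """Per-layer output shapes and parameter counts from symbolic propagation."""

    rows: list[dict] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r["n_params"] for r in self.rows)

    @property
    def output_shape(self):
        return self.rows[-1]["out_shape"] if self.rows else None

    def to_table(self) -> str:
        lines = [f"{'#':>3} {'layer':<10} {'output shape':<24} {'params':>10}"]
        for i, r in enumerate(self.rows):
            lines.append(f"{i:>3} {r['kind']:<10} {str(r['out_shape']):<24} {r['n_params']:>10}")
        lines.append(f"    total params: {self.total_params}")
        return "\n".join(lines)


def trace_shapes(spec: ArchitectureSpec, input_extents: Sequence[int] | None = None) -> ShapeTrace:
    """Propagate shapes through ``spec`` symbolically.

    Convolutions use "same" padding (spatial shape preserved, stride 1) and
    pools floor-divide each spatial axis.  Shapes are reported as
    ``(*spatial, channels)`` before flattening and as unit counts after.
    Raises ``ValueError`` naming the offending layer if an axis underflows.
    """
    spatial = tuple(int(e) for e in (input_extents if input_extents is not None else spec.input_extents))
    channels = spec.in_channels
    flat: int | None = None
    trace = ShapeTrace()
    for i, layer in enumerate(spec.layers):
        n_params = 0
        if layer.kind in ("conv3d", "conv2d"):
            nd = 3 if layer.kind == "conv3d" else 2
            if flat is not None or len(spatial) != nd:
                raise ValueError(f"layer {i} ({layer.kind}): incompatible input rank")
            n_params = layer.out_channels * (channels * prod(layer.filter_size) + 1)
            channels = layer.out_channels
        elif layer.kind == "maxpool":
            if flat is not None:
                raise ValueError(f"layer {i} (maxpool): input already flattened")
            new = tuple(s // f for s, f in zip(spatial, layer.filter_size))
            if any(n < 1 for n in new):
                raise ValueError(
                    f"layer {i} (maxpool): spatial extent underflow {spatial} -> {new}"
                )
            spatial = new
        elif layer.kind == "batchnorm":
            n_params = 2 * (flat if flat is not None else channels)
        elif layer.kind == "flatten":
            flat = channels * prod(spatial)
        elif layer.kind == "dense":
            if flat is None:
                raise ValueError(f"layer {i} (dense): flatten required before dense")
            n_params = layer.units * (flat + 1)
            flat = layer.units
        elif layer.kind in ("relu", "softmax"):
            pass
        out_shape = flat if flat is not None else spatial + (channels,)
        trace.rows.append({"kind": layer.kind, "out_shape": out_shape, "n_params": n_params})
    return trace
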