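"""Network Auto-Reduction: compound shrinking of block-based CNNs.

Compound scaling describes a CNN as a sequence of repeated layer blocks and
scales three dimensions together: depth (block repeats), width (channel
counts) and input resolution.  Reduction runs the same machinery downward:
a single user parameter φ ≥ 0 yields multipliers

    d = α^(−φ)   (depth),   w = β^(−φ)   (width),   r = γ^(−φ)   (resolution)

with the published coefficients α = 1.2, β = 1.1, γ = 1.15, which satisfy
the constraint α·β²·γ² ≈ 2.  Since the forward-pass cost of a convolutional
network is proportional to d·w²·r², every integer increment of φ halves the
theoretical FLOPS — a one-knob trade between model cost and fidelity,
useful for cheap *selector* models inside an active-learning loop.

This module owns the declarative architecture description (:class:`ArchSpec`),
the reduction rule (:func:`reduce_arch`), a MAC-based cost model
(:func:`estimate_flops`) and a builder that concretizes a spec as a small
trainable model (:func:`build_trainable`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .network import ConvNetClassifier

ALPHA, BETA, GAMMA = 1.2, 1.1, 1.15

_KINDS = ("conv", "depthwise_conv", "pool", "dense")


class ArchError(ValueError):
    """Raised for invalid or unsupported architecture descriptions."""


@dataclass(frozen=True)
class LayerBlock:
    """A block: one layer type repeated ``repeats`` times.

    The block's stride applies to its first occurrence; subsequent repeats
    run at stride 1 with ``out_channels`` in and out.
    """

    kind: str
    repeats: int = 1
    out_channels: int = 1
    kernel: tuple[int, int] = (3, 3)
    stride: int = 1

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ArchError(f"unknown block kind {self.kind!r}")
        if self.repeats < 1 or self.out_channels < 1 or self.stride < 1:
            raise ArchError("repeats, out_channels and stride must be >= 1")


@dataclass(frozen=True)
class ArchSpec:
    """Block-based CNN description: trunk blocks plus a GAP+dropout+dense head.

    The input layer's channel count (3 for RGB) is never width-scaled; only
    block channel counts are.
    """

    input_size: int
    blocks: tuple[LayerBlock, ...]
    head_classes: int = 2
    dropout_rate: float = 0.25
    input_channels: int = 3
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.input_size < 1:
            raise ArchError("input_size must be positive")
        if self.head_classes < 2:
            raise ArchError("head_classes must be >= 2")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ArchError("dropout_rate must be in [0, 1)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_size": self.input_size,
            "input_channels": self.input_channels,
            "head_classes": self.head_classes,
            "dropout_rate": self.dropout_rate,
            "blocks": [
                {"kind": b.kind, "repeats": b.repeats, "out_channels": b.out_channels,
                 "kernel": list(b.kernel), "stride": b.stride}
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        blocks = tuple(
            LayerBlock(kind=b["kind"], repeats=b.get("repeats", 1),
                       out_channels=b.get("out_channels", 1),
                       kernel=tuple(b.get("kernel", (3, 3))),
                       stride=b.get("stride", 1))
            for b in d["blocks"]
        )
        return cls(input_size=d["input_size"], blocks=blocks,
                   head_classes=d.get("head_classes", 2),
                   dropout_rate=d.get("dropout_rate", 0.25),
                   input_channels=d.get("input_channels", 3),
                   name=d.get("name", ""))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ArchSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ScaleFactors:
    """Reduction multipliers derived from φ: d = α^−φ, w = β^−φ, r = γ^−φ."""

    alpha: float
    beta: float
    gamma: float
    phi: float
    d: float
    w: float
    r: float

    @property
    def flops_multiplier(self) -> float:
        """Theoretical forward-cost multiplier d·w²·r² = (α·β²·γ²)^(−φ)."""
        return self.d * self.w ** 2 * self.r ** 2


@dataclass(frozen=True)
class FlopsCount:
    """Multiply–accumulate count for one forward pass (additive over layers)."""

    macs: int


def scale_factors(phi: float, alpha: float = ALPHA, beta: float = BETA,
                  gamma: float = GAMMA) -> ScaleFactors:
    """Evaluate the compound reduction multipliers for a given φ ≥ 0."""
    if phi < 0:
        raise ValueError("phi must be >= 0 (negative phi would enlarge the network)")
    if min(alpha, beta, gamma) <= 1.0:
        raise ValueError("alpha, beta and gamma must each exceed 1")
    return ScaleFactors(alpha=alpha, beta=beta, gamma=gamma, phi=phi,
                        d=alpha ** -phi, w=beta ** -phi, r=gamma ** -phi)


def restriction_product(alpha: float, beta: float, gamma: float) -> float:
    """The balancing constraint α·β²·γ² (≈ 2 for the published coefficients)."""
    if min(alpha, beta, gamma) <= 0:
        raise ValueError("coefficients must be positive")
    return alpha * beta ** 2 * gamma ** 2


def _round_channels(value: float, divisor: int) -> int:
    """Round to the nearest multiple of ``divisor`` (floor at one divisor),
    bumping up one step if the result fell below 90% of the target."""
    new = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if new < 0.9 * value:
        new += divisor
    return new


def reduce_arch(spec: ArchSpec, f: ScaleFactors, channel_divisor: int = 8) -> ArchSpec:
    """Apply compound reduction to an architecture description.

    Per block: repeats' = max(1, ceil(d·repeats)); channels' rounded to the
    nearest multiple of ``channel_divisor`` of w·channels (with the 90%
    bump-up rule); input resolution' = round(r·input).  Input channels, head
    classes and dropout are untouched; φ = 0 returns the spec unchanged.

    Raises :class:`ArchError` when the reduced resolution underflows a
    block's kernel anywhere in the trunk — shallow architectures therefore
    cap the usable φ.
    """
    if f.phi == 0:
        return spec
    new_blocks = []
    for b in spec.blocks:
        reps = max(1, math.ceil(f.d * b.repeats))
        if b.kind in ("conv", "depthwise_conv"):
            ch = _round_channels(f.w * b.out_channels, channel_divisor)
        else:
            ch = b.out_channels
        new_blocks.append(replace(b, repeats=reps, out_channels=ch))
    new_size = int(round(f.r * spec.input_size))
    out = replace(spec, input_size=new_size, blocks=tuple(new_blocks),
                  name=f"{spec.name}-phi{f.phi:g}" if spec.name else "")
    _check_spatial(out)
    return out


def _check_spatial(spec: ArchSpec) -> None:
    h = spec.input_size
    for i, b in enumerate(spec.blocks):
        if b.kind in ("conv", "depthwise_conv", "pool"):
            k = max(b.kernel) if b.kind != "pool" else b.stride
            if h < k:
                raise ArchError(
                    f"block {i} ({b.kind}): spatial size {h} underflows "
                    f"kernel/stride {k}; reduce phi")
            for occ in range(b.repeats):
                s = b.stride if occ == 0 else 1
                h = -(-h // s)
    if h < 1:
        raise ArchError("spatial size collapsed below 1")


def estimate_flops(spec: ArchSpec) -> FlopsCount:
    """MAC count of one forward pass through the trunk blocks.

    Per occurrence: conv = H·W·C_out·k_h·k_w·C_in; depthwise =
    H·W·C_in·k_h·k_w; dense = C_in·C_out; pool = 0.  Spatial sizes are
    propagated with 'same' padding (out = ceil(in/stride)); within a block
    the stride applies to the first occurrence only.  The classifier head is
    not counted (it is tiny and unscaled by reduction).
    """
    h = w = spec.input_size
    cin = spec.input_channels
    macs = 0
    for b in spec.blocks:
        for occ in range(b.repeats):
            s = b.stride if occ == 0 else 1
            if b.kind == "conv":
                ho, wo = -(-h // s), -(-w // s)
                macs += ho * wo * b.out_channels * b.kernel[0] * b.kernel[1] * cin
                h, w, cin = ho, wo, b.out_channels
            elif b.kind == "depthwise_conv":
                ho, wo = -(-h // s), -(-w // s)
                macs += ho * wo * cin * b.kernel[0] * b.kernel[1]
                h, w, cin = ho, wo, b.out_channels
            elif b.kind == "pool":
                h, w = -(-h // s), -(-w // s)
            elif b.kind == "dense":
                macs += cin * b.out_channels
                h = w = 1
                cin = b.out_channels
    return FlopsCount(macs=int(macs))


def build_trainable(spec: ArchSpec, seed: int) -> ConvNetClassifier:
    """Concretize an ArchSpec as a trainable numpy CNN.

    Supports ``conv`` and ``pool`` trunk blocks (the tiny reference family
    below); ``dense`` and ``depthwise_conv`` blocks are representable and
    costable but not buildable here.  Initialization is fully determined by
    ``seed``.
    """
    plan = []
    for b in spec.blocks:
        if b.kind == "conv":
            for occ in range(b.repeats):
                plan.append(("conv", b.kernel[0], b.kernel[1], b.out_channels,
                             b.stride if occ == 0 else 1))
        elif b.kind == "pool":
            for _ in range(b.repeats):
                plan.append(("pool", b.stride))
        else:
            raise ArchError(
                f"trainable builder supports conv/pool blocks only, got {b.kind!r}")
    try:
        return ConvNetClassifier(plan, input_size=spec.input_size,
                                 n_classes=spec.head_classes,
                                 dropout_rate=spec.dropout_rate, seed=seed)
    except ValueError as e:
        raise ArchError(str(e)) from e


# ---------------------------------------------------------------- reference archs

def tiny_cnn(input_size: int = 64, head_classes: int = 2,
             dropout_rate: float = 0.25) -> ArchSpec:
    """Desk-scale reference architecture: 3 strided conv blocks, ~32 features."""
    return ArchSpec(
        name="tiny",
        input_size=input_size,
        blocks=(
            LayerBlock("conv", repeats=1, out_channels=16, kernel=(3, 3), stride=2),
            LayerBlock("conv", repeats=2, out_channels=24, kernel=(3, 3), stride=2),
            LayerBlock("conv", repeats=2, out_channels=32, kernel=(3, 3), stride=2),
        ),
        head_classes=head_classes,
        dropout_rate=dropout_rate,
    )


def reference_cnn(input_size: int = 224) -> ArchSpec:
    """Large stylized architecture used for cost-model analyses (not trained)."""
    return ArchSpec(
        name="reference",
        input_size=input_size,
        blocks=(
            LayerBlock("conv", repeats=1, out_channels=64, kernel=(3, 3), stride=2),
            LayerBlock("conv", repeats=8, out_channels=64, kernel=(3, 3), stride=2),
            LayerBlock("conv", repeats=8, out_channels=128, kernel=(3, 3), stride=2),
            LayerBlock("conv", repeats=8, out_channels=256, kernel=(3, 3), stride=2),
            LayerBlock("conv", repeats=8, out_channels=512, kernel=(3, 3), stride=2),
        ),
    )
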