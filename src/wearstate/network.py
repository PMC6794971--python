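"""Declarative five-channel 1-D CNN architecture and its audit.

Each biosignal channel (ECG, EMG, respiration, BVP, accelerometer) feeds
its own branch — two valid (no-padding, stride-1) 1-D convolutions with an
adaptive kernel, flatten, dropout, dense 64, dropout, dense 32 — and the
five 32-unit branch outputs are concatenated (width 160) into a trunk of a
dense 32 layer and a 5-way softmax.  The adaptive kernel length for a
branch with ``x`` input features is ``ceil(x / 2)``, chosen so the two
stacked valid convolutions always leave a positive output length.

:class:`ModelSpec` is purely structural: parameter counts and per-layer
output shapes are derivable from it without instantiating weights, which
is what :func:`count_parameters`, :func:`forward_shapes` and
:func:`audit_table` do.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PAPER_CHANNEL_FEATURES",
    "LayerSpec",
    "ModelSpec",
    "kernel_shape",
    "build_model",
    "count_parameters",
    "forward_shapes",
    "audit_table",
]

#: The published channel widths: 4 ECG, 3 EMG, 3 RESP, 3 BVP, 15 ACCL features.
PAPER_CHANNEL_FEATURES = {"ECG": 4, "EMG": 3, "RESP": 3, "BVP": 3, "ACCL": 15}


def kernel_shape(x: int) -> tuple[int, int]:
    """Adaptive 1-D kernel shape ``(ceil(x/2), 1)`` for ``x`` input features.

    Reproduces the published kernels: 4 -> (2, 1), 3 -> (2, 1), 15 -> (8, 1).
    Requires ``x >= 2`` (a one-feature branch admits no convolution).
    """
    if x < 2:
        raise ValueError(f"channel needs >= 2 input features, got {x}")
    return (-(-x // 2), 1)


@dataclass
class LayerSpec:
    """One layer: structural fields only (shapes/params are derived)."""

    kind: str                      # input|conv1d|flatten|dropout|dense|concatenate
    units: int | None = None       # filters for conv1d, units for dense
    kernel: int | None = None      # conv kernel length
    activation: str | None = None  # relu | softmax | None
    rate: float | None = None      # dropout rate


@dataclass
class ModelSpec:
    """Structural description of the multichannel network.

    ``branches`` maps each channel name to its ordered layer list;
    ``trunk`` holds the post-concatenation layers.  Branch order is the
    concatenation order.
    """

    channel_features: dict[str, int]
    branches: dict[str, list[LayerSpec]]
    trunk: list[LayerSpec]
    dropout_rate: float = 0.25

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "channel_features": self.channel_features,
            "dropout_rate": self.dropout_rate,
            "branches": {c: [asdict(l) for l in ls] for c, ls in self.branches.items()},
            "trunk": [asdict(l) for l in self.trunk],
        }
        s = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            channel_features={k: int(v) for k, v in d["channel_features"].items()},
            branches={c: [LayerSpec(**l) for l in ls] for c, ls in d["branches"].items()},
            trunk=[LayerSpec(**l) for l in d["trunk"]],
            dropout_rate=d["dropout_rate"],
        )


def build_model(
    channel_features: dict[str, int] | None = None,
    conv1_filters: int = 128,
    conv2_filters: int = 64,
    dropout_rate: float = 0.25,
) -> ModelSpec:
    """Construct the network spec for the given channel feature counts.

    Both convolutions of a branch use that branch's adaptive kernel; there
    is no pooling anywhere; branches meet only at the concatenation layer.
    Raises if any branch's second convolution would produce a non-positive
    length.  A single-entry ``channel_features`` yields the degenerate
    one-branch model used for the single-channel comparison.
    """
    if channel_features is None:
        channel_features = PAPER_CHANNEL_FEATURES
    channel_features = dict(channel_features)
    if not channel_features:
        raise ValueError("need at least one channel")
    branches = {}
    for ch, x in channel_features.items():
        k, _ = kernel_shape(x)
        l1 = x - k + 1
        l2 = l1 - k + 1
        if l2 < 1:
            raise ValueError(
                f"channel {ch!r}: two valid convolutions with kernel {k} on "
                f"{x} features leave a non-positive length ({l2})"
            )
        branches[ch] = [
            LayerSpec("input"),
            LayerSpec("conv1d", units=conv1_filters, kernel=k, activation="relu"),
            LayerSpec("conv1d", units=conv2_filters, kernel=k, activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dropout", rate=dropout_rate),
            LayerSpec("dense", units=64, activation="relu"),
            LayerSpec("dropout", rate=dropout_rate),
            LayerSpec("dense", units=32, activation="relu"),
        ]
    trunk = [
        LayerSpec("concatenate"),
        LayerSpec("dense", units=32, activation="relu"),
        LayerSpec("dense", units=5, activation="softmax"),
    ]
    return ModelSpec(channel_features, branches, trunk, dropout_rate)


def _walk_branch(x: int, layers: list[LayerSpec]):
    """Yield (layer, in_shape, out_shape, n_params) through one branch.

    Shapes are (length, channels) for 2-D stages and plain ints after
    flattening; valid-convolution arithmetic L_out = L_in - k + 1.
    """
    shape: tuple[int, int] | int = (x, 1)
    for layer in layers:
        in_shape = shape
        if layer.kind == "input":
            params = 0
        elif layer.kind == "conv1d":
            length, chans = shape  # type: ignore[misc]
            params = layer.units * (layer.kernel * chans) + layer.units
            shape = (length - layer.kernel + 1, layer.units)
        elif layer.kind == "flatten":
            length, chans = shape  # type: ignore[misc]
            params, shape = 0, length * chans
        elif layer.kind == "dropout":
            params = 0
        elif layer.kind == "dense":
            params = layer.units * shape + layer.units  # type: ignore[operator]
            shape = layer.units
        else:
            raise ValueError(f"unexpected layer kind {layer.kind!r} in branch")
        yield layer, in_shape, shape, params


def _walk_trunk(branch_widths: list[int], layers: list[LayerSpec]):
    shape = sum(branch_widths)
    for layer in layers:
        in_shape = shape
        if layer.kind == "concatenate":
            params = 0
        elif layer.kind == "dense":
            params = layer.units * shape + layer.units
            shape = layer.units
        else:
            raise ValueError(f"unexpected layer kind {layer.kind!r} in trunk")
        yield layer, in_shape, shape, params


def forward_shapes(spec: ModelSpec) -> dict:
    """Per-layer output dimensions: ``{'branches': {ch: [...]}, 'trunk': [...]}``."""
    out = {"branches": {}, "trunk": []}
    widths = []
    for ch, layers in spec.branches.items():
        shapes = [s for _, _, s, _ in _walk_branch(spec.channel_features[ch], layers)]
        out["branches"][ch] = shapes
        widths.append(shapes[-1])
    out["trunk"] = [s for _, _, s, _ in _walk_trunk(widths, spec.trunk)]
    return out


def count_parameters(spec: ModelSpec) -> dict:
    """Per-layer and total trainable parameter counts (mirrors the shapes)."""
    out = {"branches": {}, "trunk": [], "total": 0}
    widths = []
    for ch, layers in spec.branches.items():
        counts = []
        for _, _, shape, p in _walk_branch(spec.channel_features[ch], layers):
            counts.append(p)
        out["branches"][ch] = counts
        out["total"] += sum(counts)
        widths.append(shape)
    for _, _, _, p in _walk_trunk(widths, spec.trunk):
        out["trunk"].append(p)
        out["total"] += p
    return out


def audit_table(spec: ModelSpec) -> pd.DataFrame:
    """Layer-by-layer audit: kernel, parameter count, output dimension.

    One row per (layer, channel) for branch layers and per layer for the
    trunk — the published architecture table reconstructed from the spec.
    """
    rows = []
    widths = []
    for ch, layers in spec.branches.items():
        for i, (layer, _, shape, p) in enumerate(
            _walk_branch(spec.channel_features[ch], layers), start=1
        ):
            rows.append({
                "layer": i,
                "layer_type": layer.kind,
                "channel": ch,
                "filters_or_units": layer.units,
                "kernel": f"({layer.kernel}, 1)" if layer.kernel else "",
                "n_parameters": p,
                "output_dimension": str(shape),
                "activation": layer.activation or "",
            })
        widths.append(shape)
    n_branch_layers = max(len(l) for l in spec.branches.values())
    for j, (layer, _, shape, p) in enumerate(_walk_trunk(widths, spec.trunk)):
        rows.append({
            "layer": n_branch_layers + 1 + j,
            "layer_type": layer.kind,
            "channel": "all",
            "filters_or_units": layer.units,
            "kernel": "",
            "n_parameters": p,
            "output_dimension": str(shape),
            "activation": layer.activation or "",
        })
    return pd.DataFrame(rows)
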