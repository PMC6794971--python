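"""Frequency harmonization: everything to 700 Hz, then block-aggregate to 10 Hz.

The pipeline first upsamples the low-rate wrist streams (4/32/64 Hz) onto
the 700 Hz chest grid, then downsamples all signals to 10 Hz by aggregating
every 70 consecutive samples (mean by default).  Labels are downsampled by
the block mode; ties break to the lowest class code for reproducibility, and
a block consisting solely of the -1 sentinel emits -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np

__all__ = ["ResamplePlan", "upsample", "downsample_signal", "downsample_labels"]


@dataclass
class ResamplePlan:
    common_hz: int = 700
    target_hz: int = 10
    signal_agg: str = "mean"        # or "median"
    upsample_method: str = "linear"  # or "hold"

    def __post_init__(self) -> None:
        if self.common_hz % self.target_hz != 0:
            raise ValueError("common_hz must be an integer multiple of target_hz")
        if self.signal_agg not in ("mean", "median"):
            raise ValueError(f"unknown aggregator {self.signal_agg!r}")
        if self.upsample_method not in ("linear", "hold"):
            raise ValueError(f"unknown upsample method {self.upsample_method!r}")

    @property
    def block(self) -> int:
        return self.common_hz // self.target_hz


def upsample(series, native_hz: float, plan: ResamplePlan | None = None) -> np.ndarray:
    """Resample ``series`` from ``native_hz`` onto the common 700 Hz grid.

    Output length is ``round(len(series) * common_hz / native_hz)``.  With
    the default linear method the original samples are reproduced exactly at
    their mapped grid positions and values beyond the final input sample
    hold that sample's value; ``hold`` repeats the most recent sample.
    Handles non-integer rate ratios (e.g. 32 Hz -> 700 Hz) by interpolating
    onto the target time grid.  Triaxial (n, 3) input is resampled per axis.
    """
    plan = plan or ResamplePlan()
    if native_hz <= 0:
        raise ValueError("native_hz must be positive")
    series = np.asarray(series, dtype=np.float64)
    if series.ndim == 2:
        cols = [upsample(series[:, j], native_hz, plan) for j in range(series.shape[1])]
        return np.stack(cols, axis=1)
    n = len(series)
    n_out = round(n * plan.common_hz / native_hz)
    if n == 0 or n_out == 0:
        return np.empty(0)
    t_out = np.arange(n_out) / plan.common_hz
    t_in = np.arange(n) / native_hz
    if plan.upsample_method == "hold":
        idx = np.minimum(np.searchsorted(t_in, t_out, side="right") - 1, n - 1)
        return series[np.maximum(idx, 0)]
    return np.interp(t_out, t_in, series)


def _blocks(series: np.ndarray, block: int) -> np.ndarray:
    n_out = len(series) // block
    if n_out == 0:
        warn("series shorter than one aggregation block; empty output", stacklevel=3)
    return series[: n_out * block].reshape(n_out, block)


def downsample_signal(series, plan: ResamplePlan | None = None) -> np.ndarray:
    """Aggregate every ``plan.block`` (=70) samples; trailing partial block dropped."""
    plan = plan or ResamplePlan()
    series = np.asarray(series, dtype=np.float64)
    if series.ndim == 2:
        cols = [downsample_signal(series[:, j], plan) for j in range(series.shape[1])]
        return np.stack(cols, axis=1)
    b = _blocks(series, plan.block)
    return b.mean(axis=1) if plan.signal_agg == "mean" else np.median(b, axis=1)


def downsample_labels(labels, plan: ResamplePlan | None = None) -> np.ndarray:
    """Mode of every block of 70 labels; ties -> lowest class code.

    Blocks containing only the -1 sentinel emit -1; otherwise the mode is
    taken over the labeled samples of the block, so the output is always a
    label actually present in its block.
    """
    plan = plan or ResamplePlan()
    labels = np.asarray(labels, dtype=np.int64)
    b = _blocks(labels, plan.block)
    out = np.empty(len(b), dtype=np.int64)
    for i, row in enumerate(b):
        counts = np.bincount(row + 1, minlength=6)  # slot 0 is the -1 sentinel
        labeled = counts[1:]
        out[i] = int(labeled.argmax()) if labeled.any() else -1
    return out
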