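"""Raw ADC to SI-unit conversion for the chest and wrist streams.

The chest unit emits 16-bit offset-binary samples: midscale (2^15) is the
electrical zero.  ECG and EMG map to a bipolar +/-1.5 mV / uV swing via

    converted = (raw / 2^16 - 0.5) * V_CC

with V_CC = 3 (mV for ECG, uV for EMG).  Respiration maps the same way onto
a +/-50 % displacement range.  The wrist accelerometer reports in units of
1/64 g, so one raw unit is 9.81/64 m/s^2 (the scale is configurable).  BVP
and temperature arrive already in their reporting units and pass through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConversionSpec", "convert_signal", "KINDS"]

KINDS = ("ecg", "emg", "resp", "acc", "bvp", "temp")


@dataclass
class ConversionSpec:
    """Conversion constants; defaults follow the device datasheet values.

    ``chan_bit`` is the ADC output size 2^16; ``vcc_ecg_mv``/``vcc_emg_uv``
    the 3-unit supply swings; ``acc_scale`` the m/s^2 per raw accelerometer
    unit (9.81/64 for a 1/64 g resolution).
    """

    chan_bit: int = 2**16
    vcc_ecg_mv: float = 3.0
    vcc_emg_uv: float = 3.0
    acc_scale: float = 9.81 / 64.0

    def __post_init__(self) -> None:
        if self.chan_bit <= 0:
            raise ValueError("chan_bit must be positive")
        if self.vcc_ecg_mv <= 0 or self.vcc_emg_uv <= 0 or self.acc_scale <= 0:
            raise ValueError("conversion scales must be positive")


def convert_signal(kind: str, raw, spec: ConversionSpec | None = None) -> np.ndarray:
    """Convert one raw stream to SI units.

    Parameters
    ----------
    kind
        One of ``ecg`` (-> mV), ``emg`` (-> uV), ``resp`` (-> %),
        ``acc`` (-> m/s^2, applied per axis), ``bvp``/``temp`` (identity).
    raw
        Raw samples.  For ecg/emg/resp these must lie in [0, 2^16);
        acc/bvp/temp accept any finite values.
    spec
        Conversion constants; defaults used when omitted.

    Returns
    -------
    numpy.ndarray of float64, same shape as ``raw``.
    """
    spec = spec or ConversionSpec()
    raw = np.asarray(raw, dtype=np.float64)
    if kind in ("ecg", "emg", "resp"):
        if raw.size and (raw.min() < 0 or raw.max() >= spec.chan_bit):
            raise ValueError(f"{kind}: raw values outside [0, {spec.chan_bit})")
        frac = raw / spec.chan_bit - 0.5
        if kind == "ecg":
            return frac * spec.vcc_ecg_mv
        if kind == "emg":
            return frac * spec.vcc_emg_uv
        return frac * 100.0
    if kind == "acc":
        return raw * spec.acc_scale
    if kind in ("bvp", "temp"):
        return raw.copy()
    raise ValueError(f"unknown signal kind {kind!r}; expected one of {KINDS}")
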