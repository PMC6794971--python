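"""Peak-based minute features and subject-wise accelerometer statistics.

The classifier consumes a 28-column matrix at 10 Hz grouped into five
channel blocks: ECG (4), EMG (3), respiration (3), BVP (3) and wrist
accelerometer (15).  The first four blocks carry *minute-based* features —
peak count, mean peak amplitude, mean absolute successive peak-amplitude
difference, and (ECG only) mean peaks per one-second window — computed on
each complete minute (600 samples at 10 Hz) and broadcast to every sample
of that minute.  The accelerometer block carries *subject-based* statistics
(per-axis mean, sd, kurtosis, crest factor; pairwise axis correlations)
broadcast to every sample of the subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np

from .io import FEATURE_COLUMNS, FeatureDataset, RawRecording
from .resample import ResamplePlan, downsample_labels, downsample_signal, upsample
from .units import ConversionSpec, convert_signal

__all__ = [
    "PeakParams",
    "DEFAULT_PEAK_PARAMS",
    "SAMPLES_PER_MINUTE",
    "detect_peaks",
    "minute_peak_features",
    "subject_accel_features",
    "assemble_feature_matrix",
]

#: 10 Hz x 60 s.
SAMPLES_PER_MINUTE = 600


@dataclass
class PeakParams:
    """Peak-detection thresholding for one signal kind.

    A sample is a peak when it exceeds its left neighbour strictly, its
    right neighbour weakly, and the amplitude threshold
    ``mean + threshold_k * sd`` of the analysed window.  ``min_distance``
    (samples at 10 Hz) enforces the physiological refractory gap between
    consecutive peaks; among conflicting peaks the larger survives.
    """

    threshold_k: float = 1.0
    min_distance: int = 3

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")


#: Defaults per signal kind at 10 Hz: the minimum credible interval between
#: heartbeats is ~0.3 s (ECG/BVP), between breaths ~1 s, EMG bursts ~0.2 s.
DEFAULT_PEAK_PARAMS = {
    "ecg": PeakParams(1.0, 3),
    "emg": PeakParams(1.0, 2),
    "resp": PeakParams(1.0, 10),
    "bvp": PeakParams(1.0, 3),
}


def detect_peaks(series, params: PeakParams | None = None, threshold: float | None = None) -> np.ndarray:
    """Indices of local maxima above threshold, refractory-gap enforced.

    ``threshold`` defaults to ``mean + threshold_k * sd`` of ``series``
    itself (callers analysing one minute at a time therefore get the
    per-minute threshold).  Among candidate peaks closer than
    ``min_distance`` samples the one with the larger amplitude is kept,
    ties resolved to the earlier index.  Returned indices are sorted.
    """
    params = params or PeakParams()
    x = np.asarray(series, dtype=np.float64)
    if len(x) < 3:
        return np.empty(0, dtype=np.int64)
    if threshold is None:
        threshold = x.mean() + params.threshold_k * x.std()
    interior = np.arange(1, len(x) - 1)
    cand = interior[
        (x[interior] > x[interior - 1])
        & (x[interior] >= x[interior + 1])
        & (x[interior] > threshold)
    ]
    if len(cand) == 0 or params.min_distance == 1:
        return cand
    # Greedy suppression: accept by descending amplitude (earlier index on ties).
    order = np.lexsort((cand, -x[cand]))
    keep = np.zeros(len(cand), dtype=bool)
    taken: list[int] = []
    for j in order:
        idx = cand[j]
        if all(abs(idx - t) >= params.min_distance for t in taken):
            keep[j] = True
            taken.append(idx)
    return np.sort(cand[keep])


def minute_peak_features(series, peaks, signal_kind: str) -> np.ndarray:
    """Per-complete-minute feature rows for one peak-based signal.

    Returns an (n_minutes, 4) array for ECG — columns (peaks,
    average_amplitude, differ_mean, resting) — and (n_minutes, 3) without
    ``resting`` for the other kinds.  ``differ_mean`` is the mean absolute
    difference between consecutive peak amplitudes within the minute (0
    with fewer than two peaks); ``resting`` the mean peak count over the 60
    non-overlapping one-second (10-sample) windows.  A minute without peaks
    yields all-zero features, keeping the matrix dense.  The trailing
    partial minute is dropped.
    """
    x = np.asarray(series, dtype=np.float64)
    peaks = np.asarray(peaks, dtype=np.int64)
    n_minutes = len(x) // SAMPLES_PER_MINUTE
    width = 4 if signal_kind == "ecg" else 3
    out = np.zeros((n_minutes, width))
    for m in range(n_minutes):
        lo, hi = m * SAMPLES_PER_MINUTE, (m + 1) * SAMPLES_PER_MINUTE
        p = peaks[(peaks >= lo) & (peaks < hi)]
        amps = x[p]
        out[m, 0] = len(p)
        if len(p):
            out[m, 1] = amps.mean()
        if len(p) >= 2:
            out[m, 2] = np.abs(np.diff(amps)).mean()
        if signal_kind == "ecg":
            out[m, 3] = len(p) / 60.0  # mean peaks per 1 s window of the minute
    return out


def _axis_stats(x: np.ndarray, axis_name: str, printed_forms: bool) -> tuple[float, float, float, float]:
    n = len(x)
    mean = x.mean()
    std = x.std()  # population (1/N) normalisation
    if std == 0:
        raise ValueError(f"accelerometer axis '{axis_name}' has zero variance; "
                         "kurtosis/crest/correlation undefined")
    if printed_forms:
        kurt = np.mean((x - mean) ** 4) / std**2 - 3.0
    else:
        kurt = np.mean((x - mean) ** 4) / std**4 - 3.0  # excess kurtosis
    crest = x.max() / np.sqrt(np.sum(x**2) / (n - 1))
    return mean, std, kurt, crest


def subject_accel_features(acc_xyz, printed_forms: bool = False) -> np.ndarray:
    """The 15 subject-level statistics of a triaxial 10 Hz accelerometer.

    Parameters
    ----------
    acc_xyz
        (n, 3) array (or three equal-length series) of the x/y/z axes,
        n >= 2, each axis with nonzero variance.
    printed_forms
        Compatibility flag: report kurtosis normalised by sd^2 and the raw
        (unclipped) 1/(N-1) mixed-moment correlation instead of the
        standard excess kurtosis / clipped correlation.

    Returns
    -------
    (15,) array ordered mean_xyz, std_xyz, kurt_xyz, crest_xyz,
    corr_xy, corr_xz, corr_yz.  Correlations use the 1/(N-1) mixed moment
    over population sds, which can exceed |1| slightly; by default they are
    clipped to [-1, 1].
    """
    a = np.asarray(acc_xyz, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 3:
        a = np.stack([np.asarray(v, dtype=np.float64) for v in acc_xyz], axis=1)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for accelerometer statistics")
    stats = [_axis_stats(a[:, j], "xyz"[j], printed_forms) for j in range(3)]
    means, stds, kurts, crests = (np.array(s) for s in zip(*stats))
    corrs = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        c = np.sum((a[:, i] - means[i]) * (a[:, j] - means[j])) / (n - 1) / (stds[i] * stds[j])
        corrs.append(c if printed_forms else float(np.clip(c, -1.0, 1.0)))
    return np.concatenate([means, stds, kurts, crests, corrs])


def _pipeline_10hz(rec: RawRecording, plan: ResamplePlan, spec: ConversionSpec):
    """Convert + harmonize one recording; returns 10 Hz signals dict and labels."""
    sig700 = {
        "ecg": convert_signal("ecg", rec.streams["ecg"].values, spec),
        "emg": convert_signal("emg", rec.streams["emg"].values, spec),
        "resp": convert_signal("resp", rec.streams["resp"].values, spec),
        "bvp": upsample(convert_signal("bvp", rec.streams["bvp"].values, spec),
                        rec.streams["bvp"].rate_hz, plan),
        "acc_wrist": upsample(convert_signal("acc", rec.streams["acc_wrist"].values, spec),
                              rec.streams["acc_wrist"].rate_hz, plan),
    }
    out = {k: downsample_signal(v, plan) for k, v in sig700.items()}
    labels = downsample_labels(rec.labels, plan)
    n = min(min(len(v) for v in out.values()), len(labels))
    return {k: v[:n] for k, v in out.items()}, labels[:n]


def assemble_feature_matrix(
    recordings,
    peak_params: dict[str, PeakParams] | None = None,
    plan: ResamplePlan | None = None,
    conversion: ConversionSpec | None = None,
) -> FeatureDataset:
    """Full pipeline: raw recordings -> 28-column 10 Hz feature dataset.

    Each recording is unit-converted, harmonized to 700 Hz, aggregated to
    10 Hz, cut into complete minutes, and featurized: peak features per
    minute (per-minute detection threshold), accelerometer statistics per
    subject, each broadcast to the samples they summarize.  Rows whose
    mode-aggregated label is the -1 sentinel are removed.  Recordings
    shorter than one complete minute are excluded with a warning.
    """
    peak_params = {**DEFAULT_PEAK_PARAMS, **(peak_params or {})}
    plan = plan or ResamplePlan()
    conversion = conversion or ConversionSpec()
    mats, labs, subs = [], [], []
    for rec in recordings:
        rec.validate()
        sig, labels = _pipeline_10hz(rec, plan, conversion)
        n_min = len(labels) // SAMPLES_PER_MINUTE
        if n_min == 0:
            warn(f"recording {rec.subject_id!r} is shorter than one minute; excluded",
                 stacklevel=2)
            continue
        n = n_min * SAMPLES_PER_MINUTE
        cols = []
        for kind in ("ecg", "emg", "resp", "bvp"):
            x = sig[kind][:n]
            pp = peak_params[kind]
            peaks = np.concatenate([
                m * SAMPLES_PER_MINUTE
                + detect_peaks(x[m * SAMPLES_PER_MINUTE:(m + 1) * SAMPLES_PER_MINUTE], pp)
                for m in range(n_min)
            ]) if n_min else np.empty(0, dtype=np.int64)
            per_min = minute_peak_features(x, peaks, kind)
            cols.append(np.repeat(per_min, SAMPLES_PER_MINUTE, axis=0))
        accl = subject_accel_features(sig["acc_wrist"][:n])
        cols.append(np.broadcast_to(accl, (n, 15)))
        feats = np.hstack(cols)
        lab = labels[:n]
        ok = lab >= 0
        mats.append(feats[ok])
        labs.append(lab[ok])
        subs.append(np.full(int(ok.sum()), rec.subject_id))
    if not mats:
        return FeatureDataset(np.empty((0, len(FEATURE_COLUMNS))),
                              np.empty(0, dtype=np.int64), np.empty(0, dtype=np.str_))
    ds = FeatureDataset(np.vstack(mats), np.concatenate(labs), np.concatenate(subs))
    ds.validate()
    return ds
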