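"""Data model and on-disk formats for multimodal wearable recordings.

A recording couples a chest-worn unit (ECG, EMG, respiration, accelerometer,
EDA, temperature — all sampled at 700 Hz, raw 16-bit ADC units) with a
wrist-worn unit (blood volume pulse at 64 Hz, triaxial accelerometer at
32 Hz, EDA and temperature at 4 Hz) and a 700 Hz label stream over the five
state-of-mind classes.

The canonical on-disk container is HDF5 (one group per stream, sampling rate
as an attribute) because streams at mixed rates cannot share one rectangular
table.  A CSV bundle (one file per stream plus a JSON manifest) is supported
for inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Stream",
    "RawRecording",
    "FeatureDataset",
    "FormatError",
    "ConsistencyError",
    "CLASS_NAMES",
    "FEATURE_COLUMNS",
    "CHANNEL_BLOCKS",
    "CHEST_STREAMS",
    "WRIST_STREAMS",
    "MANDATORY_STREAMS",
    "NATIVE_RATES",
    "read_recording",
    "write_recording",
    "read_feature_dataset",
    "write_feature_dataset",
]

#: Class code -> condition name (codes 0..4; -1 marks unlabeled spans).
CLASS_NAMES = ("baseline", "amusement", "stress", "meditation", "recovery")

CHEST_STREAMS = ("ecg", "emg", "resp", "acc_chest", "eda_chest", "temp_chest")
WRIST_STREAMS = ("bvp", "acc_wrist", "eda_wrist", "temp_wrist")
#: EDA and temperature streams are optional in a recording; they are
#: converted but never fed to the classifier.
MANDATORY_STREAMS = ("ecg", "emg", "resp", "acc_chest", "bvp", "acc_wrist")

NATIVE_RATES = {
    "ecg": 700.0,
    "emg": 700.0,
    "resp": 700.0,
    "acc_chest": 700.0,
    "eda_chest": 700.0,
    "temp_chest": 700.0,
    "bvp": 64.0,
    "acc_wrist": 32.0,
    "eda_wrist": 4.0,
    "temp_wrist": 4.0,
}

LABEL_RATE_HZ = 700.0

#: Feature matrix columns in channel-block order (28 total).
FEATURE_COLUMNS = (
    # ECG block (4)
    "ecg_peaks", "ecg_avg_amplitude", "ecg_differ_mean", "ecg_resting",
    # EMG block (3)
    "emg_peaks", "emg_avg_amplitude", "emg_differ_mean",
    # RESP block (3)
    "resp_peaks", "resp_avg_amplitude", "resp_differ_mean",
    # BVP block (3)
    "bvp_peaks", "bvp_avg_amplitude", "bvp_differ_mean",
    # ACCL block (15): per-axis mean/sd/kurtosis/crest + pairwise correlations
    "accl_mean_x", "accl_mean_y", "accl_mean_z",
    "accl_std_x", "accl_std_y", "accl_std_z",
    "accl_kurt_x", "accl_kurt_y", "accl_kurt_z",
    "accl_crest_x", "accl_crest_y", "accl_crest_z",
    "accl_corr_xy", "accl_corr_xz", "accl_corr_yz",
)

#: Channel block -> number of feature columns, in matrix order.
CHANNEL_BLOCKS = {"ECG": 4, "EMG": 3, "RESP": 3, "BVP": 3, "ACCL": 15}


def channel_slices() -> dict[str, slice]:
    """Column slice of each channel block within the 28-column matrix."""
    out, start = {}, 0
    for name, width in CHANNEL_BLOCKS.items():
        out[name] = slice(start, start + width)
        start += width
    return out


class FormatError(ValueError):
    """A file does not declare the streams/fields the format requires."""


class ConsistencyError(ValueError):
    """Stream lengths, rates, or labels violate the recording invariants."""


@dataclass
class Stream:
    """One sensor stream: sampling rate plus a 1-D or (n, 3) value array."""

    rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ConsistencyError(f"sampling rate must be positive, got {self.rate_hz}")
        self.values = np.asarray(self.values)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class RawRecording:
    """One subject's multimodal raw streams plus the 700 Hz label stream."""

    subject_id: str
    streams: dict[str, Stream]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def duration_s(self) -> float:
        return len(self.labels) / LABEL_RATE_HZ

    @property
    def missing_optional(self) -> tuple[str, ...]:
        """Optional (EDA/temperature) streams absent from this recording."""
        optional = set(CHEST_STREAMS + WRIST_STREAMS) - set(MANDATORY_STREAMS)
        return tuple(sorted(optional - set(self.streams)))

    def validate(self) -> None:
        """Raise if the recording violates its invariants.

        Checks: all mandatory streams present; every stream length matches
        round(duration x rate) within one sample; labels as long as the
        700 Hz streams; chest streams are non-negative integers below 2^16;
        label codes in {-1, 0..4}.
        """
        for name in MANDATORY_STREAMS:
            if name not in self.streams:
                raise FormatError(f"mandatory stream '{name}' is missing")
        dur = self.duration_s
        for name, st in self.streams.items():
            expected = round(dur * st.rate_hz)
            if abs(len(st) - expected) > 1:
                raise ConsistencyError(
                    f"stream '{name}': length {len(st)} inconsistent with "
                    f"{st.rate_hz} Hz over {dur:.3f} s (expected ~{expected})"
                )
            if name in CHEST_STREAMS:
                v = st.values
                if not np.issubdtype(v.dtype, np.integer):
                    raise ConsistencyError(f"chest stream '{name}' must hold raw integer ADC units")
                if v.size and (v.min() < 0 or v.max() >= 2**16):
                    raise ConsistencyError(f"chest stream '{name}' has raw values outside [0, 2^16)")
        bad = np.setdiff1d(np.unique(self.labels), np.arange(-1, 5))
        if bad.size:
            raise ConsistencyError(f"labels contain invalid codes {bad.tolist()}")


@dataclass
class FeatureDataset:
    """Per-sample (10 Hz) feature matrix grouped into five channel blocks.

    ``features`` is (n_samples, 28) in :data:`FEATURE_COLUMNS` order;
    ``labels`` holds one class code per sample; ``subject_ids`` tags each
    sample with its subject (needed for leave-one-subject-out splits).
    """

    features: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    columns: tuple[str, ...] = field(default=FEATURE_COLUMNS)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64).reshape(-1, len(self.columns))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.str_)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def validate(self) -> None:
        if self.features.shape[1] != 28:
            raise ConsistencyError(f"expected 28 feature columns, got {self.features.shape[1]}")
        if not (len(self.labels) == self.n_samples == len(self.subject_ids)):
            raise ConsistencyError("features, labels and subject_ids disagree in length")
        if self.n_samples and not np.isfinite(self.features).all():
            raise ConsistencyError("feature matrix contains non-finite values")
        if self.n_samples and (self.labels.min() < 0 or self.labels.max() > 4):
            raise ConsistencyError("labels must be in 0..4")

    def block(self, name: str) -> np.ndarray:
        """The columns of one channel block, e.g. ``block('ECG')`` -> (n, 4)."""
        return self.features[:, channel_slices()[name]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.columns))
        df.insert(0, "subject_id", self.subject_ids)
        df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# RawRecording readers/writers
# ---------------------------------------------------------------------------

def write_recording(rec: RawRecording, path: str | Path, format: str = "hdf5") -> None:
    """Write a recording; layout: /streams/<name>/values (+rate_hz), /labels."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["subject_id"] = rec.subject_id
            g = f.create_group("streams")
            for name, st in rec.streams.items():
                sg = g.create_group(name)
                # track_times off keeps identical recordings byte-identical
                sg.create_dataset("values", data=st.values, track_times=False)
                sg.attrs["rate_hz"] = st.rate_hz
            f.create_dataset("labels", data=rec.labels, track_times=False)
    elif format == "csv_bundle":
        path.mkdir(parents=True, exist_ok=True)
        manifest = {"subject_id": rec.subject_id, "labels_file": "labels.csv", "streams": {}}
        for name, st in rec.streams.items():
            fn = f"{name}.csv"
            vals = st.values if st.values.ndim == 2 else st.values[:, None]
            cols = ["x", "y", "z"][: vals.shape[1]] if vals.shape[1] > 1 else ["value"]
            pd.DataFrame(vals, columns=cols).to_csv(path / fn, index=False, float_format="%.17g")
            manifest["streams"][name] = {"file": fn, "rate_hz": st.rate_hz, "n_axes": vals.shape[1]}
        pd.DataFrame({"label": rec.labels}).to_csv(path / "labels.csv", index=False)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path: str | Path, format: str = "hdf5") -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming any missing mandatory stream and
    :class:`ConsistencyError` on length/rate mismatches.  Missing optional
    streams (EDA, temperature) are permitted; see
    :attr:`RawRecording.missing_optional`.
    """
    path = Path(path)
    if format == "hdf5":
        if not path.exists():
            raise FileNotFoundError(path)
        with h5py.File(path, "r") as f:
            if "streams" not in f or "labels" not in f:
                raise FormatError(f"{path}: missing /streams or /labels")
            streams = {}
            for name, sg in f["streams"].items():
                if "rate_hz" not in sg.attrs:
                    raise FormatError(f"{path}: stream '{name}' lacks rate_hz attribute")
                streams[name] = Stream(float(sg.attrs["rate_hz"]), sg["values"][()])
            rec = RawRecording(str(f.attrs.get("subject_id", path.stem)), streams, f["labels"][()])
    elif format == "csv_bundle":
        mf = path / "manifest.json"
        if not mf.exists():
            raise FormatError(f"{path}: no manifest.json")
        manifest = json.loads(mf.read_text())
        streams = {}
        for name, meta in manifest["streams"].items():
            vals = pd.read_csv(path / meta["file"], float_precision="round_trip").to_numpy()
            if meta.get("n_axes", 1) == 1:
                vals = vals[:, 0]
            if name in CHEST_STREAMS:
                vals = np.round(vals).astype(np.int64)
            streams[name] = Stream(float(meta["rate_hz"]), vals)
        labels = pd.read_csv(path / manifest["labels_file"])["label"].to_numpy()
        rec = RawRecording(manifest["subject_id"], streams, labels)
    else:
        raise ValueError(f"unknown format {format!r}")
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# FeatureDataset readers/writers
# ---------------------------------------------------------------------------

def write_feature_dataset(ds: FeatureDataset, path: str | Path, format: str = "hdf5") -> None:
    """Persist a feature dataset (bit-exact for hdf5; %.17g text for csv)."""
    ds.validate()
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=ds.features)
            f.create_dataset("labels", data=ds.labels)
            f.create_dataset("subject_ids", data=ds.subject_ids.astype("S"))
            f.attrs["columns"] = list(ds.columns)
    elif format == "csv":
        ds.to_frame().to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_feature_dataset(path: str | Path, format: str = "hdf5") -> FeatureDataset:
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "features" not in f:
                raise FormatError(f"{path}: missing /features")
            ds = FeatureDataset(
                f["features"][()].reshape(-1, 28),
                f["labels"][()],
                f["subject_ids"][()].astype("U"),
                columns=tuple(f.attrs["columns"]),
            )
    elif format == "csv":
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
        cols = [c for c in df.columns if c not in ("subject_id", "label")]
        ds = FeatureDataset(
            df[cols].to_numpy(dtype=np.float64),
            df["label"].to_numpy() if len(df) else np.empty(0, dtype=np.int64),
            df["subject_id"].to_numpy(dtype=np.str_) if len(df) else np.empty(0, dtype=np.str_),
            columns=tuple(cols),
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    ds.validate()
    return ds
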