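"""Synthetic multimodal cohort generator with class-dependent physiology.

Produces recordings shaped like the chest+wrist wearable data this package
analyses: chest streams as raw 16-bit offset-binary ADC units at 700 Hz
(so unit conversion is on the tested path, midscale 2^15 being the zero
line), wrist streams at their native 64/32/4 Hz rates, and a 700 Hz label
stream following a per-class segment schedule.

Class identity is injected only through interpretable rate/amplitude
parameters: heart rate drives the ECG and BVP periodicity, respiration
rate the breathing sinusoid, an EMG burst rate the muscle-activity bumps,
and an activity scale the accelerometer variance.  ECG beats are narrow
von-Mises-shaped pulses (one local maximum per beat after aggregation to
10 Hz) — not morphologically realistic P-QRS-T complexes, which minute
peak counting does not require.

The default class proportions follow the published class distribution of
the WESAD benchmark (573,480 aggregated samples over five conditions);
per-subject duration defaults to 600 s, a desk-scale compromise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import CLASS_NAMES, RawRecording, Stream

__all__ = [
    "BENCHMARK_CLASS_COUNTS",
    "BENCHMARK_TOTAL_SAMPLES",
    "class_proportions",
    "minute_aligned_durations",
    "CohortParams",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]

#: Published per-class 10 Hz sample counts of the WESAD benchmark.
BENCHMARK_CLASS_COUNTS = {
    "baseline": 274_790,
    "amusement": 117_150,
    "stress": 65_450,
    "meditation": 37_090,
    "recovery": 79_000,
}
BENCHMARK_TOTAL_SAMPLES = sum(BENCHMARK_CLASS_COUNTS.values())  # 573,480


def class_proportions() -> np.ndarray:
    """Benchmark class shares (~0.479, 0.204, 0.114, 0.065, 0.138)."""
    counts = np.array([BENCHMARK_CLASS_COUNTS[c] for c in CLASS_NAMES], dtype=np.float64)
    return counts / counts.sum()


def minute_aligned_durations(total_s: float = 600.0) -> np.ndarray:
    """Per-class durations in whole minutes approximating the benchmark shares.

    Every class receives at least one minute; leftover minutes go to the
    classes with the largest fractional remainders.  Minute alignment keeps
    the minute-broadcast features of one class from bleeding into another.
    """
    n_min = int(total_s // 60)
    if n_min < len(CLASS_NAMES):
        raise ValueError("need at least one minute per class")
    ideal = class_proportions() * n_min
    alloc = np.maximum(np.floor(ideal), 1).astype(int)
    rem = ideal - np.floor(ideal)
    for i in np.argsort(-rem):
        if alloc.sum() >= n_min:
            break
        alloc[i] += 1
    while alloc.sum() > n_min:  # possible when the floor+minimum overshoots
        alloc[int(alloc.argmax())] -= 1
    return alloc * 60.0


@dataclass
class CohortParams:
    """Cohort size, class schedule and per-class signal physiology.

    Per-class arrays are ordered (baseline, amusement, stress, meditation,
    recovery).  Defaults keep every adjacent pair of classes separated by
    at least ~20% in heart rate or respiration rate so the downstream
    minute features are discriminative.
    """

    n_subjects: int = 15
    total_duration_s: float = 600.0
    #: explicit per-class segment durations (s); None -> benchmark
    #: proportions of ``total_duration_s``.
    class_durations_s: np.ndarray | None = None
    hr_bpm: tuple = (70.0, 80.0, 105.0, 55.0, 65.0)
    resp_bpm: tuple = (14.0, 18.0, 24.0, 7.0, 11.0)
    emg_bursts_per_min: tuple = (8.0, 15.0, 30.0, 3.0, 6.0)
    accel_activity_g: tuple = (0.05, 0.15, 0.25, 0.02, 0.08)
    temp_baseline_c: float = 33.0
    #: fractional sd of the per-subject multiplicative jitter on rates.
    subject_jitter_sd: float = 0.05
    #: raw-ADC noise sd for the chest streams.
    noise_sd_raw: float = 300.0
    ecg_pulse_amplitude_raw: float = 8000.0
    resp_amplitude_raw: float = 6000.0
    emg_burst_amplitude_raw: float = 2500.0
    bvp_amplitude: float = 40.0
    unlabeled_lead_s: float = 0.0
    include_optional_streams: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for hr in self.hr_bpm:
            if not 40 <= hr <= 200:
                raise ValueError(f"heart rate {hr} bpm outside the physiological 40-200 range")
        for rr in self.resp_bpm:
            if not 5 <= rr <= 40:
                raise ValueError(f"respiration rate {rr}/min outside the physiological 5-40 range")
        if self.class_durations_s is not None:
            self.class_durations_s = np.asarray(self.class_durations_s, dtype=np.float64)
            if (self.class_durations_s <= 0).any():
                raise ValueError("class durations must be positive")

    def durations(self) -> np.ndarray:
        if self.class_durations_s is not None:
            return self.class_durations_s
        return class_proportions() * self.total_duration_s


def _segment_ids(durations: np.ndarray, rate: float, lead_s: float) -> tuple[np.ndarray, np.ndarray]:
    """(per-sample class index incl. -1 lead, per-sample value) at ``rate``."""
    secs = np.concatenate([[lead_s], durations]) if lead_s > 0 else durations
    classes = np.arange(-1, 5) if lead_s > 0 else np.arange(5)
    bounds = np.round(np.cumsum(np.concatenate([[0.0], secs])) * rate).astype(int)
    lengths = np.diff(bounds)
    return np.repeat(classes, lengths), bounds[-1]


def _per_sample(values: tuple | np.ndarray, seg: np.ndarray) -> np.ndarray:
    """Broadcast per-class parameter values to samples; lead (-1) gets class 0's."""
    table = np.asarray(values, dtype=np.float64)
    return table[np.where(seg >= 0, seg, 0)]


def _pulse_train(f_hz: np.ndarray, rate: float, rng: np.random.Generator,
                 kappa: float = 50.0, phase_jitter: float = 0.02) -> np.ndarray:
    """Narrow periodic pulses (one peak per cycle) via a von-Mises waveform."""
    f = f_hz * (1.0 + phase_jitter * rng.standard_normal(len(f_hz)))
    phase = 2 * np.pi * np.cumsum(f) / rate
    return np.exp(kappa * (np.cos(phase) - 1.0))


def _sine(f_hz: np.ndarray, rate: float) -> np.ndarray:
    return np.sin(2 * np.pi * np.cumsum(f_hz) / rate)


def _chest_raw(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x), 0, 2**16 - 1).astype(np.int64)


def generate_subject(subject_id: str, params: CohortParams | None = None,
                     seed: int | None = None,
                     jitter: float | None = None) -> RawRecording:
    """One subject's recording; deterministic given (params, seed).

    ``jitter`` is the subject's multiplicative physiology factor; drawn
    from ``N(1, subject_jitter_sd)`` when omitted.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if jitter is None:
        jitter = float(1.0 + params.subject_jitter_sd * rng.standard_normal())
    jitter = float(np.clip(jitter, 0.7, 1.3))
    durations = params.durations()
    lead = params.unlabeled_lead_s

    hr = np.clip(np.asarray(params.hr_bpm) * jitter, 40, 200) / 60.0
    resp = np.clip(np.asarray(params.resp_bpm) * jitter, 5, 40) / 60.0
    burst_rate = np.asarray(params.emg_bursts_per_min) * jitter
    act_g = np.asarray(params.accel_activity_g) * jitter

    streams: dict[str, Stream] = {}

    # --- chest @ 700 Hz (raw ADC) ---------------------------------------
    seg700, n700 = _segment_ids(durations, 700.0, lead)
    mid = 2**15
    ecg = mid + params.ecg_pulse_amplitude_raw * _pulse_train(_per_sample(hr, seg700), 700.0, rng) \
        + params.noise_sd_raw * rng.standard_normal(n700)
    streams["ecg"] = Stream(700.0, _chest_raw(ecg))

    resp_sig = mid + params.resp_amplitude_raw * _sine(_per_sample(resp, seg700), 700.0) \
        + 200.0 * rng.standard_normal(n700)
    streams["resp"] = Stream(700.0, _chest_raw(resp_sig))

    emg = mid + 150.0 * rng.standard_normal(n700)
    width = int(0.2 * 700)
    bump = np.sin(np.linspace(0, np.pi, width))
    edges = np.round(np.cumsum(np.concatenate([[lead], durations])) * 700).astype(int)
    for c in range(5):
        lo, hi = edges[c], edges[c + 1]
        n_bursts = rng.poisson(burst_rate[c] * (hi - lo) / 700.0 / 60.0)
        for t0 in np.sort(rng.integers(lo, max(hi - width, lo + 1), size=n_bursts)):
            seg_len = min(width, n700 - t0)
            emg[t0:t0 + seg_len] += params.emg_burst_amplitude_raw * bump[:seg_len]
    streams["emg"] = Stream(700.0, _chest_raw(emg))

    acc_chest = mid + _per_sample(act_g, seg700)[:, None] * 2000.0 * rng.standard_normal((n700, 3))
    streams["acc_chest"] = Stream(700.0, _chest_raw(acc_chest))

    if params.include_optional_streams:
        streams["eda_chest"] = Stream(700.0, _chest_raw(
            28000 + 500 * rng.standard_normal(n700)))
        streams["temp_chest"] = Stream(700.0, _chest_raw(
            30000 + 100 * rng.standard_normal(n700)))

    # --- wrist ----------------------------------------------------------
    seg64, n64 = _segment_ids(durations, 64.0, lead)
    bvp = params.bvp_amplitude * _sine(_per_sample(hr, seg64), 64.0) \
        + 0.05 * params.bvp_amplitude * rng.standard_normal(n64)
    streams["bvp"] = Stream(64.0, bvp)

    seg32, n32 = _segment_ids(durations, 32.0, lead)
    sd = _per_sample(act_g, seg32)[:, None] * 64.0  # 1/64 g raw units
    common = rng.standard_normal((n32, 1))
    mix = np.array([0.6, 0.4, 0.2])  # shared motion -> nonzero axis correlations
    axes = mix * common + np.sqrt(1 - mix**2) * rng.standard_normal((n32, 3))
    acc_wrist = sd * axes + np.array([0.0, 0.0, 64.0])  # gravity on z
    streams["acc_wrist"] = Stream(32.0, acc_wrist)

    if params.include_optional_streams:
        _, n4 = _segment_ids(durations, 4.0, lead)
        streams["eda_wrist"] = Stream(4.0, 0.5 + 0.05 * rng.standard_normal(n4))
        streams["temp_wrist"] = Stream(
            4.0, params.temp_baseline_c * jitter + 0.05 * rng.standard_normal(n4))

    labels, _ = _segment_ids(durations, 700.0, lead)
    rec = RawRecording(subject_id, streams, labels)
    rec.validate()
    return rec


def generate_cohort(params: CohortParams | None = None) -> list[RawRecording]:
    """``n_subjects`` recordings with per-subject physiology jitter.

    Subject ids are S1..Sn; per-subject seeds derive deterministically from
    ``params.seed``.
    """
    params = params or CohortParams()
    base = np.random.default_rng(params.seed)
    seeds = base.integers(2**31, size=params.n_subjects)
    jitters = 1.0 + params.subject_jitter_sd * base.standard_normal(params.n_subjects)
    return [
        generate_subject(f"S{i + 1}", params, seed=int(seeds[i]), jitter=float(jitters[i]))
        for i in range(params.n_subjects)
    ]


def write_cohort(recordings: list[RawRecording], out_dir: str | Path,
                 params: CohortParams | None = None) -> list[Path]:
    """Write one HDF5 per recording plus a cohort manifest JSON."""
    from .io import write_recording

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        p = out_dir / f"{rec.subject_id}.h5"
        write_recording(rec, p)
        paths.append(p)
    manifest = {
        "subjects": [r.subject_id for r in recordings],
        "files": [p.name for p in paths],
    }
    if params is not None:
        manifest["params"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(params).items()
        }
    (out_dir / "cohort.json").write_text(json.dumps(manifest, indent=1))
    return paths
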