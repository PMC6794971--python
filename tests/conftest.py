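"""Shared fixtures: a small synthetic cohort, its features, and a trained model.

Session scope keeps the expensive artifacts (feature pipeline, network
training) computed once for the whole run.
"""

from __future__ import annotations

import numpy as np
import pytest

import wearstate as ws
from wearstate.synthetic import CohortParams, minute_aligned_durations


@pytest.fixture(scope="session")
def cohort_params() -> CohortParams:
    return CohortParams(
        n_subjects=3,
        class_durations_s=minute_aligned_durations(600.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(cohort_params):
    return ws.generate_cohort(cohort_params)


@pytest.fixture(scope="session")
def features(cohort):
    return ws.assemble_feature_matrix(cohort)


@pytest.fixture(scope="session")
def trained_type1(features):
    """Network trained on a Type I split of the 3-subject cohort."""
    spec = ws.build_model()
    plan = ws.split_type1(features.n_samples, seed=1)
    opt = ws.OptimizerConfig(epochs=5, batch_size=256)
    model = ws.train_model(spec, features, plan, opt, seed=1)
    return model, plan


def brute_force_peaks(x: np.ndarray, threshold_k: float, min_distance: int) -> list[int]:
    """Independent exhaustive peak oracle: scan all local maxima above the
    mean + k*sd threshold, then keep larger-amplitude peaks greedily
    (ties -> earlier index) under the refractory distance."""
    x = np.asarray(x, dtype=float)
    thr = x.mean() + threshold_k * x.std()
    cands = [
        i for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] >= x[i + 1] and x[i] > thr
    ]
    chosen: list[int] = []
    for i in sorted(cands, key=lambda i: (-x[i], i)):
        if all(abs(i - j) >= min_distance for j in chosen):
            chosen.append(i)
    return sorted(chosen)
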