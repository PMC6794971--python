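"""Sequential model-based hyperparameter optimization with expected improvement.

A Gaussian-process surrogate (Matern-5/2 kernel) is fitted to the observed
(hyperparameter, objective) pairs; each iteration scores a quasi-random
candidate set with the expected-improvement acquisition

    EI(x) = E[max(f(x) - f*, 0)]
          = (mu - f*) Phi(z) + sigma phi(z),   z = (mu - f*) / sigma,

where f* is the best objective observed so far, and evaluates the
maximizer.  The objective is *maximized* (e.g. validation accuracy).  The
default search space covers the four Adam hyperparameters that were tuned
for this model: learning rate (log scale), beta_1, beta_2 and decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["Dimension", "HyperSpace", "SMBOResult", "expected_improvement", "smbo_search"]


@dataclass
class Dimension:
    """One search dimension; ``log=True`` samples uniformly in log10 space."""

    name: str
    low: float
    high: float
    log: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: lower bound must be below upper")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log-scale bounds must be positive")

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        if self.log:
            lo, hi = np.log10(self.low), np.log10(self.high)
            return 10 ** (lo + u * (hi - lo))
        return self.low + u * (self.high - self.low)


@dataclass
class HyperSpace:
    """Search space plus the evaluation budget.

    Defaults are the bounds used to tune the optimizer hyperparameters:
    learning_rate in [1e-5, 1e-2] (log), beta_1 in [0.8, 0.999],
    beta_2 in [0.8, 0.9999], decay in [0, 1e-3].
    """

    dimensions: list[Dimension] = field(default_factory=lambda: [
        Dimension("learning_rate", 1e-5, 1e-2, log=True),
        Dimension("beta_1", 0.8, 0.999),
        Dimension("beta_2", 0.8, 0.9999),
        Dimension("decay", 0.0, 1e-3),
    ])
    n_initial: int = 8
    n_iterations: int = 20
    seed: int = 0
    n_candidates: int = 1024

    def __post_init__(self) -> None:
        if self.n_initial < 2:
            raise ValueError("n_initial must be >= 2")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")

    def to_params(self, u_row: np.ndarray) -> dict[str, float]:
        return {d.name: float(d.from_unit(np.asarray(u))) for d, u in zip(self.dimensions, u_row)}


def expected_improvement(mu, sigma, f_star: float) -> np.ndarray:
    """Closed-form EI of a Gaussian surrogate prediction over best-so-far.

    Vectorized over ``mu``/``sigma``; ``sigma = 0`` degenerates to
    ``max(mu - f_star, 0)``.  Always >= 0.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if (sigma < 0).any():
        raise ValueError("sigma must be non-negative")
    imp = mu - f_star
    out = np.maximum(imp, 0.0)
    pos = sigma > 0
    z = np.divide(imp, sigma, out=np.zeros_like(mu), where=pos)
    ei = imp * norm.cdf(z) + sigma * norm.pdf(z)
    return np.where(pos, np.maximum(ei, 0.0), out)


@dataclass
class SMBOResult:
    best_params: dict[str, float]
    best_value: float
    trace: pd.DataFrame


def smbo_search(objective, space: HyperSpace | None = None) -> SMBOResult:
    """Maximize ``objective(params_dict)`` under the sequential GP/EI loop.

    The initial design is a seeded Latin hypercube of ``n_initial`` points;
    each of the ``n_iterations`` steps fits the GP to all successful
    evaluations, scores ``n_candidates`` Sobol points by EI and evaluates
    the best.  An objective that raises is recorded as a failed point and
    the search continues.  Identical seeds give identical traces.
    """
    space = space or HyperSpace()
    d = len(space.dimensions)
    rng = np.random.default_rng(space.seed)

    U = qmc.LatinHypercube(d, seed=space.seed).random(space.n_initial)
    rows, X_ok, y_ok = [], [], []

    def evaluate(u_row: np.ndarray, phase: str, iteration: int) -> None:
        params = space.to_params(u_row)
        try:
            val = float(objective(params))
            failed = False
        except Exception:
            val, failed = np.nan, True
        rows.append({"iteration": iteration, "phase": phase, **params,
                     "objective": val, "failed": failed})
        if not failed and np.isfinite(val):
            X_ok.append(u_row)
            y_ok.append(val)

    for i in range(space.n_initial):
        evaluate(U[i], "initial", i)

    sobol = qmc.Sobol(d, scramble=True, seed=space.seed + 1)
    for it in range(space.n_iterations):
        if len(X_ok) >= 2:
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.3), nu=2.5)
                + WhiteKernel(1e-6, noise_level_bounds=(1e-12, 1e-1)),
                normalize_y=True,
                random_state=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                # near-noise-free observations routinely pin the GP noise
                # at its bound; harmless for an acquisition surrogate
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.filterwarnings("ignore", message="Predicted variances smaller")
                gp.fit(np.asarray(X_ok), np.asarray(y_ok))
                cand = sobol.random(space.n_candidates)
                mu, sd = gp.predict(cand, return_std=True)
            ei = expected_improvement(mu, sd, max(y_ok))
            u_next = cand[int(ei.argmax())]
        else:  # everything failed so far: keep exploring at random
            u_next = rng.random(d)
        evaluate(u_next, "smbo", space.n_initial + it)

    trace = pd.DataFrame(rows)
    ok = trace[~trace["failed"]]
    if ok.empty:
        raise RuntimeError("every objective evaluation failed")
    best = ok.loc[ok["objective"].idxmax()]
    best_params = {dim.name: float(best[dim.name]) for dim in space.dimensions}
    return SMBOResult(best_params, float(best["objective"]), trace)
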