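"""Bayesian sequential model-based optimization with expected improvement.

A Gaussian-process surrogate over the observed (hyperparameter, score)
pairs proposes the next point by maximizing EI(x) = E[max(f(x) - f*, 0)].
Here the objective is a cheap analytic stand-in; swap in a closure that
trains the network and returns validation accuracy for the real search
(see wearstate.cli's `smbo` subcommand).
"""

import numpy as np

from wearstate import Dimension, HyperSpace, smbo_search


def objective(params):
    # peak at learning_rate ~ 1e-3, beta_1 ~ 0.95
    return -(np.log10(params["learning_rate"]) + 3) ** 2 - 50 * (params["beta_1"] - 0.95) ** 2


space = HyperSpace(
    dimensions=[Dimension("learning_rate", 1e-5, 1e-2, log=True),
                Dimension("beta_1", 0.8, 0.999)],
    n_initial=6, n_iterations=15, seed=2,
)
result = smbo_search(objective, space)

print(result.trace[["iteration", "phase", "learning_rate", "beta_1", "objective"]]
      .round(5).to_string(index=False))
print(f"\nbest: {result.best_params} -> {result.best_value:.5f}")
print("The search concentrates evaluations near the optimum after the "
      "initial Latin-hypercube design.")
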