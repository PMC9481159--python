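"""Simulate a three-cluster multi-omics mixture and recover the clusters.

Generates 150 samples from a mixture of three Bayesian networks over 20
continuous and 5 binary nodes at medium separation, fits the mixture
model by EM, and compares recovered assignments to the truth.
"""

import numpy as np

from mixnets import FitConfig, SimulationConfig, ari, fit, generate_mixture

bundle = generate_mixture(SimulationConfig(
    K=3, n_c=20, n_b=5, cluster_sizes=(50, 50, 50), preset="medium", seed=0))
print(f"dataset: {bundle.dataset.n_samples} samples x "
      f"{bundle.dataset.n_features} features, "
      f"achieved structural separation eta = {bundle.achieved_eta:.2f}")

result = fit(bundle.dataset, K=3, config=FitConfig(patience=30), seed=100)
model = result.model
print(f"log-likelihood {model.loglik:.1f}, AIC {model.aic:.1f}, "
      f"BIC {model.bic:.1f} after {model.n_outer_iterations} outer iterations")
print("mixture weights:", np.round(model.tau, 3))
print(f"ARI vs ground truth: {ari(result.memberships.hard, bundle.labels):.3f}")
# ARI near 1 means the latent clusters were recovered almost perfectly;
# the mixture weights should sit near the simulated 1/3 each.
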