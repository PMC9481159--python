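# mixnets

Unsupervised clustering of multi-omics patient samples with **mixtures of
Bayesian networks** — and, jointly, the cluster-specific networks
themselves.

Most multi-omics clustering tools group samples by differences in means or
covariance summaries. `mixnets` targets the setting where sample groups
differ in their *interaction structure*: each latent group k is modeled as
a Bayesian network B_k = (G_k, θ_k) over the same mixed set of omics
features — binary (mutations, M), ordinal (copy number, CN) and continuous
(transcripts T, proteins P, phosphosites PP) — and samples arise from the
mixture

    D_i | (Z_i = k)  ~  B_k = (G_k, θ_k),      k = 1..K with weights τ_k.

Continuous nodes follow linear-Gaussian local models given their parents,
binary nodes are Bernoulli(λ), ordinal nodes marginal Gaussians; discrete
nodes may be parents of continuous nodes but never children. An EM
algorithm alternates MAP structure search per cluster (order MCMC with the
BGe marginal-likelihood score on soft-weighted sufficient statistics) with
parameter/membership updates; after convergence, DAGs are sampled from
each cluster's structure posterior to give per-edge posterior
probabilities and consensus networks. Prior knowledge enters through a
blacklist of forbidden edges (e.g. only central-dogma directions) and an
edge penalization matrix κ built from interaction databases
(STRING/Omnipath style): edges missing from the databases are penalized by
a factor of 2 (or `2 − 2·score` for weak evidence), shared across all
clusters.

The package is aimed at methodologists and computational biologists who
want patient subtypes with a mechanistic readout: who is in which group,
*and* which gene–gene dependencies define each group.

## Worked example

```python
from mixnets import FitConfig, SimulationConfig, ari, fit, generate_mixture

bundle = generate_mixture(SimulationConfig(
    K=3, n_c=20, n_b=5, cluster_sizes=(50, 50, 50), preset="medium", seed=0))
result = fit(bundle.dataset, K=3, config=FitConfig(patience=30), seed=100)
print(round(result.model.loglik, 1), round(result.model.bic, 1))
print(round(ari(result.memberships.hard, bundle.labels), 3))
```

prints

```
-4565.5 10569.0
0.94
```

The simulated cohort has 150 samples from three Bayesian networks whose
structures differ in ~20% of edges ("medium" separation, where
mean-based clustering largely fails); the fitted mixture recovers the
latent groups with adjusted Rand index 0.94, and `result.model.dags`
holds the three learned networks. The scripts in `examples/` walk
through the other capabilities: posterior edge sampling and consensus
graphs, database-driven edge penalization, and BIC selection of the
number of clusters.

A thin CLI mirrors the library (`mixnets simulate | fit | select-k |
evaluate | consensus`) for shell-based runs on TSV matrices bound by a
small YAML manifest; see `mixnets --help`.

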