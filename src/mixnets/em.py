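"""EM algorithm for the Bayesian-network mixture model.

Each of K mixture components is a Bayesian network over the same mixed
set of nodes: Bernoulli parameters for binary nodes, marginal Gaussians
for ordinal nodes (consumed as reals), and linear-Gaussian local models
for continuous nodes given their parents.  The EM loop alternates MAP
structure search per cluster (given soft membership weights) with inner
cycles of parameter M-steps and membership E-steps; memberships are
initialized from a Gaussian-mixture fit on the leading principal
components.  AIC/BIC over the fitted models select the number of
clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .data_model import Dag, OmicsDataset, zero_variance_columns
from .scoring import ScoringConfig, weighted_suffstats
from .structure import (EdgePosteriors, SearchConfig, init_search_space,
                        map_search, sample_edge_posteriors)

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-3


@dataclass
class ComponentParams:
    """Parameters of one mixture component's local distributions.

    ``lam`` holds Bernoulli success probabilities over binary nodes
    (pseudocounted, strictly inside (0, 1)); ``m`` and ``sigma`` intercepts
    and residual/marginal SDs over ordinal+continuous nodes (indexed by
    node); ``beta[node]`` maps each parent of ``node`` to its regression
    coefficient.
    """

    lam: dict[int, float]
    m: dict[int, float]
    sigma: dict[int, float]
    beta: dict[int, dict[int, float]]


@dataclass
class MixtureModel:
    K: int
    tau: np.ndarray
    dags: list[Dag]
    params: list[ComponentParams]
    loglik: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    n_outer_iterations: int = 0
    seed: int | None = None
    restarts: int = 1


@dataclass
class MembershipWeights:
    gamma: np.ndarray  # N x K, rows sum to 1

    @property
    def hard(self) -> np.ndarray:
        return np.argmax(self.gamma, axis=1)


@dataclass
class FitConfig:
    """EM control knobs.

    ``q`` inner parameter/E cycles per structure update; the outer loop
    stops on relative log-likelihood change below ``tol`` or after
    ``max_outer`` iterations.  ``em_chain_factor`` shortens the order-MCMC
    chains used inside the EM loop relative to the final pass.
    """

    q: int = 10
    tol: float = 1e-6
    max_outer: int = 30
    patience: int = 4
    restarts: int = 1
    estimator: str = "map"
    sample_posteriors: bool = False
    posterior_samples: int = 500
    em_chain_factor: float = 0.5
    search: SearchConfig = field(default_factory=SearchConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)


def init_memberships(dataset: OmicsDataset, K: int,
                     seed: int | np.random.Generator) -> MembershipWeights:
    """Soft memberships from model-based clustering on K+2 principal components.

    The data are projected onto the first K+2 principal components and a
    K-component full-covariance Gaussian mixture (best of 5 seeded
    initializations) provides hard labels g_i; the soft weights are
    3/(K+2) for the assigned cluster and 1/(K+2) otherwise, normalized.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    N = dataset.n_samples
    if N <= K:
        raise ValueError("need more samples than clusters")
    if K == 1:
        return MembershipWeights(np.ones((N, 1)))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_comp = min(K + 2, N, dataset.n_features)
    if n_comp < K + 2:
        warnings.warn(f"only {n_comp} principal components available "
                      f"(requested {K + 2})")
    x = dataset.values
    pcs = PCA(n_components=n_comp,
              random_state=int(rng.integers(2**31 - 1))).fit_transform(x)
    gmm = GaussianMixture(n_components=K, covariance_type="full",
                          n_init=5, reg_covar=1e-4,
                          random_state=int(rng.integers(2**31 - 1)))
    g = gmm.fit_predict(pcs)
    gamma = np.full((N, K), 1.0 / (K + 2))
    gamma[np.arange(N), g] = 3.0 / (K + 2)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return MembershipWeights(gamma)


def m_step_params(dataset: OmicsDataset, weights: np.ndarray, dag: Dag,
                  scoring: ScoringConfig | None = None,
                  estimator: str = "map") -> ComponentParams:
    """MAP (or ML) parameter estimates for one component.

    With ``estimator="map"`` (default), parameters are conjugate
    posterior modes, so each M-step exactly maximizes the EM surrogate
    plus log prior and MAP-EM ascends the penalized likelihood: binary
    rates are pseudocounted, ``(sum_i gamma_i x_i + 1)/(sum_i gamma_i + 2)``
    (the Beta(2, 2) mode); regression coefficients solve a
    ridge-regularized weighted least squares with prior precision
    ``t_scale * I`` from the scoring prior; residual variances are
    inverse-gamma posterior modes.  ``estimator="mle"`` drops the priors
    (weighted maximum likelihood), under which the observed-data
    log-likelihood is non-decreasing across E/M cycles.
    """
    if estimator not in ("map", "mle"):
        raise ValueError("estimator must be 'map' or 'mle'")
    x = dataset.values
    w = np.asarray(weights, dtype=float)
    ess = float(w.sum())
    if ess <= 0:
        raise ValueError("all-zero weights: empty cluster")
    omega, phi, psi = dataset.partition()
    cfg = (scoring or ScoringConfig()).resolve(dataset.n_features)
    use_map = estimator == "map"
    t = cfg.t_scale if use_map else 0.0
    # inverse-gamma prior aligned with the Wishart marginal: for a node
    # with p parents, shape a0 = (alpha_w - n + p + 1)/2, scale b0 = t/2
    a_base = cfg.alpha_w - cfg.n

    if use_map:
        lam = {int(j): float((w @ x[:, j] + 1.0) / (ess + 2.0))
               for j in omega}
    else:
        lam = {int(j): float(np.clip(w @ x[:, j] / ess, 1e-12, 1 - 1e-12))
               for j in omega}
    m: dict[int, float] = {}
    sigma: dict[int, float] = {}
    beta: dict[int, dict[int, float]] = {}
    if ess < 2.0:
        warnings.warn(f"effective sample size {ess:.2f} < 2; "
                      "variances floored")

    psi_set = set(psi.tolist())
    for j in np.concatenate([phi, psi]).astype(int):
        j = int(j)
        pa = sorted(dag.parents(j)) if j in psi_set else []
        mean_j = float(w @ x[:, j] / ess)
        p = len(pa)
        penalty = 0.0
        if not pa:
            m[j] = mean_j
            rss = float(w @ (x[:, j] - mean_j) ** 2)
        else:
            xp = x[:, pa]
            mp = w @ xp / ess
            xc = xp - mp
            yc = x[:, j] - mean_j
            xtw = xc.T * w
            gram = xtw @ xc + max(t, 1e-10) * np.eye(p)
            coef = np.linalg.solve(gram, xtw @ yc)
            beta[j] = {int(s): float(c) for s, c in zip(pa, coef)}
            m[j] = mean_j - float(mp @ coef)
            resid = yc - xc @ coef
            rss = float(w @ resid ** 2)
            penalty = t * float(coef @ coef)
        if use_map:
            a0 = 0.5 * (a_base + p + 1.0)
            b0 = 0.5 * t
            var = (2.0 * b0 + rss + penalty) / (2.0 * a0 + ess + p + 2.0)
        else:
            var = rss / ess
        sigma[j] = float(max(np.sqrt(var), SIGMA_FLOOR))
    return ComponentParams(lam, m, sigma, beta)


def log_parameter_prior(params: ComponentParams, n: int,
                        scoring: ScoringConfig | None = None) -> float:
    """log prior density of component parameters under the conjugate priors.

    Beta(2, 2) on each Bernoulli rate; normal-inverse-gamma on each
    (beta, sigma^2) pair with prior precision ``t_scale`` and the
    Wishart-aligned inverse-gamma shape; flat on intercepts.  The MAP-EM
    objective ``observed loglik + sum_k log prior`` is non-decreasing
    under the default M-step.
    """
    from scipy.stats import beta as beta_dist

    cfg = (scoring or ScoringConfig()).resolve(n)
    t = cfg.t_scale
    a_base = cfg.alpha_w - cfg.n
    total = 0.0
    for lam in params.lam.values():
        total += float(beta_dist.logpdf(lam, 2, 2))
    for j, s in params.sigma.items():
        var = s * s
        p = len(params.beta.get(j, {}))
        a0 = 0.5 * (a_base + p + 1.0)
        b0 = 0.5 * t
        # inverse-gamma log-density (unnormalized constants included)
        total += (a0 * np.log(b0) - lgamma_(a0)
                  - (a0 + 1.0) * np.log(var) - b0 / var)
        if p:
            coefs = np.array(list(params.beta[j].values()))
            total += (0.5 * p * np.log(t / (2 * np.pi * var))
                      - 0.5 * t * float(coefs @ coefs) / var)
    return total


def lgamma_(x: float) -> float:
    from math import lgamma
    return lgamma(x)


def component_loglik(dataset: OmicsDataset | np.ndarray, dag: Dag,
                     params: ComponentParams,
                     partition: tuple | None = None) -> np.ndarray:
    """Per-sample log-likelihood log P(D_i | G, theta).

    Sums conditional-Gaussian terms for continuous nodes given their
    observed parent values, marginal Gaussians for ordinal nodes and
    Bernoulli terms for binary nodes.  Returns a vector over samples.
    """
    if isinstance(dataset, OmicsDataset):
        x = dataset.values
        omega, phi, psi = dataset.partition()
    else:
        x = np.asarray(dataset, float)
        if partition is None:
            raise ValueError("partition required for raw arrays")
        omega, phi, psi = partition
    out = np.zeros(x.shape[0])
    log2pi = np.log(2 * np.pi)
    for j, lam in params.lam.items():
        xj = x[:, j]
        out += xj * np.log(lam) + (1 - xj) * np.log1p(-lam)
    for j in np.concatenate([phi, psi]).astype(int):
        j = int(j)
        mu = params.m[j]
        bj = params.beta.get(j)
        if bj:
            pa = sorted(bj)
            mu = mu + x[:, pa] @ np.array([bj[s] for s in pa])
        s = params.sigma[j]
        out += -0.5 * log2pi - np.log(s) - 0.5 * ((x[:, j] - mu) / s) ** 2
    return out


def _loglik_matrix(dataset: OmicsDataset, model: MixtureModel) -> np.ndarray:
    return np.column_stack([
        component_loglik(dataset, model.dags[k], model.params[k])
        for k in range(model.K)])


def e_step(dataset: OmicsDataset, model: MixtureModel,
           ) -> tuple[MembershipWeights, np.ndarray, float]:
    """Membership update in log space; returns (gamma, tau, observed loglik)."""
    ll = _loglik_matrix(dataset, model)  # N x K
    logw = ll + np.log(model.tau)[None, :]
    norm = logsumexp(logw, axis=1)
    gamma = np.exp(logw - norm[:, None])
    tau = gamma.mean(axis=0)
    return MembershipWeights(gamma), tau, float(norm.sum())


def observed_loglik(dataset: OmicsDataset, model: MixtureModel) -> float:
    ll = _loglik_matrix(dataset, model)
    return float(logsumexp(ll + np.log(model.tau)[None, :], axis=1).sum())


def information_criteria(model: MixtureModel, N: int,
                         n_b: int, n_o: int, n_c: int) -> tuple[float, float]:
    """AIC/BIC with d = sum_k (n_b + 2 n_o + 2 n_c + |E_k|) + (K - 1)."""
    d = sum(n_b + 2 * n_o + 2 * n_c + dag.n_edges for dag in model.dags)
    d += model.K - 1
    aic = -2.0 * model.loglik + 2.0 * d
    bic = -2.0 * model.loglik + d * np.log(N)
    return float(aic), float(bic)


@dataclass
class FitResult:
    model: MixtureModel
    memberships: MembershipWeights
    posteriors: list[EdgePosteriors] | None = None
    loglik_trace: list[float] = field(default_factory=list)


def _random_memberships(N: int, K: int,
                        rng: np.random.Generator) -> MembershipWeights:
    """Random hard labels passed through the same soft-weight rule."""
    g = rng.integers(K, size=N)
    gamma = np.full((N, K), 1.0 / (K + 2))
    gamma[np.arange(N), g] = 3.0 / (K + 2)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return MembershipWeights(gamma)


def _fit_once(dataset: OmicsDataset, K: int, config: FitConfig,
              penalization: np.ndarray | None,
              blacklist: np.ndarray | None,
              rng: np.random.Generator,
              random_init: bool = False) -> FitResult:
    N, n = dataset.n_samples, dataset.n_features
    omega, phi, psi = dataset.partition()
    discrete = np.concatenate([omega, phi])
    scoring = config.scoring
    em_search = SearchConfig(
        chain_factor=max(20, int(config.search.chain_factor
                                 * config.em_chain_factor)),
        burn_in=config.search.burn_in, moves=config.search.moves,
        max_candidates=config.search.max_candidates,
        max_expand=max(1, config.search.max_expand - 1))

    if random_init:
        memberships = _random_memberships(N, K, rng)
    else:
        memberships = init_memberships(dataset, K,
                                       int(rng.integers(2**31 - 1)))
    gamma = memberships.gamma
    tau = gamma.mean(axis=0)
    model = MixtureModel(K, tau, [Dag(n, discrete=discrete)] * K,
                         [None] * K)
    prev_ll = -np.inf
    prev_dags: list[Dag] | None = None
    trace: list[float] = []
    best_ll = -np.inf
    best_state = None
    stale = 0
    for outer in range(config.max_outer):
        # structure step per cluster, warm-started from the previous
        # cluster structure, under current soft weights
        dags = []
        for k in range(K):
            stats = weighted_suffstats(dataset, gamma[:, k])
            space = init_search_space(stats, scoring, penalization,
                                      blacklist, psi,
                                      em_search.max_candidates)
            warm = model.dags[k] if outer > 0 else None
            dag, _ = map_search(stats, scoring, penalization, space,
                                rng, blacklist=blacklist,
                                discrete=discrete, search=em_search,
                                init_dag=warm)
            dags.append(dag)
        model.dags = dags
        # q inner cycles of {M-step, E-step}
        ll = np.nan
        for _ in range(config.q):
            model.params = [m_step_params(dataset, gamma[:, k], dags[k],
                                          scoring, config.estimator)
                            for k in range(K)]
            model.tau = tau
            memberships, tau, ll = e_step(dataset, model)
            gamma = memberships.gamma
            trace.append(ll)
        model.tau = tau
        model.n_outer_iterations = outer + 1
        if (tau * N < 1.0).any():
            warnings.warn("cluster collapsed (tau_k * N < 1)")
        # keep the best state seen; MCMC noise in the structure step can
        # make the observed likelihood jitter between outer iterations
        if ll > best_ll + config.tol * abs(best_ll):
            best_ll = ll
            best_state = (list(dags), list(model.params), tau.copy(),
                          MembershipWeights(gamma.copy()), outer + 1)
            stale = 0
        else:
            stale += 1
        ll_stable = (np.isfinite(prev_ll)
                     and abs(ll - prev_ll) <= config.tol * abs(prev_ll))
        dags_stable = prev_dags is not None and all(
            d == p for d, p in zip(dags, prev_dags))
        prev_ll = ll
        prev_dags = dags
        if ll_stable or dags_stable or stale >= config.patience:
            break
    if best_state is not None:
        (model.dags, model.params, model.tau, memberships,
         model.n_outer_iterations) = best_state
    model.loglik = best_ll if best_state is not None else prev_ll
    model.aic, model.bic = information_criteria(
        model, N, len(omega), len(phi), len(psi))
    result = FitResult(model, memberships, loglik_trace=trace)
    if config.sample_posteriors:
        result.posteriors = posterior_sample_model(
            dataset, memberships, config, penalization, blacklist, rng)
    return result


def posterior_sample_model(dataset: OmicsDataset,
                           memberships: MembershipWeights,
                           config: FitConfig,
                           penalization: np.ndarray | None,
                           blacklist: np.ndarray | None,
                           rng: np.random.Generator | int,
                           ) -> list[EdgePosteriors]:
    """Per-cluster posterior edge sampling at the converged memberships."""
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    omega, phi, psi = dataset.partition()
    out = []
    for k in range(memberships.gamma.shape[1]):
        stats = weighted_suffstats(dataset, memberships.gamma[:, k])
        space = init_search_space(stats, config.scoring, penalization,
                                  blacklist, psi,
                                  config.search.max_candidates)
        out.append(sample_edge_posteriors(
            stats, config.scoring, penalization, space,
            config.posterior_samples, rng, search=config.search))
    return out


def fit(dataset: OmicsDataset, K: int,
        config: FitConfig | None = None,
        penalization: np.ndarray | None = None,
        blacklist: np.ndarray | None = None,
        seed: int | np.random.Generator = 0,
        restarts: int | None = None) -> FitResult:
    """Fit a K-component Bayesian-network mixture by EM.

    With ``restarts`` > 1 the EM is restarted from fresh initializations
    and the highest-likelihood run is returned.  A collapsed cluster
    (tau_k * N < 1) triggers a bounded number of re-seeded attempts.
    Deterministic given the seed.
    """
    config = config or FitConfig()
    zv = zero_variance_columns(dataset)
    if zv:
        raise ValueError(
            f"zero-variance ordinal/continuous columns (drop before fitting): "
            f"{[dataset.features[j].feature_id for j in zv]}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_runs = restarts if restarts is not None else config.restarts
    best: FitResult | None = None
    attempts = 0
    runs = 0
    while runs < n_runs and attempts < n_runs + 3:
        attempts += 1
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = _fit_once(dataset, K, config, penalization, blacklist,
                               rng, random_init=attempts > 1)
        collapsed = any("collapsed" in str(w.message) for w in caught)
        for w in caught:
            if "collapsed" not in str(w.message):
                warnings.warn_explicit(w.message, w.category, w.filename,
                                       w.lineno)
        if best is None or result.model.loglik > best.model.loglik:
            best = result
        if collapsed:
            # re-seeded attempt, bounded by the attempts budget
            logger.warning("cluster collapse; restarting with a fresh seed")
            continue
        runs += 1
    assert best is not None
    if isinstance(seed, int):
        best.model.seed = seed
    best.model.restarts = n_runs
    return best


def select_k(dataset: OmicsDataset, k_min: int, k_max: int,
             criterion: str = "bic",
             config: FitConfig | None = None,
             penalization: np.ndarray | None = None,
             blacklist: np.ndarray | None = None,
             seed: int = 0) -> tuple[list[dict], int, dict[int, FitResult]]:
    """Fit each K in [k_min, k_max]; return the score table and chosen K.

    The chosen K minimizes the requested criterion ("aic" or "bic").
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    rng = np.random.default_rng(seed)
    table, results = [], {}
    for K in range(k_min, k_max + 1):
        res = fit(dataset, K, config, penalization, blacklist, rng)
        results[K] = res
        table.append({"K": K, "loglik": res.model.loglik,
                      "aic": res.model.aic, "bic": res.model.bic})
    chosen = min(table, key=lambda r: r[criterion])["K"]
    return table, chosen, results
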