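"""BGe marginal-likelihood scoring for continuous nodes with mixed parents.

The network score decomposes over continuous nodes: each node contributes
the log marginal likelihood of its column given its parent columns under a
Normal-Wishart prior (the BGe score).  Binary and ordinal nodes never have
parents, so their terms are constant across structures and omitted; they
may still appear as parents, in which case their 0/1 or integer codes
enter the Gaussian sufficient statistics as real covariates.

To support soft EM membership weights, all sufficient statistics are
weighted: the effective sample size ``ess = sum_i w_i`` replaces the
integer sample count everywhere in the BGe formulas.  With 0/1 weights
this is exactly the ordinary score on the selected subsample.

The per-node score in ratio form, for node psi with parent set Pa of size
p, posterior scatter ``R = T + S_w`` (prior scatter ``T = t I``, prior
mean equal to the weighted sample mean so the mean-shift term vanishes):

    log S = 1/2 log(a_mu / (ess + a_mu)) - ess/2 log(pi)
          + lgamma((ess + a_w - n + p + 1)/2) - lgamma((a_w - n + p + 1)/2)
          + (a_w - n + p + 1)/2 log|T_Q| - (ess + a_w - n + p + 1)/2 log|R_Q|
          - (a_w - n + p)/2 log|T_Pa| + (ess + a_w - n + p)/2 log|R_Pa|

with Q = Pa + {psi}.  The score is equal for Markov-equivalent DAGs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, pi

import numpy as np

from .data_model import Dag, OmicsDataset


@dataclass(frozen=True)
class ScoringConfig:
    """Hyperparameters of the Normal-Wishart parameter prior.

    ``alpha_mu`` is the prior precision on the mean, ``alpha_w`` the
    Wishart degrees of freedom (must exceed n + 1 for a proper prior) and
    ``t_scale`` the isotropic prior scatter scale.  ``None`` values are
    resolved against the data dimension by :func:`resolve_config`.
    """

    alpha_mu: float = 1.0
    alpha_w: float | None = None  # default n + 2
    t_scale: float | None = None  # default alpha_mu*(alpha_w - n - 1)/(alpha_mu + 1)
    max_parents: int = 4

    def resolve(self, n: int) -> "ResolvedScoringConfig":
        aw = self.alpha_w if self.alpha_w is not None else n + 2.0
        if aw <= n + 1:
            raise ValueError(f"alpha_w={aw} must exceed n+1={n + 1}")
        t = (self.t_scale if self.t_scale is not None
             else self.alpha_mu * (aw - n - 1.0) / (self.alpha_mu + 1.0))
        if t <= 0:
            raise ValueError("t_scale must be positive")
        return ResolvedScoringConfig(self.alpha_mu, float(aw), float(t),
                                     int(self.max_parents), n)


@dataclass(frozen=True)
class ResolvedScoringConfig:
    alpha_mu: float
    alpha_w: float
    t_scale: float
    max_parents: int
    n: int


class SingularScatterError(ValueError):
    """Posterior scatter sub-matrix is singular (degenerate columns)."""


@dataclass
class WeightedSuffStats:
    """Weighted first/second moments of all n columns.

    ``mean = sum_i w_i x_i / ess``; ``scatter`` is the weighted centered
    scatter matrix ``sum_i w_i (x_i - mean)(x_i - mean)^T``.
    """

    ess: float
    mean: np.ndarray
    scatter: np.ndarray

    @property
    def n(self) -> int:
        return self.mean.shape[0]


def weighted_suffstats(dataset: OmicsDataset | np.ndarray,
                       weights: np.ndarray | None = None) -> WeightedSuffStats:
    """Weighted sufficient statistics of the observation matrix.

    Unit weights reduce to the ordinary sample mean and scatter.  All-zero
    weights (an empty cluster) raise ``ValueError``.
    """
    x = dataset.values if isinstance(dataset, OmicsDataset) else np.asarray(dataset, float)
    n_samples = x.shape[0]
    if weights is None:
        w = np.ones(n_samples)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_samples,):
            raise ValueError("weights length must equal the sample count")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
    ess = float(w.sum())
    if ess <= 0:
        raise ValueError("all-zero weights: empty cluster")
    mean = w @ x / ess
    xc = x - mean
    scatter = (xc * w[:, None]).T @ xc
    scatter = 0.5 * (scatter + scatter.T)  # enforce symmetry
    return WeightedSuffStats(ess, mean, scatter)


def _logdet_psub(mat: np.ndarray, idx: np.ndarray) -> float:
    """log-determinant of a positive-definite sub-matrix via Cholesky.

    Falls back to adding 1e-9 jitter once; raises SingularScatterError if
    still not positive definite.
    """
    if idx.size == 0:
        return 0.0
    sub = mat[np.ix_(idx, idx)]
    try:
        chol = np.linalg.cholesky(sub)
    except np.linalg.LinAlgError:
        try:
            chol = np.linalg.cholesky(sub + 1e-9 * np.eye(idx.size))
        except np.linalg.LinAlgError:
            raise SingularScatterError(
                f"singular posterior scatter for columns {idx.tolist()}")
    return 2.0 * float(np.log(np.diag(chol)).sum())


class BgeScorer:
    """Caches the posterior scatter and scores (node, parent-set) pairs."""

    def __init__(self, stats: WeightedSuffStats, config: ScoringConfig | ResolvedScoringConfig):
        self.stats = stats
        n = stats.n
        self.cfg = config.resolve(n) if isinstance(config, ScoringConfig) else config
        cfg = self.cfg
        self.ess = stats.ess
        # posterior scatter R = T + S_w (prior mean = weighted sample mean)
        self.R = cfg.t_scale * np.eye(n) + stats.scatter
        self.log_t = log(cfg.t_scale)
        # constant pieces per parent-set size p
        self._const_cache: dict[int, float] = {}

    def _const(self, p: int) -> float:
        # pieces depending only on |Pa| = p; A = alpha_w - n
        c = self._const_cache.get(p)
        if c is None:
            cfg, ess = self.cfg, self.ess
            a = cfg.alpha_w - cfg.n
            c = (0.5 * log(cfg.alpha_mu / (ess + cfg.alpha_mu))
                 - 0.5 * ess * log(pi)
                 + lgamma(0.5 * (ess + a + p + 1.0))
                 - lgamma(0.5 * (a + p + 1.0))
                 + 0.5 * (a + 2.0 * p + 1.0) * self.log_t)
            self._const_cache[p] = c
        return c

    def local_score(self, node: int, parents) -> float:
        """log BGe marginal likelihood of ``node`` given ``parents``."""
        pa = np.asarray(sorted(parents), dtype=int)
        p = pa.size
        if p > self.cfg.max_parents:
            raise ValueError(
                f"parent set size {p} exceeds max_parents={self.cfg.max_parents}")
        if node in pa:
            raise ValueError("node cannot be its own parent")
        cfg, ess = self.cfg, self.ess
        a = cfg.alpha_w - cfg.n
        q = np.append(pa, node)
        score = self._const(p)
        score -= 0.5 * (ess + a + p + 1.0) * _logdet_psub(self.R, q)
        if p:
            score += 0.5 * (ess + a + p) * _logdet_psub(self.R, pa)
        return score

    def batch_local_scores(self, node: int, subsets) -> np.ndarray:
        """Scores of many parent sets of one node, batched by subset size.

        Equivalent to ``[local_score(node, s) for s in subsets]`` but uses
        stacked Cholesky factorizations.
        """
        subsets = [tuple(sorted(int(v) for v in s)) for s in subsets]
        ess, a = self.ess, self.cfg.alpha_w - self.cfg.n
        out = np.empty(len(subsets))
        # group by parent-set size
        by_size: dict[int, list[int]] = {}
        for i, s in enumerate(subsets):
            if len(s) > self.cfg.max_parents:
                raise ValueError("parent set exceeds max_parents")
            if node in s:
                raise ValueError("node cannot be its own parent")
            by_size.setdefault(len(s), []).append(i)
        for p, idxs in by_size.items():
            q_idx = np.array([subsets[i] + (node,) for i in idxs], dtype=int)
            ld_q = self._batch_logdet(q_idx)
            val = (self._const(p) - 0.5 * (ess + a + p + 1.0) * ld_q)
            if p:
                pa_idx = np.array([subsets[i] for i in idxs], dtype=int)
                val += 0.5 * (ess + a + p) * self._batch_logdet(pa_idx)
            out[np.asarray(idxs)] = val
        return out

    def _batch_logdet(self, idx: np.ndarray) -> np.ndarray:
        """log-determinants of stacked principal sub-matrices of R."""
        sub = self.R[idx[:, :, None], idx[:, None, :]]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return np.array([_logdet_psub(self.R, row) for row in idx])
        return 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)


def local_bge_score(node: int, parents, stats: WeightedSuffStats,
                    config: ScoringConfig | ResolvedScoringConfig) -> float:
    """Convenience wrapper around :class:`BgeScorer` for one-off scores."""
    return BgeScorer(stats, config).local_score(node, parents)


def structure_log_score(dag: Dag, stats: WeightedSuffStats,
                        config: ScoringConfig | ResolvedScoringConfig,
                        penalization: np.ndarray | None = None,
                        psi: np.ndarray | None = None) -> float:
    """Penalized log structure score log R'(G | D).

    Sum of local BGe scores over continuous nodes minus ``log kappa`` for
    each edge present.  ``psi`` gives the continuous node indices; if
    omitted, every node with parents plus every node not flagged discrete
    is scored — callers should normally pass it explicitly.
    """
    scorer = BgeScorer(stats, config)
    if psi is None:
        psi = np.arange(dag.n)
    total = 0.0
    for node in np.asarray(psi, dtype=int):
        pa = dag.parents(int(node))
        total += scorer.local_score(int(node), pa)
        if penalization is not None:
            for s in pa:
                k = penalization[s, node]
                if k > 1.0:
                    total -= log(k)
    return total
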