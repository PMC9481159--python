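"""Synthetic Bayesian-network mixtures with controllable separation.

The generator emulates a multi-omics cohort drawn from a mixture of K
Bayesian networks over ``n_c`` continuous (Gaussian) and ``n_b`` binary
(Bernoulli) nodes, optionally ``n_o`` ordinal nodes.  Cluster separation
is controlled by two knobs: ``eta``, the fraction of edges rewired
between cluster DAGs (measured as pairwise SHD divided by edges per
DAG), and ``delta``, the fraction of continuous nodes whose means are
shifted between clusters.  The presets (small, medium, large) map to
(eta, delta) = (0.1, 0.0), (0.2, 0.03), (0.3, 0.05).

A companion routine simulates a prior interaction database from the
ground-truth structures with a stated false-discovery rate ``a`` and
false-negative rate ``b``, for benchmarking penalized structure priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (Dag, DataClass, FeatureDescriptor, OmicsDataset,
                         partition_indices)
from .em import ComponentParams, MixtureModel
from .priors import InteractionRecord, InteractionTable

SEPARATION_PRESETS = {
    "small": (0.1, 0.00),
    "medium": (0.2, 0.03),
    "large": (0.3, 0.05),
}


@dataclass
class SimulationConfig:
    """Ground-truth mixture settings.

    ``cluster_sizes`` gives the observation count per cluster (NZk).
    ``edges_per_node`` is the expected edge count per continuous node in
    the base DAG; ``shift`` the mean-shift magnitude applied to the
    delta-fraction of continuous nodes.
    """

    K: int = 3
    n_c: int = 20
    n_b: int = 5
    n_o: int = 0
    cluster_sizes: tuple[int, ...] | None = None  # default 50 per cluster
    edges_per_node: float = 3.0
    eta: float = 0.2
    delta: float = 0.03
    shift: float = 0.5
    beta_range: tuple[float, float] = (0.8, 1.8)
    lambda_range: tuple[float, float] = (0.05, 0.3)
    sigma: float = 1.0
    preset: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset is not None:
            if self.preset not in SEPARATION_PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}")
            self.eta, self.delta = SEPARATION_PRESETS[self.preset]
        if not (0 <= self.eta <= 1 and 0 <= self.delta <= 1):
            raise ValueError("eta and delta must lie in [0, 1]")
        if self.cluster_sizes is None:
            self.cluster_sizes = tuple([50] * self.K)
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        if len(self.cluster_sizes) != self.K:
            raise ValueError("cluster_sizes length must equal K")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")


@dataclass
class SimulationBundle:
    config: SimulationConfig
    dataset: OmicsDataset
    labels: np.ndarray
    truth: MixtureModel
    achieved_eta: float  # mean pairwise SHD / |E|
    features: list[FeatureDescriptor] = field(default_factory=list)


def _make_features(cfg: SimulationConfig) -> list[FeatureDescriptor]:
    feats = []
    for i in range(cfg.n_b):
        feats.append(FeatureDescriptor(f"G{i:03d}-M", f"G{i:03d}", "M",
                                       DataClass.BINARY))
    for i in range(cfg.n_o):
        feats.append(FeatureDescriptor(f"G{i + cfg.n_b:03d}-CN",
                                       f"G{i + cfg.n_b:03d}", "CN",
                                       DataClass.ORDINAL))
    off = cfg.n_b + cfg.n_o
    for i in range(cfg.n_c):
        feats.append(FeatureDescriptor(f"G{i + off:03d}-T", f"G{i + off:03d}",
                                       "T", DataClass.CONTINUOUS))
    return feats


def _random_base_edges(cfg: SimulationConfig, psi: np.ndarray,
                       rng: np.random.Generator) -> set[tuple[int, int]]:
    """Random DAG with edges only into continuous nodes.

    Continuous nodes take a random topological order; each legal
    (source, target) pair is included with probability chosen to hit an
    expected ``edges_per_node`` edges per continuous node.
    """
    n = cfg.n_b + cfg.n_o + cfg.n_c
    order = psi.copy()
    rng.shuffle(order)
    rank = {int(v): i for i, v in enumerate(order)}
    legal = []
    discrete = [j for j in range(n) if j not in rank]
    for t in psi:
        for s in discrete:
            legal.append((int(s), int(t)))
        for s in psi:
            if rank[int(s)] < rank[int(t)]:
                legal.append((int(s), int(t)))
    # cap density so eta-rewiring always has legal non-edges to draw from
    target_edges = cfg.edges_per_node * cfg.n_c
    p = min(0.7, target_edges / max(1, len(legal)))
    mask = rng.random(len(legal)) < p
    return {e for e, keep in zip(legal, mask) if keep}, rank


def _pairwise_shd(edge_sets: list[set[tuple[int, int]]]) -> float:
    tot, cnt = 0, 0
    for i in range(len(edge_sets)):
        for j in range(i + 1, len(edge_sets)):
            tot += len(edge_sets[i] ^ edge_sets[j])
            cnt += 1
    return tot / max(1, cnt)


def _rewire(base: set[tuple[int, int]], r: int, rank: dict[int, int],
            discrete: list[int], psi: np.ndarray,
            rng: np.random.Generator) -> set[tuple[int, int]]:
    """Delete r edges and add r new legal edges (order-respecting)."""
    edges = sorted(base)
    if r > len(edges):
        raise ValueError("rewiring amount exceeds available edges")
    drop_idx = rng.choice(len(edges), size=r, replace=False)
    kept = set(e for i, e in enumerate(edges) if i not in set(drop_idx.tolist()))
    legal = []
    for t in psi:
        for s in discrete:
            legal.append((int(s), int(t)))
        for s in psi:
            if rank[int(s)] < rank[int(t)]:
                legal.append((int(s), int(t)))
    pool = sorted(set(legal) - base)
    if r > len(pool):
        raise ValueError("not enough legal non-edges for rewiring")
    add_idx = rng.choice(len(pool), size=r, replace=False)
    return kept | {pool[i] for i in add_idx}


def generate_mixture(config: SimulationConfig) -> SimulationBundle:
    """Ground-truth mixture plus data sampled by ancestral sampling.

    Cluster DAGs are derived from a common base DAG by delete+add
    rewiring calibrated so that the achieved mean pairwise SHD divided by
    the edge count is within 0.05 of ``eta``; a ``delta`` fraction of
    continuous nodes get cluster-specific mean shifts of magnitude
    ``shift`` (cluster k is shifted by k * shift).  Deterministic given
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    feats = _make_features(cfg)
    omega, phi, psi = partition_indices(feats)
    discrete = sorted(set(omega.tolist()) | set(phi.tolist()))
    base, rank = _random_base_edges(cfg, psi, rng)
    n_edges = max(1, len(base))

    # calibrate the per-cluster rewiring amount to the eta target
    if cfg.eta == 0 or cfg.K == 1:
        cluster_edges = [set(base) for _ in range(cfg.K)]
        achieved = 0.0
    else:
        r = max(1, round(cfg.eta * n_edges / 4.0))
        best_sets, best_gap = None, np.inf
        for _ in range(30):
            cand = [_rewire(base, r, rank, discrete, psi, rng)
                    for _ in range(cfg.K)]
            ach = _pairwise_shd(cand) / n_edges
            gap = abs(ach - cfg.eta)
            if gap < best_gap:
                best_sets, best_gap, achieved = cand, gap, ach
            if gap <= 0.05:
                break
            r = max(1, r + (1 if ach < cfg.eta else -1))
        cluster_edges = best_sets

    # shared parameters on the base graph; per-edge coefficients redrawn
    # for rewired edges
    lam_lo, lam_hi = cfg.lambda_range
    lam = {int(j): float(rng.uniform(lam_lo, lam_hi)) for j in omega}
    b_lo, b_hi = cfg.beta_range

    def draw_beta() -> float:
        return float(rng.choice([-1.0, 1.0]) * rng.uniform(b_lo, b_hi))

    base_beta = {e: draw_beta() for e in sorted(base)}
    base_mean = {int(j): float(rng.normal(0.0, 1.0))
                 for j in np.concatenate([phi, psi])}

    n_shift = round(cfg.delta * cfg.n_c)
    shifted_nodes = (rng.choice(psi, size=n_shift, replace=False)
                     if n_shift else np.array([], dtype=int))

    dags, params = [], []
    for k, edges in enumerate(cluster_edges):
        dag = Dag(len(feats), sorted(edges), discrete=discrete)
        beta = {}
        for (s, t) in sorted(edges):
            b = base_beta.get((s, t))
            beta.setdefault(t, {})[s] = b if b is not None else draw_beta()
        m = dict(base_mean)
        for j in shifted_nodes:
            m[int(j)] = base_mean[int(j)] + cfg.shift * k
        sigma = {int(j): cfg.sigma for j in np.concatenate([phi, psi])}
        dags.append(dag)
        params.append(ComponentParams(dict(lam), m, sigma, beta))

    sizes = np.asarray(cfg.cluster_sizes)
    tau = sizes / sizes.sum()
    truth = MixtureModel(cfg.K, tau, dags, params, seed=cfg.seed)

    # ancestral sampling per cluster
    rows, labels = [], []
    for k in range(cfg.K):
        rows.append(_sample_component(dags[k], params[k], omega, phi, psi,
                                      int(sizes[k]), rng))
        labels.extend([k] * int(sizes[k]))
    values = np.vstack(rows)
    sample_ids = [f"S{i:04d}" for i in range(values.shape[0])]
    dataset = OmicsDataset(sample_ids, feats, values)
    ach_eta = (_pairwise_shd([set(d.edges) for d in dags]) / n_edges
               if cfg.K > 1 else 0.0)
    return SimulationBundle(cfg, dataset, np.asarray(labels), truth,
                            ach_eta, feats)


def _sample_component(dag: Dag, params: ComponentParams, omega, phi, psi,
                      size: int, rng: np.random.Generator) -> np.ndarray:
    n = dag.n
    x = np.zeros((size, n))
    for j in omega:
        x[:, j] = rng.random(size) < params.lam[int(j)]
    for j in phi:
        j = int(j)
        x[:, j] = np.round(rng.normal(params.m[j], params.sigma[j], size))
    # topological order over continuous nodes
    remaining = [int(j) for j in psi]
    done = set(int(j) for j in omega) | set(int(j) for j in phi)
    order = []
    while remaining:
        progress = False
        for j in list(remaining):
            if dag.parents(j) <= done:
                order.append(j)
                done.add(j)
                remaining.remove(j)
                progress = True
        if not progress:  # pragma: no cover - DAG guarantees progress
            raise RuntimeError("cycle in ground-truth DAG")
    for j in order:
        mu = np.full(size, params.m[j])
        for s in sorted(dag.parents(j)):
            mu += params.beta[j][s] * x[:, s]
        x[:, j] = rng.normal(mu, params.sigma[j])
    return x


def simulate_prior_db(truth_dags: list[Dag],
                      features: list[FeatureDescriptor],
                      a: float, b: float,
                      seed: int | np.random.Generator,
                      blacklist: np.ndarray | None = None,
                      additive: bool = False) -> InteractionTable:
    """Simulated interaction database with FDR ``a`` and FNR ``b``.

    Takes the union U of edges over the ground-truth DAGs, drops
    ``round(b |U|)`` of them (false negatives), then adds false edges
    from the non-true, non-blacklisted pool: ``round(a/(1-a) |kept|)`` so
    the realized fraction of false records is ``a`` (or ``round(a |U|)``
    when ``additive``).  Records are returned as undirected, unscored
    gene pairs.
    """
    if not (0 <= a < 1 and 0 <= b < 1):
        raise ValueError("a and b must lie in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    union: set[tuple[int, int]] = set()
    for dag in truth_dags:
        union |= set(dag.edges)
    u = sorted(union)
    n_drop = round(b * len(u))
    if n_drop:
        drop = set(rng.choice(len(u), size=n_drop, replace=False).tolist())
        kept = [e for i, e in enumerate(u) if i not in drop]
    else:
        kept = list(u)
    # pool of candidate false edges at gene-pair level
    true_pairs = {frozenset((features[s].gene, features[t].gene))
                  for s, t in union}
    kept_pairs = []
    seen = set()
    for s, t in kept:
        key = frozenset((features[s].gene, features[t].gene))
        if key not in seen:
            seen.add(key)
            kept_pairs.append((features[s].gene, features[t].gene))
    n_false = (round(a * len(u)) if additive
               else round(a / (1.0 - a) * len(kept_pairs)))
    n = len(features)
    pool = []
    genes_seen = set()
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            if blacklist is not None and blacklist[s, t]:
                continue
            key = frozenset((features[s].gene, features[t].gene))
            if key in true_pairs or key in genes_seen or len(key) < 2:
                continue
            genes_seen.add(key)
            pool.append((features[s].gene, features[t].gene))
    if n_false > len(pool):
        raise ValueError("not enough non-true edges to reach the requested FDR")
    records = [InteractionRecord(ga, gb) for ga, gb in kept_pairs]
    if n_false:
        idx = rng.choice(len(pool), size=n_false, replace=False)
        records.extend(InteractionRecord(*pool[i]) for i in idx)
    return InteractionTable(records)
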