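"""MAP structure search and posterior edge sampling by order MCMC.

The search runs a Metropolis chain over orderings of the continuous
nodes (discrete nodes never have parents, so they implicitly precede
everything).  Conditional on an order, each continuous node's parent set
ranges over pre-scored candidate subsets compatible with the order; the
order score marginalizes (log-sum-exp) over those subsets, the MAP score
maximizes over them.  Restricting parents to per-node candidate sets --
the strongest single parents plus any parents left unpenalized by the
prior -- keeps the subset tables small; the search is made less greedy by
iteratively re-ranking candidates around the current best graph.

Posterior edge probabilities are estimated by sampling one DAG per
retained order (per node, a parent set drawn proportionally to its
exponentiated score) and averaging edge indicators over the L draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import log

import numpy as np

from .data_model import Dag
from .priors import is_trivial_penalization
from .scoring import BgeScorer, ResolvedScoringConfig, ScoringConfig, WeightedSuffStats


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the order-MCMC structure search.

    ``chain_factor`` scales the chain length (steps = chain_factor * n);
    ``moves`` are the proposal probabilities for (adjacent transposition,
    random pair swap, single-node relocation).
    """

    chain_factor: int = 200
    burn_in: float = 0.2
    moves: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_candidates: int = 14
    max_expand: int = 3


@dataclass
class SearchSpace:
    """Per-continuous-node candidate parent sets."""

    psi: np.ndarray                       # continuous node indices
    candidates: dict[int, np.ndarray]     # node -> candidate parent indices

    def __post_init__(self) -> None:
        for node, cand in self.candidates.items():
            if node in cand:
                raise ValueError(f"node {node} is its own candidate parent")


@dataclass
class EdgePosteriors:
    """Estimated edge posterior probabilities for one cluster."""

    probs: np.ndarray  # n x n, entries in [0, 1]; blacklisted entries 0
    n_samples: int

    def edges_above(self, threshold: float) -> list[tuple[int, int]]:
        src, tgt = np.nonzero(self.probs > threshold)
        return list(zip(src.tolist(), tgt.tolist()))


@dataclass(frozen=True)
class ConsensusThresholds:
    """Posterior-threshold rules for the joint selected-edge list.

    An edge enters the selected list if its posterior exceeds ``p_high``
    in at least one cluster, or if the posteriors summed over clusters
    exceed ``p_sum`` while the maximum exceeds ``p_mid``.  Cluster-k keeps
    a selected edge if its own posterior exceeds ``p_include``.
    """

    p_high: float = 0.9
    p_sum: float = 1.2
    p_mid: float = 0.5
    p_include: float = 0.4

    def __post_init__(self) -> None:
        if not (0 <= self.p_include <= self.p_mid <= self.p_high <= 1):
            raise ValueError("need 0 <= p_include <= p_mid <= p_high <= 1")


def init_search_space(stats: WeightedSuffStats,
                      config: ScoringConfig | ResolvedScoringConfig,
                      penalization: np.ndarray | None,
                      blacklist: np.ndarray | None,
                      psi: np.ndarray,
                      max_candidates: int | None = None) -> SearchSpace:
    """Candidate parents per node: top-m single parents by score gain.

    m defaults to 2 * max_parents.  When a non-trivial penalization
    matrix is supplied, parents left unpenalized (kappa = 1) are added on
    top, since the prior marks them as plausible.  Blacklisted and self
    edges are never candidates.
    """
    scorer = BgeScorer(stats, config)
    cfg = scorer.cfg
    n = stats.n
    psi = np.asarray(psi, dtype=int)
    m = 2 * cfg.max_parents
    cap = max_candidates
    use_kappa = not is_trivial_penalization(penalization)
    candidates: dict[int, np.ndarray] = {}
    for node in psi:
        node = int(node)
        allowed = [s for s in range(n) if s != node
                   and (blacklist is None or not blacklist[s, node])]
        base = scorer.local_score(node, [])
        single = scorer.batch_local_scores(node, [(s,) for s in allowed])
        gains = {}
        for s, sc in zip(allowed, single):
            pen = log(penalization[s, node]) if use_kappa else 0.0
            gains[s] = sc - base - pen
        top = sorted(allowed, key=lambda s: -gains[s])[:m]
        chosen = set(top)
        if use_kappa:
            chosen |= {s for s in allowed if penalization[s, node] <= 1.0}
        if cap is not None and len(chosen) > cap:
            chosen = set(sorted(chosen, key=lambda s: -gains[s])[:cap])
        candidates[node] = np.asarray(sorted(chosen), dtype=int)
    return SearchSpace(psi, candidates)


@dataclass
class _NodeTable:
    """Scored candidate subsets of one continuous node."""

    node: int
    candidates: np.ndarray      # candidate parent indices
    cont_bits: np.ndarray       # per candidate: bit if continuous, else 0
    always_mask: int            # OR of bits of discrete candidates (always allowed)
    masks: np.ndarray           # int64 subset bitmasks over candidates
    scores: np.ndarray          # penalized local scores
    subsets: list[tuple[int, ...]]


def _build_tables(space: SearchSpace, scorer: BgeScorer,
                  penalization: np.ndarray | None) -> dict[int, _NodeTable]:
    psi_set = set(int(p) for p in space.psi)
    use_kappa = not is_trivial_penalization(penalization)
    tables = {}
    for node in space.psi:
        node = int(node)
        cand = space.candidates[node]
        c = len(cand)
        bits = np.array([1 << i for i in range(c)], dtype=np.int64)
        cont_bits = np.where(np.isin(cand, list(psi_set)), bits, 0)
        always = int(bits[~np.isin(cand, list(psi_set))].sum())
        masks, subsets = [], []
        for size in range(0, scorer.cfg.max_parents + 1):
            for combo in combinations(range(c), size):
                masks.append(int(sum(bits[list(combo)])))
                subsets.append(tuple(int(s) for s in cand[list(combo)]))
        scores = scorer.batch_local_scores(node, subsets)
        if use_kappa:
            logk = np.log(np.maximum(penalization[:, node], 1.0))
            scores = scores - np.array([sum(logk[list(s)]) for s in subsets])
        tables[node] = _NodeTable(node, cand, cont_bits, always,
                                  np.asarray(masks, dtype=np.int64),
                                  np.asarray(scores, dtype=float), subsets)
    return tables


class _OrderState:
    """Chain state: an order over continuous nodes plus per-node score caches."""

    def __init__(self, tables: dict[int, _NodeTable], order: np.ndarray):
        self.tables = tables
        self.order = np.asarray(order, dtype=int)
        n_total = 1 + max(max(t.node for t in tables.values()),
                          int(self.order.max()) if self.order.size else 0)
        self.pos = np.full(n_total, -1, dtype=np.int64)
        self.pos[self.order] = np.arange(len(self.order))
        self.logsum = np.zeros(n_total)
        self.best = np.zeros(n_total)
        self.best_idx = np.zeros(n_total, dtype=np.int64)
        # per node: continuous candidate ids and their bits, dense
        self._cont_ids = {}
        self._cont_bits = {}
        for node, t in tables.items():
            sel = t.cont_bits != 0
            self._cont_ids[node] = t.candidates[sel]
            self._cont_bits[node] = t.cont_bits[sel]
        for v in self.order:
            self._recompute(int(v))

    def _allowed_mask(self, node: int) -> int:
        t = self.tables[node]
        ids = self._cont_ids[node]
        if ids.size == 0:
            return t.always_mask
        before = self.pos[ids] < self.pos[node]
        # bits are distinct powers of two, so OR equals sum
        return t.always_mask | int(self._cont_bits[node][before].sum())

    def _recompute(self, node: int) -> None:
        t = self.tables[node]
        allowed = self._allowed_mask(node)
        ok_idx = np.nonzero((t.masks & ~allowed) == 0)[0]
        sc = t.scores[ok_idx]
        m = sc.max()
        self.logsum[node] = m + np.log(np.exp(sc - m).sum())
        k = int(np.argmax(sc))
        self.best[node] = sc[k]
        self.best_idx[node] = ok_idx[k]

    def total_logsum(self) -> float:
        return float(self.logsum[self.order].sum())

    def total_best(self) -> float:
        return float(self.best[self.order].sum())

    def sample_dag_parent_sets(self, rng: np.random.Generator) -> dict[int, tuple[int, ...]]:
        out = {}
        for node, t in self.tables.items():
            allowed = self._allowed_mask(node)
            idx = np.nonzero((t.masks & ~allowed) == 0)[0]
            sc = t.scores[idx]
            m = sc.max()
            w = np.exp(sc - m)
            out[node] = t.subsets[int(rng.choice(idx, p=w / w.sum()))]
        return out

    def apply_order(self, new_order: np.ndarray, touched):
        """Switch to ``new_order``; return the old cache entries for undo."""
        touched = np.asarray(touched, dtype=int)
        old = (self.logsum[touched].copy(), self.best[touched].copy(),
               self.best_idx[touched].copy())
        self.order = new_order
        self.pos[new_order] = np.arange(len(new_order))
        for v in touched:
            self._recompute(int(v))
        return touched, old

    def undo(self, old_order: np.ndarray, saved) -> None:
        self.order = old_order
        self.pos[old_order] = np.arange(len(old_order))
        touched, (ls, bs, bi) = saved
        self.logsum[touched] = ls
        self.best[touched] = bs
        self.best_idx[touched] = bi


def _propose(order: np.ndarray, rng: np.random.Generator,
             moves: tuple[float, float, float]) -> tuple[np.ndarray, list[int]]:
    """Propose a new order; return it with the nodes whose predecessors change."""
    k = len(order)
    u = rng.random()
    new = order.copy()
    if k < 2:
        return new, []
    if u < moves[0]:  # adjacent transposition
        i = int(rng.integers(k - 1))
        new[i], new[i + 1] = new[i + 1], new[i]
        touched = [int(order[i]), int(order[i + 1])]
    elif u < moves[0] + moves[1]:  # random pair swap
        i, j = sorted(rng.choice(k, size=2, replace=False).tolist())
        new[i], new[j] = new[j], new[i]
        touched = [int(v) for v in order[i:j + 1]]
    else:  # single-node relocation
        i = int(rng.integers(k))
        j = int(rng.integers(k))
        if i == j:
            return new, []
        node = new[i]
        new = np.delete(new, i)
        new = np.insert(new, j, node)
        lo, hi = min(i, j), max(i, j)
        touched = [int(v) for v in order[lo:hi + 1]]
    return new, touched


def _run_chain(tables: dict[int, _NodeTable], psi: np.ndarray,
               steps: int, rng: np.random.Generator,
               moves: tuple[float, float, float],
               collect_every: int = 0,
               burn_in: int = 0,
               init_order: np.ndarray | None = None):
    """Metropolis chain over orders.

    Returns (state at end, best MAP parent-sets seen, best MAP score,
    list of sampled per-node parent sets if ``collect_every`` > 0).
    """
    if init_order is not None:
        order = np.asarray(init_order, dtype=int).copy()
    else:
        order = psi.copy()
        rng.shuffle(order)
    state = _OrderState(tables, order)
    cur = state.total_logsum()
    best_score = state.total_best()
    best_sets = {node: tables[node].subsets[state.best_idx[node]]
                 for node in state.tables}
    samples = []
    for step in range(steps):
        new_order, touched = _propose(state.order, rng, moves)
        if touched:
            old_order = state.order
            saved = state.apply_order(new_order, touched)
            new = state.total_logsum()
            if np.log(rng.random()) < new - cur:
                cur = new
                tb = state.total_best()
                if tb > best_score + 1e-12:
                    best_score = tb
                    best_sets = {node: tables[node].subsets[state.best_idx[node]]
                                 for node in state.tables}
            else:
                state.undo(old_order, saved)
        if collect_every and step >= burn_in and (step - burn_in) % collect_every == 0:
            samples.append(state.sample_dag_parent_sets(rng))
    return state, best_sets, best_score, samples


def _expand_space(space: SearchSpace, best_sets: dict[int, tuple[int, ...]],
                  scorer: BgeScorer, penalization, blacklist,
                  max_candidates: int) -> tuple[SearchSpace, bool]:
    """Re-rank candidates conditional on the current best parent sets."""
    use_kappa = not is_trivial_penalization(penalization)
    n = scorer.stats.n
    m = 2 * scorer.cfg.max_parents
    changed = False
    new_cands = {}
    for node in space.psi:
        node = int(node)
        pa = set(best_sets.get(node, ()))
        base_pa = sorted(pa)[:scorer.cfg.max_parents - 1]
        base = scorer.local_score(node, base_pa)
        allowed = [s for s in range(n) if s != node and s not in pa
                   and (blacklist is None or not blacklist[s, node])]
        gains = {}
        for s in allowed:
            pen = log(penalization[s, node]) if use_kappa and penalization[s, node] > 1 else 0.0
            gains[s] = scorer.local_score(node, base_pa + [s]) - base - pen
        top = sorted(allowed, key=lambda s: -gains[s])[:m]
        chosen = pa | set(top)
        if use_kappa:
            chosen |= {s for s in range(n) if s != node
                       and (blacklist is None or not blacklist[s, node])
                       and penalization[s, node] <= 1.0}
        if len(chosen) > max_candidates:
            ranked = sorted(chosen - pa, key=lambda s: -gains.get(s, np.inf))
            chosen = pa | set(ranked[:max_candidates - len(pa)])
        arr = np.asarray(sorted(chosen), dtype=int)
        if not np.array_equal(arr, space.candidates[node]):
            changed = True
        new_cands[node] = arr
    return SearchSpace(space.psi, new_cands), changed


def _topological_psi_order(dag: Dag, psi: np.ndarray) -> np.ndarray:
    """Topological order of the continuous nodes of a DAG."""
    psi_set = {int(v) for v in psi}
    done: set[int] = set(range(dag.n)) - psi_set
    order: list[int] = []
    remaining = [int(v) for v in psi]
    while remaining:
        for v in list(remaining):
            if dag.parents(v) <= done:
                order.append(v)
                done.add(v)
                remaining.remove(v)
    return np.asarray(order, dtype=int)


def map_search(stats: WeightedSuffStats,
               config: ScoringConfig | ResolvedScoringConfig,
               penalization: np.ndarray | None,
               space: SearchSpace,
               seed: int | np.random.Generator,
               blacklist: np.ndarray | None = None,
               discrete=(),
               search: SearchConfig = SearchConfig(),
               init_dag: Dag | None = None) -> tuple[Dag, float]:
    """Iterative order-MCMC search for the MAP structure.

    Runs a chain restricted to the candidate space, takes the best DAG,
    re-ranks candidates around it, and repeats until the MAP graph is
    stable (at most ``max_expand`` rounds).  ``init_dag`` warm-starts the
    chain from a topological order of a previous estimate and guarantees
    its edges are in the candidate space.  Deterministic given the seed.
    Returns the best DAG found and its penalized log score.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    scorer = BgeScorer(stats, config)
    psi = space.psi
    steps = max(search.chain_factor * stats.n, 20)
    best_score = -np.inf
    best_sets: dict[int, tuple[int, ...]] = {}
    init_order = None
    if init_dag is not None:
        init_sets = {int(v): tuple(sorted(init_dag.parents(int(v))))
                     for v in psi}
        space, _ = _expand_space(space, init_sets, scorer, penalization,
                                 blacklist, search.max_candidates)
        init_order = _topological_psi_order(init_dag, psi)
    for round_ in range(max(1, search.max_expand)):
        tables = _build_tables(space, scorer, penalization)
        _, sets_r, score_r, _ = _run_chain(tables, psi, steps, rng,
                                           search.moves,
                                           init_order=init_order)
        init_order = None
        if score_r > best_score + 1e-9:
            best_score, best_sets = score_r, sets_r
            improved = True
        else:
            improved = False
        space, changed = _expand_space(space, best_sets, scorer, penalization,
                                       blacklist, search.max_candidates)
        if not changed and not improved and round_ > 0:
            break
        if not improved and round_ > 0:
            break
    parent_sets = [() for _ in range(stats.n)]
    for node, pa in best_sets.items():
        parent_sets[node] = pa
    dag = Dag.from_parent_sets(parent_sets, discrete=discrete,
                               blacklist=blacklist)
    return dag, best_score


def sample_edge_posteriors(stats: WeightedSuffStats,
                           config: ScoringConfig | ResolvedScoringConfig,
                           penalization: np.ndarray | None,
                           space: SearchSpace,
                           L: int,
                           seed: int | np.random.Generator,
                           search: SearchConfig = SearchConfig()) -> EdgePosteriors:
    """Estimate edge posteriors from L DAGs sampled via order MCMC.

    The chain is run past burn-in and thinned so that exactly L orders are
    retained; per order one DAG is drawn with per-node parent sets sampled
    proportionally to their exponentiated scores.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    scorer = BgeScorer(stats, config)
    tables = _build_tables(space, scorer, penalization)
    steps = max(search.chain_factor * stats.n, 20)
    burn = int(search.burn_in * steps)
    collect_every = max(1, (steps - burn) // L)
    # lengthen the chain slightly so exactly L samples fit
    steps = burn + collect_every * L
    _, _, _, samples = _run_chain(tables, space.psi, steps, rng, search.moves,
                                  collect_every=collect_every, burn_in=burn)
    samples = samples[:L]
    n = stats.n
    counts = np.zeros((n, n))
    for ps in samples:
        for node, pa in ps.items():
            for s in pa:
                counts[s, node] += 1
    return EdgePosteriors(counts / len(samples), len(samples))


def consensus_graphs(posteriors: list[EdgePosteriors],
                     thresholds: ConsensusThresholds = ConsensusThresholds(),
                     ) -> tuple[list[list[tuple[int, int]]], list[tuple[int, int]]]:
    """Joint selected-edge list plus per-cluster consensus edge sets.

    Selected = edges above ``p_high`` in at least one cluster, plus edges
    whose posterior sum exceeds ``p_sum`` while the maximum exceeds
    ``p_mid``.  Cluster k keeps selected edges with posterior above
    ``p_include``.
    """
    if not posteriors:
        raise ValueError("no posterior matrices given")
    shape = posteriors[0].probs.shape
    if any(p.probs.shape != shape for p in posteriors):
        raise ValueError("posterior matrices have inconsistent node sets")
    stack = np.stack([p.probs for p in posteriors])  # K x n x n
    high = (stack > thresholds.p_high).any(axis=0)
    summed = (stack.sum(axis=0) > thresholds.p_sum) & \
        (stack.max(axis=0) > thresholds.p_mid)
    selected_mask = high | summed
    selected = [tuple(e) for e in np.argwhere(selected_mask)]
    per_cluster = []
    for p in posteriors:
        keep = selected_mask & (p.probs > thresholds.p_include)
        per_cluster.append([tuple(e) for e in np.argwhere(keep)])
    return per_cluster, selected


def threshold_graph(posteriors: EdgePosteriors, threshold: float,
                    ) -> list[tuple[int, int]]:
    """Plain consensus: edges with posterior above a single threshold."""
    return posteriors.edges_above(threshold)
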