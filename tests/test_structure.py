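"""Order-MCMC search, posterior sampling and consensus rules."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mixnets.scoring import BgeScorer, ScoringConfig, weighted_suffstats
from mixnets.structure import (ConsensusThresholds, EdgePosteriors,
                               SearchSpace, consensus_graphs,
                               init_search_space, map_search,
                               sample_edge_posteriors, threshold_graph)


def full_space(n, max_parents=2):
    return SearchSpace(np.arange(n),
                       {i: np.array([j for j in range(n) if j != i])
                        for i in range(n)})


def exhaustive_best(x, max_parents=2):
    n = x.shape[1]
    scorer = BgeScorer(weighted_suffstats(x),
                       ScoringConfig(max_parents=max_parents))
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        edges = [p for p, b in zip(pairs, bits) if b]
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            continue
        if any(len(list(g.predecessors(v))) > max_parents for v in range(n)):
            continue
        s = sum(scorer.local_score(v, sorted(g.predecessors(v)))
                for v in range(n))
        best = max(best, s)
    return best


def order_space_posterior(x, max_parents=2):
    """Exact edge posteriors of the order-marginal distribution.

    Enumerates every order of the nodes and every order-compatible parent
    set; this is the stationary distribution the order sampler targets,
    computed without any MCMC.
    """
    n = x.shape[1]
    scorer = BgeScorer(weighted_suffstats(x),
                       ScoringConfig(max_parents=max_parents))
    logws, econds = [], []
    for order in itertools.permutations(range(n)):
        lw = 0.0
        emat = np.zeros((n, n))
        for i, node in enumerate(order):
            preds = set(order[:i])
            subsets = [s for size in range(max_parents + 1)
                       for s in itertools.combinations(sorted(preds), size)]
            scores = np.array([scorer.local_score(node, s) for s in subsets])
            m = scores.max()
            w = np.exp(scores - m)
            z = w.sum()
            lw += m + np.log(z)
            for s, wi in zip(subsets, w):
                for src in s:
                    emat[src, node] += wi / z
        logws.append(lw)
        econds.append(emat)
    logws = np.array(logws)
    ws = np.exp(logws - logws.max())
    ws /= ws.sum()
    return sum(w * e for w, e in zip(ws, econds))


class TestSearchSpace:
    def test_single_unblacklisted_edge(self, rng):
        x = rng.normal(size=(30, 3))
        stats = weighted_suffstats(x)
        bl = np.ones((3, 3), dtype=bool)
        bl[0, 2] = False
        space = init_search_space(stats, ScoringConfig(), None, bl,
                                  np.arange(3))
        assert space.candidates[2].tolist() == [0]
        assert space.candidates[0].size == 0

    def test_small_system_gets_all_parents(self, rng):
        x = rng.normal(size=(30, 3))
        space = init_search_space(weighted_suffstats(x), ScoringConfig(),
                                  None, None, np.arange(3))
        for node in range(3):
            assert sorted(space.candidates[node].tolist()) == \
                sorted(set(range(3)) - {node})

    def test_candidate_bound(self, rng):
        x = rng.normal(size=(40, 12))
        cfg = ScoringConfig(max_parents=2)
        space = init_search_space(weighted_suffstats(x), cfg, None, None,
                                  np.arange(12))
        for node in range(12):
            assert len(space.candidates[node]) <= 2 * cfg.max_parents

    def test_unpenalized_parents_added(self, rng):
        x = rng.normal(size=(40, 12))
        cfg = ScoringConfig(max_parents=2)
        kappa = np.full((12, 12), 2.0)
        kappa[10, 0] = 1.0  # prior interaction 10 -> 0
        space = init_search_space(weighted_suffstats(x), cfg, kappa, None,
                                  np.arange(12))
        assert 10 in space.candidates[0]


class TestMapSearch:
    def test_matches_exhaustive_enumeration(self, continuous_chain_data):
        x = continuous_chain_data
        stats = weighted_suffstats(x)
        cfg = ScoringConfig(max_parents=2)
        _, score = map_search(stats, cfg, None, full_space(3), seed=0)
        assert score == pytest.approx(exhaustive_best(x), abs=1e-9)

    def test_pure_noise_beats_empty_graph(self, rng):
        x = rng.normal(size=(200, 4))
        stats = weighted_suffstats(x)
        cfg = ScoringConfig(max_parents=2)
        scorer = BgeScorer(stats, cfg.resolve(4))
        empty = sum(scorer.local_score(v, []) for v in range(4))
        dag, score = map_search(stats, cfg, None, full_space(4), seed=1)
        assert score >= empty - 1e-9
        assert dag.n_edges <= 2  # near-empty on independent columns

    def test_determinism(self, continuous_chain_data):
        stats = weighted_suffstats(continuous_chain_data)
        cfg = ScoringConfig(max_parents=2)
        d1, s1 = map_search(stats, cfg, None, full_space(3), seed=7)
        d2, s2 = map_search(stats, cfg, None, full_space(3), seed=7)
        assert d1 == d2 and s1 == s2


class TestEdgePosteriors:
    def test_strong_two_node_dependence(self, rng):
        n = 200
        x = np.zeros((n, 2))
        x[:, 0] = rng.normal(size=n)
        x[:, 1] = x[:, 0] + 0.33 * rng.normal(size=n)  # corr ~ 0.95
        stats = weighted_suffstats(x)
        post = sample_edge_posteriors(stats, ScoringConfig(max_parents=1),
                                      None, full_space(2, 1), L=500, seed=0)
        either = post.probs[0, 1] + post.probs[1, 0]
        assert either >= 0.95

    def test_independent_columns_low_posteriors(self, rng):
        x = rng.normal(size=(500, 3))
        stats = weighted_suffstats(x)
        post = sample_edge_posteriors(stats, ScoringConfig(max_parents=2),
                                      None, full_space(3), L=500, seed=0)
        assert post.probs.max() <= 0.5

    def test_matches_exact_order_space_enumeration(self, rng):
        # collider x2 <- x0, x1: the sampler's stationary distribution,
        # enumerated exhaustively, within MC error at L=2000
        n = 500
        x = np.zeros((n, 3))
        x[:, 0] = rng.normal(size=n)
        x[:, 1] = rng.normal(size=n)
        x[:, 2] = 1.2 * x[:, 0] - x[:, 1] + rng.normal(size=n)
        stats = weighted_suffstats(x)
        post = sample_edge_posteriors(stats, ScoringConfig(max_parents=2),
                                      None, full_space(3), L=2000, seed=0)
        oracle = order_space_posterior(x)
        assert np.abs(post.probs - oracle).max() < 0.05

    def test_blacklisted_edge_posterior_zero(self, rng):
        x = rng.normal(size=(100, 3))
        x[:, 1] += x[:, 0]
        stats = weighted_suffstats(x)
        bl = np.zeros((3, 3), dtype=bool)
        bl[0, 1] = True
        space = init_search_space(stats, ScoringConfig(max_parents=2), None,
                                  bl, np.arange(3))
        post = sample_edge_posteriors(stats, ScoringConfig(max_parents=2),
                                      None, space, L=200, seed=0)
        assert post.probs[0, 1] == 0.0


class TestConsensus:
    def _mats(self, triples):
        # triples: per-cluster posterior of the single edge (0, 1)
        out = []
        for p in triples:
            m = np.zeros((2, 2))
            m[0, 1] = p
            out.append(EdgePosteriors(m, 100))
        return out

    def test_high_rule(self):
        per_cluster, selected = consensus_graphs(self._mats([0.95, 0.10, 0.45]))
        assert selected == [(0, 1)]
        assert [(0, 1) in g for g in per_cluster] == [True, False, True]

    def test_sum_rule_needs_mid_threshold(self):
        _, selected = consensus_graphs(self._mats([0.45, 0.45, 0.45]))
        assert selected == []  # sum 1.35 > 1.2 but max < 0.5

    def test_sum_rule_selects(self):
        per_cluster, selected = consensus_graphs(self._mats([0.55, 0.50, 0.20]))
        assert selected == [(0, 1)]
        assert [(0, 1) in g for g in per_cluster] == [True, True, False]

    def test_monotone_in_thresholds(self, rng):
        mats = [EdgePosteriors(rng.random((5, 5)) * (1 - np.eye(5)), 10)
                for _ in range(3)]
        base = ConsensusThresholds()
        _, sel = consensus_graphs(mats, base)
        for stricter in [ConsensusThresholds(p_high=0.95),
                         ConsensusThresholds(p_sum=1.5),
                         ConsensusThresholds(p_mid=0.7)]:
            _, sel2 = consensus_graphs(mats, stricter)
            assert set(sel2) <= set(sel)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ConsensusThresholds(p_high=0.3, p_mid=0.5)

    def test_inconsistent_node_sets_rejected(self):
        mats = [EdgePosteriors(np.zeros((2, 2)), 1),
                EdgePosteriors(np.zeros((3, 3)), 1)]
        with pytest.raises(ValueError):
            consensus_graphs(mats)

    def test_plain_threshold_graph(self):
        m = np.zeros((3, 3))
        m[0, 1], m[1, 2] = 0.8, 0.3
        assert threshold_graph(EdgePosteriors(m, 10), 0.5) == [(0, 1)]
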