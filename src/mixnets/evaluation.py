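"""Clustering and structure-recovery metrics plus network summaries.

Clustering accuracy is measured by the adjusted Rand index and by
sample-weighted precision/F1 after matching predicted to true clusters
with a Hungarian assignment on the contingency table.  Structure
accuracy compares graphs on their CPDAG (Markov equivalence class)
representations: true positive rate, false discovery rate, and
structural Hamming distance where an edge insertion, deletion or
orientation change each cost one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .data_model import Dag


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (permutation invariant)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two samples")
    return float(adjusted_rand_score(a, b))


def clustering_metrics(pred, truth) -> tuple[float, float, float]:
    """(precision, F1, ARI) with clusters matched by maximum overlap.

    Predicted clusters are matched one-to-one to true clusters by a
    Hungarian assignment maximizing the contingency-table overlap; the
    per-cluster precision and F1 are then sample-weighted by true cluster
    size.
    """
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("label vectors must have equal length")
    pred_labels = np.unique(p)
    true_labels = np.unique(t)
    cont = np.zeros((len(pred_labels), len(true_labels)))
    for i, pl in enumerate(pred_labels):
        for j, tl in enumerate(true_labels):
            cont[i, j] = np.sum((p == pl) & (t == tl))
    rows, cols = linear_sum_assignment(-cont)
    tp_total = 0.0
    f1 = 0.0
    n = len(t)
    for i, j in zip(rows, cols):
        tp = cont[i, j]
        tp_total += tp
        pred_size = cont[i].sum()
        true_size = cont[:, j].sum()
        prec = tp / pred_size if pred_size else 0.0
        rec = tp / true_size if true_size else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        f1 += true_size / n * f
    # micro-averaged precision: matched overlap over all samples; true
    # clusters left unmatched (fewer predicted than true) contribute 0
    return float(tp_total / n), float(f1), ari(p, t)


@dataclass(frozen=True)
class Cpdag:
    """Completed partially directed acyclic graph.

    ``directed`` holds compelled edges (s, t); ``undirected`` holds
    reversible edges as frozensets {s, t}.
    """

    n: int
    directed: frozenset[tuple[int, int]]
    undirected: frozenset[frozenset[int]]

    @property
    def skeleton(self) -> frozenset[frozenset[int]]:
        return frozenset({frozenset(e) for e in self.directed}
                         | self.undirected)


def dag_to_cpdag(dag: Dag | nx.DiGraph) -> Cpdag:
    """Markov-equivalence-class representative of a DAG.

    Keeps the skeleton, directs v-structure edges, and propagates the
    orientation rules (Meek's rules) until fixpoint; all remaining edges
    are left undirected.
    """
    if isinstance(dag, Dag):
        n = dag.n
        edges = dag.edges
    else:
        g = dag
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("input graph is cyclic")
        n = g.number_of_nodes()
        edges = list(g.edges())
    parents: dict[int, set[int]] = {v: set() for v in range(n)}
    for s, t in edges:
        parents[t].add(s)
    adj: dict[int, set[int]] = {v: set() for v in range(n)}
    for s, t in edges:
        adj[s].add(t)
        adj[t].add(s)
    # v-structures: s -> t <- u with s, u non-adjacent
    directed: set[tuple[int, int]] = set()
    for t in range(n):
        for s, u in combinations(sorted(parents[t]), 2):
            if u not in adj[s]:
                directed.add((s, t))
                directed.add((u, t))
    undirected = {frozenset((s, t)) for s, t in edges
                  if (s, t) not in directed}
    _apply_meek(n, adj, directed, undirected)
    return Cpdag(n, frozenset(directed), frozenset(undirected))


def _apply_meek(n: int, adj: dict[int, set[int]],
                directed: set[tuple[int, int]],
                undirected: set[frozenset[int]]) -> None:
    """Meek orientation rules R1-R4 to fixpoint (in place)."""

    def orient(a: int, b: int) -> bool:
        e = frozenset((a, b))
        if e in undirected:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, z not adjacent to y  =>  x -> y
                if any((z, x) in directed and y not in adj[z] and z != y
                       for z in adj[x]):
                    changed |= orient(x, y)
                    break
                # R2: x -> z -> y  =>  x -> y
                if any((x, z) in directed and (z, y) in directed
                       for z in adj[x] & adj[y]):
                    changed |= orient(x, y)
                    break
                # R3: x - z1 -> y, x - z2 -> y, z1,z2 non-adjacent
                zs = [z for z in adj[x] & adj[y]
                      if frozenset((x, z)) in undirected
                      and (z, y) in directed]
                if any(z2 not in adj[z1] for z1, z2 in combinations(zs, 2)):
                    changed |= orient(x, y)
                    break
                # R4: x - z1, z1 -> z2, z2 -> y, z1 adj y... (background
                # knowledge rule; cannot fire from v-structures alone)
            if changed:
                break


@dataclass(frozen=True)
class StructureMetrics:
    tpr: float
    fdr: float
    shd: int


def edges_to_pdag(n: int, edges) -> Cpdag:
    """Partially directed graph from a raw edge list.

    Pairs present in both directions collapse to an undirected edge.
    Used for consensus graphs, which need not be acyclic.
    """
    es = {(int(s), int(t)) for s, t in edges}
    undirected = {frozenset(e) for e in es if (e[1], e[0]) in es}
    directed = {e for e in es if frozenset(e) not in undirected}
    return Cpdag(n, frozenset(directed), frozenset(undirected))


def structure_metrics(predicted: Dag | Cpdag | list, truth: Dag | Cpdag,
                      n_nodes: int | None = None) -> StructureMetrics:
    """TPR/FDR/SHD of a predicted graph against the true CPDAG.

    DAG inputs are converted to CPDAGs; raw edge lists (consensus graphs,
    possibly cyclic) are compared as partially directed graphs.  A
    predicted edge is a true positive if it matches a true edge in
    skeleton and orientation type (directed edges must agree in
    direction; undirected must be undirected).  SHD counts skeleton
    insertions/deletions plus orientation mismatches, one each.
    """
    tc = truth if isinstance(truth, Cpdag) else dag_to_cpdag(truth)
    if isinstance(predicted, Cpdag):
        pc = predicted
    elif isinstance(predicted, Dag):
        pc = dag_to_cpdag(predicted)
    else:
        # consensus edge list: use the equivalence class when it is a DAG,
        # otherwise compare as a partially directed graph
        n = n_nodes if n_nodes is not None else tc.n
        try:
            pc = dag_to_cpdag(Dag(n, predicted))
        except ValueError:
            pc = edges_to_pdag(n, predicted)
    if pc.n != tc.n:
        raise ValueError("graphs are over different node sets")
    p_skel, t_skel = pc.skeleton, tc.skeleton
    tp = 0
    mismatch = 0
    for e in p_skel & t_skel:
        a, b = tuple(e)
        p_dir = (a, b) if (a, b) in pc.directed else \
            ((b, a) if (b, a) in pc.directed else None)
        t_dir = (a, b) if (a, b) in tc.directed else \
            ((b, a) if (b, a) in tc.directed else None)
        if p_dir == t_dir:
            tp += 1
        else:
            mismatch += 1
    n_pred = len(p_skel)
    n_true = len(t_skel)
    tpr = tp / n_true if n_true else (1.0 if n_pred == 0 else 0.0)
    fdr = (n_pred - tp) / n_pred if n_pred else 0.0
    shd = len(p_skel ^ t_skel) + mismatch
    return StructureMetrics(float(tpr), float(fdr), int(shd))


@dataclass
class NetworkSummaries:
    venn_counts: dict[frozenset[int], int]
    degree: dict[int, int]
    hubs: list[int]
    betweenness: dict[int, float]
    shared_neighbors: dict[int, int]
    specific_neighbors: dict[int, int]


def network_summaries(graphs: list[list[tuple[int, int]]],
                      n_nodes: int,
                      hub_degree: int = 20) -> NetworkSummaries:
    """Cross-cluster edge overlap counts and joint-network node statistics.

    Edge directions are disregarded.  ``venn_counts`` maps each non-empty
    cluster subset to the number of edges present in exactly those
    clusters.  Degree, hub flags (degree > ``hub_degree``) and
    betweenness are computed on the union network; per-node counts of
    neighbors shared by >= 2 clusters vs cluster-specific neighbors are
    returned alongside.
    """
    k = len(graphs)
    membership: dict[frozenset[int], set[int]] = {}
    for ci, edges in enumerate(graphs):
        for s, t in edges:
            e = frozenset((s, t))
            if len(e) < 2:
                continue
            membership.setdefault(e, set()).add(ci)
    venn: dict[frozenset[int], int] = {}
    for e, clusters in membership.items():
        key = frozenset(clusters)
        venn[key] = venn.get(key, 0) + 1
    union = nx.Graph()
    union.add_nodes_from(range(n_nodes))
    union.add_edges_from(tuple(e) for e in membership)
    degree = {v: int(d) for v, d in union.degree()}
    hubs = sorted(v for v, d in degree.items() if d > hub_degree)
    betweenness = nx.betweenness_centrality(union)
    shared = {v: 0 for v in range(n_nodes)}
    specific = {v: 0 for v in range(n_nodes)}
    for e, clusters in membership.items():
        a, b = tuple(e)
        if len(clusters) >= 2:
            shared[a] += 1
            shared[b] += 1
        else:
            specific[a] += 1
            specific[b] += 1
    return NetworkSummaries(venn, degree, hubs, betweenness, shared, specific)
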