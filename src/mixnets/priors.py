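"""Structure-prior machinery: forbidden-edge masks and edge penalization.

Two mechanisms steer structure learning toward biologically plausible
networks.  The *blacklist* is a hard mask: blacklisted edges can never be
learned.  Incoming edges to binary/ordinal nodes are always blacklisted;
additional omics-class rules (e.g. no transcript-transcript edges) can be
layered on top.  The *penalization matrix* kappa is soft: each edge's
contribution to the structure prior is divided by a factor kappa >= 1, so
edges absent from interaction databases are down-weighted rather than
forbidden.  Penalization factors are shared across mixture components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import DataClass, FeatureDescriptor, partition_indices


@dataclass(frozen=True)
class EdgeRuleSet:
    """Allowed (source omics-class, target omics-class) pairs.

    ``same_gene_only_pairs`` restricts listed class pairs to edges between
    features of the same gene (e.g. CN -> T only within a gene).
    """

    allowed_pairs: frozenset[tuple[str, str]]
    same_gene_only_pairs: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs, same_gene_only=()) -> "EdgeRuleSet":
        return cls(frozenset(tuple(p) for p in pairs),
                   frozenset(tuple(p) for p in same_gene_only))


def hcc_default_rules() -> EdgeRuleSet:
    """Default rule set for M/CN/T/P/PP data.

    Edges follow the central dogma's information flow: genome classes (M,
    CN) feed any continuous class; transcripts feed proteins and
    phosphosites but not other transcripts; all edges among P and PP are
    allowed.  CN -> T is restricted to the same gene (a copy-number change
    directly affects its own transcript's abundance).
    """
    pairs = [
        ("M", "T"), ("M", "P"), ("M", "PP"),
        ("CN", "T"), ("CN", "P"), ("CN", "PP"),
        ("T", "P"), ("T", "PP"),
        ("P", "P"), ("P", "PP"), ("PP", "P"), ("PP", "PP"),
    ]
    return EdgeRuleSet.from_pairs(pairs, same_gene_only=[("CN", "T")])


def generic_rules(features: Sequence[FeatureDescriptor]) -> EdgeRuleSet:
    """Permissive rule set: any class may feed any continuous class."""
    classes = {f.omics_class for f in features}
    cont = {f.omics_class for f in features
            if f.data_class == DataClass.CONTINUOUS}
    return EdgeRuleSet.from_pairs([(a, b) for a in classes for b in cont])


def build_blacklist(features: Sequence[FeatureDescriptor],
                    rules: EdgeRuleSet | None = None) -> np.ndarray:
    """Boolean n x n mask, ``True`` where the edge source->target is forbidden.

    Every edge into a binary or ordinal node is forbidden regardless of the
    rule set; self-edges are forbidden; everything not explicitly allowed
    by the rules is forbidden.
    """
    n = len(features)
    omega, phi, _ = partition_indices(features)
    mask = np.zeros((n, n), dtype=bool)
    mask[:, omega] = True
    mask[:, phi] = True
    np.fill_diagonal(mask, True)
    if rules is None:
        return mask
    known = {f.omics_class for f in features}
    for a, b in rules.allowed_pairs | rules.same_gene_only_pairs:
        if a not in known or b not in known:
            raise ValueError(f"rule references unknown omics class: ({a}, {b})")
    for s, fs in enumerate(features):
        for t, ft in enumerate(features):
            if mask[s, t]:
                continue
            pair = (fs.omics_class, ft.omics_class)
            if pair not in rules.allowed_pairs:
                mask[s, t] = True
            elif pair in rules.same_gene_only_pairs and fs.gene != ft.gene:
                mask[s, t] = True
    return mask


@dataclass(frozen=True)
class InteractionRecord:
    gene_a: str
    gene_b: str
    score: float | None = None  # None = unscored (curated, full confidence)
    directed: bool = False

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"interaction score {self.score} outside [0, 1]")


@dataclass
class InteractionTable:
    """Gene-level prior interactions (STRING/Omnipath style)."""

    records: list[InteractionRecord] = field(default_factory=list)

    @classmethod
    def from_tuples(cls, tuples) -> "InteractionTable":
        recs = []
        for t in tuples:
            recs.append(InteractionRecord(*t))
        return cls(recs)

    def __len__(self) -> int:
        return len(self.records)


def build_penalization(features: Sequence[FeatureDescriptor],
                       interactions: InteractionTable | Sequence[InteractionTable] | None,
                       base_factor: float = 2.0,
                       score_cutoff: float = 0.5,
                       respect_direction: bool = True) -> np.ndarray:
    """Edge penalization matrix kappa aligned with ``features``.

    kappa = ``base_factor`` for gene pairs absent from all tables; 1 for
    pairs present with score >= ``score_cutoff`` or from an unscored table;
    ``base_factor * (1 - score)`` for scored pairs below the cutoff; and 1
    for any edge between two omics measurements of the same gene.  With
    ``respect_direction`` directed records exempt only the stated
    direction; undirected records always apply both ways.  Duplicate
    records keep the most favourable (maximum) score.
    """
    if base_factor < 1:
        raise ValueError("base_factor must be >= 1")
    if not (0 < score_cutoff <= 1):
        raise ValueError("score_cutoff must lie in (0, 1]")
    n = len(features)
    kappa = np.full((n, n), float(base_factor))
    genes = [f.gene for f in features]
    # same-gene cross-omics edges are never penalized
    gene_arr = np.array(genes)
    same_gene = gene_arr[:, None] == gene_arr[None, :]
    kappa[same_gene] = 1.0

    if interactions is None:
        tables: list[InteractionTable] = []
    elif isinstance(interactions, InteractionTable):
        tables = [interactions]
    else:
        tables = list(interactions)

    # best evidence per directed gene pair; unscored records count as 1.0
    best: dict[tuple[str, str], float] = {}
    for table in tables:
        for rec in table.records:
            if rec.score is not None and not (0 <= rec.score <= 1):
                raise ValueError("interaction score outside [0, 1]")
            pairs = [(rec.gene_a, rec.gene_b)]
            if not (rec.directed and respect_direction):
                pairs.append((rec.gene_b, rec.gene_a))
            sc = 1.0 if rec.score is None else float(rec.score)
            for key in pairs:
                best[key] = max(best.get(key, -1.0), sc)

    if best:
        gene_index: dict[str, list[int]] = {}
        for j, g in enumerate(genes):
            gene_index.setdefault(g, []).append(j)
        for (ga, gb), sc in best.items():
            if ga not in gene_index or gb not in gene_index:
                continue
            factor = 1.0 if sc >= score_cutoff else base_factor * (1.0 - sc)
            factor = min(factor, base_factor)
            for s in gene_index[ga]:
                for t in gene_index[gb]:
                    if not same_gene[s, t]:
                        kappa[s, t] = min(kappa[s, t], factor)
    return kappa


def uniform_penalization(n: int) -> np.ndarray:
    """kappa = 1 everywhere (flat structure prior)."""
    return np.ones((n, n))


def is_trivial_penalization(kappa: np.ndarray | None) -> bool:
    return kappa is None or bool(np.all(kappa <= 1.0))
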