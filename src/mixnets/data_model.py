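"""Typed containers for mixed multi-omics observations.

A dataset couples an ``N x n`` observation matrix (samples in rows) with a
list of feature descriptors.  Each feature carries an omics class label
(e.g. ``M`` for mutations, ``CN`` for copy number, ``T``/``P``/``PP`` for
transcript, protein and phosphosite abundances) and a statistical data
class: binary, ordinal or continuous.  The data-class partition drives all
structural constraints downstream: binary and ordinal nodes may act as
parents of continuous nodes but can never receive edges themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np


class DataClass(str, Enum):
    BINARY = "binary"
    ORDINAL = "ordinal"
    CONTINUOUS = "continuous"


#: default mapping of common omics-class labels to data classes
DEFAULT_OMICS_DATA_CLASS = {
    "M": DataClass.BINARY,
    "CN": DataClass.ORDINAL,
    "T": DataClass.CONTINUOUS,
    "P": DataClass.CONTINUOUS,
    "PP": DataClass.CONTINUOUS,
}


class ValidationError(ValueError):
    """Raised when a dataset violates its declared typing contract."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity and typing of a single omics feature.

    ``feature_id`` follows the ``GENE-OMICS`` convention (``TP53-M``) with
    phosphosites written ``GENE_SITE-PP`` (``RB1_S37-PP``).
    """

    feature_id: str
    gene: str
    omics_class: str
    data_class: DataClass
    site: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data_class, DataClass):
            object.__setattr__(self, "data_class", DataClass(self.data_class))


def descriptor_from_id(feature_id: str, omics_class: str,
                       data_class: DataClass | str | None = None) -> FeatureDescriptor:
    """Build a descriptor from a ``GENE-OMICS`` / ``GENE_SITE-PP`` style id."""
    if data_class is None:
        try:
            data_class = DEFAULT_OMICS_DATA_CLASS[omics_class]
        except KeyError:
            raise ValidationError(
                f"no default data class for omics class {omics_class!r}")
    stem = feature_id.rsplit("-", 1)[0] if "-" in feature_id else feature_id
    if "_" in stem:
        gene, site = stem.split("_", 1)
    else:
        gene, site = stem, None
    return FeatureDescriptor(feature_id, gene, omics_class,
                             DataClass(data_class), site)


@dataclass
class OmicsDataset:
    """Samples-by-features observation matrix with typed columns.

    Invariants: no missing values; binary columns take values in {0, 1};
    ordinal columns hold integer codes (consumed as reals by the Gaussian
    approximation); feature ids unique.
    """

    sample_ids: list[str]
    features: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n_samples, n_features = self.values.shape
        if n_samples != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {n_samples} rows")
        if n_features != len(self.features):
            raise ValidationError(
                f"{len(self.features)} descriptors but {n_features} columns")
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if n_samples < 1:
            raise ValidationError("dataset needs at least one sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def partition(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return partition_indices(self.features)


def partition_indices(features: Sequence[FeatureDescriptor],
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split feature indices into (binary, ordinal, continuous) index sets.

    The three sets are disjoint and exhaustive.
    """
    if len(features) == 0:
        raise ValidationError("empty feature list")
    omega, phi, psi = [], [], []
    for j, f in enumerate(features):
        if f.data_class == DataClass.BINARY:
            omega.append(j)
        elif f.data_class == DataClass.ORDINAL:
            phi.append(j)
        elif f.data_class == DataClass.CONTINUOUS:
            psi.append(j)
        else:  # pragma: no cover - enum is closed
            raise ValidationError(f"unknown data class {f.data_class!r}")
    return (np.asarray(omega, dtype=int), np.asarray(phi, dtype=int),
            np.asarray(psi, dtype=int))


@dataclass
class ColumnReport:
    feature_id: str
    data_class: DataClass
    conforming: bool
    zero_variance: bool
    message: str = ""


def validate_dataset(dataset: OmicsDataset, *, strict: bool = True,
                     ) -> list[ColumnReport]:
    """Per-column type-conformity and degeneracy checks.

    Zero-variance continuous/ordinal columns are flagged because they make
    the network score degenerate (singular posterior scatter).  With
    ``strict`` (the default) NaNs or domain violations raise
    :class:`ValidationError`; otherwise they are reported only.
    """
    reports: list[ColumnReport] = []
    vals = dataset.values
    if strict and np.isnan(vals).any():
        bad = [dataset.features[j].feature_id
               for j in np.unique(np.argwhere(np.isnan(vals))[:, 1])]
        raise ValidationError(f"NaN values in columns: {bad}")
    for j, f in enumerate(dataset.features):
        col = vals[:, j]
        conforming = True
        msg = ""
        if np.isnan(col).any():
            conforming = False
            msg = "contains NaN"
        elif f.data_class == DataClass.BINARY:
            if not np.isin(col, (0.0, 1.0)).all():
                conforming = False
                msg = "binary column with values outside {0, 1}"
        elif f.data_class == DataClass.ORDINAL:
            if not np.allclose(col, np.round(col)):
                conforming = False
                msg = "ordinal column with non-integer codes"
        zero_var = bool(np.ptp(col) == 0) if not np.isnan(col).any() else False
        if strict and not conforming:
            raise ValidationError(f"{f.feature_id}: {msg}")
        reports.append(ColumnReport(f.feature_id, f.data_class, conforming,
                                    zero_var, msg))
    return reports


def zero_variance_columns(dataset: OmicsDataset) -> list[int]:
    """Indices of ordinal/continuous columns with no variation (reject at fit)."""
    out = []
    for j, f in enumerate(dataset.features):
        if f.data_class in (DataClass.ORDINAL, DataClass.CONTINUOUS):
            if np.ptp(dataset.values[:, j]) == 0:
                out.append(j)
    return out


class Dag:
    """Directed acyclic graph aligned with a feature list.

    Enforces acyclicity, the no-edges-into-discrete-nodes rule, and an
    optional blacklist mask at construction / edge insertion.
    """

    def __init__(self, n: int, edges: Iterable[tuple[int, int]] = (),
                 discrete: Iterable[int] = (),
                 blacklist: np.ndarray | None = None):
        self.n = int(n)
        self._discrete = frozenset(int(i) for i in discrete)
        self._blacklist = blacklist
        self._parents: list[set[int]] = [set() for _ in range(self.n)]
        for s, t in edges:
            self.add_edge(int(s), int(t))

    @classmethod
    def from_features(cls, features: Sequence[FeatureDescriptor],
                      edges: Iterable[tuple[int, int]] = (),
                      blacklist: np.ndarray | None = None) -> "Dag":
        omega, phi, _ = partition_indices(features)
        return cls(len(features), edges,
                   discrete=np.concatenate([omega, phi]), blacklist=blacklist)

    def add_edge(self, source: int, target: int) -> None:
        if source == target:
            raise ValueError("self-loops are not allowed")
        if target in self._discrete:
            raise ValueError(
                f"edge {source}->{target}: discrete nodes cannot have parents")
        if self._blacklist is not None and self._blacklist[source, target]:
            raise ValueError(f"edge {source}->{target} is blacklisted")
        self._parents[target].add(source)
        if self._creates_cycle(source, target):
            self._parents[target].discard(source)
            raise ValueError(f"edge {source}->{target} creates a cycle")

    def _creates_cycle(self, source: int, target: int) -> bool:
        # DFS from source following parent links; cycle iff target reachable
        stack, seen = [source], set()
        while stack:
            v = stack.pop()
            if v == target:
                return True
            if v in seen:
                continue
            seen.add(v)
            stack.extend(self._parents[v])
        return False

    def parents(self, node: int) -> frozenset[int]:
        return frozenset(self._parents[node])

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(s, t) for t in range(self.n) for s in sorted(self._parents[t])]

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self._parents)

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n, self.n), dtype=bool)
        for s, t in self.edges:
            adj[s, t] = True
        return adj

    @classmethod
    def from_parent_sets(cls, parent_sets: Sequence[Iterable[int]],
                         discrete: Iterable[int] = (),
                         blacklist: np.ndarray | None = None) -> "Dag":
        edges = [(s, t) for t, ps in enumerate(parent_sets) for s in ps]
        return cls(len(parent_sets), edges, discrete=discrete,
                   blacklist=blacklist)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Dag) and self.n == other.n
                and self._parents == other._parents)

    def __hash__(self) -> int:
        return hash((self.n, tuple(frozenset(p) for p in self._parents)))

    def __repr__(self) -> str:
        return f"Dag(n={self.n}, edges={self.edges})"
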