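"""Reading omics matrices, interaction tables and writing fit results.

Input matrices are delimited text (TSV/CSV), one file per omics type,
bound together by a manifest (YAML or JSON) that records each file's
omics class, data class and orientation.  Results are written as plain
text: an assignments table with soft membership columns, a JSON model
document, a long-format edge-posterior table, and GraphML + SIF consensus
graphs per cluster.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .data_model import (FeatureDescriptor, OmicsDataset, descriptor_from_id,
                         validate_dataset)
from .em import FitResult, MixtureModel
from .priors import InteractionRecord, InteractionTable

logger = logging.getLogger(__name__)


def _read_table(path: Path, sep: str | None = None) -> pd.DataFrame:
    sep = sep or ("," if path.suffix.lower() == ".csv" else "\t")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_dataset(manifest_path: str | Path) -> OmicsDataset:
    """Assemble a dataset from the files listed in a manifest.

    Manifest schema::

        layers:
          - path: mutations.tsv
            omics_class: M
            data_class: binary        # optional, defaults per omics class
            features_as_rows: true    # optional, default true

    Files with features as rows (the bioinformatics convention) are
    transposed on read.  Samples are aligned across layers by
    intersection, warning when samples are dropped.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = (json.load(fh) if manifest_path.suffix == ".json"
                    else yaml.safe_load(fh))
    layers = manifest["layers"] if isinstance(manifest, dict) else manifest
    frames: list[tuple[pd.DataFrame, dict]] = []
    for layer in layers:
        path = Path(layer["path"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        df = _read_table(path, layer.get("sep"))
        if layer.get("features_as_rows", True):
            df = df.T
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no samples")
        frames.append((df, layer))
    shared = None
    for df, _ in frames:
        ids = list(df.index.astype(str))
        shared = ids if shared is None else [s for s in shared if s in set(ids)]
    if not shared:
        raise ValueError("no samples shared across all layers")
    total = {str(s) for df, _ in frames for s in df.index}
    if len(total) > len(shared):
        warnings.warn(f"dropping {len(total) - len(shared)} samples not "
                      "present in every layer")
    features: list[FeatureDescriptor] = []
    blocks = []
    for df, layer in frames:
        df = df.loc[shared]
        oc = layer["omics_class"]
        dc = layer.get("data_class")
        for fid in df.columns.astype(str):
            full_id = fid if fid.endswith(f"-{oc}") else f"{fid}-{oc}"
            features.append(descriptor_from_id(full_id, oc, dc))
        blocks.append(df.to_numpy(dtype=float))
    values = np.hstack(blocks)
    ids = [f.feature_id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids across layers")
    dataset = OmicsDataset(list(shared), features, values)
    validate_dataset(dataset, strict=True)
    return dataset


def write_dataset(dataset: OmicsDataset, outdir: str | Path,
                  ) -> Path:
    """Write one TSV per omics class (features as rows) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layers = []
    classes = sorted({f.omics_class for f in dataset.features})
    for oc in classes:
        idx = [j for j, f in enumerate(dataset.features)
               if f.omics_class == oc]
        df = pd.DataFrame(dataset.values[:, idx].T,
                          index=[dataset.features[j].feature_id for j in idx],
                          columns=dataset.sample_ids)
        fname = f"{oc}.tsv"
        df.to_csv(outdir / fname, sep="\t")
        dc = dataset.features[idx[0]].data_class.value
        layers.append({"path": fname, "omics_class": oc, "data_class": dc,
                       "features_as_rows": True})
    manifest = outdir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"layers": layers}, fh)
    return manifest


def read_interactions(path: str | Path) -> InteractionTable:
    """Interaction table from delimited text.

    Expected columns: ``gene_a``, ``gene_b``, optional ``score`` in
    [0, 1], optional boolean ``directed``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    records = []
    for _, row in df.iterrows():
        score = row.get("score")
        if score is not None and pd.isna(score):
            score = None
        directed = bool(row.get("directed", False))
        records.append(InteractionRecord(str(row["gene_a"]),
                                         str(row["gene_b"]),
                                         None if score is None else float(score),
                                         directed))
    return InteractionTable(records)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    rows = [{"gene_a": r.gene_a, "gene_b": r.gene_b,
             "score": r.score, "directed": r.directed}
            for r in table.records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _model_document(model: MixtureModel, feature_ids: list[str]) -> dict:
    comps = []
    for k in range(model.K):
        params = model.params[k]
        comps.append({
            "edges": [[feature_ids[s], feature_ids[t]]
                      for s, t in model.dags[k].edges],
            "lambda": {feature_ids[j]: v for j, v in params.lam.items()},
            "m": {feature_ids[j]: v for j, v in params.m.items()},
            "sigma": {feature_ids[j]: v for j, v in params.sigma.items()},
            "beta": {feature_ids[j]: {feature_ids[s]: b
                                      for s, b in bs.items()}
                     for j, bs in params.beta.items()},
        })
    return {
        "K": model.K,
        "tau": model.tau.tolist(),
        "loglik": model.loglik,
        "aic": model.aic,
        "bic": model.bic,
        "seed": model.seed,
        "restarts": model.restarts,
        "n_outer_iterations": model.n_outer_iterations,
        "components": comps,
    }


def _edge_graph(edges: list[tuple[int, int]], feature_ids: list[str],
                ) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(feature_ids)
    g.add_edges_from((feature_ids[s], feature_ids[t]) for s, t in edges)
    return g


def write_results(result: FitResult, dataset: OmicsDataset,
                  outdir: str | Path,
                  consensus: list[list[tuple[int, int]]] | None = None,
                  ) -> dict[str, Path]:
    """Write assignments, model JSON, edge posteriors and consensus graphs.

    Returns a mapping of artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = result.model
    fids = dataset.feature_ids
    written: dict[str, Path] = {}

    gamma = result.memberships.gamma
    assign = pd.DataFrame(gamma,
                          columns=[f"gamma_{k + 1}" for k in range(model.K)])
    assign.insert(0, "sample", dataset.sample_ids)
    assign.insert(1, "cluster", result.memberships.hard + 1)
    p = outdir / "assignments.tsv"
    assign.to_csv(p, sep="\t", index=False)
    written["assignments"] = p

    p = outdir / "model.json"
    with open(p, "w") as fh:
        json.dump(_model_document(model, fids), fh, indent=1)
    written["model"] = p

    if result.posteriors is not None:
        rows = []
        for k, post in enumerate(result.posteriors):
            src, tgt = np.nonzero(post.probs > 0)
            for s, t in zip(src.tolist(), tgt.tolist()):
                rows.append({"source": fids[s], "target": fids[t],
                             "cluster": k + 1,
                             "posterior": float(post.probs[s, t])})
        p = outdir / "edge_posteriors.tsv"
        pd.DataFrame(rows, columns=["source", "target", "cluster",
                                    "posterior"]).to_csv(p, sep="\t",
                                                         index=False)
        written["edge_posteriors"] = p

    graphs = consensus if consensus is not None else \
        [dag.edges for dag in model.dags]
    for k, edges in enumerate(graphs):
        g = _edge_graph(edges, fids)
        pg = outdir / f"network_cluster{k + 1}.graphml"
        nx.write_graphml(g, pg)
        written[f"graphml_{k + 1}"] = pg
        ps = outdir / f"network_cluster{k + 1}.sif"
        with open(ps, "w") as fh:
            for s, t in edges:
                fh.write(f"{fids[s]}\tdirected\t{fids[t]}\n")
        written[f"sif_{k + 1}"] = ps

    p = outdir / "run.log"
    with open(p, "w") as fh:
        fh.write(f"K={model.K} seed={model.seed} restarts={model.restarts} "
                 f"loglik={model.loglik:.6f} aic={model.aic:.3f} "
                 f"bic={model.bic:.3f} "
                 f"outer_iterations={model.n_outer_iterations}\n")
    written["log"] = p
    return written
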