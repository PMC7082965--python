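"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are TSV; graphs are exported both as a weighted edge
list (convenient) and GraphML (faithful, keeps isolated nodes).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .community import Partition
from .errors import ValidationError
from .feature_selection import COMBINED_COLUMNS, DE_COLUMNS, DETable


def read_expression(path) -> pd.DataFrame:
    """Gene x sample expression TSV (first column gene_id, rest samples)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise ValidationError(f"{path}: empty expression matrix")
    frame.index.name = "gene_id"
    return frame.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path, label: str | None = None) -> DETable:
    """DE table TSV with header ``gene_id log2_fc p_value fdr``.

    The comparison label defaults to the file stem.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing DE columns {missing}")
    return DETable(label=label or Path(path).stem, frame=frame)


def write_de_table(table: DETable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_combined(records: pd.DataFrame, path) -> None:
    records.loc[:, COMBINED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_combined(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in COMBINED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing combined columns {missing}")
    return frame


def write_partition(partition: Partition, path) -> None:
    """Partition TSV ``gene_id  module`` with 0 meaning unassigned."""
    frame = pd.DataFrame(
        sorted(partition.assignment.items(), key=lambda kv: str(kv[0])),
        columns=["gene_id", "module"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_partition(path) -> Partition:
    frame = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "module"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing partition column {col!r}")
    if frame["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_ids in partition")
    return Partition(dict(zip(frame["gene_id"], frame["module"].astype(int))))


def write_edge_list(graph: nx.Graph, path) -> None:
    """Weighted edge list TSV ``gene_a gene_b correlation adjacency``."""
    rows = [
        {
            "gene_a": u,
            "gene_b": v,
            "correlation": data.get("correlation", float("nan")),
            "adjacency": data.get("weight", float("nan")),
        }
        for u, v, data in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation", "adjacency"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> nx.Graph:
    """Rebuild a graph from an edge list (isolated nodes are not recoverable)."""
    frame = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for row in frame.itertuples(index=False):
        graph.add_edge(
            row.gene_a, row.gene_b,
            correlation=float(row.correlation), weight=float(row.adjacency),
        )
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def write_sweep(points, path) -> None:
    frame = pd.DataFrame(
        [
            {
                "fdr_cutoff": p.fdr_cutoff,
                "n_genes": p.n_genes,
                "n_modules": p.n_modules,
                "median_module_size": p.median_module_size,
                "degenerate": p.degenerate,
            }
            for p in points
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
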