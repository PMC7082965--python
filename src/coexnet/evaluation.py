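"""Partition comparison and the FDR-sweep cutoff selection.

The Rand index counts pairs of genes on which two partitions agree —
together in both or apart in both — as a fraction of all pairs.  Genes
unassigned to any module are treated as singleton clusters of their own
(they are not similar to each other, so they should not be counted as one
big agreeing cluster).

The FDR sweep reruns feature selection, network construction and module
detection over a grid of FDR cutoffs and records how many genes and
modules survive and the median module size; the cutoff maximizing the
median module size marks the best trade-off between stringency and
interpretable module structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .community import UNASSIGNED, Partition, maximize
from .errors import PartitionMismatchError
from .feature_selection import filter_significant
from .network import pearson_correlation, pick_soft_threshold, soft_adjacency, threshold_edges


@dataclass
class RandIndexResult:
    ri: float
    n_items: int
    agreements: int
    pairs: int


@dataclass
class SweepPoint:
    fdr_cutoff: float
    n_genes: int
    n_modules: int
    median_module_size: float
    degenerate: bool = False


def _singletonized(partition: Partition, offset: int) -> dict:
    """Assignment with each unassigned item given a unique label."""
    labels = {}
    counter = 0
    for item, lab in partition.assignment.items():
        if lab == UNASSIGNED:
            counter += 1
            labels[item] = ("u", offset, counter)
        else:
            labels[item] = ("m", lab)
    return labels


def rand_index(
    p1: Partition, p2: Partition, unassigned_as_singletons: bool = True
) -> RandIndexResult:
    """Rand index of two partitions over the same items.

    With ``unassigned_as_singletons`` (the default), every unassigned item
    is first converted into a cluster by itself within its own partition.
    Agreements are counted through the contingency table:
    ``a + b = C(n,2) - sum_i C(n_i.,2) - sum_j C(n_.j,2) + 2*sum_ij C(n_ij,2)``.
    """
    items1, items2 = set(p1.assignment), set(p2.assignment)
    if items1 != items2:
        raise PartitionMismatchError(items1 - items2, items2 - items1)
    n = len(items1)
    pairs = comb(n, 2)
    if unassigned_as_singletons:
        l1 = _singletonized(p1, 1)
        l2 = _singletonized(p2, 2)
    else:
        l1 = dict(p1.assignment)
        l2 = dict(p2.assignment)
    contingency: dict[tuple, int] = {}
    row: dict = {}
    col: dict = {}
    for item in items1:
        a, b = l1[item], l2[item]
        contingency[(a, b)] = contingency.get((a, b), 0) + 1
        row[a] = row.get(a, 0) + 1
        col[b] = col.get(b, 0) + 1
    same_both = sum(comb(c, 2) for c in contingency.values())
    same1 = sum(comb(c, 2) for c in row.values())
    same2 = sum(comb(c, 2) for c in col.values())
    agreements = pairs - same1 - same2 + 2 * same_both
    ri = agreements / pairs if pairs else 1.0
    return RandIndexResult(ri=float(ri), n_items=n, agreements=int(agreements), pairs=pairs)


def count_unassigned(partition: Partition) -> int:
    """Number of items carrying the UNASSIGNED label."""
    return partition.n_unassigned


def median_module_size(partition: Partition) -> float:
    """Median size over assigned modules (unassigned singletons excluded)."""
    sizes = partition.module_sizes()
    return float(np.median(sizes)) if sizes else float("nan")


def fdr_sweep(
    records: pd.DataFrame,
    expr: pd.DataFrame,
    cutoffs: list[float],
    min_abs_log2fc: float = 0.59,
    beta: int | None = None,
    target_r2: float = 0.9,
    min_abs_corr: float = 0.7,
    objective: str = "Qds",
    seed: int = 0,
) -> list[SweepPoint]:
    """Run select -> network -> cluster across a grid of FDR cutoffs.

    ``beta=None`` refits the soft threshold at each cutoff; a fixed integer
    pins it.  Cutoffs yielding fewer than 3 genes are flagged degenerate
    and skipped rather than failing the whole sweep.
    """
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    missing = set(records["gene_id"]) - set(expr.index)
    if missing:
        raise ValueError(
            f"expression matrix lacks {len(missing)} combined genes "
            f"(e.g. {sorted(missing)[:5]})"
        )
    points = []
    for cutoff in cutoffs:
        selected = filter_significant(records, cutoff, min_abs_log2fc)
        genes = selected["gene_id"].tolist()
        if len(genes) < 3:
            points.append(
                SweepPoint(cutoff, len(genes), 0, float("nan"), degenerate=True)
            )
            continue
        corr = pearson_correlation(expr.loc[genes])
        power = beta if beta is not None else pick_soft_threshold(corr, target_r2=target_r2).beta
        graph = threshold_edges(corr, soft_adjacency(corr, power), min_abs_corr)
        if graph.number_of_edges() == 0:
            points.append(
                SweepPoint(cutoff, len(genes), 0, float("nan"), degenerate=True)
            )
            continue
        partition, _ = maximize(graph, objective=objective, seed=seed)
        points.append(
            SweepPoint(
                fdr_cutoff=cutoff,
                n_genes=len(genes),
                n_modules=partition.n_modules,
                median_module_size=median_module_size(partition),
            )
        )
    return points


def select_cutoff(points: list[SweepPoint]) -> SweepPoint:
    """Sweep point with the largest median module size (first on ties)."""
    usable = [p for p in points if not p.degenerate and np.isfinite(p.median_module_size)]
    if not usable:
        raise ValueError("no usable sweep points")
    return max(usable, key=lambda p: p.median_module_size)
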