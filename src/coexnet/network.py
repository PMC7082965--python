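"""Soft-threshold co-expression network construction.

The network is built in the unsigned weighted-correlation convention: the
Pearson correlation matrix ``r`` of gene expression rows is raised to a
power, ``a_ij = |r_ij|**beta``, which suppresses weak correlations smoothly
instead of cutting them.  ``beta`` is chosen so the resulting connectivity
distribution approximates a scale-free topology, assessed by the R² of a
log-log regression of the connectivity histogram.  A hard filter on
``|r_ij|`` then decides which pairs become graph edges; edge weights carry
the soft adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantGeneError, DegenerateFitError

DEFAULT_BETA_GRID = tuple(range(1, 21))


@dataclass
class ScaleFreeFit:
    """R² and slope of the log10(frequency) ~ log10(connectivity) regression."""

    r_squared: float
    slope: float


@dataclass
class SoftThresholdFit:
    """Chosen soft-threshold power and its scale-free fit.

    ``target_met`` is False when no candidate reached the target R², in which
    case ``beta`` is the candidate with the best fit (flagged, not fatal —
    a weaker scale-free fit is a data property, not an error).
    """

    beta: int
    r_squared: float
    slope: float
    target_met: bool
    candidate_grid: list[int]
    table: pd.DataFrame = field(repr=False, default=None)


def pearson_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation across samples.

    Parameters
    ----------
    expr
        Genes in rows, samples in columns; at least 3 of each, no missing
        values, no constant rows.
    """
    values = expr.to_numpy(float)
    n, m = values.shape
    if n < 3 or m < 3:
        raise ValueError(f"need at least 3 genes and 3 samples, got {n}x{m}")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    constant = values.std(axis=1) == 0
    if constant.any():
        raise ConstantGeneError(expr.index[constant])
    r = np.corrcoef(values)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def soft_adjacency(corr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Power adjacency ``a_ij = |r_ij|**beta`` with a zero diagonal.

    The diagonal is zeroed (no self-loops) so connectivity
    ``k_i = sum_j a_ij`` counts only neighbours.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    a = np.abs(corr.to_numpy(float)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def _powerlaw_fit(connectivity: np.ndarray, n_bins: int) -> ScaleFreeFit:
    """Regress log10(bin frequency) on log10(mean connectivity per bin)."""
    k = np.asarray(connectivity, float)
    if k.max() == k.min():
        raise DegenerateFitError(
            "all connectivities are equal; scale-free fit undefined"
        )
    counts, edges = np.histogram(k, bins=n_bins)
    bin_idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.full(n_bins, np.nan)
    for b in range(n_bins):
        members = k[bin_idx == b]
        if members.size:
            mean_k[b] = members.mean()
    keep = (counts > 0) & (mean_k > 0)
    if keep.sum() < 3:
        raise DegenerateFitError(
            f"only {int(keep.sum())} usable bins; need >= 3 for a fit"
        )
    x = np.log10(mean_k[keep])
    y = np.log10(counts[keep])
    fit = stats.linregress(x, y)
    return ScaleFreeFit(r_squared=float(fit.rvalue**2), slope=float(fit.slope))


def scale_free_fit(adjacency: pd.DataFrame | np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit of a weighted adjacency matrix.

    Connectivity is the row sum of the adjacency (diagonal excluded); its
    histogram over ``n_bins`` equal-width bins is regressed on the mean
    connectivity per bin in log-log space.  Empty bins are dropped.  A
    negative slope with high R² indicates approximate scale-free topology.
    """
    a = np.asarray(adjacency, float)
    if a.shape[0] < 10:
        raise ValueError("scale-free fit needs at least 10 nodes")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    return _powerlaw_fit(a.sum(axis=1), n_bins)


def pick_soft_threshold(
    corr: pd.DataFrame,
    grid: tuple[int, ...] = DEFAULT_BETA_GRID,
    target_r2: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdFit:
    """Choose the smallest power whose scale-free fit reaches ``target_r2``.

    If no candidate reaches the target, the best-fitting power is returned
    with ``target_met=False``.  All candidate fits are kept in ``table``.
    """
    grid = sorted(int(b) for b in grid)
    if not grid or grid[0] < 1:
        raise ValueError("grid must be non-empty positive integers")
    if not (0 < target_r2 < 1):
        raise ValueError(f"target_r2 must be in (0, 1), got {target_r2}")
    rows = []
    for beta in grid:
        adj = soft_adjacency(corr, beta)
        try:
            fit = scale_free_fit(adj, n_bins=n_bins)
            rows.append(
                {"beta": beta, "r_squared": fit.r_squared, "slope": fit.slope}
            )
        except DegenerateFitError:
            rows.append({"beta": beta, "r_squared": np.nan, "slope": np.nan})
    table = pd.DataFrame(rows)
    ok = table[table["r_squared"] >= target_r2]
    if len(ok):
        row = ok.iloc[0]
        met = True
    else:
        if table["r_squared"].isna().all():
            raise DegenerateFitError("no candidate power produced a usable fit")
        row = table.loc[table["r_squared"].idxmax()]
        met = False
    return SoftThresholdFit(
        beta=int(row["beta"]),
        r_squared=float(row["r_squared"]),
        slope=float(row["slope"]),
        target_met=met,
        candidate_grid=grid,
        table=table,
    )


def threshold_edges(
    corr: pd.DataFrame,
    adjacency: pd.DataFrame,
    min_abs_corr: float = 0.7,
    signed: bool = False,
) -> nx.Graph:
    """Hard-threshold the correlation matrix into a weighted graph.

    An edge (i, j) is kept when ``|r_ij| >= min_abs_corr`` (or
    ``r_ij >= min_abs_corr`` with ``signed=True``).  Every gene stays in the
    node set, so genes with no retained edge remain as isolated nodes —
    these are the genes later reported as unassigned.  Edges carry both the
    raw ``correlation`` and the soft-adjacency ``weight``.
    """
    if not (0 < min_abs_corr < 1):
        raise ValueError(f"min_abs_corr must be in (0, 1), got {min_abs_corr}")
    r = corr.to_numpy(float)
    a = adjacency.to_numpy(float)
    genes = list(corr.index)
    strength = r if signed else np.abs(r)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = strength[iu, ju] >= min_abs_corr
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(
        (genes[i], genes[j], {"correlation": float(r[i, j]), "weight": float(a[i, j])})
        for i, j in zip(iu[keep], ju[keep])
    )
    return graph
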