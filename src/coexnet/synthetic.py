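"""Synthetic data with the statistical structure the pipeline assumes.

Two generators are provided:

* ``generate_modular_expression`` plants co-expression modules with a
  latent-factor construction: every gene in a module is
  ``sqrt(rho) * f + sqrt(1 - rho) * noise`` for a shared per-module factor
  ``f`` across samples, giving expected within-module Pearson correlation
  ``rho``.  This mirrors the eigengene picture of a co-expression module —
  many genes tracking one underlying profile.  Noise genes are independent
  normals and form the planted "unassigned" set.

* ``generate_counts`` emulates the upstream RNA-seq experiment: negative
  binomial counts for two groups (control vs. treated) at several
  timepoints, with a fraction of genes shifted by a log2 fold change in
  the treated group and log-normal library-size factors.

``approximate_de_test`` is a deliberately simple two-sample test on
normalized log counts with Benjamini–Hochberg correction.  It is NOT
equivalent to a negative-binomial GLM fit (edgeR-style); it exists only so
synthetic end-to-end runs can produce DE tables of the right shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import UNASSIGNED, Partition
from .feature_selection import DETable

DEFAULT_TIMEPOINTS = ("1_month", "2_months", "4_months", "9_months", "12_months")


@dataclass
class ModuleSpec:
    """Planted-module expression design.

    Defaults: five modules of 20 genes at within-module correlation 0.95
    over 30 samples — strong, clearly separated modules on a sample size
    matching a two-group, five-timepoint, three-replicate design.
    """

    sizes: tuple = (20, 20, 20, 20, 20)
    within_correlation: float = 0.95
    n_noise_genes: int = 0
    n_samples: int = 30
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.sizes):
            raise ValueError("module sizes must all be >= 2")
        if not (0 < self.within_correlation <= 1):
            raise ValueError("within_correlation must be in (0, 1]")
        if self.n_noise_genes < 0 or self.n_samples < 3:
            raise ValueError("need n_noise_genes >= 0 and n_samples >= 3")


@dataclass
class CountSimSpec:
    """Negative-binomial count design with condition x timepoint effects.

    Defaults follow a small two-group serial-sacrifice design: 3 replicates
    per group at 5 timepoints, 10% of genes differentially expressed with a
    2-fold log2 effect, NB dispersion 0.1 (variance = mu + 0.1 mu^2).
    """

    n_genes: int = 1000
    n_per_group: int = 3
    timepoints: tuple = DEFAULT_TIMEPOINTS
    de_fraction: float = 0.1
    log2_fc_effect: float = 2.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


def generate_modular_expression(spec: ModuleSpec) -> tuple[pd.DataFrame, Partition]:
    """Expression matrix with planted modules, plus the truth partition.

    Noise genes carry the UNASSIGNED label in the truth partition.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_correlation
    rows, gene_ids, truth = [], [], {}
    counter = 0
    for module, size in enumerate(spec.sizes, start=1):
        factor = rng.standard_normal(spec.n_samples)
        noise = rng.standard_normal((size, spec.n_samples))
        rows.append(np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise)
        for _ in range(size):
            counter += 1
            gid = f"gene_{counter:04d}"
            gene_ids.append(gid)
            truth[gid] = module
    if spec.n_noise_genes:
        rows.append(rng.standard_normal((spec.n_noise_genes, spec.n_samples)))
        for _ in range(spec.n_noise_genes):
            counter += 1
            gid = f"gene_{counter:04d}"
            gene_ids.append(gid)
            truth[gid] = UNASSIGNED
    values = np.vstack(rows)
    samples = [f"sample_{j:02d}" for j in range(1, spec.n_samples + 1)]
    expr = pd.DataFrame(values, index=gene_ids, columns=samples)
    expr.index.name = "gene_id"
    return expr, Partition(truth)


def generate_counts(
    spec: CountSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """NB count matrix, sample metadata, and the truth DE table.

    Returns ``(counts, samples, truth)`` where ``samples`` has columns
    ``sample, group, timepoint, replicate`` and ``truth`` has
    ``gene_id, is_de, log2_fc``.  The same DE gene set is shifted at every
    timepoint (a persistent exposure effect); effect direction is random
    per gene.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"gene_{i:05d}" for i in range(1, spec.n_genes + 1)]
    base_mean = rng.lognormal(mean=4.0, sigma=1.5, size=spec.n_genes)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    log2_fc = np.zeros(spec.n_genes)
    log2_fc[de_idx] = signs * spec.log2_fc_effect
    r = 1.0 / spec.nb_dispersion

    columns, data, meta = [], [], []
    for timepoint in spec.timepoints:
        for group, shift in (("control", 0.0), ("treated", 1.0)):
            mu_group = base_mean * 2.0 ** (log2_fc * shift)
            for rep in range(1, spec.n_per_group + 1):
                lib = rng.lognormal(mean=0.0, sigma=0.15)
                mu = np.maximum(mu_group * lib, 1e-8)
                p = r / (r + mu)
                data.append(rng.negative_binomial(r, p))
                name = f"{group}_{timepoint}_r{rep}"
                columns.append(name)
                meta.append(
                    {"sample": name, "group": group, "timepoint": timepoint,
                     "replicate": rep}
                )
    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=columns)
    counts.index.name = "gene_id"
    samples = pd.DataFrame(meta)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": log2_fc != 0, "log2_fc": log2_fc}
    )
    return counts, samples, truth


def approximate_de_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    timepoint: str,
    prior_df: float = 4.0,
) -> DETable:
    """Two-sample normal-approximation Wald test on normalized log counts.

    Counts are library-size normalized to counts-per-million and log2(x+1)
    transformed.  The per-gene pooled variance is moderated toward the
    genome-wide mean variance with ``prior_df`` pseudo-observations (an
    empirical-Bayes squeeze, default equal to the residual df of a
    3-vs-3 design); the group-difference Wald statistic is referred to the
    standard normal and BH-adjusted.  A coarse stand-in for an NB GLM fit,
    for synthetic end-to-end runs only — the normal reference remains
    approximate with few replicates.
    """
    sub = samples[samples["timepoint"] == timepoint]
    ctrl = sub.loc[sub["group"] == "control", "sample"].tolist()
    trt = sub.loc[sub["group"] == "treated", "sample"].tolist()
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError(f"timepoint {timepoint!r}: need >= 2 samples per group")
    cpm = counts / counts.sum(axis=0) * 1e6
    log_expr = np.log2(cpm + 1.0)
    a = log_expr[trt].to_numpy()
    b = log_expr[ctrl].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    resid_df = n1 + n2 - 2
    pooled = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / resid_df
    moderated = (prior_df * pooled.mean() + resid_df * pooled) / (prior_df + resid_df)
    se = np.sqrt(moderated * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = (a.mean(axis=1) - b.mean(axis=1)) / se
    p_values = np.where(np.isfinite(wald), 2.0 * stats.norm.sf(np.abs(wald)), 1.0)
    fdr = multipletests(p_values, method="fdr_bh")[1]
    frame = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2_fc": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p_values,
            "fdr": fdr,
        }
    )
    return DETable(label=timepoint, frame=frame)


@dataclass
class PipelineBundle:
    """A complete, internally consistent set of synthetic pipeline inputs."""

    expression: pd.DataFrame
    de_tables: list = field(repr=False)
    truth: Partition = field(repr=False)


def generate_pipeline_bundle(
    seed: int = 0,
    module_sizes: tuple = (20, 20, 20, 20, 20),
    within_correlation: float = 0.95,
    n_unassignable: int = 10,
    n_subthreshold: int = 30,
    n_samples: int = 30,
    timepoints: tuple = DEFAULT_TIMEPOINTS,
) -> PipelineBundle:
    """Expression matrix plus matching DE tables for an end-to-end run.

    Three gene classes are planted:

    * module genes — highly significant (min FDR well below 1e-5) and
      co-expressed in blocks, so they pass selection and cluster;
    * ``n_unassignable`` significant-but-uncorrelated genes, which pass
      selection, stay isolated after edge thresholding and should end up
      unassigned (their truth label is UNASSIGNED);
    * ``n_subthreshold`` genes significant per-timepoint (FDR <= 0.05) but
      above the network-stage cutoff, which selection should drop.

    The truth partition covers the genes expected to enter the network
    (modules + unassignable); deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    expr_spec = ModuleSpec(
        sizes=tuple(module_sizes),
        within_correlation=within_correlation,
        n_noise_genes=n_unassignable + n_subthreshold,
        n_samples=n_samples,
        seed=int(rng.integers(2**31)),
    )
    expression, expr_truth = generate_modular_expression(expr_spec)
    genes = list(expression.index)
    n_network = sum(module_sizes) + n_unassignable
    network_genes = genes[:n_network]
    sub_genes = genes[n_network:]
    truth = Partition({g: expr_truth.assignment[g] for g in network_genes})

    min_fdr = {}
    lfc = {}
    for g in network_genes:
        min_fdr[g] = 10.0 ** (-rng.uniform(6.0, 11.0))
        lfc[g] = rng.choice([-1, 1]) * rng.uniform(0.65, 3.0)
    for g in sub_genes:
        min_fdr[g] = 10.0 ** (-rng.uniform(1.5, 4.0))
        lfc[g] = rng.choice([-1, 1]) * rng.uniform(0.3, 2.0)

    tables = []
    best_tp = {g: rng.integers(len(timepoints)) for g in genes}
    for t, label in enumerate(timepoints):
        rows = []
        for g in genes:
            present = t == best_tp[g] or rng.random() < 0.4
            if not present:
                continue
            fdr = min_fdr[g] if t == best_tp[g] else min(
                min_fdr[g] * 10.0 ** rng.uniform(0.5, 3.0), 0.05
            )
            # the min-FDR row keeps the exact planted effect so the
            # fold-change filter sees |log2_fc| >= 0.65 for network genes
            rows.append(
                {
                    "gene_id": g,
                    "log2_fc": lfc[g] if t == best_tp[g] else lfc[g] * rng.uniform(0.8, 1.2),
                    "p_value": fdr * rng.uniform(0.05, 1.0),
                    "fdr": fdr,
                }
            )
        tables.append(DETable(label=label, frame=pd.DataFrame(rows)))
    return PipelineBundle(expression=expression, de_tables=tables, truth=truth)
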