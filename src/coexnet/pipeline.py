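"""End-to-end orchestration: select features, build the network, cluster,
test significance, optionally sweep the FDR cutoff, and write artifacts."""

from __future__ import annotations

import importlib.metadata
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import yaml

from . import community, evaluation, io, network, significance
from .errors import PipelineError
from .feature_selection import combine_timepoints, filter_significant

# stage-specific seed offsets so stages are independently reproducible
_SEED_CLUSTER = 0
_SEED_NULL = 1
_SEED_SWEEP = 2


@dataclass
class PipelineConfig:
    """Tunable parameters; defaults follow the stringent network workflow.

    ``beta=None`` selects the soft threshold automatically as the smallest
    power on ``beta_grid`` reaching ``target_r2``.
    """

    fdr_max: float = 1e-5
    min_abs_log2fc: float = 0.59
    beta: int | None = None
    beta_grid: tuple = network.DEFAULT_BETA_GRID
    target_r2: float = 0.9
    min_abs_corr: float = 0.7
    signed: bool = False
    objective: str = "Qds"
    n_permutations: int = 1000
    null_model: str = "uniform"
    null_objective: str = "Q"
    min_module_size: int = 1
    restarts: int = 1
    seed: int = 0
    sweep_cutoffs: tuple | None = None

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["beta_grid"] = list(self.beta_grid)
        if self.sweep_cutoffs is not None:
            payload["sweep_cutoffs"] = list(self.sweep_cutoffs)
        return payload

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("beta_grid", "sweep_cutoffs"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    outdir: Path
    partition: community.Partition
    score: community.ObjectiveScore
    null_summary: significance.NullSummary | None
    fit: network.SoftThresholdFit | None
    n_selected: int
    sweep_points: list = field(default_factory=list)


def _versions() -> dict:
    vers = {
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
    try:
        vers["coexnet"] = importlib.metadata.version("coexnet")
    except importlib.metadata.PackageNotFoundError:
        vers["coexnet"] = "unknown"
    return vers


def run_pipeline(
    config: PipelineConfig,
    expression_path,
    de_table_paths,
    outdir,
    run_significance: bool = True,
) -> PipelineResult:
    """Run every stage and write the artifact set to ``outdir``.

    Writes: ``combined.tsv`` (merged DE records), ``selected.tsv``,
    ``edges.tsv`` + ``network.graphml``, ``partition.tsv``,
    ``clustering.json``, ``significance.json`` (unless disabled),
    ``sweep.tsv`` (if requested) and ``run_log.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(expression_path)
    tables = [io.read_de_table(p) for p in de_table_paths]

    combined = combine_timepoints(tables)
    io.write_combined(combined, outdir / "combined.tsv")
    selected = filter_significant(combined, config.fdr_max, config.min_abs_log2fc)
    io.write_combined(selected, outdir / "selected.tsv")
    genes = selected["gene_id"].tolist()
    if len(genes) < 3:
        raise PipelineError(
            f"only {len(genes)} genes pass FDR <= {config.fdr_max} and "
            f"|log2FC| >= {config.min_abs_log2fc}; need at least 3"
        )
    missing = sorted(set(genes) - set(expr.index))
    if missing:
        raise PipelineError(
            f"{len(missing)} selected genes absent from the expression "
            f"matrix: {missing[:10]}"
        )

    corr = network.pearson_correlation(expr.loc[genes])
    if config.beta is None:
        fit = network.pick_soft_threshold(
            corr, grid=config.beta_grid, target_r2=config.target_r2
        )
        beta = fit.beta
    else:
        beta = int(config.beta)
        adj_tmp = network.soft_adjacency(corr, beta)
        sf = network.scale_free_fit(adj_tmp)
        fit = network.SoftThresholdFit(
            beta=beta,
            r_squared=sf.r_squared,
            slope=sf.slope,
            target_met=sf.r_squared >= config.target_r2,
            candidate_grid=[beta],
        )
    adjacency = network.soft_adjacency(corr, beta)
    graph = network.threshold_edges(
        corr, adjacency, config.min_abs_corr, signed=config.signed
    )
    io.write_edge_list(graph, outdir / "edges.tsv")
    io.write_graphml(graph, outdir / "network.graphml")
    if graph.number_of_edges() == 0:
        raise PipelineError(
            f"no gene pair reaches |r| >= {config.min_abs_corr}; nothing to cluster"
        )

    partition, _ = community.maximize(
        graph,
        objective=config.objective,
        seed=config.seed + _SEED_CLUSTER,
        restarts=config.restarts,
    )
    partition = community.finalize_partition(partition, graph, config.min_module_size)
    score = community.ObjectiveScore(
        q=community.modularity(graph, partition),
        qds=community.modularity_density(graph, partition),
        objective_used=config.objective,
    )
    io.write_partition(partition, outdir / "partition.tsv")
    io.write_json(
        {
            "objective": score.objective,
            "objective_used": score.objective_used,
            "Q": score.q,
            "Qds": score.qds,
            "n_modules": partition.n_modules,
            "n_unassigned": partition.n_unassigned,
            "module_sizes": partition.module_sizes(),
            "beta": beta,
            "scale_free_r_squared": fit.r_squared,
            "scale_free_target_met": fit.target_met,
        },
        outdir / "clustering.json",
    )

    null_summary = None
    if run_significance:
        null_summary = significance.modularity_zscore(
            graph,
            n_permutations=config.n_permutations,
            objective=config.null_objective,
            seed=config.seed + _SEED_NULL,
            null_model=config.null_model,
        )
        io.write_json(null_summary.to_dict(), outdir / "significance.json")

    sweep_points = []
    if config.sweep_cutoffs:
        sweep_points = evaluation.fdr_sweep(
            combined,
            expr,
            sorted(config.sweep_cutoffs),
            min_abs_log2fc=config.min_abs_log2fc,
            beta=config.beta,
            target_r2=config.target_r2,
            min_abs_corr=config.min_abs_corr,
            objective=config.objective,
            seed=config.seed + _SEED_SWEEP,
        )
        io.write_sweep(sweep_points, outdir / "sweep.tsv")

    io.write_json(
        {
            "config": config.to_dict(),
            "versions": _versions(),
            "n_input_genes": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
            "n_combined": int(len(combined)),
            "n_selected": len(genes),
            "n_edges": graph.number_of_edges(),
        },
        outdir / "run_log.json",
    )
    return PipelineResult(
        outdir=outdir,
        partition=partition,
        score=score,
        null_summary=null_summary,
        fit=fit,
        n_selected=len(genes),
        sweep_points=sweep_points,
    )
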