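"""End-to-end orchestration: config, Stage I-III pipeline, network export.

``run_causnet`` wires the stages together: load/validate -> replicate
summaries -> point-estimate network on the unperturbed means -> B
perturbation runs -> weight aggregation -> threshold -> export.  Defaults
reproduce the study settings: k = 3 regulators per target, alpha = 0.05,
B = 100 perturbations, virtual time shift on.

Exports: weighted edge-list TSV (with a reproducibility metadata header),
Cytoscape SIF, and GraphML via networkx.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from causnet.dataset import (
    ExpressionDataset,
    load_expression,
    summarize_replicates,
)
from causnet.granger import GrangerResult
from causnet.perturbation import (
    SingleRunNetwork,
    WeightedNetwork,
    infer_single_run,
    run_perturbation_analysis,
    threshold_network,
)
from causnet.regression import SparseFit

__all__ = [
    "RunConfig",
    "RunResult",
    "run_causnet",
    "export_sif",
    "export_graphml",
    "write_weighted_tsv",
    "load_weighted_tsv",
]

logger = logging.getLogger("causnet")

SIF_RELATION = {"activation": "activates", "repression": "represses", "ambiguous": "ambiguous"}


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one inference run.

    Defaults are the study settings: ``k=3``, ``alpha=0.05``,
    ``n_perturbations=100``, virtual time shift enabled, perturbation
    variance = squared standard error of the replicate mean.
    """

    input_path: str | None = None
    gene_list: str | None = None
    conditions: tuple[str, ...] | None = None
    k: int = 3
    alpha: float = 0.05
    n_perturbations: int = 100
    virtual_shift: bool = True
    variance_mode: str = "sem"
    granger_literal: bool = False
    intercept: bool = True
    standardize: bool = False
    method: str = "exhaustive"
    signed: bool = False
    seed: int | None = None
    weight_threshold: float = 0.0
    out_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perturbations < 0:
            raise ValueError("n_perturbations must be >= 0")
        if self.n_perturbations > 0 and self.seed is None:
            raise ValueError(
                "a master seed is required when perturbations are requested "
                "(no silent nondeterminism)"
            )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    point_estimate: SingleRunNetwork
    weighted: WeightedNetwork | None
    thresholded: WeightedNetwork | None
    fits: list[SparseFit]
    granger_results: list[GrangerResult]
    timings: dict[str, float] = field(default_factory=dict)


def run_causnet(
    config: RunConfig, dataset: ExpressionDataset | None = None
) -> RunResult:
    """Run the full three-stage pipeline under ``config``.

    ``dataset`` may be passed directly (e.g. a simulated one); otherwise it
    is loaded from ``config.input_path``.  When ``config.out_prefix`` is
    set, the weighted network, SIF, GraphML, and Stage I/II diagnostics are
    written with a shared metadata header.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if dataset is None:
        if config.input_path is None:
            raise ValueError("either a dataset or config.input_path is required")
        dataset = load_expression(
            config.input_path, gene_list=config.gene_list, signed=config.signed
        )
    if config.conditions is not None:
        dataset = dataset.subset(conditions=list(config.conditions))
    if config.n_perturbations > 0 and dataset.n_replicates < 2:
        raise ValueError(
            "perturbation analysis needs >= 2 replicates; "
            "set n_perturbations=0 for a point estimate only"
        )
    stats = summarize_replicates(dataset)
    timings["load"] = time.perf_counter() - t0
    logger.info(
        "loaded %d genes x %d conditions x %d times x %d replicates",
        *dataset.shape,
    )

    t0 = time.perf_counter()
    point, fits, granger_results = infer_single_run(
        stats.mean,
        dataset.gene_ids,
        dataset.condition_ids,
        dataset.time_labels,
        k=config.k,
        alpha=config.alpha,
        virtual_shift=config.virtual_shift,
        intercept=config.intercept,
        granger_literal=config.granger_literal,
        standardize=config.standardize,
        method=config.method,
        provenance="point-estimate",
        collect_diagnostics=True,
    )
    timings["point_estimate"] = time.perf_counter() - t0
    logger.info(
        "point estimate: %d edges (%.2fs)", len(point.edges), timings["point_estimate"]
    )

    weighted = thresholded = None
    if config.n_perturbations > 0:
        t0 = time.perf_counter()

        def _progress(done: int, total: int) -> None:
            if done % 10 == 0 or done == total:
                logger.info("perturbation %d/%d", done, total)

        weighted = run_perturbation_analysis(
            stats,
            dataset.gene_ids,
            dataset.condition_ids,
            dataset.time_labels,
            n_perturbations=config.n_perturbations,
            seed=config.seed if config.seed is not None else 0,
            k=config.k,
            alpha=config.alpha,
            virtual_shift=config.virtual_shift,
            intercept=config.intercept,
            granger_literal=config.granger_literal,
            variance_mode=config.variance_mode,  # type: ignore[arg-type]
            standardize=config.standardize,
            method=config.method,
            progress=_progress,
        )
        thresholded = threshold_network(weighted, config.weight_threshold)
        timings["perturbation"] = time.perf_counter() - t0
        logger.info(
            "aggregated %d perturbations: %d edges, %d above weight %.3g (%.2fs)",
            config.n_perturbations,
            len(weighted.edges),
            len(thresholded.edges),
            config.weight_threshold,
            timings["perturbation"],
        )

    result = RunResult(
        config=config,
        point_estimate=point,
        weighted=weighted,
        thresholded=thresholded,
        fits=fits,
        granger_results=granger_results,
        timings=timings,
    )
    if config.out_prefix:
        _write_outputs(result)
    return result


def _metadata_lines(config: RunConfig) -> list[str]:
    from causnet import __version__

    return [
        f"# causnet {__version__}",
        f"# config_hash: {config.config_hash()}",
        f"# seed: {config.seed}",
        f"# k: {config.k}  alpha: {config.alpha}  perturbations: {config.n_perturbations}",
        f"# virtual_shift: {config.virtual_shift}  variance_mode: {config.variance_mode}",
    ]


def _write_outputs(result: RunResult) -> None:
    prefix = Path(result.config.out_prefix)  # type: ignore[arg-type]
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = _metadata_lines(result.config)
    net = result.thresholded if result.thresholded is not None else None
    if net is not None:
        write_weighted_tsv(net, f"{prefix}.weighted.tsv", metadata=meta)
        export_sif(net, f"{prefix}.sif")
        export_graphml(net, f"{prefix}.graphml")
    # Stage I/II diagnostics
    fit_rows = [
        (
            f.target,
            ",".join(f.regulators),
            ",".join(f"{c:.10g}" for c in f.coefficients),
            f"{f.self_coefficient:.10g}",
            f"{f.intercept:.10g}",
            f"{f.rss:.10g}",
        )
        for f in result.fits
    ]
    pd.DataFrame(
        fit_rows,
        columns=["target", "regulators", "coefficients", "self_coefficient", "intercept", "rss"],
    ).to_csv(f"{prefix}.fits.tsv", sep="\t", index=False)
    gr_rows = [
        (g.target, g.regulator, g.f_stat, g.p_value, g.kept)
        for g in result.granger_results
    ]
    pd.DataFrame(
        gr_rows, columns=["target", "regulator", "f_stat", "p_value", "kept"]
    ).to_csv(f"{prefix}.granger.tsv", sep="\t", index=False)


def write_weighted_tsv(
    net: WeightedNetwork, path: str | Path, metadata: Sequence[str] | None = None
) -> None:
    """Weighted edge list TSV; edge rows are already in canonical order."""
    lines = list(metadata or [])
    lines.append(
        "regulator\ttarget\tsign\texistence_weight\tsign_weight\tn_occurrences"
    )
    for e in net.edges:
        lines.append(
            f"{e.regulator}\t{e.target}\t{e.consensus_sign}\t"
            f"{e.existence_weight:.10g}\t{e.sign_weight:.10g}\t{e.n_occurrences}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_weighted_tsv(path: str | Path) -> WeightedNetwork:
    """Read a weighted edge list written by :func:`write_weighted_tsv`.

    The gene universe is reconstructed from the edge endpoints; the
    perturbation count is the maximum ``n_occurrences`` consistent with the
    smallest weight (exact when any edge has weight 1).
    """
    from causnet.perturbation import WeightedEdge

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"regulator": str, "target": str})
    edges = []
    genes: list[str] = []
    n_pert = 1
    for row in df.itertuples(index=False):
        if row.existence_weight > 0:
            n_pert = max(n_pert, round(row.n_occurrences / row.existence_weight))
        for g in (row.regulator, row.target):
            if g not in genes:
                genes.append(g)
        edges.append(
            WeightedEdge(
                regulator=row.regulator,
                target=row.target,
                existence_weight=float(row.existence_weight),
                consensus_sign=row.sign,
                sign_weight=float(row.sign_weight),
                n_occurrences=int(row.n_occurrences),
            )
        )
    return WeightedNetwork(
        gene_ids=tuple(genes), edges=tuple(edges), n_perturbations=n_pert
    )


def export_sif(net: WeightedNetwork, path: str | Path) -> None:
    """Cytoscape SIF: one ``regulator<TAB>relation<TAB>target`` line per edge."""
    lines = [
        f"{e.regulator}\t{SIF_RELATION[e.consensus_sign]}\t{e.target}"
        for e in net.edges
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def export_graphml(net: WeightedNetwork, path: str | Path) -> None:
    """GraphML with per-edge existence weight, sign, and sign weight attributes."""
    graph = nx.DiGraph()
    graph.add_nodes_from(net.gene_ids)
    for e in net.edges:
        graph.add_edge(
            e.regulator,
            e.target,
            existence_weight=e.existence_weight,
            sign=e.consensus_sign,
            sign_weight=e.sign_weight,
            n_occurrences=e.n_occurrences,
        )
    nx.write_graphml(graph, path)
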