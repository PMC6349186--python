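"""End-to-end orchestration of the subpathway-detection workflow.

Stages: ceRNA pair inference -> permutation DE -> pathway-graph
reconstruction -> key-node annotation and ce-scoring -> node-set merging
and subpathway extraction -> enrichment significance -> (optional)
survival evaluation of significant subpathway signatures.  The whole run
is deterministic for a fixed config (all stochastic stages consume the
config seed), and every stage writes a self-describing TSV so a run can
be resumed or inspected per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cerna import (
    CeRNAPair,
    CernaConfig,
    MiRNATargetMap,
    discover_cerna_pairs,
    pairs_to_frame,
    read_target_table,
)
from .diffexpr import DEResult, permutation_de
from .kgml import PathwayGraph, background_genes, parse_kgml, reconstruct_graph
from .locator import (
    CeScore,
    Subpathway,
    all_ce_scores,
    annotate_key_nodes,
    build_node_sets,
    estimate_threshold,
    extract_subpathways,
)
from .significance import SubpathwayTestResult, test_subpathways
from .survival import fit_risk_model, logrank_split, risk_scores

__all__ = ["PipelineConfig", "PipelineResult", "run_from_objects",
           "run_pipeline", "load_graphs", "copathway_predicate"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and knobs of a pipeline run (file paths live separately)."""

    min_shared: int = 3
    share_fdr: float = 0.05
    p_cor: float = 0.05
    de_fdr: float = 0.01
    omega_quantile: float = 0.75
    min_size: int = 5
    result_fdr: float = 0.05
    score_form: str = "exp_neg_d_times_z"
    count_mode: str = "union"
    seed: int = 0
    permutations: int = 1000

    def __post_init__(self) -> None:
        for name in ("share_fdr", "p_cor", "de_fdr", "omega_quantile",
                     "result_fdr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_shared < 0 or self.min_size < 1:
            raise ValueError("min_shared must be >= 0 and min_size >= 1")
        if self.permutations < 100:
            raise ValueError("permutations must be >= 100")


@dataclass
class PipelineResult:
    graphs: list[PathwayGraph]
    de: DEResult
    cerna_pairs: list[CeRNAPair]
    scores: list[CeScore]
    omega: float
    subpathways: list[Subpathway]
    results: list[SubpathwayTestResult]
    survival_results: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)

    def significant(self, alpha: float | None = None) -> list[SubpathwayTestResult]:
        alpha = 0.05 if alpha is None else alpha
        return [r for r in self.results if r.fdr < alpha]


def copathway_predicate(graphs: Sequence[PathwayGraph]):
    """Predicate: do two genes co-occur in at least one pathway?"""
    membership: dict[str, set[str]] = {}
    for g in graphs:
        for gene in g.genes():
            membership.setdefault(gene, set()).add(g.pathway_id)

    def copathway(a: str, b: str) -> bool:
        pa = membership.get(a)
        pb = membership.get(b)
        return bool(pa and pb and pa & pb)

    return copathway


def locate_and_test(
    graphs: Sequence[PathwayGraph],
    de: DEResult,
    pairs: Sequence[CeRNAPair],
    cfg: PipelineConfig,
) -> tuple[list[CeScore], float, list[Subpathway], list[SubpathwayTestResult]]:
    """Key-node annotation, ce-scoring, location and significance."""
    annotations = {
        g.pathway_id: annotate_key_nodes(g, de, pairs) for g in graphs
    }
    scores = all_ce_scores(graphs, annotations, score_form=cfg.score_form)
    omega = estimate_threshold((s.score for s in scores), q=cfg.omega_quantile)
    subpathways: list[Subpathway] = []
    for g in graphs:
        node_sets = build_node_sets(g, scores, omega)
        subpathways.extend(
            extract_subpathways(g, node_sets, min_size=cfg.min_size,
                                scores=scores, omega=omega)
        )
    cerna_genes = {x for p in pairs for x in (p.gene_a, p.gene_b)}
    results = test_subpathways(
        subpathways, cerna_genes, de.de_genes, background_genes(graphs),
        count_mode=cfg.count_mode,
    )
    return scores, omega, subpathways, results


def run_from_objects(
    graphs: Sequence[PathwayGraph],
    target_map: MiRNATargetMap,
    expr: pd.DataFrame,
    labels: pd.Series,
    cfg: PipelineConfig | None = None,
    survival: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full workflow on in-memory inputs."""
    cfg = cfg or PipelineConfig()
    graphs = list(graphs)
    labels = pd.Series(labels).reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some expression samples")

    pairs = discover_cerna_pairs(
        target_map,
        expr,
        copathway_predicate(graphs),
        CernaConfig(min_shared=cfg.min_shared, share_fdr=cfg.share_fdr,
                    p_cor=cfg.p_cor),
    )
    logger.info("retained %d ceRNA pairs", len(pairs))
    de = permutation_de(expr, labels.to_numpy(), B=cfg.permutations,
                        seed=cfg.seed, alpha=cfg.de_fdr)
    logger.info("called %d DE genes of %d", len(de.de_genes), len(de.table))
    scores, omega, subpathways, results = locate_and_test(graphs, de, pairs, cfg)
    logger.info(
        "scored %d key-node pairs, omega=%.4g, %d subpathways, %d significant",
        len(scores), omega, len(subpathways),
        sum(r.fdr < cfg.result_fdr for r in results),
    )

    surv_df = None
    if survival is not None:
        surv = survival.set_index("sample").reindex(expr.columns).dropna()
        rows = []
        sp_by_id = {sp.subpathway_id: sp for sp in subpathways}
        for res in results:
            if res.fdr >= cfg.result_fdr:
                continue
            sp = sp_by_id[res.subpathway_id]
            genes = sorted(g for g in sp.genes if g in expr.index)
            if len(genes) < 1:
                continue
            sub_expr = expr[surv.index]
            model = fit_risk_model(genes, sub_expr, surv["time"], surv["event"])
            strat = logrank_split(
                risk_scores(model, sub_expr), surv["time"], surv["event"]
            )
            rows.append(
                {
                    "subpathway_id": res.subpathway_id,
                    "k": len(genes),
                    "logrank_chi2": strat.logrank_chi2,
                    "logrank_p": strat.logrank_p,
                }
            )
        surv_df = pd.DataFrame(
            rows, columns=["subpathway_id", "k", "logrank_chi2", "logrank_p"]
        )

    counts = {
        "pathways": len(graphs),
        "background_genes": len(background_genes(graphs)),
        "cerna_pairs": len(pairs),
        "cerna_genes": len({x for p in pairs for x in (p.gene_a, p.gene_b)}),
        "de_genes": len(de.de_genes),
        "key_node_pairs_scored": len(scores),
        "omega": omega,
        "subpathways": len(subpathways),
        "significant_subpathways": sum(
            r.fdr < cfg.result_fdr for r in results
        ),
    }
    return PipelineResult(
        graphs=graphs,
        de=de,
        cerna_pairs=pairs,
        scores=scores,
        omega=omega,
        subpathways=subpathways,
        results=results,
        survival_results=surv_df,
        counts=counts,
    )


def load_graphs(kgml_paths: Sequence, id_map_path=None) -> list[PathwayGraph]:
    """Parse KGML files and reconstruct their gene-product graphs."""
    id_map: dict[str, str] = {}
    if id_map_path is not None:
        df = pd.read_csv(id_map_path, sep="\t", dtype=str)
        id_map = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    graphs = []
    for path in kgml_paths:
        kp = parse_kgml(Path(path).read_text())
        graphs.append(reconstruct_graph(kp, id_map))
    return graphs


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "gene"
    return expr


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def results_to_frame(results: Sequence[SubpathwayTestResult]) -> pd.DataFrame:
    cols = ["subpathway_id", "pathway_id", "n_nodes", "t", "r_ce", "r_de",
            "p_value", "fdr"]
    return pd.DataFrame(
        [[getattr(r, c) for c in cols] for r in results], columns=cols
    )


def scores_to_frame(scores: Sequence[CeScore]) -> pd.DataFrame:
    cols = ["pathway_id", "node_i", "node_j", "P_DE", "P_cor", "P", "z", "d",
            "score"]
    return pd.DataFrame(
        [[getattr(s, c) for c in cols] for s in scores], columns=cols
    )


def subpathways_to_frame(subpathways: Sequence[Subpathway]) -> pd.DataFrame:
    rows = [
        {
            "subpathway_id": sp.subpathway_id,
            "pathway_id": sp.pathway_id,
            "n_nodes": len(sp.nodes),
            "genes": ";".join(sorted(sp.genes)),
        }
        for sp in subpathways
    ]
    return pd.DataFrame(
        rows, columns=["subpathway_id", "pathway_id", "n_nodes", "genes"]
    )


def run_pipeline(
    kgml_paths: Sequence,
    id_map_path,
    targets_path,
    expression_path,
    labels_path,
    out_dir,
    cfg: PipelineConfig | None = None,
    survival_path=None,
) -> PipelineResult:
    """File-based end-to-end run; writes stage TSVs and a run manifest."""
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graphs = load_graphs(kgml_paths, id_map_path)
    target_map = read_target_table(targets_path)
    expr = read_expression(expression_path)
    labels = read_labels(labels_path)
    survival = (
        pd.read_csv(survival_path, sep="\t") if survival_path else None
    )
    result = run_from_objects(graphs, target_map, expr, labels, cfg, survival)

    pairs_to_frame(result.cerna_pairs).to_csv(
        out / "cerna_pairs.tsv", sep="\t", index=False
    )
    result.de.table.rename_axis("gene").to_csv(out / "de_genes.tsv", sep="\t")
    scores_to_frame(result.scores).to_csv(
        out / "ce_scores.tsv", sep="\t", index=False
    )
    subpathways_to_frame(result.subpathways).to_csv(
        out / "subpathways.tsv", sep="\t", index=False
    )
    results_to_frame(result.results).to_csv(
        out / "subpathway_results.tsv", sep="\t", index=False
    )
    # per-subpathway qualifying pairs at gene resolution
    pair_rows = []
    for sp in result.subpathways:
        for sc in sp.pairs:
            pair_rows.append(
                {
                    "subpathway_id": sp.subpathway_id,
                    "node_i": sc.node_i,
                    "node_j": sc.node_j,
                    "P_DE": sc.P_DE,
                    "P_cor": sc.P_cor,
                    "d": sc.d,
                    "ce_score": sc.score,
                }
            )
    pd.DataFrame(
        pair_rows,
        columns=["subpathway_id", "node_i", "node_j", "P_DE", "P_cor", "d",
                 "ce_score"],
    ).to_csv(out / "subpathway_pairs.tsv", sep="\t", index=False)
    if result.survival_results is not None:
        result.survival_results.to_csv(
            out / "survival_results.tsv", sep="\t", index=False
        )
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {
            "kgml": [str(p) for p in kgml_paths],
            "id_map": str(id_map_path),
            "targets": str(targets_path),
            "expression": str(expression_path),
            "labels": str(labels_path),
            "survival": str(survival_path) if survival_path else None,
        },
        "counts": result.counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
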