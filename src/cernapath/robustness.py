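"""Robustness of subpathway detection to DE-gene removal.

A fraction of the called DE genes is removed (the gene is dropped from
the DE list and every ceRNA pair involving it is discarded), location
and significance testing are re-run on the reduced input, and the
surviving significant subpathways are compared with the original run.
An original subpathway counts as recovered when some new significant
subpathway matches its node set with Jaccard >= ``match_jaccard``.

Each repetition draws one random ordering of the DE genes and removes a
prefix, so removal sets are nested across fractions within a repetition
(common random numbers keep the averaged curve comparable between
fractions).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .cerna import CeRNAPair
from .diffexpr import DEResult
from .kgml import PathwayGraph
from .pipeline import PipelineConfig, locate_and_test

__all__ = ["removal_curve"]

DEFAULT_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


def _overlap_ratio(
    original: list[frozenset],
    new: list[frozenset],
    match_jaccard: float,
) -> float:
    if not original:
        return float("nan")
    hits = 0
    for o in original:
        for s in new:
            inter = len(o & s)
            union = len(o | s)
            if union and inter / union >= match_jaccard:
                hits += 1
                break
    return hits / len(original)


def removal_curve(
    graphs: Sequence[PathwayGraph],
    de: DEResult,
    pairs: Sequence[CeRNAPair],
    cfg: PipelineConfig,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    repetitions: int = 20,
    seed: int = 0,
    match_jaccard: float = 0.5,
) -> pd.DataFrame:
    """Mean overlap ratio with the original significant subpathways.

    Returns a DataFrame with columns ``fraction``, ``mean_overlap`` and
    ``sd_overlap`` (across repetitions).
    """
    graphs = list(graphs)
    _, _, subpathways0, results0 = locate_and_test(graphs, de, pairs, cfg)
    sig_ids0 = {r.subpathway_id for r in results0 if r.fdr < cfg.result_fdr}
    original_sets = [
        sp.nodes for sp in subpathways0 if sp.subpathway_id in sig_ids0
    ]
    de_genes = sorted(de.de_genes)
    rng = np.random.default_rng(seed)

    rows = []
    per_rep_orders = [rng.permutation(len(de_genes)) for _ in range(repetitions)]
    for frac in fractions:
        n_remove = math.ceil(frac * len(de_genes))
        overlaps = []
        for order in per_rep_orders:
            removed = {de_genes[i] for i in order[:n_remove]}
            de_r = de.drop_genes(removed)
            pairs_r = [
                p for p in pairs
                if p.gene_a not in removed and p.gene_b not in removed
            ]
            try:
                _, _, subs, res = locate_and_test(graphs, de_r, pairs_r, cfg)
            except ValueError:
                # no scorable key-node pairs left: nothing recovered
                overlaps.append(0.0)
                continue
            sig = {r.subpathway_id for r in res if r.fdr < cfg.result_fdr}
            new_sets = [sp.nodes for sp in subs if sp.subpathway_id in sig]
            overlaps.append(
                _overlap_ratio(original_sets, new_sets, match_jaccard)
            )
        rows.append(
            {
                "fraction": frac,
                "mean_overlap": float(np.nanmean(overlaps)),
                "sd_overlap": float(np.nanstd(overlaps)),
            }
        )
    return pd.DataFrame(rows)
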