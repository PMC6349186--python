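"""Permutation-based differential expression with a moderated t statistic.

Per gene the statistic is d = (mean1 - mean2) / (s + s0), where s is the
pooled standard error of the mean difference and s0 a small positive
fudge factor (a percentile, by default the median, of the per-gene s
values) that stabilises genes with near-zero variance.  Significance
comes from label permutations: permuted |d*| values are pooled across all
genes into one null distribution, per-gene p-values use add-one smoothing
(so no p is exactly zero), and BH adjustment yields per-gene FDR values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["DEResult", "sam_statistic", "permutation_de", "load_external_de"]

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene differential-expression calls.

    ``table`` is indexed by gene with columns ``d``, ``p_raw``, ``p_fdr``
    and ``is_de`` (``d``/``p_raw`` are NaN for externally loaded results).
    """

    table: pd.DataFrame
    alpha: float = 0.01

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])

    def de_p(self, gene: str) -> float:
        """FDR-adjusted p of a DE gene; 1.0 for non-DE or unknown genes."""
        if gene in self.table.index and bool(self.table.at[gene, "is_de"]):
            return float(self.table.at[gene, "p_fdr"])
        return 1.0

    def drop_genes(self, genes) -> "DEResult":
        """Copy with the given genes marked non-DE (removal experiments)."""
        table = self.table.copy()
        table.loc[table.index.isin(set(genes)), "is_de"] = False
        return DEResult(table=table, alpha=self.alpha)


def _group_masks(labels, group_order=None) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if group_order is None:
        group_order = list(dict.fromkeys(labels.tolist()))
    if len(group_order) != 2:
        raise ValueError(f"exactly two groups required, got {group_order}")
    m1 = labels == group_order[0]
    m2 = labels == group_order[1]
    if not (m1 | m2).all():
        raise ValueError("labels contain values outside the two groups")
    return m1, m2


def _d_stats(values: np.ndarray, m1: np.ndarray, m2: np.ndarray,
             s0: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (d, s) for a genes x samples matrix and two masks."""
    n1, n2 = int(m1.sum()), int(m2.sum())
    x1, x2 = values[:, m1], values[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + (
        (x2 - mean2[:, None]) ** 2
    ).sum(axis=1)
    s = np.sqrt(ss / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = float(np.median(s))
    return (mean1 - mean2) / (s + s0), s


def sam_statistic(expr_row, labels, s0: float, group_order=None) -> float:
    """Moderated two-sample statistic d = (mean1 - mean2) / (s + s0).

    ``s`` is the pooled standard error of the mean difference.  Both
    groups need >= 2 samples; ``s0`` must be non-negative.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    row = np.asarray(expr_row, dtype=float)[None, :]
    m1, m2 = _group_masks(labels, group_order)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    d, _ = _d_stats(row, m1, m2, s0=s0)
    return float(d[0])


def permutation_de(
    expr: pd.DataFrame,
    labels,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    s0_percentile: float = 50.0,
    group_order=None,
) -> DEResult:
    """Permutation DE over a genes x samples matrix with two-group labels.

    ``p_raw`` for gene g is (1 + #{pooled permuted |d*| >= |d_g|}) /
    (1 + B_eff * n_genes); ``p_fdr`` is BH over genes.  When fewer than
    ``B`` distinct label assignments exist they are enumerated exhaustively
    (with a logged warning).  Deterministic for a fixed seed.
    """
    if B < 100:
        raise ValueError("at least 100 permutations required")
    values = expr.to_numpy(dtype=float)
    m1, m2 = _group_masks(labels, group_order)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    n = values.shape[1]
    n1 = int(m1.sum())

    _, s = _d_stats(values, m1, m2, s0=0.0)
    s0 = float(np.percentile(s, s0_percentile))
    d_obs, _ = _d_stats(values, m1, m2, s0=s0)

    n_distinct = math.comb(n, n1)
    rng = np.random.default_rng(seed)
    perm_masks: list[np.ndarray] = []
    if n_distinct <= B:
        logger.warning(
            "only %d distinct label assignments (< B=%d); enumerating all",
            n_distinct, B,
        )
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            perm_masks.append(mask)
    else:
        for _ in range(B):
            idx = rng.choice(n, size=n1, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            perm_masks.append(mask)

    abs_null = np.empty((len(perm_masks), values.shape[0]))
    for b, mask in enumerate(perm_masks):
        db, _ = _d_stats(values, mask, ~mask, s0=s0)
        abs_null[b] = np.abs(db)
    pooled = np.sort(abs_null.ravel())
    total = pooled.size
    # count of pooled null values >= |d| via searchsorted on the sorted pool
    ge_counts = total - np.searchsorted(pooled, np.abs(d_obs), side="left")
    p_raw = (1.0 + ge_counts) / (1.0 + total)
    p_fdr = multipletests(p_raw, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "d": d_obs,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "is_de": p_fdr < alpha,
        },
        index=expr.index,
    )
    return DEResult(table=table, alpha=alpha)


def load_external_de(table: pd.DataFrame | str, alpha: float = 0.01) -> DEResult:
    """Build a :class:`DEResult` from an external gene/p_fdr table.

    Accepts a DataFrame or a TSV path with columns ``gene`` and ``p_fdr``.
    Duplicate genes or p-values outside [0, 1] raise ``ValueError``.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    missing = {"gene", "p_fdr"} - set(table.columns)
    if missing:
        raise ValueError(f"external DE table lacks columns: {sorted(missing)}")
    dup = table["gene"][table["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene rows: {sorted(set(dup))[:5]}")
    p = pd.to_numeric(table["p_fdr"], errors="raise")
    if ((p < 0) | (p > 1)).any():
        bad = table["gene"][(p < 0) | (p > 1)].iloc[0]
        raise ValueError(f"p_fdr outside [0, 1] for gene {bad!r}")
    out = pd.DataFrame(
        {
            "d": np.nan,
            "p_raw": np.nan,
            "p_fdr": p.to_numpy(dtype=float),
            "is_de": p.to_numpy(dtype=float) < alpha,
        },
        index=pd.Index(table["gene"], name="gene"),
    )
    return DEResult(table=out, alpha=alpha)
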