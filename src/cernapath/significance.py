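"""Subpathway significance: joint ceRNA/DE hypergeometric enrichment.

Each located subpathway is tested for over-representation of the
submitted signature (ceRNAs and DE genes) against the background of all
pathway genes:

    P = 1 - sum_{x=0}^{r-1} C(t, x) * C(m - t, n - x) / C(m, n)

with m background genes, t genes in the subpathway, n signature genes and
r of them inside the subpathway — i.e. the upper tail P(X >= r) of a
hypergeometric distribution.  By default the signature counts use the
set union of ceRNAs and DE genes (``count_mode="union"``), which keeps
the hypergeometric support valid when a gene is both; ``"sum"`` adds the
two counts verbatim.  BH adjustment controls the FDR across the tested
subpathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .locator import Subpathway

__all__ = ["SubpathwayTestResult", "eq5_pvalue", "test_subpathways"]


@dataclass(frozen=True)
class SubpathwayTestResult:
    subpathway_id: str
    pathway_id: str
    n_nodes: int
    t: int
    r_ce: int
    r_de: int
    p_value: float
    fdr: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.fdr < alpha


def eq5_pvalue(m: int, n: int, t: int, r: int) -> float:
    """Upper-tail hypergeometric P(X >= r) for signature enrichment.

    ``m``: background size; ``n``: signature size; ``t``: subpathway
    size; ``r``: signature genes inside the subpathway.  ``r = 0`` gives
    P = 1 (empty sum).  Bounds are validated and violations raise
    ``ValueError``.
    """
    if not (0 <= r <= min(n, t) and n <= m and t <= m):
        raise ValueError(
            f"invalid enrichment counts: m={m}, n={n}, t={t}, r={r}"
        )
    return float(stats.hypergeom.sf(r - 1, m, t, n))


def test_subpathways(
    subpathways: Sequence[Subpathway],
    cerna_genes: Iterable[str],
    de_genes: Iterable[str],
    background: Iterable[str],
    count_mode: str = "union",
) -> list[SubpathwayTestResult]:
    """Score subpathways and BH-adjust; results sorted by FDR ascending.

    Signature sets are intersected with the background before counting.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    if count_mode not in ("union", "sum"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    ce = set(cerna_genes) & background
    de = set(de_genes) & background
    m = len(background)
    n = len(ce | de) if count_mode == "union" else len(ce) + len(de)

    raw: list[tuple[Subpathway, int, int, int, float]] = []
    for sp in subpathways:
        genes = set(sp.genes) & background
        t = len(genes)
        r_ce = len(genes & ce)
        r_de = len(genes & de)
        if count_mode == "union":
            r = len(genes & (ce | de))
            p = eq5_pvalue(m, n, t, r)
        else:
            # verbatim summed counts may double-count genes that are both
            # ceRNA and DE; beyond the hypergeometric support the summation
            # has exhausted all non-zero terms and the tail is 0
            r = r_ce + r_de
            if n > m:
                raise ValueError(
                    f"summed signature count n={n} exceeds background m={m}"
                )
            p = eq5_pvalue(m, n, t, r) if r <= min(n, t) else 0.0
        raw.append((sp, t, r_ce, r_de, p))

    if not raw:
        return []
    fdrs = multipletests([x[4] for x in raw], method="fdr_bh")[1]
    out = [
        SubpathwayTestResult(
            subpathway_id=sp.subpathway_id,
            pathway_id=sp.pathway_id,
            n_nodes=len(sp.nodes),
            t=t,
            r_ce=r_ce,
            r_de=r_de,
            p_value=float(p),
            fdr=float(q),
        )
        for (sp, t, r_ce, r_de, p), q in zip(raw, fdrs)
    ]
    out.sort(key=lambda r: (r.fdr, r.p_value, r.subpathway_id))
    return out
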