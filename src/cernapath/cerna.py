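"""ceRNA (competing endogenous RNA) pair inference.

Two mRNAs are candidate ceRNA partners when they are targeted by an
unusually large set of common miRNAs.  Candidates sharing at least
``min_shared`` miRNAs are scored by an upper-tail hypergeometric test on
the overlap (population = the miRNA universe), BH-adjusted over the whole
tested family, and then filtered by (i) sharing FDR, (ii) positive Pearson
correlation of the two expression profiles with a significant two-sided
p-value, and (iii) co-membership in at least one pathway.  The Pearson
p-value of a retained pair (``p_cor``) is kept as the downstream measure
of ceRNA-interaction strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MiRNATargetMap",
    "CeRNAPair",
    "CernaConfig",
    "mirna_sharing_test",
    "pearson_test",
    "discover_cerna_pairs",
    "read_target_table",
    "pairs_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class MiRNATargetMap:
    """Bipartite miRNA-to-mRNA target relation.

    ``targets`` maps each mRNA symbol to the set of miRNAs targeting it;
    ``mirna_universe`` is the full miRNA population (size N of the
    sharing test), a superset of every target set.
    """

    targets: dict[str, set[str]]
    mirna_universe: set[str]

    def __post_init__(self) -> None:
        if not self.mirna_universe:
            raise ValueError("miRNA universe must be non-empty")
        stray = set().union(*self.targets.values(), set()) - self.mirna_universe
        if stray:
            raise ValueError(
                f"{len(stray)} miRNAs in target sets missing from universe, "
                f"e.g. {sorted(stray)[:3]}"
            )

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_universe)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], universe: Iterable[str] | None = None
    ) -> "MiRNATargetMap":
        """Build from (mirna, mrna) pairs; universe defaults to observed miRNAs."""
        targets: dict[str, set[str]] = {}
        seen: set[str] = set()
        for mirna, mrna in pairs:
            targets.setdefault(mrna, set()).add(mirna)
            seen.add(mirna)
        return cls(targets=targets, mirna_universe=set(universe) if universe else seen)


@dataclass(frozen=True)
class CeRNAPair:
    """Retained mRNA-mRNA ceRNA pair (gene_a < gene_b lexicographically)."""

    gene_a: str
    gene_b: str
    shared: int
    share_p: float
    share_fdr: float
    pearson_r: float
    p_cor: float


@dataclass
class CernaConfig:
    min_shared: int = 3
    share_fdr: float = 0.05
    p_cor: float = 0.05
    require_positive_r: bool = True


def mirna_sharing_test(Ka: int, Kb: int, s: int, N: int) -> float:
    """Upper-tail hypergeometric probability of sharing >= ``s`` miRNAs.

    ``Ka``/``Kb`` are the two genes' miRNA-target counts out of a universe
    of ``N`` miRNAs; the overlap under the null of independent targeting is
    hypergeometric, and the returned value is P(X >= s).
    """
    if not (0 <= s <= min(Ka, Kb) <= max(Ka, Kb) <= N):
        raise ValueError(
            f"invalid sharing-test bounds: Ka={Ka}, Kb={Kb}, s={s}, N={N}"
        )
    return float(stats.hypergeom.sf(s - 1, N, Ka, Kb))


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.
    Requires n >= 4 and non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError(f"need at least 4 samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _shared_counts(tm: MiRNATargetMap, genes: list[str]) -> sparse.csr_matrix:
    """Sparse gene x gene matrix of shared-miRNA counts (upper triangle used)."""
    mirnas = sorted(tm.mirna_universe)
    m_index = {m: i for i, m in enumerate(mirnas)}
    rows, cols = [], []
    for gi, g in enumerate(genes):
        for m in tm.targets.get(g, ()):
            rows.append(gi)
            cols.append(m_index[m])
    a = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(genes), len(mirnas)),
    )
    return (a @ a.T).tocsr()


def discover_cerna_pairs(
    tm: MiRNATargetMap,
    expr: pd.DataFrame,
    copathway: Callable[[str, str], bool],
    cfg: CernaConfig | None = None,
) -> list[CeRNAPair]:
    """Infer ceRNA pairs from target sharing, correlation and co-pathway.

    ``expr`` is a genes x samples matrix (>= 4 samples).  The BH family is
    every unordered pair with shared >= ``min_shared`` (before the pathway
    and correlation filters).  Pairs whose genes are missing from ``expr``
    are skipped with a logged count.  Output is deduplicated, each pair in
    canonical (gene_a < gene_b) order, sorted lexicographically.
    """
    cfg = cfg or CernaConfig()
    if expr.shape[1] < 4:
        raise ValueError("expression matrix must have at least 4 samples")

    genes = sorted(tm.targets)
    counts = _shared_counts(tm, genes)
    coo = sparse.triu(counts, k=1).tocoo()
    mask = coo.data >= cfg.min_shared
    ii, jj, ss = coo.row[mask], coo.col[mask], coo.data[mask]
    if ii.size == 0:
        return []

    N = tm.n_mirnas
    k = np.array([len(tm.targets[g]) for g in genes])
    # vectorised upper-tail hypergeometric on the tested family
    share_p = stats.hypergeom.sf(ss - 1, N, k[ii], k[jj])
    share_fdr = multipletests(share_p, method="fdr_bh")[1]

    expr_index = set(expr.index)
    values = expr.to_numpy(dtype=float)
    row_of = {g: r for r, g in enumerate(expr.index)}

    out: list[CeRNAPair] = []
    n_missing = 0
    keep = share_fdr < cfg.share_fdr
    for gi, gj, s, p, q in zip(ii[keep], jj[keep], ss[keep], share_p[keep],
                               share_fdr[keep]):
        a, b = genes[gi], genes[gj]
        if a > b:
            a, b = b, a
        if not copathway(a, b):
            continue
        if a not in expr_index or b not in expr_index:
            n_missing += 1
            continue
        xa, xb = values[row_of[a]], values[row_of[b]]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            n_missing += 1
            continue
        r, p_cor = pearson_test(xa, xb)
        if cfg.require_positive_r and r <= 0:
            continue
        if p_cor >= cfg.p_cor:
            continue
        out.append(
            CeRNAPair(
                gene_a=a,
                gene_b=b,
                shared=int(s),
                share_p=float(p),
                share_fdr=float(q),
                pearson_r=r,
                p_cor=p_cor,
            )
        )
    if n_missing:
        logger.info(
            "skipped %d candidate pairs lacking usable expression", n_missing
        )
    out.sort(key=lambda pr: (pr.gene_a, pr.gene_b))
    return out


def read_target_table(path) -> MiRNATargetMap:
    """Read a two-column miRNA-target TSV (mirna_id, gene_symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("target table needs two columns: mirna_id, gene_symbol")
    mirna_col, gene_col = df.columns[:2]
    return MiRNATargetMap.from_pairs(
        zip(df[mirna_col], df[gene_col])
    )


def pairs_to_frame(pairs: Iterable[CeRNAPair]) -> pd.DataFrame:
    cols = ["gene_a", "gene_b", "shared", "share_p", "share_fdr",
            "pearson_r", "p_cor"]
    return pd.DataFrame(
        [[getattr(p, c) for c in cols] for p in pairs], columns=cols
    )
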