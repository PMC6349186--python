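"""ceRNA-mediated subpathway location.

Key nodes of a pathway graph are nodes carrying at least one DE gene or
one ceRNA.  Every connected pair of key nodes is scored by the ce-score,
which combines

* ``P_DE`` — the smaller of the two nodes' FDR-adjusted DE p-values
  (1 when a node carries no DE gene),
* ``P_cor`` — the Pearson p-value of the ceRNA interaction between the
  nodes (1 when they are not ceRNA partners),
* ``d`` — the BFS shortest-path length between the nodes,

as z = Phi^-1(1 - P_DE * P_cor) and, in the default parameterisation,
score = exp(-d) * z.  The score therefore grows with DE significance,
ceRNA-interaction strength and topological closeness.  Pairs scoring
above the pooled 75%-quantile threshold omega contribute the union of
nodes on all of their shortest paths to a node set; overlapping node sets
are merged to a fixed point, and merged sets of at least ``min_size``
nodes are reported as subpathways (induced subgraphs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .cerna import CeRNAPair
from .diffexpr import DEResult
from .kgml import PathwayGraph, path_distance_and_union

__all__ = [
    "KeyNodeAnnotation",
    "CeScore",
    "Subpathway",
    "annotate_key_nodes",
    "ce_score",
    "all_ce_scores",
    "estimate_threshold",
    "build_node_sets",
    "extract_subpathways",
]

#: clamp bounds applied to P before the normal quantile
P_MIN = 1e-300
P_MAX = 1.0 - 1e-16

SCORE_FORMS = ("exp_neg_d_times_z", "exp_neg_dz")


@dataclass
class KeyNodeAnnotation:
    """Key-node evidence for one pathway graph.

    ``node_de_p`` maps node -> min FDR-adjusted p over its DE member
    genes (1.0 when none); ``cerna_nodes`` are nodes hosting at least one
    ceRNA; ``pair_p_cor`` maps an unordered node pair (frozenset) to the
    min ``p_cor`` over cross-node ceRNA gene pairs (absent means 1.0).
    A node is a key node iff its DE p is < 1 or it hosts a ceRNA.
    """

    pathway_id: str
    node_de_p: dict[str, float] = field(default_factory=dict)
    cerna_nodes: set[str] = field(default_factory=set)
    pair_p_cor: dict[frozenset, float] = field(default_factory=dict)

    def de_p(self, node: str) -> float:
        return self.node_de_p.get(node, 1.0)

    def p_cor(self, u: str, v: str) -> float:
        return self.pair_p_cor.get(frozenset((u, v)), 1.0)

    @property
    def key_nodes(self) -> set[str]:
        keys = {n for n, p in self.node_de_p.items() if p < 1.0}
        return keys | self.cerna_nodes


def annotate_key_nodes(
    graph: PathwayGraph,
    de: DEResult,
    pairs: Sequence[CeRNAPair],
) -> KeyNodeAnnotation:
    """Map DE genes and ceRNAs onto the nodes of one pathway graph."""
    ann = KeyNodeAnnotation(pathway_id=graph.pathway_id)
    cerna_genes: set[str] = set()
    p_cor_of: dict[frozenset, float] = {}
    for pr in pairs:
        cerna_genes.update((pr.gene_a, pr.gene_b))
        key = frozenset((pr.gene_a, pr.gene_b))
        p_cor_of[key] = min(p_cor_of.get(key, 1.0), pr.p_cor)

    node_genes = graph.node_genes
    for node, genes in node_genes.items():
        p = min((de.de_p(g) for g in genes), default=1.0)
        if p < 1.0:
            ann.node_de_p[node] = p
        if genes & cerna_genes:
            ann.cerna_nodes.add(node)

    nodes = sorted(ann.key_nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            best = 1.0
            for ga in node_genes[u]:
                for gb in node_genes[v]:
                    if ga == gb:
                        continue
                    best = min(best, p_cor_of.get(frozenset((ga, gb)), 1.0))
            if best < 1.0:
                ann.pair_p_cor[frozenset((u, v))] = best
    return ann


@dataclass(frozen=True)
class CeScore:
    """ce-score record for one connected key-node pair."""

    pathway_id: str
    node_i: str
    node_j: str
    P_DE: float
    P_cor: float
    P: float
    z: float
    d: int
    score: float


def ce_score(
    P_i_DE: float,
    P_j_DE: float,
    P_cor: float,
    d: int,
    score_form: str = "exp_neg_d_times_z",
) -> tuple[float, float, float, float]:
    """Combine node DE p-values, interaction p-value and distance.

    Returns ``(P_DE, P, z, score)`` with P_DE = min of the node p-values,
    P = P_DE * P_cor, z = Phi^-1(1 - P) (P clamped into
    [1e-300, 1 - 1e-16] first; P >= 1 pre-clamp yields z = score = -inf),
    and score = exp(-d) * z (default) or exp(-d * z).
    """
    for name, p in (("P_i_DE", P_i_DE), ("P_j_DE", P_j_DE), ("P_cor", P_cor)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if d < 1:
        raise ValueError(f"shortest-path length must be >= 1, got d={d}")
    if score_form not in SCORE_FORMS:
        raise ValueError(f"unknown score_form {score_form!r}")
    P_DE = min(P_i_DE, P_j_DE)
    P = P_DE * P_cor
    if P >= 1.0:
        return P_DE, 1.0, float("-inf"), float("-inf")
    z = float(stats.norm.isf(min(max(P, P_MIN), P_MAX)))
    if score_form == "exp_neg_d_times_z":
        score = float(np.exp(-d) * z)
    else:  # literal reading of the printed formula
        score = float(np.exp(-d * z))
    return P_DE, P, z, score


def all_ce_scores(
    graphs: Sequence[PathwayGraph],
    annotations: Mapping[str, KeyNodeAnnotation],
    score_form: str = "exp_neg_d_times_z",
) -> list[CeScore]:
    """ce-scores for every connected unordered key-node pair per pathway."""
    out: list[CeScore] = []
    for g in graphs:
        ann = annotations[g.pathway_id]
        keys = sorted(ann.key_nodes & g.nodes)
        dist = {
            u: nx.single_source_shortest_path_length(g.graph, u) for u in keys
        }
        for i, u in enumerate(keys):
            for v in keys[i + 1 :]:
                d = dist[u].get(v)
                if d is None or d == 0:
                    continue
                P_DE, P, z, score = ce_score(
                    ann.de_p(u), ann.de_p(v), ann.p_cor(u, v), d, score_form
                )
                out.append(
                    CeScore(
                        pathway_id=g.pathway_id,
                        node_i=u,
                        node_j=v,
                        P_DE=P_DE,
                        P_cor=ann.p_cor(u, v),
                        P=P,
                        z=z,
                        d=d,
                        score=score,
                    )
                )
    return out


def estimate_threshold(scores: Iterable[float], q: float = 0.75) -> float:
    """Empirical q-quantile (linear interpolation) of the finite scores.

    The pool spans all pathways; non-finite scores (P = 1 pairs) are
    excluded.  Raises ``ValueError`` when no finite score exists.
    """
    finite = np.asarray(
        [s for s in scores if np.isfinite(s)], dtype=float
    )
    if finite.size == 0:
        raise ValueError("no scorable key-node pairs")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile must be in [0, 1], got {q}")
    return float(np.quantile(finite, q))


def build_node_sets(
    graph: PathwayGraph,
    scores: Sequence[CeScore],
    omega: float,
) -> list[set[str]]:
    """Merged node sets from qualifying (score > omega) key-node pairs.

    Each qualifying pair contributes the union of nodes on all of its
    shortest paths; sets sharing at least one node are merged until a
    fixed point (union-find), so the result is independent of processing
    order.  Returned sets are sorted by descending size, then by their
    sorted node tuple.
    """
    if not np.isfinite(omega):
        raise ValueError("omega must be finite")
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for sc in scores:
        if sc.pathway_id != graph.pathway_id or not sc.score > omega:
            continue
        _, members = path_distance_and_union(graph, sc.node_i, sc.node_j)
        members = sorted(members)
        for m in members:
            parent.setdefault(m, m)
        for m in members[1:]:
            union(members[0], m)

    groups: dict[str, set[str]] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return sorted(groups.values(), key=lambda s: (-len(s), sorted(s)))


@dataclass
class Subpathway:
    """Located subpathway: an induced subgraph of one pathway graph."""

    subpathway_id: str
    pathway_id: str
    nodes: frozenset
    genes: frozenset
    subgraph: nx.Graph
    pairs: tuple[CeScore, ...] = ()


def extract_subpathways(
    graph: PathwayGraph,
    node_sets: Sequence[set[str]],
    min_size: int = 5,
    scores: Sequence[CeScore] = (),
    omega: float | None = None,
) -> list[Subpathway]:
    """Induced subgraphs of the node sets with >= ``min_size`` nodes.

    Ids are ``<pathway_id>_<k>`` with k assigned by descending node-set
    size, ties broken by sorted node order.  When ``scores`` and
    ``omega`` are given, each subpathway also records its qualifying
    key-node pairs.
    """
    unknown = set().union(*node_sets, set()) - graph.nodes
    if unknown:
        raise ValueError(f"node sets contain unknown nodes: {sorted(unknown)[:3]}")
    surviving = sorted(
        (s for s in node_sets if len(s) >= min_size),
        key=lambda s: (-len(s), sorted(s)),
    )
    out: list[Subpathway] = []
    for k, node_set in enumerate(surviving, start=1):
        sub = graph.graph.subgraph(node_set).copy()
        genes: set[str] = set()
        for n in node_set:
            genes |= graph.graph.nodes[n]["genes"]
        qualifying = tuple(
            sc
            for sc in scores
            if sc.pathway_id == graph.pathway_id
            and omega is not None
            and sc.score > omega
            and sc.node_i in node_set
            and sc.node_j in node_set
        )
        out.append(
            Subpathway(
                subpathway_id=f"{graph.pathway_id}_{k}",
                pathway_id=graph.pathway_id,
                nodes=frozenset(node_set),
                genes=frozenset(genes),
                subgraph=sub,
                pairs=qualifying,
            )
        )
    return out
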