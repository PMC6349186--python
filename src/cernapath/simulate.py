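"""Seeded synthetic input bundles with planted structure.

The generator emulates the four input kinds the pipeline consumes —
KGML pathway files with an id-mapping table, a miRNA-target table, a
two-group expression matrix with labels, and a survival table — and
plants a single dysregulated region so that end-to-end recovery can be
verified against a known truth record.

Planted structure
-----------------
* Each pathway is a random connected graph (random spanning tree plus
  extra edges at ``edge_density``); one pathway hosts a densely
  interconnected planted region (a complete subgraph), mimicking a
  tightly coupled dysregulated complex and making the truth region
  unambiguous.
* Planted genes share a common block of miRNAs (so every planted pair
  clears the sharing test), are sampled with pairwise expression
  correlation ``cerna_r`` (equicorrelated Gaussian), and receive a mean
  shift of ``de_effect`` residual standard deviations in the disease
  group.  A configurable number of background DE genes in the other
  pathways receive the same shift without correlation structure,
  providing realistic non-ceRNA DE signal.
* All other miRNA targeting is uniform at random, giving a calibrated
  null for the sharing test.
* Survival times are exponential with hazard proportional to
  exp(beta_true * u), where u is the standardised mean expression of the
  planted genes; censoring is independent exponential.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cerna import MiRNATargetMap
from .kgml import (
    KgmlEntry,
    KgmlPathway,
    KgmlRelation,
    KgmlReaction,
    serialize_kgml,
)

__all__ = ["ScenarioSpec", "SyntheticBundle", "make_pathways", "make_inputs",
           "simulate_survival_times", "write_bundle"]


@dataclass
class ScenarioSpec:
    """Study-condition parameters of one synthetic scenario."""

    n_pathways: int = 3
    nodes_per_pathway: int = 20
    edge_density: float = 0.08  # extra-edge probability beyond the tree
    n_mirnas: int = 386
    n_mrnas: int = 150
    targets_per_mirna: int = 8
    planted_pathway: int = 0
    planted_size: int = 6
    planted_shared_mirnas: int = 12
    n_background_de: int = 12
    de_effect: float = 2.0  # mean shift in residual SDs
    cerna_r: float = 0.8
    n_samples: int = 50  # per group
    baseline_hazard: float = 0.1
    beta_true: float = 0.5
    censor_rate: float = 0.025
    seed: int = 0
    #: expression/survival draw; defaults to ``seed``.  Two specs sharing
    #: ``seed`` but differing here yield independent cohorts over the same
    #: pathway structure and planted region (training vs evaluation).
    expression_seed: int | None = None

    def __post_init__(self) -> None:
        if self.planted_size < 5:
            raise ValueError("planted region must have >= 5 nodes")
        if self.planted_size > self.nodes_per_pathway:
            raise ValueError("planted region larger than its pathway")
        if not 0 < self.cerna_r < 1:
            raise ValueError("cerna_r must lie in (0, 1)")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples per group")
        if not 0 <= self.planted_pathway < self.n_pathways:
            raise ValueError("planted_pathway out of range")
        for name in ("n_pathways", "nodes_per_pathway", "n_mirnas", "n_mrnas",
                     "targets_per_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticBundle:
    """In-memory synthetic inputs plus the planted-truth record."""

    kgml_texts: list[str]
    id_map: dict[str, str]
    target_map: MiRNATargetMap
    expr: pd.DataFrame  # genes x samples
    labels: pd.Series  # sample -> "disease" | "normal"
    survival: pd.DataFrame  # sample, time, event
    truth: dict
    spec: ScenarioSpec


def _gene_symbol(idx: int) -> str:
    return f"G{idx:04d}"


def _kegg_id(idx: int) -> str:
    return f"hsa:{1000 + idx}"


def _random_connected_edges(n: int, density: float, rng) -> set[frozenset]:
    """Random spanning tree plus independent extra edges."""
    edges: set[frozenset] = set()
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(0, i)]
        edges.add(frozenset((int(order[i]), int(j))))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                edges.add(frozenset((i, j)))
    return edges


def make_pathways(spec: ScenarioSpec) -> tuple[list[str], dict[str, str], dict]:
    """Generate KGML texts, a KEGG-id -> symbol map and the truth record.

    Each pathway also carries one map-link entry (wired to a gene by a
    relation) and one compound entry consumed/produced by two gene
    reactions, so reconstruction exercises map removal and compound
    collapsing; the compound-mediated gene pair is part of the recorded
    truth topology.
    """
    rng = np.random.default_rng(spec.seed)
    texts: list[str] = []
    id_map: dict[str, str] = {}
    truth: dict = {"pathways": [], "planted": {}}
    gene_counter = 0
    for p in range(spec.n_pathways):
        n = spec.nodes_per_pathway
        pathway_id = f"path:{90000 + p}"
        local_genes = [gene_counter + i for i in range(n)]
        gene_counter += n
        edges = _random_connected_edges(n, spec.edge_density, rng)
        planted_local: list[int] = []
        if p == spec.planted_pathway:
            planted_local = sorted(
                rng.choice(n, size=spec.planted_size, replace=False).tolist()
            )
            for i, a in enumerate(planted_local):
                for b in planted_local[i + 1 :]:
                    edges.add(frozenset((a, b)))

        entries: list[KgmlEntry] = []
        relations: list[KgmlRelation] = []
        reactions: list[KgmlReaction] = []
        for i in range(n):
            kegg = _kegg_id(local_genes[i])
            symbol = _gene_symbol(local_genes[i])
            id_map[kegg] = symbol
            entries.append(
                KgmlEntry(
                    entry_id=str(i + 1),
                    entry_type="gene",
                    name=kegg,
                    member_gene_ids=(kegg,),
                )
            )
        # gene-gene relations for the random topology, minus one edge that
        # is rewired through a compound reaction below
        sorted_edges = sorted(tuple(sorted(e)) for e in edges)
        compound_edge = sorted_edges[int(rng.integers(0, len(sorted_edges)))]
        compound_id = str(n + 1)
        map_id = str(n + 2)
        entries.append(
            KgmlEntry(entry_id=compound_id, entry_type="compound",
                      name=f"cpd:C{90000 + p}")
        )
        entries.append(
            KgmlEntry(entry_id=map_id, entry_type="map",
                      name=f"path:{91000 + p}")
        )
        ca, cb = compound_edge
        ea, eb = str(ca + 1), str(cb + 1)
        entries[ca] = KgmlEntry(
            entry_id=ea, entry_type="gene", name=entries[ca].name,
            member_gene_ids=entries[ca].member_gene_ids,
            reaction=f"rn:R{p}0001",
        )
        entries[cb] = KgmlEntry(
            entry_id=eb, entry_type="gene", name=entries[cb].name,
            member_gene_ids=entries[cb].member_gene_ids,
            reaction=f"rn:R{p}0002",
        )
        reactions.append(
            KgmlReaction(name=f"rn:R{p}0001", reaction_type="irreversible",
                         gene_entry_ids=(ea,), substrate_ids=(),
                         product_ids=(compound_id,))
        )
        reactions.append(
            KgmlReaction(name=f"rn:R{p}0002", reaction_type="irreversible",
                         gene_entry_ids=(eb,), substrate_ids=(compound_id,),
                         product_ids=())
        )
        for a, b in sorted_edges:
            if (a, b) == compound_edge:
                continue
            relations.append(
                KgmlRelation(
                    entry1=str(a + 1), entry2=str(b + 1),
                    relation_type="PPrel",
                    subtypes=(("activation", "-->"),),
                )
            )
        # a map-link relation that must disappear at reconstruction
        relations.append(
            KgmlRelation(entry1=map_id, entry2="1", relation_type="maplink",
                         subtypes=(("indirect effect", "..>"),))
        )
        kp = KgmlPathway(
            pathway_id=pathway_id,
            title=f"synthetic pathway {p}",
            entries=tuple(entries),
            relations=tuple(relations),
            reactions=tuple(reactions),
        )
        texts.append(serialize_kgml(kp))
        truth["pathways"].append(
            {
                "pathway_id": pathway_id,
                "genes": [_gene_symbol(g) for g in local_genes],
                "edges": [
                    [str(a + 1), str(b + 1)] for a, b in sorted_edges
                ],
            }
        )
        if planted_local:
            truth["planted"] = {
                "pathway_id": pathway_id,
                "nodes": [str(i + 1) for i in planted_local],
                "genes": [_gene_symbol(local_genes[i]) for i in planted_local],
            }
    return texts, id_map, truth


def simulate_survival_times(
    risk: np.ndarray,
    beta: float,
    baseline_hazard: float,
    censor_rate: float,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with hazard = h0 * exp(beta * risk).

    Censoring is independent exponential with rate ``censor_rate``; the
    returned event indicator is 1 for observed deaths.
    """
    risk = np.asarray(risk, dtype=float)
    hazard = baseline_hazard * np.exp(beta * risk)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=risk.size)
    else:
        t_cens = np.full(risk.size, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def make_inputs(spec: ScenarioSpec) -> SyntheticBundle:
    """Generate the full synthetic input bundle for one scenario."""
    texts, id_map, truth = make_pathways(spec)
    draw_seed = spec.seed if spec.expression_seed is None else spec.expression_seed
    rng = np.random.default_rng((draw_seed, 1))

    n_pathway_genes = spec.n_pathways * spec.nodes_per_pathway
    if spec.n_mrnas < n_pathway_genes:
        raise ValueError("n_mrnas must cover all pathway genes")
    all_genes = [_gene_symbol(i) for i in range(spec.n_mrnas)]
    planted_genes = list(truth["planted"]["genes"])
    planted_idx = [all_genes.index(g) for g in planted_genes]

    # --- miRNA targeting ------------------------------------------------
    mirnas = [f"miR-{i:04d}" for i in range(spec.n_mirnas)]
    targets: dict[str, set[str]] = {g: set() for g in all_genes}
    for m_i, mirna in enumerate(mirnas):
        chosen = rng.choice(spec.n_mrnas, size=min(spec.targets_per_mirna,
                                                   spec.n_mrnas),
                            replace=False)
        for g_i in chosen:
            targets[all_genes[g_i]].add(mirna)
    shared_block = rng.choice(spec.n_mirnas, size=spec.planted_shared_mirnas,
                              replace=False)
    for m_i in shared_block:
        for g in planted_genes:
            targets[g].add(mirnas[m_i])
    target_map = MiRNATargetMap(
        targets={g: s for g, s in targets.items() if s},
        mirna_universe=set(mirnas),
    )

    # --- expression -----------------------------------------------------
    n_total = 2 * spec.n_samples
    samples = [f"S{i:03d}" for i in range(n_total)]
    labels = pd.Series(
        ["disease"] * spec.n_samples + ["normal"] * spec.n_samples,
        index=samples, name="group",
    )
    x = rng.standard_normal((spec.n_mrnas, n_total))
    # equicorrelated block for the planted genes: shared factor + noise
    common = rng.standard_normal(n_total)
    rho = spec.cerna_r
    for gi in planted_idx:
        x[gi] = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(
            n_total
        )
    disease = np.asarray(labels == "disease")
    for gi in planted_idx:
        x[gi, disease] += spec.de_effect
    # background DE genes live in non-planted pathways
    non_planted_pathway_genes = [
        g
        for pw in truth["pathways"]
        if pw["pathway_id"] != truth["planted"]["pathway_id"]
        for g in pw["genes"]
    ]
    bg_de = sorted(
        rng.choice(non_planted_pathway_genes,
                   size=min(spec.n_background_de,
                            len(non_planted_pathway_genes)),
                   replace=False).tolist()
    )
    for j, g in enumerate(bg_de):
        sign = 1.0 if j % 2 == 0 else -1.0
        x[all_genes.index(g), disease] += sign * spec.de_effect
    expr = pd.DataFrame(x, index=pd.Index(all_genes, name="gene"),
                        columns=samples)

    # --- survival -------------------------------------------------------
    u = x[planted_idx].mean(axis=0)
    u = (u - u.mean()) / u.std()
    time, event = simulate_survival_times(
        u, spec.beta_true, spec.baseline_hazard, spec.censor_rate, rng
    )
    survival = pd.DataFrame(
        {"sample": samples, "time": time, "event": event}
    )

    truth = dict(truth)
    truth["background_de_genes"] = bg_de
    truth["planted_de_genes"] = planted_genes
    truth["n_pathway_genes"] = n_pathway_genes
    return SyntheticBundle(
        kgml_texts=texts,
        id_map=id_map,
        target_map=target_map,
        expr=expr,
        labels=labels,
        survival=survival,
        truth=truth,
        spec=spec,
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> None:
    """Write the bundle as plain-text inputs plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for text, pw in zip(bundle.kgml_texts, bundle.truth["pathways"]):
        name = pw["pathway_id"].replace(":", "_")
        (out / f"{name}.xml").write_text(text)
    with open(out / "id_map.tsv", "w") as fh:
        fh.write("kegg_gene_id\tsymbol\n")
        for k, v in sorted(bundle.id_map.items()):
            fh.write(f"{k}\t{v}\n")
    with open(out / "targets.tsv", "w") as fh:
        fh.write("mirna_id\tgene_symbol\n")
        for g in sorted(bundle.target_map.targets):
            for m in sorted(bundle.target_map.targets[g]):
                fh.write(f"{m}\t{g}\n")
    bundle.expr.to_csv(out / "expression.tsv", sep="\t")
    bundle.labels.rename_axis("sample").to_frame().to_csv(
        out / "labels.tsv", sep="\t"
    )
    bundle.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    spec_dict = asdict(bundle.spec)
    (out / "truth.json").write_text(
        json.dumps({"spec": spec_dict, "truth": bundle.truth}, indent=2)
    )
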