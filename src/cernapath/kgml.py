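"""KEGG KGML pathway parsing and gene-product graph reconstruction.

A KGML file describes one KEGG pathway map as a set of *entries* (gene
products, compounds, nested group/complex entries, links to other maps),
*relations* between entries and, for metabolic maps, *reactions* that
consume and produce compounds.  For topology-aware analysis the map is
reconstructed as an undirected gene-product graph: map-link entries are
removed, group entries are expanded to cliques of their member gene
entries, and compound entries are collapsed so that gene products touching
a common compound (through a reaction or a compound-mediated relation)
become adjacent.  One graph node corresponds to one KEGG entry and may
carry several gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from lxml import etree

__all__ = [
    "KgmlEntry",
    "KgmlRelation",
    "KgmlReaction",
    "KgmlPathway",
    "PathwayGraph",
    "KgmlParseError",
    "KgmlStructureError",
    "parse_kgml",
    "serialize_kgml",
    "reconstruct_graph",
    "path_distance_and_union",
    "background_genes",
    "write_graph_exports",
]

#: entry types treated as gene products during reconstruction
_GENE_LIKE = {"gene", "ortholog", "enzyme"}


class KgmlParseError(ValueError):
    """Raised when the XML is malformed or not in the KGML dialect."""


class KgmlStructureError(ValueError):
    """Raised when relations/reactions reference undeclared entries."""


@dataclass(frozen=True)
class KgmlEntry:
    entry_id: str
    entry_type: str  # gene | compound | map | group | ortholog | other
    name: str  # space-separated KEGG identifiers, e.g. "hsa:7157"
    #: KEGG gene ids split out of ``name`` (empty for non-gene entries)
    member_gene_ids: tuple[str, ...] = ()
    #: component entry ids (group entries only)
    components: tuple[str, ...] = ()
    #: reaction name carried by the entry (metabolic maps), "" if none
    reaction: str = ""


@dataclass(frozen=True)
class KgmlRelation:
    entry1: str
    entry2: str
    relation_type: str  # PPrel | ECrel | GErel | PCrel | maplink | ...
    #: (subtype name, subtype value) pairs; a value may be a compound entry id
    subtypes: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class KgmlReaction:
    name: str
    reaction_type: str  # reversible | irreversible
    gene_entry_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...]  # compound entry ids
    product_ids: tuple[str, ...]  # compound entry ids


@dataclass(frozen=True)
class KgmlPathway:
    pathway_id: str
    title: str
    entries: tuple[KgmlEntry, ...]
    relations: tuple[KgmlRelation, ...]
    reactions: tuple[KgmlReaction, ...]

    def entry_index(self) -> dict[str, KgmlEntry]:
        return {e.entry_id: e for e in self.entries}


@dataclass
class PathwayGraph:
    """Reconstructed undirected gene-product graph of one pathway.

    Nodes are KEGG entry ids; ``graph.nodes[n]["genes"]`` is the non-empty
    frozenset of gene symbols carried by the entry (KEGG ids are kept as
    symbols when no mapping is available).
    """

    pathway_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def node_genes(self) -> dict[str, frozenset[str]]:
        return {n: self.graph.nodes[n]["genes"] for n in self.graph.nodes}

    def genes(self) -> set[str]:
        out: set[str] = set()
        for n in self.graph.nodes:
            out |= self.graph.nodes[n]["genes"]
        return out

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


def _split_gene_ids(name: str) -> tuple[str, ...]:
    return tuple(tok for tok in name.split() if tok and tok != "undefined")


def parse_kgml(xml_text: str | bytes) -> KgmlPathway:
    """Parse one KGML document into a :class:`KgmlPathway`.

    Raises :class:`KgmlParseError` for malformed XML, a non-``pathway``
    root or a missing pathway ``name`` attribute, and
    :class:`KgmlStructureError` when entry ids are duplicated.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message detail
        raise KgmlParseError(f"malformed KGML XML: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(f"root element is <{root.tag}>, expected <pathway>")
    pathway_id = root.get("name") or ""
    if not pathway_id:
        raise KgmlParseError("<pathway> element lacks a 'name' attribute")
    title = root.get("title", "")

    entries: list[KgmlEntry] = []
    seen: set[str] = set()
    for el in root.findall("entry"):
        eid = el.get("id")
        etype = el.get("type", "other")
        name = el.get("name", "")
        if eid is None:
            raise KgmlParseError("<entry> element lacks an 'id' attribute")
        if eid in seen:
            raise KgmlStructureError(f"duplicate entry id {eid!r}")
        seen.add(eid)
        components = tuple(
            c.get("id") for c in el.findall("component") if c.get("id")
        )
        gene_ids = _split_gene_ids(name) if etype in _GENE_LIKE else ()
        entries.append(
            KgmlEntry(
                entry_id=eid,
                entry_type=etype,
                name=name,
                member_gene_ids=gene_ids,
                components=components,
                reaction=el.get("reaction", ""),
            )
        )

    relations = tuple(
        KgmlRelation(
            entry1=el.get("entry1", ""),
            entry2=el.get("entry2", ""),
            relation_type=el.get("type", ""),
            subtypes=tuple(
                (s.get("name", ""), s.get("value", ""))
                for s in el.findall("subtype")
            ),
        )
        for el in root.findall("relation")
    )

    reaction_name_to_genes: dict[str, list[str]] = {}
    for e in entries:
        if e.reaction:
            for rname in e.reaction.split():
                reaction_name_to_genes.setdefault(rname, []).append(e.entry_id)
    reactions = []
    for el in root.findall("reaction"):
        rname = el.get("name", "")
        genes: list[str] = []
        for tok in rname.split():
            genes.extend(reaction_name_to_genes.get(tok, []))
        rid = el.get("id")
        if rid is not None and rid in seen and rid not in genes:
            genes.append(rid)
        reactions.append(
            KgmlReaction(
                name=rname,
                reaction_type=el.get("type", ""),
                gene_entry_ids=tuple(dict.fromkeys(genes)),
                substrate_ids=tuple(
                    s.get("id", "") for s in el.findall("substrate")
                ),
                product_ids=tuple(
                    p.get("id", "") for p in el.findall("product")
                ),
            )
        )

    return KgmlPathway(
        pathway_id=pathway_id,
        title=title,
        entries=tuple(entries),
        relations=relations,
        reactions=tuple(reactions),
    )


def serialize_kgml(kp: KgmlPathway) -> str:
    """Serialize a :class:`KgmlPathway` back to KGML XML text.

    ``parse_kgml(serialize_kgml(kp))`` reproduces ``kp`` exactly.
    """
    root = etree.Element("pathway", name=kp.pathway_id, title=kp.title)
    for e in kp.entries:
        attrs = {"id": e.entry_id, "name": e.name, "type": e.entry_type}
        if e.reaction:
            attrs["reaction"] = e.reaction
        el = etree.SubElement(root, "entry", **attrs)
        for cid in e.components:
            etree.SubElement(el, "component", id=cid)
    for r in kp.relations:
        el = etree.SubElement(
            root, "relation", entry1=r.entry1, entry2=r.entry2, type=r.relation_type
        )
        for name, value in r.subtypes:
            etree.SubElement(el, "subtype", name=name, value=value)
    for rx in kp.reactions:
        el = etree.SubElement(root, "reaction", name=rx.name, type=rx.reaction_type)
        for sid in rx.substrate_ids:
            etree.SubElement(el, "substrate", id=sid, name="")
        for pid in rx.product_ids:
            etree.SubElement(el, "product", id=pid, name="")
    return etree.tostring(root, pretty_print=True).decode()


def _expand_groups(index: Mapping[str, KgmlEntry], entry_id: str) -> list[str]:
    """Resolve an entry id to the gene-like entry ids it stands for."""
    e = index.get(entry_id)
    if e is None:
        return []
    if e.entry_type == "group":
        out: list[str] = []
        for cid in e.components:
            out.extend(_expand_groups(index, cid))
        return out
    if e.entry_type in _GENE_LIKE:
        return [entry_id]
    return []


def reconstruct_graph(
    kp: KgmlPathway, id_map: Mapping[str, str] | None = None
) -> PathwayGraph:
    """Reconstruct the undirected gene-product graph of one pathway.

    Rules applied, in order:

    * map-link entries are removed together with their relations;
    * group (complex) entries are expanded: members form a clique and any
      relation touching the group propagates to every member;
    * relations between gene-product entries become edges; a relation
      carrying a ``compound`` subtype still yields a direct edge between
      its two gene endpoints;
    * compound entries are collapsed: gene products whose reactions or
      relations involve a common compound become pairwise adjacent;
    * entry ids with no symbol in ``id_map`` keep their KEGG identifiers
      as gene symbols so topology is preserved.

    Raises :class:`KgmlStructureError` when a relation or reaction
    references an undeclared entry.
    """
    id_map = dict(id_map or {})
    index = kp.entry_index()

    def check(eid: str, where: str) -> None:
        if eid and eid not in index:
            raise KgmlStructureError(
                f"{where} references undeclared entry {eid!r} "
                f"in pathway {kp.pathway_id}"
            )

    pg = PathwayGraph(pathway_id=kp.pathway_id)
    g = pg.graph
    for e in kp.entries:
        if e.entry_type not in _GENE_LIKE:
            continue
        raw_ids = e.member_gene_ids or tuple(filter(None, [e.name])) or (e.entry_id,)
        symbols = frozenset(id_map.get(gid, gid) for gid in raw_ids)
        g.add_node(e.entry_id, genes=symbols)

    def add_edge(u: str, v: str) -> None:
        if u != v and g.has_node(u) and g.has_node(v):
            g.add_edge(u, v)

    # genes grouped by touching compound entry
    compound_contacts: dict[str, set[str]] = {}

    for r in kp.relations:
        check(r.entry1, "relation")
        check(r.entry2, "relation")
        e1, e2 = index[r.entry1], index[r.entry2]
        if "map" in (e1.entry_type, e2.entry_type):
            continue  # map nodes are removed with their relations
        side1 = _expand_groups(index, r.entry1)
        side2 = _expand_groups(index, r.entry2)
        for eid, side in ((r.entry1, side1), (r.entry2, side2)):
            if index[eid].entry_type == "group":
                for a in side:
                    for b in side:
                        if a < b:
                            add_edge(a, b)
        # compound endpoints: record contacts for collapsing
        for comp_eid, gene_side in ((r.entry1, side2), (r.entry2, side1)):
            if index[comp_eid].entry_type == "compound":
                compound_contacts.setdefault(comp_eid, set()).update(gene_side)
        for a in side1:
            for b in side2:
                add_edge(a, b)
        # compound-mediated relation subtype (ECrel in signalling style)
        for name, value in r.subtypes:
            if name == "compound" and value:
                check(value, "relation subtype")
                compound_contacts.setdefault(value, set()).update(side1)
                compound_contacts[value].update(side2)

    for rx in kp.reactions:
        members: list[str] = []
        for gid in rx.gene_entry_ids:
            check(gid, "reaction")
            members.extend(_expand_groups(index, gid))
        for cid in rx.substrate_ids + rx.product_ids:
            check(cid, "reaction")
            if index[cid].entry_type == "compound":
                compound_contacts.setdefault(cid, set()).update(members)

    for contacts in compound_contacts.values():
        ordered = sorted(contacts)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                add_edge(a, b)

    return pg


def path_distance_and_union(
    g: PathwayGraph, u: str, v: str
) -> tuple[int | None, set[str]]:
    """Shortest-path length between two nodes and the union of nodes lying
    on *any* shortest path (endpoints included).

    Returns ``(None, set())`` when the nodes are disconnected.  A node x is
    on some shortest u-v path iff dist(u,x) + dist(x,v) == dist(u,v).
    """
    graph = g.graph
    for node in (u, v):
        if not graph.has_node(node):
            raise KeyError(f"node {node!r} not in pathway {g.pathway_id}")
    if u == v:
        return 0, {u}
    du = nx.single_source_shortest_path_length(graph, u)
    if v not in du:
        return None, set()
    dv = nx.single_source_shortest_path_length(graph, v)
    d = du[v]
    union = {x for x, dux in du.items() if x in dv and dux + dv[x] == d}
    return d, union


def background_genes(graphs: Iterable[PathwayGraph]) -> set[str]:
    """Union of gene symbols over all pathway graphs (the Eq-5 background)."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("at least one pathway graph is required")
    out: set[str] = set()
    for g in graphs:
        out |= g.genes()
    return out


def write_graph_exports(graphs: Sequence[PathwayGraph], out_dir) -> None:
    """Write GML, edge-list TSV and node-annotation TSV for each graph."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    safe = lambda pid: pid.replace(":", "_").replace("/", "_")
    with open(os.path.join(out_dir, "nodes.tsv"), "w") as nh, open(
        os.path.join(out_dir, "edges.tsv"), "w"
    ) as eh:
        nh.write("node_id\tpathway_id\tgenes\n")
        eh.write("node_id\tnode_id\tpathway_id\n")
        for g in graphs:
            export = nx.Graph()
            for n, data in g.graph.nodes(data=True):
                export.add_node(n, genes=";".join(sorted(data["genes"])))
                nh.write(f"{n}\t{g.pathway_id}\t{';'.join(sorted(data['genes']))}\n")
            export.add_edges_from(g.graph.edges)
            for a, b in sorted(map(sorted, g.graph.edges)):
                eh.write(f"{a}\t{b}\t{g.pathway_id}\n")
            nx.write_gml(export, os.path.join(out_dir, f"{safe(g.pathway_id)}.gml"))
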