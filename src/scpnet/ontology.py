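"""Ontologies, annotation propagation, size filtering and SCP interaction networks.

An :class:`Ontology` is a directed acyclic graph of pathway terms (in MBCO
parlance, subcellular processes or SCPs) with per-term gene annotations.
Hierarchical relations (``is_a``, ``part_of`` and the annotated parent-child
relation of flat ontology tables) carry annotation propagation and connector
insertion; ``regulates``-family relations are retained as a separate,
non-hierarchical edge class.

Two dialects are supported: a flat tab-delimited parent/child table with a
term/gene annotation table (the MBCO distribution format, optionally carrying
a 1-4 level per term), and OBO plus a two-column annotation table (the GO
format).  Weighted term-term functional interactions live in
:class:`InteractionNetwork` and support "top x% of interactions" selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: relations along which gene annotations propagate child -> parent
HIERARCHICAL_RELATIONS = frozenset({"is_a", "part_of", "annotated_hierarchy"})
#: relations kept as a separate, non-hierarchical edge class
REGULATORY_RELATIONS = frozenset(
    {"regulates", "positively_regulates", "negatively_regulates"}
)


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or annotation files."""


@dataclass
class Term:
    """A single ontology term.

    Parameters
    ----------
    id:
        Unique term identifier (e.g. ``GO:0007049`` or an SCP name).
    name:
        Human-readable label; defaults to the id.
    level:
        Optional MBCO-style level (1-4).  Present for every term of a leveled
        ontology, absent for all terms otherwise.
    genes:
        Uppercase gene symbols annotated to the term.
    """

    id: str
    name: str = ""
    level: int | None = None
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id


@dataclass
class Ontology:
    """A DAG of terms with typed parent-child edges and gene annotations."""

    terms: dict[str, Term]
    edges: set[tuple[str, str, str]]  # (parent_id, child_id, relation)
    propagated: bool = False
    name: str = "ontology"

    # -- structure ---------------------------------------------------------

    def hierarchy_graph(self) -> nx.DiGraph:
        """Directed parent->child graph over hierarchical relations only."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for parent, child, rel in self.edges:
            if rel in HIERARCHICAL_RELATIONS:
                g.add_edge(parent, child, relation=rel)
        return g

    def regulatory_edges(self) -> set[tuple[str, str, str]]:
        return {e for e in self.edges if e[2] in REGULATORY_RELATIONS}

    @property
    def leveled(self) -> bool:
        return bool(self.terms) and all(
            t.level is not None for t in self.terms.values()
        )

    def levels(self) -> list[int]:
        """Sorted distinct term levels (empty for unleveled ontologies)."""
        return sorted({t.level for t in self.terms.values() if t.level is not None})

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return out

    def copy(self) -> "Ontology":
        return Ontology(
            terms={tid: replace(t, genes=set(t.genes)) for tid, t in self.terms.items()},
            edges=set(self.edges),
            propagated=self.propagated,
            name=self.name,
        )

    def _validate_dag(self) -> None:
        g = self.hierarchy_graph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise OntologyError(
            "hierarchical relations contain a cycle: "
            + ", ".join(f"{u}->{v}" for u, v, *_ in cycle)
        )


#: ortholog table: uppercase source symbol -> set of uppercase target symbols
OrthologTable = dict[str, set[str]]


class TranslationResult(NamedTuple):
    """Outcome of an ortholog translation: mapped symbols plus the drop count."""

    genes: set[str]
    dropped: int


class SizeFilter(NamedTuple):
    """Inclusive bounds on the number of genes annotated to a candidate term."""

    min_genes: int = 0
    max_genes: float = math.inf

    def admits(self, n_genes: int) -> bool:
        return self.min_genes <= n_genes <= self.max_genes


@dataclass(frozen=True)
class InteractionNetwork:
    """Weighted undirected term-term functional interactions.

    Edges are stored with canonically ordered endpoints so that the network is
    order-independent; weights are strictly positive.  ``level`` optionally
    scopes the edges to one SCP level.
    """

    edges: frozenset[tuple[str, str, float]]
    level: int | None = None

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], level: int | None = None
    ) -> "InteractionNetwork":
        canon = set()
        for a, b, w in edges:
            if w <= 0:
                raise ValueError(f"interaction weight must be positive: {a}-{b} ({w})")
            if a == b:
                raise ValueError(f"self interaction not allowed: {a}")
            canon.add((min(a, b), max(a, b), float(w)))
        return cls(edges=frozenset(canon), level=level)

    def terms(self) -> set[str]:
        return {t for a, b, _ in self.edges for t in (a, b)}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _load_flat(hierarchy_source: str | Path) -> Ontology:
    df = _read_table(hierarchy_source)
    for col in ("parent", "child"):
        if col not in df.columns:
            raise OntologyError(
                f"flat ontology file {hierarchy_source} lacks required column {col!r}"
            )
    has_rel = "relation" in df.columns
    has_level = "level" in df.columns

    terms: dict[str, Term] = {}
    edges: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        parent = str(row.parent).strip()
        child = str(row.child).strip()
        rel = str(row.relation).strip() if has_rel and pd.notna(row.relation) else "annotated_hierarchy"
        if rel not in HIERARCHICAL_RELATIONS | REGULATORY_RELATIONS:
            raise OntologyError(f"unknown relation {rel!r} in {hierarchy_source}")
        for tid in (parent, child):
            if tid not in terms:
                terms[tid] = Term(id=tid)
        if has_level and pd.notna(row.level):
            terms[child].level = int(float(row.level))
        edges.add((parent, child, rel))

    if has_level:
        # roots carry no child row; one level above their shallowest child
        g = nx.DiGraph((p, c) for p, c, r in edges if r in HIERARCHICAL_RELATIONS)
        for tid, term in terms.items():
            if term.level is None:
                child_levels = [
                    terms[c].level for c in g.successors(tid)
                    if tid in g and terms[c].level is not None
                ] if tid in g else []
                term.level = max(1, min(child_levels) - 1) if child_levels else 1
    return Ontology(terms=terms, edges=edges, name=Path(hierarchy_source).stem)


_OBO_RELATION_ALIASES = {
    "is_a": "is_a",
    "part_of": "part_of",
    "regulates": "regulates",
    "positively_regulates": "positively_regulates",
    "negatively_regulates": "negatively_regulates",
}


def _load_obo(hierarchy_source: str | Path) -> Ontology:
    graph = obonet.read_obo(hierarchy_source)  # obsolete terms skipped by default
    terms: dict[str, Term] = {}
    for tid, data in graph.nodes(data=True):
        terms[tid] = Term(id=tid, name=data.get("name", tid))
    edges: set[tuple[str, str, str]] = set()
    # obonet edges run child -> parent keyed by relation
    for child, parent, rel in graph.edges(keys=True):
        rel = _OBO_RELATION_ALIASES.get(rel)
        if rel is None:
            continue  # other typedefs (e.g. occurs_in) are not modeled
        if parent in terms and child in terms:
            edges.add((parent, child, rel))
    return Ontology(terms=terms, edges=edges, name=Path(hierarchy_source).stem)


def _attach_annotations(o: Ontology, annotation_source: str | Path) -> None:
    df = _read_table(annotation_source)
    for col in ("term", "gene"):
        if col not in df.columns:
            raise OntologyError(
                f"annotation file {annotation_source} lacks required column {col!r}"
            )
    unknown = sorted(set(df["term"]) - set(o.terms))
    if unknown:
        raise OntologyError(
            "annotation references unknown terms: " + ", ".join(unknown)
        )
    for term, gene in zip(df["term"], df["gene"]):
        if pd.isna(gene):
            continue
        o.terms[term].genes.add(str(gene).strip().upper())


def load_ontology(
    hierarchy_source: str | Path,
    annotation_source: str | Path,
    dialect: str = "flat",
) -> Ontology:
    """Load an unpropagated ontology from disk.

    ``dialect='flat'`` expects a tab-delimited header row with columns
    ``parent``/``child`` (optional ``relation``, ``level``) plus a
    ``term``/``gene`` annotation table.  ``dialect='obo'`` expects an OBO
    file plus the same two-column annotation table.  Gene symbols are
    uppercased at parse time; cycles among hierarchical relations and
    annotations referencing unknown terms are rejected.
    """
    if dialect == "flat":
        o = _load_flat(hierarchy_source)
    elif dialect == "obo":
        o = _load_obo(hierarchy_source)
    else:
        raise ValueError(f"unknown ontology dialect {dialect!r}")
    o._validate_dag()
    _attach_annotations(o, annotation_source)
    return o


def load_interactions(path: str | Path) -> dict[int | None, InteractionNetwork]:
    """Read a weighted term-term interaction edge list.

    Columns ``term_a``/``term_b``/``weight`` with an optional ``level``
    column; returns one network per level (key ``None`` when the column is
    absent).
    """
    df = _read_table(path)
    for col in ("term_a", "term_b", "weight"):
        if col not in df.columns:
            raise OntologyError(f"interaction file {path} lacks column {col!r}")
    nets: dict[int | None, list[tuple[str, str, float]]] = {}
    has_level = "level" in df.columns
    for row in df.itertuples(index=False):
        lvl = int(float(row.level)) if has_level and pd.notna(row.level) else None
        nets.setdefault(lvl, []).append(
            (str(row.term_a), str(row.term_b), float(row.weight))
        )
    return {lvl: InteractionNetwork.from_edges(e, level=lvl) for lvl, e in nets.items()}


def load_ortholog_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``source``/``target`` ortholog table, uppercased."""
    df = _read_table(path)
    for col in ("source", "target"):
        if col not in df.columns:
            raise OntologyError(f"ortholog table {path} lacks column {col!r}")
    table: dict[str, set[str]] = {}
    for src, tgt in zip(df["source"], df["target"]):
        if pd.isna(src) or pd.isna(tgt):
            continue
        table.setdefault(str(src).strip().upper(), set()).add(str(tgt).strip().upper())
    return table


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------


def propagate_annotations(o: Ontology) -> Ontology:
    """Populate every term with the genes of all its hierarchical descendants.

    A single bottom-up pass in reverse topological order reaches the fixed
    point; regulatory edges are ignored.  Idempotent; returns a new ontology
    with ``propagated`` set.
    """
    out = o.copy()
    g = out.hierarchy_graph()
    for tid in reversed(list(nx.topological_sort(g))):
        genes = out.terms[tid].genes
        for child in g.successors(tid):
            genes |= out.terms[child].genes
    out.propagated = True
    return out


def filter_by_size(o: Ontology, f: SizeFilter) -> Ontology:
    """Drop terms whose gene count falls outside ``f``, bypassing them in the DAG.

    Removed terms are transitively reconnected (every hierarchical parent of a
    removed term is wired to each of its hierarchical children) so that
    reachability among the surviving terms is preserved.  Regulatory edges
    incident to removed terms are dropped.
    """
    survivors = {tid for tid, t in o.terms.items() if f.admits(len(t.genes))}
    g = o.hierarchy_graph()
    for victim in [t for t in nx.topological_sort(g) if t not in survivors]:
        preds = list(g.predecessors(victim))
        succs = list(g.successors(victim))
        for p in preds:
            rel = g.edges[p, victim]["relation"]
            for c in succs:
                if not g.has_edge(p, c):
                    g.add_edge(p, c, relation=rel)
        g.remove_node(victim)
    edges = {(u, v, d["relation"]) for u, v, d in g.edges(data=True)}
    edges |= {
        e for e in o.regulatory_edges() if e[0] in survivors and e[1] in survivors
    }
    return Ontology(
        terms={tid: replace(o.terms[tid], genes=set(o.terms[tid].genes))
               for tid in survivors},
        edges=edges,
        propagated=o.propagated,
        name=o.name,
    )


def top_interactions(net: InteractionNetwork, fraction: float) -> InteractionNetwork:
    """Keep the top ``fraction`` percent highest-weight interactions.

    The edge count is ``ceil(fraction/100 * |edges|)``; edges tied with the
    cutoff weight are all included, making the selection order-independent.
    """
    if not 0 < fraction <= 100:
        raise ValueError(f"fraction must be in (0, 100], got {fraction}")
    if not net.edges:
        return net
    n_keep = math.ceil(fraction / 100.0 * len(net.edges))
    weights = sorted((w for _, _, w in net.edges), reverse=True)
    cutoff = weights[n_keep - 1]
    kept = {e for e in net.edges if e[2] >= cutoff}
    return InteractionNetwork(edges=frozenset(kept), level=net.level)


def merge_terms(o: Ontology, member_ids: list[str], new_name: str) -> Ontology:
    """Add a user-defined merged term whose genes are the union of the members.

    The merged term sits alongside (not replacing) its members, parentless,
    at the minimum member level, and behaves as an ordinary term in
    subsequent enrichment.
    """
    if len(member_ids) < 2:
        raise ValueError("merging requires at least two member terms")
    unknown = [m for m in member_ids if m not in o.terms]
    if unknown:
        raise ValueError("unknown member term ids: " + ", ".join(unknown))
    if new_name in o.terms:
        raise ValueError(f"term id {new_name!r} already in use")
    out = o.copy()
    genes: set[str] = set()
    levels = []
    for m in member_ids:
        genes |= out.terms[m].genes
        if out.terms[m].level is not None:
            levels.append(out.terms[m].level)
    out.terms[new_name] = Term(
        id=new_name, name=new_name, level=min(levels) if levels else None, genes=genes
    )
    return out


def translate_genes(
    genes: Iterable[str], table: Mapping[str, set[str]]
) -> TranslationResult:
    """Map gene symbols through an ortholog table.

    Returns the union of all mapped target symbols together with the number
    of source symbols that had no mapping (and were dropped).
    """
    out: set[str] = set()
    dropped = 0
    for g in genes:
        targets = table.get(g.upper())
        if targets:
            out |= {t.upper() for t in targets}
        else:
            dropped += 1
    if dropped:
        logger.warning("%d gene symbols had no ortholog mapping and were dropped", dropped)
    return TranslationResult(genes=out, dropped=dropped)


# ---------------------------------------------------------------------------
# network writing (delegates serialization to export_render)
# ---------------------------------------------------------------------------


def write_hierarchy_network(
    o: Ontology, path: str | Path, dialect: str = "graphml"
) -> Path:
    """Write the full parent-child DAG as a GraphML or XGMML file."""
    from . import export_render, network_build

    net = network_build.PathwayNetwork(name=f"{o.name}_hierarchy")
    for tid in sorted(o.terms):
        t = o.terms[tid]
        net.nodes[tid] = network_build.PieNode(
            term_id=tid, label=t.name, level=t.level, connector_only=True
        )
    for parent, child, rel in sorted(o.edges):
        kind = "hierarchical" if rel in HIERARCHICAL_RELATIONS else "regulatory"
        net.edges.append(
            network_build.NetworkEdge(source=parent, target=child, kind=kind)
        )
    network_build.compute_node_geometry(net, network_build.ScalingOptions(mode="uniform"))
    return _write_dialect(net, path, dialect)


def write_interaction_network(
    net: InteractionNetwork,
    path: str | Path,
    fraction: float = 100.0,
    dialect: str = "graphml",
) -> Path:
    """Write the top ``fraction`` percent weighted interactions to a file."""
    from . import export_render, network_build

    top = top_interactions(net, fraction)
    pnet = network_build.PathwayNetwork(name="interactions")
    for tid in sorted(top.terms()):
        pnet.nodes[tid] = network_build.PieNode(
            term_id=tid, label=tid, level=top.level, connector_only=True
        )
    for a, b, w in sorted(top.edges):
        pnet.edges.append(
            network_build.NetworkEdge(source=a, target=b, kind="functional", weight=w)
        )
    network_build.compute_node_geometry(pnet, network_build.ScalingOptions(mode="uniform"))
    return _write_dialect(pnet, path, dialect)


def _write_dialect(pnet, path, dialect: str) -> Path:
    from . import export_render

    if dialect == "graphml":
        return export_render.write_graphml(pnet, path)
    if dialect == "xgmml":
        return export_render.write_xgmml(pnet, path)
    raise ValueError(f"unknown export dialect {dialect!r}")
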