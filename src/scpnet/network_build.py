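"""Merge per-dataset enrichment results into pie-chart pathway networks.

Every term predicted by at least one dataset of an integration group becomes
a pie node whose slices are the predicting datasets (slice value = -log10 p,
or the per-term split score for dynamic combinations).  Predicted terms are
connected through the ontology hierarchy — either by inserting only the
connector terms lying on directed paths between predicted terms, or by adding
the full ancestor closure — and optionally by functional (top-x% interaction)
and regulatory edges.  Node areas, slice angles and label sizes are computed
here; serialization lives in :mod:`scpnet.export_render`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import networkx as nx

from .datasets_io import Dataset
from .enrichment import EnrichmentResult, split_combination_scores
from .ontology import InteractionNetwork, Ontology, top_interactions


@dataclass
class PieSlice:
    """One dataset's contribution to a pie node."""

    dataset_name: str
    value: float  # -log10 p or count-mode weight, >= 0
    color: str
    angle: float = 0.0  # degrees, set by compute_node_geometry


@dataclass
class PieNode:
    """A pathway node (pie chart) or an inserted connector/gene node."""

    term_id: str
    label: str
    level: int | None = None
    slices: list[PieSlice] = field(default_factory=list)
    area: float = 1.0
    diameter: float = 1.0
    label_size: float = 10.0
    connector_only: bool = False
    node_type: Literal["term", "gene"] = "term"


@dataclass
class NetworkEdge:
    """Typed network edge.

    ``hierarchical`` and ``regulatory`` edges are directed (parent to child /
    regulator to target), ``functional`` edges undirected with a weight, and
    ``gene_membership`` edges run from a term to a gene child node.
    """

    source: str
    target: str
    kind: Literal["hierarchical", "functional", "regulatory", "gene_membership"]
    weight: float = 1.0


@dataclass
class PathwayNetwork:
    name: str = "network"
    nodes: dict[str, PieNode] = field(default_factory=dict)
    edges: list[NetworkEdge] = field(default_factory=list)
    #: level -> node ids, populated when level boxes are requested
    level_boxes: dict[int, list[str]] = field(default_factory=dict)

    def pie_nodes(self) -> list[PieNode]:
        return [n for n in self.nodes.values() if n.node_type == "term"]


@dataclass(frozen=True)
class ScalingOptions:
    """Visual scaling and topology options for network construction.

    ``mode`` selects what node area encodes: the summed -log10 p of the
    slices, the number of predicting datasets, the number of distinct slice
    colors, or nothing (uniform).  In all but the sum mode slice angles are
    equal within a pie.  ``label_range`` linearly maps node areas onto label
    point sizes; ``scope`` normalizes areas per network or across a batch.
    """

    mode: Literal[
        "sum_neg_log10_p", "dataset_count", "same_color_count", "uniform"
    ] = "sum_neg_log10_p"
    label_range: tuple[float, float] = (10.0, 24.0)
    scope: Literal["per_network", "global"] = "per_network"
    ancestor_mode: Literal["intermediate_only", "all_ancestors"] = "intermediate_only"
    box_levels: bool = False
    add_gene_children: bool = False
    functional_fraction: float = 0.0  # percent of top interactions; 0 disables
    include_regulatory: bool = False
    max_area: float = 1800.0  # square points given to the largest node in scope
    min_area_fraction: float = 0.05  # visibility floor for tiny nodes


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _per_term_values(results: Sequence[EnrichmentResult]) -> dict[str, float]:
    """Per-term slice values for one dataset: split scores over all results."""
    return split_combination_scores(results)


def _connector_ids(
    hierarchy: nx.DiGraph, predicted: set[str], mode: str
) -> set[str]:
    """Unpredicted terms to insert so predicted terms connect through the DAG."""
    present = predicted & set(hierarchy.nodes)
    if mode == "all_ancestors":
        out: set[str] = set()
        for t in present:
            out |= nx.ancestors(hierarchy, t)
        return out - predicted
    if mode == "intermediate_only":
        # nodes on a directed path between two predicted terms:
        # reachable from some predicted term AND reaching some predicted term
        below: set[str] = set()
        above: set[str] = set()
        for t in present:
            below |= nx.descendants(hierarchy, t)
            above |= nx.ancestors(hierarchy, t)
        return (below & above) - predicted
    raise ValueError(f"unknown ancestor mode {mode!r}")


def build_group_network(
    group_results: Mapping[str, Sequence[EnrichmentResult]],
    datasets: Sequence[Dataset],
    o: Ontology,
    net: InteractionNetwork | None = None,
    opts: ScalingOptions | None = None,
    name: str = "network",
) -> PathwayNetwork:
    """Merge the filtered results of one integration group into one network.

    ``group_results`` maps dataset name to that dataset's rank/p-filtered
    results (standard or dynamic).  Dynamic combinations are split into
    per-term slice values.  Slices are ordered by dataset order index;
    connector terms are inserted per ``opts.ancestor_mode``; functional and
    regulatory edges are optional per ``opts``.
    """
    opts = opts or ScalingOptions()
    meta = {d.name: d for d in datasets}
    ordered_names = sorted(
        group_results, key=lambda n: (meta[n].order_index if n in meta else 0, n)
    )

    pnet = PathwayNetwork(name=name)
    overlap_by_term: dict[str, set[str]] = {}
    for ds_name in ordered_names:
        results = group_results[ds_name]
        values = _per_term_values(results)
        color = meta[ds_name].color if ds_name in meta else "#1F77B4"
        for r in results:
            for tid in r.term_ids:
                overlap_by_term.setdefault(tid, set()).update(r.overlap_genes)
        for tid in sorted(values):
            node = pnet.nodes.get(tid)
            if node is None:
                term = o.terms.get(tid)
                node = pnet.nodes[tid] = PieNode(
                    term_id=tid,
                    label=term.name if term else tid,
                    level=term.level if term else None,
                )
            node.slices.append(
                PieSlice(dataset_name=ds_name, value=values[tid], color=color)
            )

    predicted = set(pnet.nodes)
    hierarchy = o.hierarchy_graph()
    for cid in sorted(_connector_ids(hierarchy, predicted, opts.ancestor_mode)):
        term = o.terms[cid]
        pnet.nodes[cid] = PieNode(
            term_id=cid, label=term.name, level=term.level, connector_only=True
        )

    present = set(pnet.nodes)
    for parent, child in sorted(hierarchy.subgraph(present).edges):
        pnet.edges.append(
            NetworkEdge(source=parent, target=child, kind="hierarchical")
        )

    if net is not None and opts.functional_fraction > 0:
        top = top_interactions(net, opts.functional_fraction)
        for a, b, w in sorted(top.edges):
            if a in predicted and b in predicted:  # predicted-to-predicted only
                na, nb = pnet.nodes[a], pnet.nodes[b]
                if na.level == nb.level:
                    pnet.edges.append(
                        NetworkEdge(source=a, target=b, kind="functional", weight=w)
                    )

    if opts.include_regulatory:
        for parent, child, _rel in sorted(o.regulatory_edges()):
            if parent in present and child in present:
                pnet.edges.append(
                    NetworkEdge(source=parent, target=child, kind="regulatory")
                )

    if opts.add_gene_children:
        for tid in sorted(predicted):
            for gene in sorted(overlap_by_term.get(tid, ())):
                gid = f"gene:{gene}"
                if gid not in pnet.nodes:
                    pnet.nodes[gid] = PieNode(
                        term_id=gid, label=gene, node_type="gene", connector_only=True
                    )
                pnet.edges.append(
                    NetworkEdge(source=tid, target=gid, kind="gene_membership")
                )

    if opts.box_levels:
        for tid in sorted(pnet.nodes):
            node = pnet.nodes[tid]
            if node.node_type == "term" and node.level is not None:
                pnet.level_boxes.setdefault(node.level, []).append(tid)

    return pnet


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _node_score(node: PieNode, mode: str) -> float:
    if node.connector_only or not node.slices:
        return 0.0
    if mode == "sum_neg_log10_p":
        return sum(s.value for s in node.slices)
    if mode == "dataset_count":
        return float(len(node.slices))
    if mode == "same_color_count":
        return float(len({s.color for s in node.slices}))
    if mode == "uniform":
        return 1.0
    raise ValueError(f"unknown scaling mode {mode!r}")


def compute_node_geometry(
    net: PathwayNetwork,
    opts: ScalingOptions | None = None,
    norm_max: float | None = None,
) -> PathwayNetwork:
    """Assign node areas, diameters, slice angles and label sizes in place.

    Areas are proportional to the mode's node score, normalized so the
    largest score in scope receives ``opts.max_area`` (pass ``norm_max`` to
    share one normalization across the networks of a batch, i.e. global
    scope).  Slice angles split the pie proportionally to slice values in
    sum mode and equally otherwise; angles always total 360 degrees.  Label
    sizes interpolate linearly from the node-area range onto
    ``opts.label_range``.  Connector and gene nodes get the floor area.
    """
    opts = opts or ScalingOptions()
    scores = {tid: _node_score(n, opts.mode) for tid, n in net.nodes.items()}
    max_score = norm_max if norm_max is not None else max(scores.values(), default=0.0)
    if max_score <= 0:
        max_score = 1.0
    floor = opts.min_area_fraction * opts.max_area
    for tid, node in net.nodes.items():
        area = opts.max_area * scores[tid] / max_score
        node.area = max(area, floor)
        node.diameter = math.sqrt(4.0 * node.area / math.pi)
        total = sum(s.value for s in node.slices)
        for s in node.slices:
            if opts.mode == "sum_neg_log10_p" and total > 0:
                s.angle = 360.0 * s.value / total
            elif node.slices:
                s.angle = 360.0 / len(node.slices)

    areas = [n.area for n in net.nodes.values()]
    lo_pt, hi_pt = opts.label_range
    if areas:
        a_min, a_max = min(areas), max(areas)
        for node in net.nodes.values():
            if a_max > a_min and hi_pt != lo_pt:
                node.label_size = lo_pt + (node.area - a_min) / (a_max - a_min) * (
                    hi_pt - lo_pt
                )
            else:
                node.label_size = lo_pt
    return net
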