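"""Serialize pathway networks to GraphML (yEd) and XGMML (Cytoscape); charts.

Neither plain GraphML nor XGMML standardizes pie glyphs, so every export
carries the computed node geometry (area, diameter, label size) plus
per-slice records (dataset names, values, colors in dataset order) as data
attributes from which pies are reconstructable — in Cytoscape via style
binding to the exported list attributes, in yEd via the embedded yFiles
shape graphics.  Writing is deterministic: nodes and edges are emitted in
sorted order and numbers are formatted at 12 significant digits, so
write -> parse -> write is byte-stable.  An auxiliary SVG renderer draws true
pies for inspection, and bar/heatmap/timeline charts summarize enrichment
results.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .enrichment import EnrichmentResult
from .network_build import NetworkEdge, PathwayNetwork, PieNode, PieSlice

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
Y_NS = "http://www.yworks.com/xml/graphml"

_NODE_KEYS = [
    ("label", "string"), ("level", "string"), ("node_type", "string"),
    ("connector_only", "boolean"), ("area", "double"), ("diameter", "double"),
    ("label_size", "double"), ("slice_datasets", "string"),
    ("slice_values", "string"), ("slice_colors", "string"),
]
_EDGE_KEYS = [("kind", "string"), ("weight", "double")]


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _sorted_edges(net: PathwayNetwork) -> list[NetworkEdge]:
    return sorted(net.edges, key=lambda e: (e.kind, e.source, e.target))


def _slice_fields(node: PieNode) -> dict[str, str]:
    return {
        "slice_datasets": ";".join(s.dataset_name for s in node.slices),
        "slice_values": ";".join(_fmt(s.value) for s in node.slices),
        "slice_colors": ";".join(s.color for s in node.slices),
    }


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def write_graphml(net: PathwayNetwork, path: str | Path) -> Path:
    """Write the network as GraphML with yFiles node graphics.

    Level boxes become nested graphs inside group nodes; slice data is
    attached as string-valued keys so pies can be rebuilt from the file.
    """
    path = Path(path)
    nsmap = {None: GRAPHML_NS, "y": Y_NS}
    root = etree.Element(f"{{{GRAPHML_NS}}}graphml", nsmap=nsmap)
    for i, (name, typ) in enumerate(_NODE_KEYS):
        etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id=f"d{i}",
                         attrib={"for": "node", "attr.name": name, "attr.type": typ})
    etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id="dg",
                     attrib={"for": "node", "yfiles.type": "nodegraphics"})
    for i, (name, typ) in enumerate(_EDGE_KEYS):
        etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id=f"e{i}",
                         attrib={"for": "edge", "attr.name": name, "attr.type": typ})
    graph = etree.SubElement(root, f"{{{GRAPHML_NS}}}graph",
                             id=net.name, edgedefault="directed")

    boxed = {tid for ids in net.level_boxes.values() for tid in ids}

    def emit_node(parent, tid: str, node: PieNode) -> None:
        el = etree.SubElement(parent, f"{{{GRAPHML_NS}}}node", id=tid)
        fields = {
            "label": node.label,
            "level": "" if node.level is None else str(node.level),
            "node_type": node.node_type,
            "connector_only": "true" if node.connector_only else "false",
            "area": _fmt(node.area),
            "diameter": _fmt(node.diameter),
            "label_size": _fmt(node.label_size),
            **_slice_fields(node),
        }
        for i, (name, _) in enumerate(_NODE_KEYS):
            d = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key=f"d{i}")
            d.text = fields[name]
        d = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="dg")
        shape = etree.SubElement(d, f"{{{Y_NS}}}ShapeNode")
        etree.SubElement(shape, f"{{{Y_NS}}}Geometry",
                         height=_fmt(node.diameter), width=_fmt(node.diameter),
                         x="0", y="0")
        fill = node.slices[0].color if node.slices else "#FFFFFF"
        etree.SubElement(shape, f"{{{Y_NS}}}Fill", color=fill, transparent="false")
        lab = etree.SubElement(shape, f"{{{Y_NS}}}NodeLabel",
                               fontSize=str(int(round(node.label_size))))
        lab.text = node.label
        etree.SubElement(shape, f"{{{Y_NS}}}Shape", type="ellipse")

    for level in sorted(net.level_boxes):
        group = etree.SubElement(graph, f"{{{GRAPHML_NS}}}node",
                                 id=f"box:level{level}")
        etree.SubElement(group, f"{{{GRAPHML_NS}}}data", key="d0").text = (
            f"Level {level}"
        )
        sub = etree.SubElement(group, f"{{{GRAPHML_NS}}}graph",
                               id=f"box:level{level}:", edgedefault="directed")
        for tid in sorted(net.level_boxes[level]):
            emit_node(sub, tid, net.nodes[tid])
    for tid in sorted(net.nodes):
        if tid not in boxed:
            emit_node(graph, tid, net.nodes[tid])

    for j, e in enumerate(_sorted_edges(net)):
        el = etree.SubElement(graph, f"{{{GRAPHML_NS}}}edge",
                              id=f"e{j}", source=e.source, target=e.target)
        etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="e0").text = e.kind
        etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="e1").text = _fmt(e.weight)

    path.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                       pretty_print=True)
    )
    return path


def read_graphml(path: str | Path) -> PathwayNetwork:
    """Parse a network previously written by :func:`write_graphml`."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    key_names = {
        k.get("id"): k.get("attr.name")
        for k in root.findall(f"{{{GRAPHML_NS}}}key")
        if k.get("attr.name")
    }
    graph = root.find(f"{{{GRAPHML_NS}}}graph")
    net = PathwayNetwork(name=graph.get("id"))

    def read_node(el, level_box: int | None) -> None:
        tid = el.get("id")
        if tid.startswith("box:level"):
            level = int(tid[len("box:level"):])
            sub = el.find(f"{{{GRAPHML_NS}}}graph")
            net.level_boxes.setdefault(level, [])
            for child in sub.findall(f"{{{GRAPHML_NS}}}node"):
                read_node(child, level)
            return
        fields = {}
        for d in el.findall(f"{{{GRAPHML_NS}}}data"):
            name = key_names.get(d.get("key"))
            if name:
                fields[name] = d.text or ""
        node = PieNode(
            term_id=tid,
            label=fields.get("label", tid),
            level=int(fields["level"]) if fields.get("level") else None,
            connector_only=fields.get("connector_only") == "true",
            node_type=fields.get("node_type", "term"),
            area=float(fields.get("area", 1.0)),
            diameter=float(fields.get("diameter", 1.0)),
            label_size=float(fields.get("label_size", 10.0)),
        )
        names = fields.get("slice_datasets", "")
        if names:
            values = fields["slice_values"].split(";")
            colors = fields["slice_colors"].split(";")
            for nm, v, col in zip(names.split(";"), values, colors):
                node.slices.append(PieSlice(dataset_name=nm, value=float(v), color=col))
            total = sum(s.value for s in node.slices)
            for s in node.slices:
                s.angle = (360.0 * s.value / total if total > 0
                           else 360.0 / len(node.slices))
        net.nodes[tid] = node
        if level_box is not None:
            net.level_boxes[level_box].append(tid)

    for el in graph.findall(f"{{{GRAPHML_NS}}}node"):
        read_node(el, None)
    for el in graph.findall(f"{{{GRAPHML_NS}}}edge"):
        fields = {key_names.get(d.get("key"), d.get("key")): d.text or ""
                  for d in el.findall(f"{{{GRAPHML_NS}}}data")}
        net.edges.append(NetworkEdge(
            source=el.get("source"), target=el.get("target"),
            kind=fields.get("kind", "hierarchical"),
            weight=float(fields.get("weight", 1.0)),
        ))
    return net


# ---------------------------------------------------------------------------
# XGMML
# ---------------------------------------------------------------------------


def write_xgmml(net: PathwayNetwork, path: str | Path) -> Path:
    """Write the network as XGMML with list-typed slice attributes.

    Slice datasets/values/colors are emitted as XGMML list attributes in
    dataset order, bindable to Cytoscape pie-chart styles; level box
    membership is a plain node attribute.
    """
    path = Path(path)
    root = etree.Element("graph", label=net.name, directed="1")
    box_of = {tid: lvl for lvl, ids in net.level_boxes.items() for tid in ids}
    ids = {tid: str(i) for i, tid in enumerate(sorted(net.nodes))}

    def att(parent, name, value, typ):
        etree.SubElement(parent, "att", name=name, value=value, type=typ)

    for tid in sorted(net.nodes):
        node = net.nodes[tid]
        el = etree.SubElement(root, "node", id=ids[tid], label=node.label)
        att(el, "term_id", tid, "string")
        att(el, "level", "" if node.level is None else str(node.level), "string")
        att(el, "node_type", node.node_type, "string")
        att(el, "connector_only",
            "true" if node.connector_only else "false", "boolean")
        att(el, "area", _fmt(node.area), "real")
        att(el, "label_size", _fmt(node.label_size), "real")
        if tid in box_of:
            att(el, "level_box", str(box_of[tid]), "integer")
        for name, values, typ in (
            ("slice_datasets", [s.dataset_name for s in node.slices], "string"),
            ("slice_values", [_fmt(s.value) for s in node.slices], "real"),
            ("slice_colors", [s.color for s in node.slices], "string"),
        ):
            lst = etree.SubElement(el, "att", name=name, type="list")
            for v in values:
                etree.SubElement(lst, "att", name=name, value=v, type=typ)
        fill = node.slices[0].color if node.slices else "#FFFFFF"
        etree.SubElement(
            el, "graphics", type="ELLIPSE",
            h=_fmt(node.diameter), w=_fmt(node.diameter), fill=fill,
        )

    for j, e in enumerate(_sorted_edges(net)):
        el = etree.SubElement(
            root, "edge", id=f"e{j}",
            label=f"{e.source} ({e.kind}) {e.target}",
            source=ids[e.source], target=ids[e.target],
        )
        att(el, "kind", e.kind, "string")
        att(el, "weight", _fmt(e.weight), "real")

    path.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                       pretty_print=True)
    )
    return path


def read_xgmml(path: str | Path) -> PathwayNetwork:
    """Parse a network previously written by :func:`write_xgmml`."""
    root = etree.parse(str(path)).getroot()
    net = PathwayNetwork(name=root.get("label"))
    id_to_term: dict[str, str] = {}
    for el in root.findall("node"):
        atts = {a.get("name"): a for a in el.findall("att")}
        tid = atts["term_id"].get("value")
        id_to_term[el.get("id")] = tid
        node = PieNode(
            term_id=tid,
            label=el.get("label"),
            level=int(atts["level"].get("value")) if atts["level"].get("value") else None,
            node_type=atts["node_type"].get("value"),
            connector_only=atts["connector_only"].get("value") == "true",
            area=float(atts["area"].get("value")),
            label_size=float(atts["label_size"].get("value")),
        )
        graphics = el.find("graphics")
        node.diameter = (float(graphics.get("h")) if graphics is not None
                         else math.sqrt(4.0 * node.area / math.pi))
        names = [a.get("value") for a in atts["slice_datasets"].findall("att")]
        values = [float(a.get("value")) for a in atts["slice_values"].findall("att")]
        colors = [a.get("value") for a in atts["slice_colors"].findall("att")]
        for nm, v, col in zip(names, values, colors):
            node.slices.append(PieSlice(dataset_name=nm, value=v, color=col))
        total = sum(s.value for s in node.slices)
        for s in node.slices:
            s.angle = (360.0 * s.value / total if total > 0
                       else 360.0 / len(node.slices))
        if "level_box" in atts:
            net.level_boxes.setdefault(
                int(atts["level_box"].get("value")), []
            ).append(tid)
        net.nodes[tid] = node
    for el in root.findall("edge"):
        atts = {a.get("name"): a.get("value") for a in el.findall("att")}
        net.edges.append(NetworkEdge(
            source=id_to_term[el.get("source")],
            target=id_to_term[el.get("target")],
            kind=atts.get("kind", "hierarchical"),
            weight=float(atts.get("weight", 1.0)),
        ))
    return net


# ---------------------------------------------------------------------------
# SVG pie rendering & charts
# ---------------------------------------------------------------------------


def render_network_svg(net: PathwayNetwork, path: str | Path) -> Path:
    """Draw the network's pies (true slice angles) on a simple grid layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nodes = sorted(net.nodes.values(), key=lambda n: n.term_id)
    n = max(len(nodes), 1)
    cols = math.ceil(math.sqrt(n))
    fig, ax = plt.subplots(figsize=(2.2 * cols, 2.2 * math.ceil(n / cols)))
    ax.set_aspect("equal")
    ax.axis("off")
    pos = {}
    for i, node in enumerate(nodes):
        x, y = (i % cols) * 3.0, -(i // cols) * 3.0
        pos[node.term_id] = (x, y)
        r = max(node.diameter / 2.0, 1.0) / 30.0
        start = 90.0
        if node.slices:
            for s in node.slices:
                wedge = matplotlib.patches.Wedge(
                    (x, y), r, start - s.angle, start,
                    facecolor=s.color, edgecolor="black", linewidth=0.4,
                )
                ax.add_patch(wedge)
                start -= s.angle
        else:
            ax.add_patch(matplotlib.patches.Circle(
                (x, y), r * 0.5, facecolor="#DDDDDD", edgecolor="black",
                linewidth=0.4,
            ))
        ax.annotate(node.label, (x, y - r - 0.25), ha="center",
                    fontsize=max(node.label_size / 2.5, 4))
    for e in net.edges:
        if e.source in pos and e.target in pos:
            (x1, y1), (x2, y2) = pos[e.source], pos[e.target]
            style = {"hierarchical": "-", "functional": "--",
                     "regulatory": ":", "gene_membership": "-."}[e.kind]
            ax.plot([x1, x2], [y1, y2], style, color="gray",
                    linewidth=0.6, zorder=0)
    ax.autoscale_view()
    path = Path(path)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path


def render_charts(
    results: Sequence[EnrichmentResult],
    datasets: Sequence,
    kinds: Iterable[str],
    out_dir: str | Path,
    prefix: str = "charts",
) -> list[Path]:
    """Render bar / heatmap / timeline SVG charts of filtered results.

    Bars show -log10 p per term and dataset; the heatmap is the
    terms x datasets matrix of -log10 p with blanks where a term was not
    predicted; timelines trace each term's -log10 p across the datasets'
    timepoint order.  Datasets are ordered by their order index throughout.
    A timeline request is skipped with a warning when no dataset carries a
    timepoint.
    """
    import logging

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    logger = logging.getLogger(__name__)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meta = {d.name: d for d in datasets}
    ds_names = sorted(
        {r.dataset_name for r in results},
        key=lambda n: (meta[n].order_index if n in meta else 0, n),
    )
    terms = sorted({";".join(r.term_ids) for r in results})
    score = {(";".join(r.term_ids), r.dataset_name): r.minus_log10_p for r in results}

    written: list[Path] = []
    if not results:
        return written

    if "bar" in kinds:
        fig, ax = plt.subplots(
            figsize=(6, 0.4 * max(len(terms) * max(len(ds_names), 1), 4))
        )
        ypos, labels = [], []
        y = 0
        for term in terms:
            for ds in ds_names:
                v = score.get((term, ds))
                if v is not None:
                    color = meta[ds].color if ds in meta else "#1F77B4"
                    ax.barh(y, v, color=color)
                    ypos.append(y)
                    labels.append(f"{term} | {ds}")
                    y += 1
            y += 1
        ax.set_yticks(ypos, labels, fontsize=6)
        ax.invert_yaxis()
        ax.set_xlabel("-log10 p")
        p = out_dir / f"{prefix}_bar.svg"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    if "heatmap" in kinds:
        mat = np.full((len(terms), len(ds_names)), np.nan)
        for i, term in enumerate(terms):
            for j, ds in enumerate(ds_names):
                if (term, ds) in score:
                    mat[i, j] = score[(term, ds)]
        fig, ax = plt.subplots(
            figsize=(1 + 0.6 * len(ds_names), 1 + 0.3 * len(terms))
        )
        masked = np.ma.masked_invalid(mat)
        im = ax.pcolormesh(masked, cmap="viridis")
        ax.set_xticks(np.arange(len(ds_names)) + 0.5, ds_names,
                      rotation=90, fontsize=6)
        ax.set_yticks(np.arange(len(terms)) + 0.5, terms, fontsize=6)
        fig.colorbar(im, ax=ax, label="-log10 p")
        p = out_dir / f"{prefix}_heatmap.svg"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    if "timeline" in kinds:
        with_tp = [n for n in ds_names
                   if n in meta and meta[n].timepoint is not None]
        if not with_tp:
            logger.warning("timeline requested but no dataset has a timepoint; skipped")
        else:
            fig, ax = plt.subplots(figsize=(6, 4))
            for term in terms:
                xs, ys = [], []
                for ds in with_tp:
                    if (term, ds) in score:
                        xs.append(meta[ds].timepoint)
                        ys.append(score[(term, ds)])
                if xs:
                    ax.plot(xs, ys, marker="o", label=term)
            ax.set_ylabel("-log10 p")
            ax.set_xlabel("timepoint")
            ax.legend(fontsize=5)
            p = out_dir / f"{prefix}_timeline.svg"
            fig.savefig(p, bbox_inches="tight")
            plt.close(fig)
            written.append(p)

    return written


def network_filename(
    ontology_name: str,
    species: str,
    dataset_or_group: str,
    direction: str | None,
    analysis_type: str,
    dialect: str,
) -> str:
    """Compose the conventional network file name.

    Pattern: ``<ontology>_<species>_<name>[-<Direction>]_<analysis>.<ext>``
    with extension ``.graphml`` (yEd) or ``.xgmml`` (Cytoscape).
    """
    ext = {"yed": "graphml", "graphml": "graphml",
           "cytoscape": "xgmml", "xgmml": "xgmml"}[dialect]
    stem = f"{ontology_name}_{species}_{dataset_or_group}"
    if direction:
        stem += f"-{direction.capitalize()}"
    stem += f"_{analysis_type}"
    safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in stem)
    return f"{safe}.{ext}"


EDITOR_README = """How to view the exported networks
=================================

GraphML files (.graphml) open directly in the yEd graph editor. After
opening, choose Layout > Tree > Directed and activate 'Consider Node
Labels'; hierarchical edges point from parent to child pathway. Node sizes
and label sizes are precomputed; pie slice data (dataset, value, color) is
stored in the node attributes slice_datasets / slice_values / slice_colors.

XGMML files (.xgmml) import into Cytoscape via File > Import > Network from
File. Bind a pie-chart style to the list attributes slice_values and
slice_colors to reproduce the per-dataset pies; node sizes are carried in
the 'area' attribute.

Edge types are stored in the 'kind' attribute: hierarchical (parent->child),
functional (weighted interaction), regulatory, gene_membership.
"""


def write_editor_readme(out_dir: str | Path) -> Path:
    p = Path(out_dir) / "README_graph_editors.txt"
    p.write_text(EDITOR_README, encoding="utf-8")
    return p
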