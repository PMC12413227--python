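"""Merge two datasets of one integration group into a pie-chart network.

Each pathway predicted by at least one dataset becomes a pie node (one slice
per predicting dataset, slice value = -log10 p), connected through the
ontology hierarchy and the top 25% of functional interactions, then exported
to GraphML (yEd), XGMML (Cytoscape) and an SVG preview.
"""

from pathlib import Path

from scpnet import (
    LevelCutoffs,
    ScalingOptions,
    build_group_network,
    compute_node_geometry,
    enrich_standard,
    propagate_annotations,
    rank_and_filter,
)
from scpnet.export_render import render_network_svg, write_graphml, write_xgmml
from scpnet.fixtures import make_planted_dataset, make_toy_ontology

ontology, interactions = make_toy_ontology(seed=11)
ontology = propagate_annotations(ontology)

ds1 = make_planted_dataset(ontology, "SCP_1.1.1", seed=21, name="ds1")
ds2 = make_planted_dataset(ontology, "SCP_1.2.1", seed=22, name="ds2")
ds2.color, ds2.order_index = "#FF7F0E", 2

cutoffs = LevelCutoffs(max_p=0.01, max_rank=3)
results = {d.name: rank_and_filter(enrich_standard(d, ontology), cutoffs)
           for d in (ds1, ds2)}

network = build_group_network(
    results, [ds1, ds2], ontology, interactions,
    ScalingOptions(mode="sum_neg_log10_p", ancestor_mode="intermediate_only",
                   functional_fraction=25.0),
)
compute_node_geometry(network, ScalingOptions())

out = Path("scratch/example_networks")
out.mkdir(parents=True, exist_ok=True)
write_graphml(network, out / "group.graphml")
write_xgmml(network, out / "group.xgmml")
render_network_svg(network, out / "group.svg")

print(f"nodes: {len(network.nodes)}  edges: {len(network.edges)}")
for tid, node in sorted(network.nodes.items()):
    slices = ", ".join(f"{s.dataset_name}:{s.value:.1f}" for s in node.slices)
    tag = "connector" if node.connector_only else f"slices [{slices}]"
    print(f"  {tid:<12s} area {node.area:7.1f}  label {node.label_size:5.2f}pt  {tag}")
# Node areas are proportional to the summed -log10 p across datasets; the
# root collects both datasets' signal, so it shows two slices.
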