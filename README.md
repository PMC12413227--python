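# scpnet

Multi-dataset pathway over-representation analysis and pie-chart pathway
networks over leveled ontologies.

High-throughput experiments routinely produce not one but dozens of gene or
protein lists — cell lines × drugs, time points, up/down directions, single-cell
subtypes.  Interpreting them one enrichment table at a time hides what the
conditions share and where they diverge.  `scpnet` is for researchers who want
to run over-representation analysis (ORA) on many such lists at once and see
the integrated outcome as a single network: every predicted pathway is a pie
chart whose slices are the datasets that predicted it, connected through the
ontology's parent–child hierarchy and through weighted functional
pathway–pathway interactions.

## The statistics

**Standard enrichment** is the right-tailed Fisher's exact test.  For a
dataset with *n* analyzed genes inside a background of *N* genes, and a
pathway with *K* annotated genes in that background, the probability of
seeing an overlap of at least *k* genes under random draws is the
hypergeometric tail

p = Σᵢ₌ₖ^min(n,K) C(K,i) · C(N−K, n−i) / C(N,n),

computed in log space for numerical stability.  Annotations are first
propagated up the ontology DAG (each term absorbs its descendants' genes via
`is_a`/`part_of`/annotated parent–child relations), and candidate terms can
be size-filtered (min/max annotated genes).  Significance is controlled per
ontology level by two cutoffs — maximum p value and maximum competition rank —
and a pathway must meet both.

**Dynamic enrichment** additionally uses a weighted pathway–pathway
interaction network.  For each dataset it merges functionally related terms
that each contain at least one analyzed gene into dataset-selective
combinations (connected sets of 2–3 terms within the top-x% of interactions),
adds them to the candidate universe, and tests the gene union of each
combination with the same Fisher test.  A combination's −log₁₀ p is split
equally among its member terms (and summed per term) when drawing pies.

**Networks.**  Datasets belong to integration groups; each group's filtered
results are merged into one network.  Unpredicted ancestor terms are inserted
either as minimal connectors (terms on a directed hierarchy path between two
predictions) or as the full ancestor closure.  Pie and slice areas are
proportional to summed and individual −log₁₀ p (or dataset counts, color
counts, or uniform), label sizes scale linearly with node area, and networks
are written as GraphML (yEd) or XGMML (Cytoscape) plus an SVG preview.

## Worked example

`examples/02_dynamic_enrichment.py` builds two level-3 pathways A and B of
10 genes each, a dataset covering 5 genes of each, a background of 1000, and
one A–B functional interaction:

```
dataset-selective combinations: [['A', 'B']]
A+B      rank 1  p=7.01e-19  -log10 p=18.15
A        rank 2  p=7.54e-09  -log10 p=8.12
B        rank 2  p=7.54e-09  -log10 p=8.12
per-term split scores (pie slice values): {'A': 17.2, 'B': 17.2}
```

Individually, 5 hits out of 10 pathway genes gives p ≈ 7.5×10⁻⁹; testing the
combination — all 10 dataset genes inside the 20-gene union — gives
p ≈ 7×10⁻¹⁹ and rank 1.  That is the point of dynamic enrichment: coordinated
partial activation of interacting pathways is detected even when no single
pathway dominates.  The combined score then splits equally back onto A and B
(18.15/2 plus their own singleton contributions ≈ 17.2 each) for pie drawing.

The other examples show standard ORA on a planted dataset
(`01_standard_enrichment.py`), group-network construction and export
(`03_group_network_export.py`), and a full headless batch run
(`04_headless_batch.py`).

## Command line

For pipeline use, a complete analysis cycle — read every data file and
`*_bgGenes` background list in a directory, apply the parameter-settings
file, run standard + dynamic enrichment, write tables, charts, networks and
a reproducible `Input_data` snapshot — runs headlessly:

```bash
scpnet --input-dir my_data/ --results-dir results/ --max-p 0.01 --editor yed
```

On success, `Analysis finished.txt` sentinel files appear in every results
subdirectory (for wrapping pipelines to poll); any error exits nonzero with
an `Error_report.txt` and no sentinels.  Rerunning on a produced
`Results/<group>/Input_data` directory reproduces the results tables
byte-identically.

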