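# Methods

## Model and procedure

`scpnet` implements over-representation analysis (ORA) of gene/protein lists
against a hierarchically organized ontology, in two variants, and merges the
per-dataset results of an *integration group* into one pathway network.

**Contingency model.**  Each (dataset, pathway) pair is a 2×2 table drawn
without replacement from a shared background universe of N genes: n analyzed
dataset genes, K pathway genes, overlap k.  The reported p value is the exact
hypergeometric right tail P(X ≥ k).  It is computed as a log-space sum of
log-binomial terms (log-gamma plus log-sum-exp), which is stable down to
p ≈ 10⁻³⁰⁰ and agrees with an exact big-integer evaluation to better than
1e−12 relative error (verified in the test suite for all N ≤ 60).  k = 0
returns exactly 1.  Both the dataset genes and the pathway genes are
intersected with the background before counting, so the universe always
contains the draw; dataset genes missing from an explicit background are
dropped with a warning.  When a dataset has no explicit background, the
fallback is the set of all genes annotated anywhere in the loaded (propagated,
size-filtered) ontology — the standard ORA default; explicit experimental
backgrounds (all genes tested for significance) are more accurate and are
supported through the `*_bgGenes` file convention.

**Annotation propagation.**  Hierarchy relations (`is_a`, `part_of`, and the
annotated parent–child relation of flat ontology tables) form a DAG; each
term's effective annotation is the union of its own and all hierarchical
descendants' genes, computed in one reverse-topological pass (provably the
fixed point of repeated passes; idempotent).  `regulates`-family relations
are retained as a separate edge class that never carries propagation.

**Size filtering.**  Candidate terms outside a [min_genes, max_genes] band
(applied to propagated gene counts) are removed; their hierarchical parents
are transitively reconnected to their children so reachability among
survivors is preserved.  This matters for connector insertion: predicted
terms are linked through ancestors that themselves satisfy the size band.

**Ranking and cutoffs.**  Within each (dataset, level) stratum, results are
sorted by ascending p (ties broken by larger overlap, then term id) and given
competition ranks — equal p values share the lowest rank of their block, a
deterministic convention chosen because upstream ordering of tied p values is
arbitrary.  A result is significant iff p ≤ max_p and rank ≤ max_rank for its
level; max_rank = 0 disables a level entirely (useful for restricting figure
legends to one level).  No multiple-testing correction enters this filtering
path; Benjamini–Hochberg q values over each dataset's full candidate set are
attached as an informational column only.

**Dynamic enrichment.**  Given a weighted term–term interaction network
scoped to an ontology level, the top x% of interactions (ceil of the edge
count; edges tied with the cutoff weight all included, making the selection
order-independent) define a functional graph.  For one dataset, all connected
induced subsets of 2..max_arity terms whose members *each* contain at least
one analyzed gene become combinations; a combination is tested like a term
with K = |union of member genes ∩ background|.  Candidates are the ontology's
terms plus these combinations, ranked jointly per level under separate
dynamic cutoffs.  Enumeration uses ESU-style connected-subgraph expansion and
is cross-checked in the tests against brute-force enumeration.  Default
max_arity is 3: pairs and connected triples capture coordinated partial
activation while keeping the candidate set near-linear in practice; higher
arities grow combinatorially and dilute the per-member signal split.
Whether "contains at least one analyzed gene" binds each member or only the
union is genuinely ambiguous; the strict per-member reading is the default
and the union reading is available via `require_gene_in_each_member=False`.

**Score splitting.**  For pie geometry, each dynamic result's −log₁₀ p is
split equally among its member terms and summed per term across results; the
total over terms equals the total over results exactly (conservation is a
tested invariant).

**Network assembly.**  One pie node per term predicted by ≥ 1 dataset of the
group, slices ordered by dataset order index.  Connector insertion:
`intermediate_only` inserts exactly the unpredicted terms lying on a directed
hierarchy path between two predicted terms (forward-reachability ∩
backward-reachability), `all_ancestors` inserts the full ancestor closure;
the former is always a subset of the latter.  Functional edges connect
predicted (never connector) same-level nodes from the top-x% interaction
graph; regulatory edges and per-term gene child nodes are optional.  Gene
children are deduplicated (one node per gene, one membership edge per owning
term).

## Geometry and scaling

Node **area** (not diameter) encodes the selected statistic; diameter =
√(4·area/π).  Modes: summed −log₁₀ p (slice angles proportional to slice
values), dataset count, same-color count, or uniform (equal angles in the
last three).  The largest score in scope gets `max_area` (default 1800 pt²,
a comfortable yEd node size); a visibility floor of 5% of max_area (default,
configurable) keeps barely significant and connector nodes legible.  Label
sizes interpolate linearly from the node-area range onto a [min_pt, max_pt]
range (default 10–24 pt), collapsing to the minimum when either range is
degenerate.  Scope `per_network` normalizes within one network;
`global` accepts a shared normalization constant so all networks of a batch
are comparable.

## File formats and conventions

* Flat ontology: tab-delimited `parent/child[/relation][/level]` plus a
  `term/gene` annotation table.  The level column states the child's level;
  roots receive min(child level) − 1 (floor 1).  OBO (1.2/1.4) via obonet
  plus the same two-column annotation table; obsolete terms are skipped,
  `is_a`/`part_of` are hierarchical, `regulates` variants non-hierarchical.
* Interactions: `term_a/term_b/weight[/level]`, weights strictly positive,
  edges undirected with canonical endpoint order.
* Datasets: tab-delimited with a header; the column mapping defaults to
  `gene/value/dataset/group/color/timepoint/direction/order` (only the gene
  column is required to exist when explicitly mapped; unset fields are
  ignored).  Symbols are uppercased everywhere.  `X_bgGenes.txt` is a
  headerless single-column background attached to every dataset read from
  `X.txt`.  Duplicate gene rows keep the smallest (most significant) value,
  matching the p-value-like default use of the value column.
* Ortholog translation is table-driven (`source/target`, one-to-many
  allowed); unmapped symbols are dropped and counted.
* Parameter settings: flat `key<TAB>value`, one per line; per-level cutoff
  keys look like `max_p_level3` / `dynamic_max_rank_level2`.  Unknown keys
  and malformed lines are rejected by name/line.  Precedence: CLI overrides >
  parameter file > defaults.
* Results layout: `results/<group>/{standard,dynamic}_results.txt`,
  `SCP_networks/` (GraphML or XGMML + SVG preview + an editor how-to),
  `Charts/`, `Input_data/` (the snapshot), with `Analysis finished.txt`
  sentinels written into each directory only on full success.
* The `Input_data` snapshot contains the analyzed gene lists, re-suffixed
  background files, the copied ontology inputs and a parameter file pointing
  at them, so a rerun on that directory alone reproduces the results tables
  byte-identically (row order preserved; all floats serialized at full
  precision).
* GraphML carries yFiles shape graphics plus per-slice data keys; XGMML
  carries list-typed slice attributes bindable to Cytoscape pie styles and a
  `level_box` attribute (XGMML has no portable nested-graph idiom, unlike
  GraphML where level boxes are true nested graphs).  Writers emit nodes and
  edges in sorted order with numbers at 12 significant digits, so
  write→parse→write is byte-stable; neither dialect standardizes pie glyphs,
  hence the auxiliary SVG renderer for faithful visual inspection.

## Synthetic study systems

The `fixtures` module generates the systems used by tests, examples and the
acceptance script: a balanced leveled ontology (default 3 levels, branching
3, 20 genes per leaf, 10% sibling gene overlap — small enough to inspect,
large enough that parent/child and sibling effects appear), an interaction
network in which sibling leaves carry high weights (5–10) and random
non-sibling pairs low weights (0.1–2), and planted datasets holding 80% of a
target term's genes plus 10 uniform noise genes over a background padded to
10× the annotated universe.  These defaults emulate a clearly but not
perfectly detected pathway signal.  What they do **not** emulate: realistic
GO topology (fan-in, depth variance), correlated noise, annotation bias, or
measured effect sizes — so passing tests demonstrate correctness of the
statistics and plumbing, not calibrated performance on real transcriptomes.
All generated files round-trip through the package's own loaders.

## Numerical and degenerate-input choices

* Fisher tail in log space; p clamped to ≤ 1 against rounding.
* Empty analyzable gene list → empty result with a warning, never an error.
* Empty integration group → valid empty network; empty ontology → valid
  export with zero nodes.
* Zero total slice value → equal slice angles.
* All-equal node areas or a collapsed label range → fixed (minimum) label
  size.
* `top_interactions` of an empty network is empty; fraction must be in
  (0, 100].

## Known limitations

* No GSEA-style ranked statistics or permutation nulls — the filtering model
  is raw p + rank by design.
* No graph layout: node positions are left to yEd/Cytoscape.
* Interaction weights are treated as opaque inputs; the package does not
  infer them.
* Ortholog mapping is strictly table-driven; no live database retrieval.
* GO annotation evidence codes are not modeled (two-column annotations only).
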