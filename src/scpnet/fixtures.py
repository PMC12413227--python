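"""Synthetic ontologies, interaction networks and planted-signal datasets.

The generators build small but fully structured study systems: a balanced
leveled ontology whose leaves carry gene annotations with controllable
pairwise overlap, a weighted term-term interaction network in which siblings
are strongly functionally related, and datasets that contain a known fraction
of one target term's genes plus uniform background noise.  Everything is
deterministic per seed and writable in exactly the flat-file formats the
loaders consume, so the whole pipeline is testable without any downloads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datasets_io import BG_SUFFIX, COLOR_PALETTE, Dataset
from .ontology import InteractionNetwork, Ontology, Term


def make_toy_ontology(
    levels: int = 3,
    branching: int = 3,
    genes_per_leaf: int = 20,
    gene_overlap: float = 0.1,
    seed: int = 0,
) -> tuple[Ontology, InteractionNetwork]:
    """Build a balanced leveled ontology plus a leaf-level interaction network.

    The hierarchy is a perfect ``branching``-ary tree of depth ``levels``
    (one root at level 1).  Each leaf draws ``genes_per_leaf`` genes;
    a ``gene_overlap`` fraction of a leaf's genes is shared with the previous
    sibling, the rest are leaf-private.  Interaction weights are sampled so
    sibling leaves score higher than unrelated leaves, emulating inferred
    functional relationships.  Deterministic per seed.
    """
    if not 2 <= levels <= 4:
        raise ValueError("levels must be in 2..4")
    if not 0 <= gene_overlap < 1:
        raise ValueError("gene_overlap must be in [0, 1)")
    rng = np.random.default_rng(seed)

    terms: dict[str, Term] = {}
    edges: set[tuple[str, str, str]] = set()
    by_level: dict[int, list[str]] = {}

    def add(tid: str, level: int) -> None:
        terms[tid] = Term(id=tid, name=tid.replace("_", " "), level=level)
        by_level.setdefault(level, []).append(tid)

    add("SCP_1", 1)
    previous = ["SCP_1"]
    for level in range(2, levels + 1):
        current = []
        for parent in previous:
            for b in range(1, branching + 1):
                tid = f"{parent}.{b}"
                add(tid, level)
                edges.add((parent, tid, "annotated_hierarchy"))
                current.append(tid)
        previous = current

    leaves = by_level[levels]
    gene_counter = 0
    prev_genes: list[str] = []
    parent_of = {c: p for p, c, _ in edges}
    for leaf in leaves:
        n_shared = int(round(gene_overlap * genes_per_leaf))
        shared: list[str] = []
        if prev_genes and parent_of.get(leaf) == parent_of.get(prev_leaf):
            take = min(n_shared, len(prev_genes))
            shared = list(rng.choice(prev_genes, size=take, replace=False))
        fresh = [f"G{gene_counter + i:05d}"
                 for i in range(genes_per_leaf - len(shared))]
        gene_counter += len(fresh)
        terms[leaf].genes = set(shared) | set(fresh)
        prev_genes = sorted(terms[leaf].genes)
        prev_leaf = leaf

    # sibling leaves interact strongly, random leaf pairs weakly
    inter: list[tuple[str, str, float]] = []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            if parent_of.get(a) == parent_of.get(b):
                inter.append((a, b, float(rng.uniform(5.0, 10.0))))
            elif rng.random() < 0.3:
                inter.append((a, b, float(rng.uniform(0.1, 2.0))))
    net = InteractionNetwork.from_edges(inter, level=levels)

    o = Ontology(terms=terms, edges=edges, name="toy")
    return o, net


def make_planted_dataset(
    o: Ontology,
    target_term: str,
    signal_fraction: float = 0.8,
    n_noise: int = 10,
    background_size: int | None = None,
    seed: int = 0,
    name: str | None = None,
) -> Dataset:
    """A dataset carrying a planted signal for one ontology term.

    The gene list holds ``signal_fraction`` of the target term's genes plus
    ``n_noise`` genes drawn uniformly from the background; the background is
    the annotated universe padded with unannotated genes up to
    ``background_size`` (default ten times the annotated universe).
    """
    if not 0 < signal_fraction <= 1:
        raise ValueError("signal_fraction must be in (0, 1]")
    if target_term not in o.terms:
        raise ValueError(f"unknown target term {target_term!r}")
    rng = np.random.default_rng(seed)
    annotated = sorted(o.annotated_genes())
    if background_size is None:
        background_size = 10 * len(annotated)
    if background_size < len(annotated):
        raise ValueError("background_size must cover the annotated universe")
    extra = [f"BG{j:06d}" for j in range(background_size - len(annotated))]
    background = set(annotated) | set(extra)

    target_genes = sorted(o.terms[target_term].genes)
    n_signal = max(1, int(round(signal_fraction * len(target_genes))))
    signal = list(rng.choice(target_genes, size=n_signal, replace=False))
    pool = sorted(background - set(signal))
    noise = list(rng.choice(pool, size=min(n_noise, len(pool)), replace=False))

    genes = signal + noise
    return Dataset(
        name=name or f"planted_{target_term}",
        genes=genes,
        background=background,
    )


# ---------------------------------------------------------------------------
# file fixtures
# ---------------------------------------------------------------------------


def write_ontology_files(
    o: Ontology, net: InteractionNetwork | None, out_dir: str | Path
) -> dict[str, Path]:
    """Write an ontology (and optional interactions) in the flat dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    lines = ["parent\tchild\trelation\tlevel"]
    for parent, child, rel in sorted(o.edges):
        level = o.terms[child].level
        lines.append(f"{parent}\t{child}\t{rel}\t{'' if level is None else level}")
    paths["hierarchy"] = out_dir / "ontology_hierarchy.txt"
    paths["hierarchy"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["term\tgene"]
    for tid in sorted(o.terms):
        for g in sorted(o.terms[tid].genes):
            lines.append(f"{tid}\t{g}")
    paths["annotations"] = out_dir / "ontology_annotations.txt"
    paths["annotations"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    if net is not None:
        lines = ["term_a\tterm_b\tweight\tlevel"]
        for a, b, w in sorted(net.edges):
            lines.append(f"{a}\t{b}\t{w!r}\t{'' if net.level is None else net.level}")
        paths["interactions"] = out_dir / "ontology_interactions.txt"
        paths["interactions"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def write_dataset_files(
    datasets: list[Dataset], out_dir: str | Path
) -> list[Path]:
    """Write datasets (and their backgrounds) as loader-compatible flat files."""
    from .datasets_io import _safe_filename  # shared naming rule

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for d in datasets:
        stem = _safe_filename(d.name)
        lines = ["gene\tvalue\tdataset\tgroup\tcolor\ttimepoint\tdirection\torder"]
        for g in d.genes:
            value = "" if d.values is None or g not in d.values else repr(d.values[g])
            lines.append(
                f"{g}\t{value}\t{d.name}\t{d.integration_group}\t{d.color}"
                f"\t{d.timepoint or ''}\t{d.direction or ''}\t{d.order_index}"
            )
        p = out_dir / f"{stem}.txt"
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(p)
        if d.background is not None:
            bp = out_dir / f"{stem}{BG_SUFFIX}.txt"
            bp.write_text("\n".join(sorted(d.background)) + "\n", encoding="utf-8")
            written.append(bp)
    return written


def make_batch_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_datasets: int = 2,
    signal_fraction: float = 0.8,
    n_noise: int = 10,
) -> dict[str, Path]:
    """Write a complete, self-consistent input directory for a batch run.

    Produces the flat ontology, its interaction network and ``n_datasets``
    planted datasets (all targeting sibling leaf terms so they fall in one
    integration group), ready for :func:`scpnet.cli_config.run_batch`.
    """
    out_dir = Path(out_dir)
    o, net = make_toy_ontology(seed=seed)
    paths = write_ontology_files(o, net, out_dir)
    leaves = sorted(t.id for t in o.terms.values() if t.level == max(o.levels()))
    datasets = []
    for i in range(n_datasets):
        d = make_planted_dataset(
            o, leaves[i], signal_fraction=signal_fraction, n_noise=n_noise,
            seed=seed + i + 1, name=f"replicate{i + 1}",
        )
        d.integration_group = "toy_group"
        d.color = COLOR_PALETTE[i % len(COLOR_PALETTE)]
        d.order_index = i + 1
        datasets.append(d)
    for p in write_dataset_files(datasets, out_dir):
        paths[p.stem] = p
    return paths
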