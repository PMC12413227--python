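"""Standard and dynamic pathway over-representation analysis.

Standard analysis tests each ontology term with the right-tailed Fisher's
exact test: the probability of drawing at least the observed overlap between
the analyzed gene list and the term's annotated genes, with both treated as
random draws from a shared background.  With a leveled ontology and a
weighted term-term interaction network, dynamic analysis augments the
candidate set with dataset-selective combinations — connected sets of
functionally interacting terms that each contain at least one analyzed gene —
whose gene unions are tested like ordinary terms.  Significance is controlled
per level by a maximum p value and a maximum competition rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .datasets_io import Dataset
from .ontology import InteractionNetwork, Ontology

logger = logging.getLogger(__name__)

STANDARD = "standard"
DYNAMIC = "dynamic"


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts of the 2x2 over-representation table.

    ``k`` dataset genes annotated to the term, out of ``n`` analyzed dataset
    genes, ``K`` term genes within the background, and ``N`` background genes.
    """

    k: int
    n: int
    K: int
    N: int

    def validate(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid overlap: k={self.k}, n={self.n}, K={self.K}")
        if not (0 <= self.n <= self.N and 0 <= self.K <= self.N):
            raise ValueError(
                f"counts exceed background: n={self.n}, K={self.K}, N={self.N}"
            )


def fisher_right_tail(c: ContingencyCounts) -> float:
    """Right-tailed Fisher's exact test p value.

    Computes ``P(X >= k)`` for hypergeometric ``X`` by summing
    ``C(K,i) C(N-K,n-i) / C(N,n)`` for ``i = k .. min(n,K)`` in log space
    (log-gamma binomials combined with log-sum-exp) for numerical stability.
    ``k = 0`` gives exactly 1.
    """
    c.validate()
    if c.k == 0:
        return 1.0
    i = np.arange(c.k, min(c.n, c.K) + 1)
    log_terms = (
        _log_binom(c.K, i)
        + _log_binom(c.N - c.K, c.n - i)
        - _log_binom(c.N, c.n)
    )
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def _log_binom(n: int | np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class EnrichmentResult:
    """One tested candidate (term or term combination) for one dataset."""

    term_ids: tuple[str, ...]
    term_names: tuple[str, ...]
    dataset_name: str
    p_value: float
    minus_log10_p: float
    level: int | None
    rank: int
    overlap_genes: frozenset[str]
    analysis_type: str = STANDARD
    q_value: float | None = None  # BH-adjusted, informational only

    @property
    def is_combination(self) -> bool:
        return len(self.term_ids) > 1

    def key(self) -> tuple:
        return (self.dataset_name, self.analysis_type, self.level, self.term_ids)


@dataclass(frozen=True)
class LevelCutoffs:
    """Per-level maximum p value and maximum rank (0 disables a level).

    ``by_level`` overrides the global defaults for individual levels; a
    result is kept only if it meets both cutoffs within its (dataset, level)
    stratum.
    """

    max_p: float = 0.05
    max_rank: int = 5
    by_level: Mapping[int, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, _ in list(self.by_level.values()) + [(self.max_p, self.max_rank)]:
            if not 0 < p <= 1:
                raise ValueError(f"max_p must be in (0, 1], got {p}")

    def for_level(self, level: int | None) -> tuple[float, int]:
        if level is not None and level in self.by_level:
            return self.by_level[level]
        return (self.max_p, self.max_rank)


@dataclass(frozen=True)
class Combination:
    """A connected set of same-level interacting terms tested as one unit."""

    member_term_ids: frozenset[str]
    union_genes: frozenset[str]
    level: int | None = None


# ---------------------------------------------------------------------------
# standard analysis
# ---------------------------------------------------------------------------


def resolve_background(d: Dataset, o: Ontology) -> set[str]:
    """The dataset's own background, else all genes annotated in the ontology."""
    if d.background:
        return set(d.background)
    return o.annotated_genes()


def _bh_adjust(results: list[EnrichmentResult]) -> None:
    if not results:
        return
    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_value for r in results]
    q = multipletests(pvals, method="fdr_bh")[1]
    for r, qv in zip(results, q):
        r.q_value = float(qv)


def _make_result(
    dataset: Dataset,
    term_ids: tuple[str, ...],
    term_names: tuple[str, ...],
    level: int | None,
    candidate_genes: set[str],
    analyzed: set[str],
    N: int,
    analysis_type: str,
) -> EnrichmentResult | None:
    overlap = candidate_genes & analyzed
    k = len(overlap)
    if k == 0 or not candidate_genes:
        return None
    p = fisher_right_tail(
        ContingencyCounts(k=k, n=len(analyzed), K=len(candidate_genes), N=N)
    )
    return EnrichmentResult(
        term_ids=term_ids,
        term_names=term_names,
        dataset_name=dataset.name,
        p_value=p,
        minus_log10_p=-math.log10(p),
        level=level,
        rank=0,
        overlap_genes=frozenset(overlap),
        analysis_type=analysis_type,
    )


def enrich_standard(
    d: Dataset, o: Ontology, background: set[str] | None = None
) -> list[EnrichmentResult]:
    """Test every ontology term against one dataset (unfiltered results).

    The ontology must be propagated (and, for GO-style use, size-filtered).
    Dataset genes and term genes are intersected with the background before
    counting; terms with zero overlap are omitted.  A BH-adjusted q value is
    attached as an informational column.
    """
    if not o.propagated:
        raise ValueError("ontology must be propagated before enrichment")
    bg = background if background is not None else resolve_background(d, o)
    analyzed = d.gene_set & bg
    if len(analyzed) < len(d.genes):
        logger.warning(
            "dataset %s: %d genes outside the background ignored",
            d.name, len(d.genes) - len(analyzed),
        )
    if not analyzed:
        logger.warning("dataset %s has no analyzable genes", d.name)
        return []
    N = len(bg)
    results: list[EnrichmentResult] = []
    for tid in sorted(o.terms):
        t = o.terms[tid]
        r = _make_result(
            d, (tid,), (t.name,), t.level, t.genes & bg, analyzed, N, STANDARD
        )
        if r is not None:
            results.append(r)
    _bh_adjust(results)
    return results


# ---------------------------------------------------------------------------
# ranking / filtering
# ---------------------------------------------------------------------------


def rank_and_filter(
    results: Sequence[EnrichmentResult], cutoffs: LevelCutoffs
) -> list[EnrichmentResult]:
    """Sort, competition-rank and filter results of one dataset per level.

    Within each (dataset, level) stratum results are sorted by ascending p
    (ties broken by larger overlap, then lexicographic term ids) and given
    competition ranks: results with equal p share the lowest rank of their
    block.  A result survives if ``p <= max_p`` and ``rank <= max_rank``;
    ``max_rank = 0`` empties the stratum.
    """
    strata: dict[tuple, list[EnrichmentResult]] = {}
    for r in results:
        strata.setdefault((r.dataset_name, r.level), []).append(r)
    kept: list[EnrichmentResult] = []
    for (_, level), rs in sorted(strata.items(), key=lambda kv: (kv[0][0], -1 if kv[0][1] is None else kv[0][1])):
        max_p, max_rank = cutoffs.for_level(level)
        if max_rank <= 0:
            continue
        rs.sort(key=lambda r: (r.p_value, -len(r.overlap_genes), r.term_ids))
        rank = 0
        for i, r in enumerate(rs):
            if i == 0 or r.p_value > rs[i - 1].p_value:
                rank = i + 1  # competition ranking: ties share the block's lowest rank
            r.rank = rank
            if r.p_value <= max_p and rank <= max_rank:
                kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# dynamic analysis
# ---------------------------------------------------------------------------


def _connected_subsets(g, max_size: int) -> set[frozenset[str]]:
    """All connected induced node subsets of size 2..max_size (ESU enumeration).

    Each subset is reached exactly once by growing from its lowest-ordered
    node with extensions restricted to exclusive neighbors of later order.
    """
    order = {v: i for i, v in enumerate(sorted(g.nodes))}
    found: set[frozenset[str]] = set()

    def extend(members: set[str], ext: set[str], seed: str) -> None:
        if len(members) >= 2:
            found.add(frozenset(members))
        if len(members) == max_size:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            neighborhood = {u for m in members for u in g.neighbors(m)}
            new_ext = ext | {
                u for u in g.neighbors(w)
                if order[u] > order[seed] and u not in members and u not in neighborhood
            }
            extend(members | {w}, new_ext, seed)

    for v in sorted(g.nodes, key=order.get):
        extend({v}, {u for u in g.neighbors(v) if order[u] > order[v]}, v)
    return found


def build_combinations(
    o: Ontology,
    net_topx: InteractionNetwork,
    dataset_genes: set[str],
    max_arity: int = 3,
    require_gene_in_each_member: bool = True,
) -> list[Combination]:
    """Enumerate dataset-selective combinations of interacting terms.

    Combinations are the connected induced subsets of size ``2..max_arity``
    of the (already top-x% restricted) interaction graph whose member terms
    each contain at least one analyzed dataset gene (with
    ``require_gene_in_each_member=False``, only the union must).  The
    combination's gene set is the union of its members'.
    """
    if max_arity < 2:
        raise ValueError("max_arity must be >= 2")
    g = net_topx.graph()
    if require_gene_in_each_member:
        eligible = {
            t for t in g.nodes if t in o.terms and o.terms[t].genes & dataset_genes
        }
    else:
        eligible = {t for t in g.nodes if t in o.terms}
    sub = g.subgraph(eligible)
    found = _connected_subsets(sub, max_arity)

    combos = []
    for members in found:
        if require_gene_in_each_member is False:
            union = frozenset().union(*(o.terms[m].genes for m in members))
            if not union & dataset_genes:
                continue
        levels = {o.terms[m].level for m in members}
        combos.append(
            Combination(
                member_term_ids=members,
                union_genes=frozenset().union(*(o.terms[m].genes for m in members)),
                level=levels.pop() if len(levels) == 1 else None,
            )
        )
    combos.sort(key=lambda c: tuple(sorted(c.member_term_ids)))
    return combos


def enrich_dynamic(
    d: Dataset,
    o: Ontology,
    combos: Sequence[Combination],
    cutoffs: LevelCutoffs,
    background: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Dynamic over-representation analysis of one dataset.

    The candidate universe is the ontology's terms plus the dataset-selective
    combinations; a combination's ``K`` is the size of its gene union within
    the background.  Candidates are ranked and filtered jointly per level
    with the dynamic cutoffs.
    """
    if not o.propagated:
        raise ValueError("ontology must be propagated before enrichment")
    bg = background if background is not None else resolve_background(d, o)
    analyzed = d.gene_set & bg
    if not analyzed:
        logger.warning("dataset %s has no analyzable genes", d.name)
        return []
    N = len(bg)
    results: list[EnrichmentResult] = []
    for tid in sorted(o.terms):
        t = o.terms[tid]
        r = _make_result(
            d, (tid,), (t.name,), t.level, t.genes & bg, analyzed, N, DYNAMIC
        )
        if r is not None:
            results.append(r)
    for combo in combos:
        ids = tuple(sorted(combo.member_term_ids))
        names = tuple(o.terms[i].name for i in ids)
        r = _make_result(
            d, ids, names, combo.level,
            set(combo.union_genes) & bg, analyzed, N, DYNAMIC,
        )
        if r is not None:
            results.append(r)
    _bh_adjust(results)
    return rank_and_filter(results, cutoffs)


def split_combination_scores(
    results: Iterable[EnrichmentResult],
) -> dict[str, float]:
    """Split each result's -log10 p equally among its member terms and sum.

    A combination of m terms contributes ``minus_log10_p / m`` to each
    member; contributions for the same term across results add up.  The total
    over terms is conserved: it equals the sum of the results' -log10 p.
    """
    scores: dict[str, float] = {}
    for r in results:
        share = r.minus_log10_p / len(r.term_ids)
        for tid in r.term_ids:
            scores[tid] = scores.get(tid, 0.0) + share
    return scores


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------


def results_table(results: Sequence[EnrichmentResult]):
    """Flatten results into a tab-writable pandas DataFrame."""
    import pandas as pd

    rows = []
    for r in sorted(results, key=lambda r: r.key()):
        rows.append({
            "dataset": r.dataset_name,
            "level": "" if r.level is None else r.level,
            "term_ids": ";".join(r.term_ids),
            "term_names": ";".join(r.term_names),
            "p_value": f"{r.p_value:.12g}",
            "minus_log10_p": f"{r.minus_log10_p:.12g}",
            "q_value": "" if r.q_value is None else f"{r.q_value:.12g}",
            "rank": r.rank,
            "overlap_genes": ",".join(sorted(r.overlap_genes)),
            "analysis_type": r.analysis_type,
        })
    cols = ["dataset", "level", "term_ids", "term_names", "p_value",
            "minus_log10_p", "q_value", "rank", "overlap_genes", "analysis_type"]
    return pd.DataFrame(rows, columns=cols)
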