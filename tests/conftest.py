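"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from fractions import Fraction
from math import comb

import pytest
from hypothesis import HealthCheck, settings

from scpnet import fixtures as fx
from scpnet import propagate_annotations
from scpnet.ontology import Ontology, Term

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact right-tail hypergeometric probability via big-integer binomials.

    Independent oracle for the Fisher test: P(X >= k) as a Fraction.
    """
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(total, comb(N, n))


def random_counts(rng: random.Random, n_max: int = 60) -> tuple[int, int, int, int]:
    """A random valid (k, n, K, N) contingency tuple with N <= n_max."""
    N = rng.randint(1, n_max)
    n = rng.randint(0, N)
    K = rng.randint(0, N)
    k_hi = min(n, K)
    k_lo = max(0, n + K - N)
    k = rng.randint(k_lo, k_hi)
    return k, n, K, N


def random_dag(rng: random.Random, n_terms: int, edge_prob: float = 0.25) -> Ontology:
    """A random leveled-by-index DAG with random leaf-ward gene annotations."""
    terms = {f"T{i}": Term(id=f"T{i}") for i in range(n_terms)}
    edges = set()
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < edge_prob:
                edges.add((f"T{i}", f"T{j}", "annotated_hierarchy"))
    pool = [f"G{g}" for g in range(3 * n_terms)]
    for t in terms.values():
        t.genes = set(rng.sample(pool, rng.randint(0, 4)))
    return Ontology(terms=terms, edges=edges)


def propagate_naive(o: Ontology) -> dict[str, set[str]]:
    """Fixed point of repeated parent-absorbs-child passes (oracle)."""
    genes = {tid: set(t.genes) for tid, t in o.terms.items()}
    hier = [(p, c) for p, c, r in o.edges
            if r in ("is_a", "part_of", "annotated_hierarchy")]
    changed = True
    while changed:
        changed = False
        for p, c in hier:
            before = len(genes[p])
            genes[p] |= genes[c]
            if len(genes[p]) != before:
                changed = True
    return genes


@pytest.fixture
def toy():
    """A propagated toy ontology with its interaction network."""
    o, net = fx.make_toy_ontology(levels=3, branching=3, genes_per_leaf=20,
                                  gene_overlap=0.1, seed=11)
    return propagate_annotations(o), net


@pytest.fixture
def planted(toy):
    """Two planted datasets targeting sibling leaves, one integration group."""
    o, net = toy
    d1 = fx.make_planted_dataset(o, "SCP_1.1.1", seed=21, name="ds1")
    d2 = fx.make_planted_dataset(o, "SCP_1.1.2", seed=22, name="ds2")
    d2.color = "#FF7F0E"
    d2.order_index = 2
    return d1, d2
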