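"""Fisher test, ranking semantics, combinations and dynamic analysis."""

import itertools
import math
import random
from fractions import Fraction
from math import comb

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from scpnet.datasets_io import Dataset
from scpnet.enrichment import (
    Combination,
    ContingencyCounts,
    EnrichmentResult,
    LevelCutoffs,
    build_combinations,
    enrich_dynamic,
    enrich_standard,
    fisher_right_tail,
    rank_and_filter,
    split_combination_scores,
)
from scpnet.ontology import InteractionNetwork, Ontology, Term, propagate_annotations

from conftest import hypergeom_tail_exact, random_counts


class TestFisherRightTail:
    def test_zero_overlap_is_exactly_one(self):
        assert fisher_right_tail(ContingencyCounts(0, 5, 10, 100)) == 1.0

    def test_complete_overlap_closed_form(self):
        # all 5 drawn genes inside the 5-gene term: p = 1 / C(20, 5)
        p = fisher_right_tail(ContingencyCounts(5, 5, 5, 20))
        assert p == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_partial_overlap_against_exact_oracle(self):
        p = fisher_right_tail(ContingencyCounts(3, 5, 10, 100))
        exact = hypergeom_tail_exact(3, 5, 10, 100)
        assert float(exact) == pytest.approx(6.64e-3, rel=1e-2)
        assert p == pytest.approx(float(exact), rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_matches_big_integer_oracle(self, seed):
        k, n, K, N = random_counts(random.Random(seed))
        p = fisher_right_tail(ContingencyCounts(k, n, K, N))
        exact = float(hypergeom_tail_exact(k, n, K, N))
        assert p == pytest.approx(exact, rel=1e-12)

    @given(st.integers(0, 2_000))
    def test_matches_scipy_survival_function(self, seed):
        from scipy.stats import hypergeom

        k, n, K, N = random_counts(random.Random(seed))
        p = fisher_right_tail(ContingencyCounts(k, n, K, N))
        assert p == pytest.approx(hypergeom.sf(k - 1, N, K, n), rel=1e-9)

    @given(st.integers(0, 2_000))
    def test_monotone_in_overlap(self, seed):
        k, n, K, N = random_counts(random.Random(seed))
        if k >= min(n, K):
            return
        c1 = ContingencyCounts(k, n, K, N)
        c2 = ContingencyCounts(k + 1, n, K, N)
        assert fisher_right_tail(c2) <= fisher_right_tail(c1)

    @pytest.mark.parametrize("bad", [
        ContingencyCounts(6, 5, 10, 100),   # k > n
        ContingencyCounts(3, 5, 2, 100),    # k > K
        ContingencyCounts(1, 5, 200, 100),  # K > N
    ])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_right_tail(bad)


def _flat_ontology(term_genes: dict[str, set[str]], levels=None) -> Ontology:
    terms = {
        tid: Term(id=tid, genes=set(g),
                  level=(levels or {}).get(tid))
        for tid, g in term_genes.items()
    }
    return Ontology(terms=terms, edges=set(), propagated=True)


class TestStandardEnrichment:
    def test_planted_term_is_top_ranked(self):
        genes_t = {f"T{i}" for i in range(20)}
        o = _flat_ontology({
            "target": genes_t,
            "other": {f"O{i}" for i in range(20)},
        })
        bg = genes_t | {f"B{i}" for i in range(960)} | o.terms["other"].genes
        d = Dataset(name="d", genes=sorted(genes_t), background=bg)
        results = enrich_standard(d, o)
        best = min(results, key=lambda r: r.p_value)
        assert best.term_ids == ("target",)
        # p verified against the independent exact oracle
        assert best.p_value == pytest.approx(
            float(hypergeom_tail_exact(20, 20, 20, 1000)), rel=1e-12
        )

    def test_disjoint_dataset_yields_no_results(self):
        o = _flat_ontology({"t": {"A", "B"}})
        d = Dataset(name="d", genes=["X"], background={"X", "A", "B"})
        assert enrich_standard(d, o) == []

    def test_term_genes_outside_background_excluded_from_K(self):
        o = _flat_ontology({"t": {"A", "B", "C"}})
        d = Dataset(name="d", genes=["A"], background={"A", "B", "Z"})
        (r,) = enrich_standard(d, o)
        # K = |{A,B}| = 2, not 3; N = 3, n = 1, k = 1
        assert r.p_value == pytest.approx(
            float(hypergeom_tail_exact(1, 1, 2, 3)), rel=1e-12
        )

    def test_requires_propagated_ontology(self):
        o = _flat_ontology({"t": {"A"}})
        o.propagated = False
        with pytest.raises(ValueError):
            enrich_standard(Dataset(name="d", genes=["A"], background={"A"}), o)

    def test_bh_q_values_attached(self):
        o = _flat_ontology({"t1": {"A"}, "t2": {"A", "B"}})
        d = Dataset(name="d", genes=["A"], background={"A", "B", "C", "D"})
        for r in enrich_standard(d, o):
            assert r.q_value is not None and r.q_value >= r.p_value


def _result(term_ids, p, dataset="d", level=3, k=1):
    return EnrichmentResult(
        term_ids=tuple(term_ids), term_names=tuple(term_ids),
        dataset_name=dataset, p_value=p, minus_log10_p=-math.log10(p),
        level=level, rank=0,
        overlap_genes=frozenset(f"g{i}" for i in range(k)),
    )


class TestRankAndFilter:
    def test_worked_example_keeps_first_three(self):
        results = [_result([t], p) for t, p in
                   zip("ABCD", [1e-5, 1e-4, 1e-3, 0.02])]
        kept = rank_and_filter(results, LevelCutoffs(max_p=0.01, max_rank=3))
        assert [r.term_ids[0] for r in kept] == ["A", "B", "C"]
        assert [r.rank for r in kept] == [1, 2, 3]

    def test_rank_zero_empties_stratum(self):
        results = [_result(["A"], 1e-6)]
        assert rank_and_filter(results, LevelCutoffs(max_p=0.01, max_rank=0)) == []

    def test_per_level_rank_zero_only_disables_that_level(self):
        results = [_result(["A"], 1e-6, level=2), _result(["B"], 1e-6, level=3)]
        cutoffs = LevelCutoffs(max_p=0.01, max_rank=3, by_level={2: (0.01, 0)})
        kept = rank_and_filter(results, cutoffs)
        assert [r.term_ids[0] for r in kept] == ["B"]

    def test_ties_share_lowest_rank_and_both_kept(self):
        results = [_result(["A"], 1e-5), _result(["B"], 1e-5),
                   _result(["C"], 1e-4), _result(["D"], 1e-4)]
        kept = rank_and_filter(results, LevelCutoffs(max_p=0.01, max_rank=3))
        ranks = {r.term_ids[0]: r.rank for r in kept}
        assert ranks == {"A": 1, "B": 1, "C": 3, "D": 3}

    def test_strata_independent_across_levels(self):
        results = [_result(["A"], 1e-3, level=2), _result(["B"], 1e-3, level=3)]
        kept = rank_and_filter(results, LevelCutoffs(max_p=0.01, max_rank=1))
        assert len(kept) == 2 and all(r.rank == 1 for r in kept)

    def test_invalid_max_p_rejected(self):
        with pytest.raises(ValueError):
            LevelCutoffs(max_p=0.0)


def _interactions(pairs):
    return InteractionNetwork.from_edges([(a, b, 1.0) for a, b in pairs])


class TestBuildCombinations:
    def _ontology(self, with_genes):
        return _flat_ontology(
            {t: ({f"{t}1", f"{t}2"} if t in with_genes else {f"{t}x"})
             for t in "ABC"},
            levels={t: 3 for t in "ABC"},
        )

    def test_member_without_dataset_gene_blocks(self):
        o = self._ontology("AC")
        genes = {"A1", "C1"}
        combos = build_combinations(o, _interactions([("A", "B"), ("B", "C")]), genes)
        assert combos == []

    def test_simple_pair(self):
        o = self._ontology("AB")
        combos = build_combinations(o, _interactions([("A", "B")]), {"A1", "B1"})
        assert [set(c.member_term_ids) for c in combos] == [{"A", "B"}]
        assert combos[0].union_genes == {"A1", "A2", "B1", "B2"}
        assert combos[0].level == 3

    def test_path_connectivity_excludes_disconnected_induced_subset(self):
        o = self._ontology("ABC")
        combos = build_combinations(
            o, _interactions([("A", "B"), ("B", "C")]), {"A1", "B1", "C1"},
            max_arity=3,
        )
        members = {frozenset(c.member_term_ids) for c in combos}
        assert members == {frozenset("AB"), frozenset("BC"), frozenset("ABC")}

    @given(st.integers(0, 3_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 8)
        nodes = [f"T{i}" for i in range(n)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.4]
        if not edges:
            return
        o = _flat_ontology({t: {f"{t}g"} for t in nodes})
        genes = {f"{t}g" for t in nodes if rng.random() < 0.7}
        net = _interactions(edges)
        arity = rng.randint(2, 4)
        combos = {frozenset(c.member_term_ids)
                  for c in build_combinations(o, net, genes, max_arity=arity)}
        # oracle: filter nodes by gene membership, test induced connectivity
        g = net.graph()
        eligible = [t for t in g.nodes if o.terms[t].genes & genes]
        expected = set()
        for size in range(2, arity + 1):
            for subset in itertools.combinations(eligible, size):
                sub = g.subgraph(subset)
                if sub.number_of_nodes() == size and nx.is_connected(sub):
                    expected.add(frozenset(subset))
        assert combos == expected


class TestDynamicEnrichment:
    def _paired_system(self):
        a = {f"A{i}" for i in range(10)}
        b = {f"B{i}" for i in range(10)}
        o = _flat_ontology({"A": a, "B": b}, levels={"A": 3, "B": 3})
        bg = a | b | {f"N{i}" for i in range(980)}
        genes = sorted(a)[:5] + sorted(b)[:5]
        d = Dataset(name="d", genes=genes, background=bg)
        return o, d

    def test_combination_outranks_both_singletons(self):
        o, d = self._paired_system()
        combos = build_combinations(o, _interactions([("A", "B")]), d.gene_set)
        results = enrich_dynamic(d, o, combos, LevelCutoffs(max_p=1.0, max_rank=10))
        by_ids = {r.term_ids: r for r in results}
        p_combo = by_ids[("A", "B")].p_value
        p_single = by_ids[("A",)].p_value
        # oracle check of both p values and the ordering
        assert p_combo == pytest.approx(
            float(hypergeom_tail_exact(10, 10, 20, 1000)), rel=1e-12
        )
        assert p_single == pytest.approx(
            float(hypergeom_tail_exact(5, 10, 10, 1000)), rel=1e-12
        )
        assert p_combo < p_single
        assert by_ids[("A", "B")].rank == 1

    def test_no_combinations_degenerates_to_standard(self):
        o, d = self._paired_system()
        cutoffs = LevelCutoffs(max_p=1.0, max_rank=10)
        dyn = enrich_dynamic(d, o, [], cutoffs)
        std = rank_and_filter(enrich_standard(d, o), cutoffs)
        assert [(r.term_ids, r.p_value, r.rank) for r in dyn] == [
            (r.term_ids, r.p_value, r.rank) for r in std
        ]

    def test_shared_genes_counted_once(self):
        shared = {"S1", "S2"}
        o = _flat_ontology(
            {"A": shared | {"A1"}, "B": shared | {"B1"}},
            levels={"A": 3, "B": 3},
        )
        bg = {"S1", "S2", "A1", "B1"} | {f"N{i}" for i in range(96)}
        d = Dataset(name="d", genes=["S1", "A1", "B1"], background=bg)
        combos = build_combinations(o, _interactions([("A", "B")]), d.gene_set)
        (combo,) = combos
        assert len(combo.union_genes) == 4  # S1,S2 counted once
        results = enrich_dynamic(d, o, combos, LevelCutoffs(max_p=1.0, max_rank=10))
        r = next(r for r in results if r.term_ids == ("A", "B"))
        assert len(r.overlap_genes) == 3

    def test_standard_candidates_subset_of_dynamic(self, toy, planted):
        o, net = toy
        d, _ = planted
        loose = LevelCutoffs(max_p=1.0, max_rank=10_000)
        std_ids = {r.term_ids for r in
                   rank_and_filter(enrich_standard(d, o), loose)}
        dyn_ids = {r.term_ids for r in enrich_dynamic(d, o, [], loose)}
        assert std_ids <= dyn_ids


class TestSplitScores:
    def test_pair_splits_equally(self):
        scores = split_combination_scores([_result(["A", "B"], 1e-4)])
        assert scores == {"A": pytest.approx(2.0), "B": pytest.approx(2.0)}

    def test_repeated_member_sums(self):
        scores = split_combination_scores(
            [_result(["A", "B"], 1e-4), _result(["A", "C"], 1e-3)]
        )
        assert scores["A"] == pytest.approx(2.0 + 1.5)
        assert scores["B"] == pytest.approx(2.0)
        assert scores["C"] == pytest.approx(1.5)

    def test_singleton_keeps_full_score(self):
        scores = split_combination_scores([_result(["A"], 0.01)])
        assert scores == {"A": pytest.approx(2.0)}

    @given(st.integers(0, 5_000))
    def test_total_score_conserved(self, seed):
        rng = random.Random(seed)
        results = []
        for _ in range(rng.randint(1, 20)):
            members = rng.sample("ABCDEFGH", rng.randint(1, 3))
            results.append(_result(members, 10 ** -rng.uniform(1, 8)))
        scores = split_combination_scores(results)
        assert sum(scores.values()) == pytest.approx(
            sum(r.minus_log10_p for r in results), abs=1e-9
        )
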