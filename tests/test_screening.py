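"""Permutation test, MIS, enrichment vectors, cosine similarity, cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netscreen import (
    AnnotationCorpus,
    ESVector,
    PermutationResult,
    ScorerConfig,
    SeedSet,
    ValidationError,
    apply_cascade,
    build_representation,
    compute_es_vector,
    compute_mes,
    compute_mis,
    cosine_similarity,
    hypergeom_tail,
    run_permutation_test,
)

from conftest import make_network, random_network


def exact_tail(N, M, n, m):
    """Exact upper hypergeometric tail by integer enumeration."""
    num = sum(math.comb(M, k) * math.comb(N - M, n - k) for k in range(m, min(M, n) + 1))
    return num / math.comb(N, n)


class TestHypergeomTail:
    def test_worked_example(self):
        # N=10, M=4, n=5, m=3: tail = (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252
        tail = hypergeom_tail(10, 4, 5, 3)
        assert tail == pytest.approx(66 / 252, abs=1e-12)
        assert -math.log10(tail) == pytest.approx(0.58186, abs=1e-5)

    def test_m_zero_gives_whole_support(self):
        assert hypergeom_tail(20, 5, 7, 0) == 1.0

    def test_inconsistent_m_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            hypergeom_tail(10, 3, 4, 5)

    def test_matches_enumeration_on_grid(self):
        for N in (1, 5, 12):
            for M in range(N + 1):
                for n in range(N + 1):
                    for m in range(min(M, n) + 1):
                        assert hypergeom_tail(N, M, n, m) == pytest.approx(
                            exact_tail(N, M, n, m), abs=1e-9
                        )


class TestEsVector:
    def test_no_neighbours_zero_vector(self):
        net = make_network([("a", "b", 500)])
        from netscreen import PPINetwork

        net = PPINetwork(nodes=["a", "b", "c"], edges=dict(net.edges))
        corpus = AnnotationCorpus(terms={"T": {"a", "b"}}, universe_size=3)
        v = compute_es_vector("c", net, corpus)
        assert all(x == 0.0 for x in v.scores.values())

    def test_zero_when_tail_is_one(self, triangle):
        # b's neighbours are {a, c}; a term covering every gene has tail 1
        corpus = AnnotationCorpus(terms={"ALL": {"a", "b", "c"}}, universe_size=3)
        v = compute_es_vector("b", triangle, corpus)
        assert v.scores["ALL"] == 0.0

    def test_known_value_on_toy(self):
        # universe N=10; gene g has n=5 neighbours, term has M=4, overlap m=3
        edges = [("g", f"x{i}", 500) for i in range(5)]
        edges += [(f"y{i}", f"y{j}", 100) for i, j in [(0, 1), (1, 2), (2, 3)]]
        net = make_network(edges)
        assert net.n_nodes == 10
        corpus = AnnotationCorpus(terms={"F": {"x0", "x1", "x2", "y0"}}, universe_size=10)
        v = compute_es_vector("g", net, corpus)
        assert v.scores["F"] == pytest.approx(-math.log10(66 / 252), abs=1e-9)

    def test_min_score_restricts_neighbourhood(self, triangle):
        corpus = AnnotationCorpus(terms={"T": {"c"}}, universe_size=3)
        v_all = compute_es_vector("b", triangle, corpus, min_score=1)
        v_high = compute_es_vector("b", triangle, corpus, min_score=600)
        # with only the 999 edge kept, n=1 and m=1: stronger enrichment
        assert v_high.scores["T"] >= v_all.scores["T"]

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            ESVector(gene="g", scores={"T": -0.5})


class TestCosine:
    def test_identical_vectors(self):
        v = ESVector("a", {"T1": 1.0, "T2": 2.0})
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        v = ESVector("a", {"T1": 1.0})
        w = ESVector("b", {"T2": 3.0})
        assert cosine_similarity(v, w) == 0.0

    def test_hand_value(self):
        v = ESVector("a", {"T1": 1.0, "T2": 1.0})
        w = ESVector("b", {"T1": 1.0, "T2": 0.0})
        assert cosine_similarity(v, w) == pytest.approx(1 / math.sqrt(2), abs=1e-9)

    def test_zero_norm_convention(self):
        v = ESVector("a", {"T1": 0.0})
        w = ESVector("b", {"T1": 5.0})
        assert cosine_similarity(v, w) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.lists(st.floats(min_value=0, max_value=10), min_size=3, max_size=3),
        b=st.lists(st.floats(min_value=0, max_value=10), min_size=3, max_size=3),
    )
    def test_symmetric_and_bounded(self, a, b):
        terms = ["T1", "T2", "T3"]
        v = ESVector("a", dict(zip(terms, a)))
        w = ESVector("b", dict(zip(terms, b)))
        s1, s2 = cosine_similarity(v, w), cosine_similarity(w, v)
        assert s1 == pytest.approx(s2)
        assert -1e-12 <= s1 <= 1 + 1e-12


class TestMis:
    def test_no_seed_edge_gives_zero(self, triangle):
        seeds = SeedSet("dz", {"c"})
        net = triangle
        # a-c edge exists (10); pick a network where gene has no seed edge
        net2 = make_network([("a", "b", 500), ("c", "d", 999)])
        assert compute_mis("a", SeedSet("dz", {"c", "d"}), net2) == 0.0

    def test_max_over_seed_edges(self):
        net = make_network([("g", "s1", 300), ("g", "s2", 950), ("g", "s3", 700)])
        seeds = SeedSet("dz", {"s1", "s2", "s3"})
        assert compute_mis("g", seeds, net) == pytest.approx(0.95)

    def test_gene_not_in_network(self, triangle):
        with pytest.raises(ValidationError):
            compute_mis("zzz", SeedSet("dz", {"a"}), triangle)

    def test_brute_force_oracle_random_graphs(self):
        for trial in range(100):
            r = np.random.default_rng(3000 + trial)
            net = random_network(r, n=12, p=0.3)
            seeds = SeedSet("dz", set(r.choice(net.nodes, size=3, replace=False)))
            for g in net.nodes:
                if g in seeds.mapped:
                    continue
                brute = max(
                    (s / 1000.0 for (a, b), s in net.edges.items()
                     if {a, b} & seeds.mapped and g in (a, b)),
                    default=0.0,
                )
                assert compute_mis(g, seeds, net) == pytest.approx(brute, abs=1e-12)
                assert (compute_mis(g, seeds, net) == 0.0) == (brute == 0.0)

    def test_invariant_to_seed_order(self, rng):
        net = random_network(rng, n=15, p=0.4)
        genes = list(net.nodes)
        seeds_a = SeedSet("dz", set(genes[:4]))
        # same set, different construction order
        seeds_b = SeedSet("dz", set(reversed(genes[:4])))
        for g in genes[4:]:
            assert compute_mis(g, seeds_a, net) == compute_mis(g, seeds_b, net)


class TestMes:
    def test_identical_to_one_seed(self):
        vg = ESVector("g", {"T1": 2.0, "T2": 1.0})
        seeds = [ESVector("s1", {"T1": 4.0, "T2": 2.0}), ESVector("s2", {"T2": 1.0})]
        assert compute_mes(vg, seeds) == pytest.approx(1.0)

    def test_zero_vector_gives_zero(self):
        vg = ESVector("g", {"T1": 0.0})
        assert compute_mes(vg, [ESVector("s", {"T1": 3.0})]) == 0.0

    def test_empty_seed_vectors_rejected(self):
        with pytest.raises(ValidationError):
            compute_mes(ESVector("g", {"T1": 1.0}), [])

    def test_equals_exhaustive_max(self, rng):
        terms = ["T1", "T2", "T3", "T4"]
        vg = ESVector("g", {t: float(rng.uniform(0, 3)) for t in terms})
        seeds = [ESVector(f"s{i}", {t: float(rng.uniform(0, 3)) for t in terms}) for i in range(3)]
        exhaustive = max(cosine_similarity(vg, s) for s in seeds)
        assert compute_mes(vg, seeds) == pytest.approx(exhaustive)


class TestPermutation:
    @staticmethod
    def _small_setup(seed=0):
        r = np.random.default_rng(seed)
        net = random_network(r, n=30, p=0.2)
        seeds = SeedSet("dz", set(net.nodes[:5]))
        rep = build_representation(net, "influence")
        return net, rep, seeds

    def test_p_zero_when_observed_beats_all_nulls(self):
        perm = PermutationResult(observed={"g": 0.9}, null_counts={"g": 0}, n_random_sets=10)
        assert perm.p_value("g") == 0.0

    def test_p_one_when_null_always_ties_or_beats(self):
        perm = PermutationResult(observed={"g": 0.1}, null_counts={"g": 10}, n_random_sets=10)
        assert perm.p_value("g") == 1.0

    def test_add_one_smoothing(self):
        perm = PermutationResult(observed={"g": 0.5}, null_counts={"g": 3}, n_random_sets=10,
                                 add_one_smoothing=True)
        assert perm.p_value("g") == pytest.approx(4 / 11)

    def test_p_monotone_in_observed_with_fixed_nulls(self, rng):
        # two genes sharing identical null draws: higher observed => p no larger
        nulls = rng.uniform(size=200)
        for o1, o2 in [(0.2, 0.7), (0.5, 0.5), (0.01, 0.99)]:
            c1, c2 = int((nulls >= o1).sum()), int((nulls >= o2).sum())
            perm = PermutationResult(observed={"a": o1, "b": o2},
                                     null_counts={"a": c1, "b": c2}, n_random_sets=200)
            assert (o2 >= o1) == (perm.p_value("b") <= perm.p_value("a"))

    def test_counts_match_p_exactly(self):
        net, rep, seeds = self._small_setup()
        perm = run_permutation_test(net, rep, seeds, None, ScorerConfig(), n_random_sets=20, rng_seed=4)
        for g, c in perm.null_counts.items():
            assert perm.p_value(g) == c / 20
            assert 0.0 <= perm.p_value(g) <= 1.0

    def test_deterministic_under_seed(self):
        net, rep, seeds = self._small_setup()
        p1 = run_permutation_test(net, rep, seeds, None, ScorerConfig(), n_random_sets=10, rng_seed=7)
        p2 = run_permutation_test(net, rep, seeds, None, ScorerConfig(), n_random_sets=10, rng_seed=7)
        assert p1.null_counts == p2.null_counts

    def test_budget_cap(self):
        net, rep, seeds = self._small_setup()
        with pytest.raises(ValidationError, match="budget"):
            run_permutation_test(net, rep, seeds, None, ScorerConfig(),
                                 n_random_sets=1000, max_budget=100)

    def test_exclude_seeds_flag(self):
        net, rep, seeds = self._small_setup()
        perm = run_permutation_test(net, rep, seeds, None, ScorerConfig(),
                                    n_random_sets=5, rng_seed=1,
                                    exclude_seeds_from_null=True)
        assert set(perm.observed) == set(net.nodes) - seeds.mapped


def brute_force_filter(genes, p, mis, mes, p_cut, mis_cut, mes_cut):
    """Independent one-line re-implementation of the cascade's final set."""
    return {g for g in genes if p[g] < p_cut and mis[g] >= mis_cut and mes[g] >= mes_cut}


class TestCascade:
    @staticmethod
    def _random_instance(seed):
        r = np.random.default_rng(seed)
        net = random_network(r, n=20, p=0.35)
        seeds = SeedSet("dz", set(r.choice(net.nodes, size=4, replace=False)))
        candidates = [g for g in net.nodes if g not in seeds.mapped]
        nodes = net.nodes
        corpus = AnnotationCorpus(
            terms={f"T{i}": set(r.choice(nodes, size=6, replace=False)) for i in range(5)},
            universe_size=net.n_nodes,
        )
        observed = {g: float(r.uniform()) for g in candidates}
        counts = {g: int(r.integers(0, 101)) for g in candidates}
        perm = PermutationResult(observed=observed, null_counts=counts, n_random_sets=100)
        return net, seeds, candidates, corpus, perm

    def test_empty_candidates(self):
        net, seeds, _, corpus, perm = self._random_instance(0)
        scores = apply_cascade([], perm, net, seeds, corpus)
        assert scores.final == set() and scores.stage_removed == {}

    def test_default_thresholds(self):
        net, seeds, cands, corpus, perm = self._random_instance(1)
        scores = apply_cascade(cands, perm, net, seeds, corpus)
        assert scores.thresholds == {"p_cut": 0.05, "mis_cut": 0.9, "mes_cut": 0.95}

    def test_thresholds_out_of_range_rejected(self):
        net, seeds, cands, corpus, perm = self._random_instance(2)
        with pytest.raises(ValidationError):
            apply_cascade(cands, perm, net, seeds, corpus, p_cut=1.5)

    def test_candidate_seed_overlap_rejected(self):
        net, seeds, cands, corpus, perm = self._random_instance(3)
        bad = cands + [next(iter(seeds.mapped))]
        with pytest.raises(ValidationError, match="overlap"):
            apply_cascade(bad, perm, net, seeds, corpus)

    @pytest.mark.parametrize("p_cut,mis_cut,mes_cut", [(0.5, 0.3, 0.2), (0.05, 0.9, 0.95), (1.0, 0.0, 0.0)])
    def test_agreement_with_brute_force_filter(self, p_cut, mis_cut, mes_cut):
        """Cascade survivors match an independent filter on 100 random instances."""
        for trial in range(100):
            net, seeds, cands, corpus, perm = self._random_instance(4000 + trial)
            scores = apply_cascade(cands, perm, net, seeds, corpus,
                                   p_cut=p_cut, mis_cut=mis_cut, mes_cut=mes_cut)
            # independent MIS / MES / p computation
            p = {g: perm.p_value(g) for g in cands}
            mis = {g: max((net.q(g, s) for s in seeds.mapped), default=0.0) for g in cands}
            seed_vecs = [compute_es_vector(s, net, corpus) for s in sorted(seeds.mapped)]
            mes = {g: compute_mes(compute_es_vector(g, net, corpus), seed_vecs) for g in cands}
            expected = brute_force_filter(cands, p, mis, mes, p_cut, mis_cut, mes_cut)
            assert scores.final == expected

    def test_survivor_nesting_and_stage_labels(self):
        for trial in range(100):
            net, seeds, cands, corpus, perm = self._random_instance(5000 + trial)
            scores = apply_cascade(cands, perm, net, seeds, corpus, p_cut=0.5, mis_cut=0.3, mes_cut=0.3)
            s1 = scores.survivors("permutation")
            s2 = scores.survivors("interaction")
            s3 = scores.final
            assert s3 <= s2 <= s1 <= set(cands)
            for g in cands:
                stage = scores.stage_removed[g]
                if stage == "none":
                    assert scores.p_value[g] < 0.5 and scores.mis[g] >= 0.3 and scores.mes[g] >= 0.3

    def test_tightening_thresholds_never_enlarges_final_set(self):
        for trial in range(30):
            net, seeds, cands, corpus, perm = self._random_instance(6000 + trial)
            loose = apply_cascade(cands, perm, net, seeds, corpus, p_cut=0.6, mis_cut=0.2, mes_cut=0.2)
            for tighter in [
                dict(p_cut=0.3, mis_cut=0.2, mes_cut=0.2),
                dict(p_cut=0.6, mis_cut=0.5, mes_cut=0.2),
                dict(p_cut=0.6, mis_cut=0.2, mes_cut=0.5),
            ]:
                tight = apply_cascade(cands, perm, net, seeds, corpus, **tighter)
                assert tight.final <= loose.final

    def test_mis_mes_invariant_to_seed_iteration_order(self):
        net, seeds, cands, corpus, perm = self._random_instance(7)
        a = apply_cascade(cands, perm, net, seeds, corpus, p_cut=1.0, mis_cut=0.0, mes_cut=0.0)
        seeds_b = SeedSet("dz", set(sorted(seeds.mapped, reverse=True)))
        b = apply_cascade(cands, perm, net, seeds_b, corpus, p_cut=1.0, mis_cut=0.0, mes_cut=0.0)
        assert a.mis == b.mis
        for g in cands:
            assert a.mes[g] == pytest.approx(b.mes[g], abs=1e-12)
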