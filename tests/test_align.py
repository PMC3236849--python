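import math
import time

import numpy as np
import pytest

import helpers_oracle as oracle
from pathhmm import (
    AlignParams,
    Network,
    NetworkValidationError,
    SimilarityTable,
    align_pair,
    build_transition_scores,
    emission_scores,
    global_correspondence,
    make_illustrative_pair,
    top_k_alignments,
)

NEG_INF = float("-inf")
NO_GAPS = NEG_INF


class TestTransitionScores:
    def test_weighted_normalization(self, star):
        ts = build_transition_scores(star, "weighted")
        assert ts.get("a", "b") == pytest.approx(math.log(0.25))
        assert ts.get("a", "c") == pytest.approx(math.log(0.75))

    def test_binary_degree_rule(self, star):
        ts = build_transition_scores(star, "binary")
        assert ts.get("a", "b") == pytest.approx(math.log(0.5))
        assert ts.get("a", "c") == pytest.approx(math.log(0.5))

    def test_absent_pair_is_minus_inf(self, star):
        for mode in ("weighted", "binary"):
            assert build_transition_scores(star, mode).get("b", "c") == NEG_INF

    def test_modes_agree_on_uniform_weights(self, chain3):
        tw = build_transition_scores(chain3, "weighted")
        tb = build_transition_scores(chain3, "binary")
        assert tw.scores == pytest.approx(tb.scores)

    def test_outgoing_probabilities_sum_to_one(self, triangle):
        ts = build_transition_scores(triangle, "weighted")
        for node in triangle.node_list:
            total = sum(
                math.exp(v) for (i, _), v in ts.scores.items() if i == node
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_edgeless_raises(self):
        with pytest.raises(NetworkValidationError):
            build_transition_scores(Network("e", nodes=["a"]), "weighted")


class TestEmissionScores:
    def test_max_scaling(self):
        e = emission_scores(SimilarityTable({("a", "x"): 10.0, ("b", "y"): 5.0}))
        assert e[("a", "x")] == pytest.approx(0.0)
        assert e[("b", "y")] == pytest.approx(math.log(0.5))

    def test_single_entry_scores_zero(self):
        e = emission_scores(SimilarityTable({("a", "x"): 42.0}))
        assert e[("a", "x")] == pytest.approx(0.0)

    def test_absent_pair_means_unmatchable(self):
        e = emission_scores(SimilarityTable({("a", "x"): 1.0}))
        assert ("a", "y") not in e

    def test_empty_table_raises(self):
        with pytest.raises(NetworkValidationError):
            emission_scores(SimilarityTable())


def identity_sim(nodes, score=1.0):
    return SimilarityTable({(n, n): score for n in nodes})


class TestAlignPair:
    def test_chain_self_alignment(self, chain3):
        """Aligning the 3-chain with itself under equal identity similarities:
        the optimum is the full chain pair, score 2*log(1/2) (two transitions
        per network out of the middle-degree nodes, zero emissions)."""
        s = identity_sim(["a", "b", "c"])
        aln = align_pair(chain3, chain3, s, AlignParams(L=3, gap_penalty=NO_GAPS, transition_mode="binary"))
        expected = oracle.oracle_best_score(chain3, chain3, s, 3, "binary")
        assert aln.score == pytest.approx(expected)
        assert aln.score == pytest.approx(2 * math.log(0.5))
        assert set(aln.matched_pairs()) == {("a", "a"), ("b", "b"), ("c", "c")}

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_oracle(self, seed):
        """On small random instances with gaps off, the DP equals brute-force
        enumeration over all ordered walk pairs without repeated aligned pairs."""
        rng = np.random.default_rng(seed)
        net1, net2, s = oracle.random_instance(rng)
        L = int(rng.integers(2, 5))
        params = AlignParams(L=L, gap_penalty=NO_GAPS, max_traceback_candidates=100000)
        aln = align_pair(net1, net2, s, params)
        best = oracle.oracle_best_score(net1, net2, s, L)
        if best is None:
            assert aln is None
        else:
            assert aln is not None
            assert aln.score == pytest.approx(best, abs=1e-9)

    def test_score_decomposition(self, rng):
        """A returned score re-sums exactly from its steps' emissions,
        transitions and gap penalties."""
        net1, net2, s = oracle.random_instance(rng)
        params = AlignParams(L=4, gap_penalty=math.log(0.05))
        aln = align_pair(net1, net2, s, params)
        assert aln is not None
        t1 = build_transition_scores(net1, params.transition_mode)
        t2 = build_transition_scores(net2, params.transition_mode)
        e = emission_scores(s)
        total = 0.0
        prev_u = prev_v = None
        for u, v in aln.steps:
            if u is not None and v is not None:
                total += e[(u, v)]
                if prev_u is not None:
                    total += t1.get(prev_u, u)
                if prev_v is not None:
                    total += t2.get(prev_v, v)
            elif u is not None:
                total += params.gap_penalty + t1.get(prev_u, u)
            else:
                total += params.gap_penalty + t2.get(prev_v, v)
            prev_u = u if u is not None else prev_u
            prev_v = v if v is not None else prev_v
        assert aln.score == pytest.approx(total, abs=1e-9)

    def test_gap_bridges_missing_counterpart(self):
        """A node with no similarity partner is bridged by a gap step."""
        net1 = Network("1", edges=[("a", "b", 1.0), ("b", "c", 1.0)])
        net2 = Network("2", edges=[("x", "y", 1.0)])
        s = SimilarityTable({("a", "x"): 10.0, ("c", "y"): 10.0})
        aln = align_pair(net1, net2, s, AlignParams(L=3, gap_penalty=math.log(0.1)))
        assert aln.steps in (
            [("a", "x"), ("b", None), ("c", "y")],
            [("c", "y"), ("b", None), ("a", "x")],
        )

    def test_feasibility_invariants(self, rng):
        for _ in range(10):
            net1, net2, s = oracle.random_instance(rng)
            aln = align_pair(net1, net2, s, AlignParams(L=5, gap_penalty=math.log(0.05)))
            if aln is None:
                continue
            assert aln.L == 5
            assert all(u is not None or v is not None for u, v in aln.steps)
            pairs = aln.matched_pairs()
            assert len(set(pairs)) == len(pairs)
            for path, net in ((aln.path1(), net1), (aln.path2(), net2)):
                for x, y in zip(path, path[1:]):
                    assert net.has_edge(x, y)
            sides = [
                (u is None, v is None) for u, v in aln.steps
            ]
            for (g1a, g2a), (g1b, g2b) in zip(sides, sides[1:]):
                assert not (g2a and g2b) or not (g1a and g1b)  # no double gap same side
                assert not (g1a and g1b)
                assert not (g2a and g2b)

    def test_monotone_emission_response(self):
        """Raising the similarity of a pair used by the optimum cannot
        lower the optimal score once emissions are re-normalized together."""
        net1 = Network("1", edges=[("a", "b", 1.0)])
        net2 = Network("2", edges=[("x", "y", 1.0)])
        s = SimilarityTable({("a", "x"): 4.0, ("b", "y"): 8.0})
        params = AlignParams(L=2, gap_penalty=NO_GAPS)
        before = align_pair(net1, net2, s, params).score
        s.set("a", "x", 6.0)  # still below the max, so normalization is unchanged
        after = align_pair(net1, net2, s, params).score
        assert after >= before

    def test_no_feasible_alignment_returns_none(self):
        net1 = Network("1", edges=[("a", "b", 1.0)])
        net2 = Network("2", edges=[("x", "y", 1.0)])
        # only one matchable pair and gaps disabled: no length-2 alignment
        s = SimilarityTable({("a", "x"): 1.0})
        assert align_pair(net1, net2, s, AlignParams(L=2, gap_penalty=NO_GAPS)) is None

    def test_l_below_two_rejected(self):
        with pytest.raises(ValueError):
            AlignParams(L=1)

    def test_runtime_grows_roughly_linearly_in_l(self):
        """DP cost per step is constant: L=20 should cost far less than
        quadratic scaling from L=5 would predict."""
        from pathhmm import make_benchmark_pair

        pair = make_benchmark_pair(target_size=80, seed_size=10, seed_avg_degree=4,
                                   m=3, rng_seed=5)

        def run(L):
            best = math.inf
            for _ in range(3):
                t0 = time.perf_counter()
                align_pair(pair.net1, pair.net2, pair.sim, AlignParams(L=L))
                best = min(best, time.perf_counter() - t0)
            return best

        run(5)  # warm-up
        t5, t20 = run(5), run(20)
        assert t20 < 16 * t5  # linear predicts 4x; quadratic 16x


class TestIllustrativeFixture:
    def test_individual_scores_misled_by_decoy(self):
        net1, net2, h, core_pairs, decoys = make_illustrative_pair()
        aln = align_pair(net1, net2, h, AlignParams(L=5))
        assert any(p in set(decoys) for p in aln.matched_pairs())

    def test_global_scores_recover_core_path(self):
        net1, net2, h, core_pairs, _ = make_illustrative_pair()
        s = global_correspondence(net1, net2, h)
        aln = align_pair(net1, net2, s, AlignParams(L=5))
        assert aln.matched_pairs() in (core_pairs, core_pairs[::-1])


class TestTopK:
    def test_k_equals_one_matches_align_pair(self, rng):
        net1, net2, s = oracle.random_instance(rng)
        params = AlignParams(L=3, k=1, gap_penalty=NO_GAPS)
        single = align_pair(net1, net2, s, params)
        top = top_k_alignments(net1, net2, s, params)
        assert len(top) == 1 and top[0].steps == single.steps

    def test_two_planted_tiers_recovered_edge_disjoint(self):
        """Two edge-disjoint planted path pairs with distinct score tiers come
        out in order, and reuse no interaction."""
        net1 = Network("1", edges=[("a1", "a2", 1.0), ("a2", "a3", 1.0),
                                   ("c1", "c2", 1.0), ("c2", "c3", 1.0)])
        net2 = Network("2", edges=[("x1", "x2", 1.0), ("x2", "x3", 1.0),
                                   ("z1", "z2", 1.0), ("z2", "z3", 1.0)])
        s = SimilarityTable()
        for i in (1, 2, 3):
            s.set(f"a{i}", f"x{i}", 100.0)  # strong tier
            s.set(f"c{i}", f"z{i}", 50.0)  # weaker tier
        alns = top_k_alignments(net1, net2, s, AlignParams(L=3, k=2, gap_penalty=NO_GAPS))
        tier1 = [("a1", "x1"), ("a2", "x2"), ("a3", "x3")]
        tier2 = [("c1", "z1"), ("c2", "z2"), ("c3", "z3")]
        assert alns[0].matched_pairs() in (tier1, tier1[::-1])
        assert alns[1].matched_pairs() in (tier2, tier2[::-1])
        used1 = set()
        for a in alns:
            edges = {tuple(sorted(e)) for e in zip(a.path1(), a.path1()[1:])}
            assert not edges & used1
            used1 |= edges

    def test_exhaustion_returns_short_list(self):
        net1 = Network("1", edges=[("a", "b", 1.0)])
        net2 = Network("2", edges=[("x", "y", 1.0)])
        s = SimilarityTable({("a", "x"): 5.0, ("b", "y"): 5.0})
        alns = top_k_alignments(net1, net2, s, AlignParams(L=2, k=10, gap_penalty=NO_GAPS))
        assert len(alns) == 1  # the single edge pair is used up after one alignment

    def test_no_interaction_reused_across_alignments(self, rng):
        net1, net2, s = oracle.random_instance(rng)
        alns = top_k_alignments(net1, net2, s, AlignParams(L=3, k=5, gap_penalty=NO_GAPS))
        for paths, _net in ((0, net1), (1, net2)):
            used = set()
            for a in alns:
                path = a.path1() if paths == 0 else a.path2()
                edges = {tuple(sorted(e)) for e in zip(path, path[1:])}
                assert not edges & used
                used |= edges
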