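"""Prediction suffix tree learning, likelihoods, cross-validation,
and chunk collapse."""

import math
import warnings

import numpy as np
import pytest

import songsyntax as ss
from songsyntax.pst import (
    PSTError,
    PSTParams,
    collapse_internal_nodes,
    context_counts,
    crossvalidate_pst,
    fit_pst,
    fit_pst_from_counts,
    param_grid,
    pst_nll,
)

STRICT = PSTParams(p_min=0.007, r=1.55, gamma_min=0.001, alpha=0.12, l_max=8)


def assert_tree_invariants(tree):
    """Suffix closure and smoothing invariants (asserted on every tree)."""
    k = len(tree.alphabet)
    g = tree.params.gamma_min
    for ctx, node in tree.nodes.items():
        if ctx:
            assert ctx[1:] in tree.nodes
        probs = node.smoothed_probs
        assert abs(sum(probs.values()) - 1) < 1e-9
        assert all(p >= g - 1e-12 for p in probs.values())
        assert set(probs) == set(tree.alphabet)
    assert () in tree.nodes


def brute_force_nll(tree, seqs):
    """Naive variable-order evaluator: scan all suffixes at each position
    (no suffix-closure shortcut) with the same smoothing."""
    bits = 0.0
    n = 0
    for song in seqs:
        song = tuple(song)
        for t in range(len(song)):
            best = ()
            for l in range(0, t + 1):
                c = song[t - l : t]
                if c in tree.nodes and len(c) >= len(best):
                    best = c
            bits -= math.log2(tree.nodes[best].smoothed_probs[song[t]])
            n += 1
    return bits / n


def _simulate(model, n_songs, seed, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corpus = ss.simulate_corpus(
            model, ss.SimulationConfig(n_songs=n_songs, seed=seed, **kw)
        )
    return [tuple(s) for s in ss.corpus_to_sequences(corpus)]


class TestFit:
    def test_iid_uniform_gives_root_only(self):
        model = ss.make_ground_truth(
            {
                "alphabet": list("ABCDEF"),
                "transitions": {"": {s: 1 / 6 for s in "ABCDEF"}},
            }
        )
        seqs = _simulate(model, 1500, 3)
        tree = fit_pst(seqs, STRICT)
        assert_tree_invariants(tree)
        assert tree.depth == 0 and len(tree) == 1

    def test_first_order_chain_recovery(self):
        """Strongly distinct rows: depth-1 tree whose probabilities match
        the chain within +-0.02."""
        rows = {
            "A": {"B": 0.7, "C": 0.2, "D": 0.1},
            "B": {"C": 0.7, "D": 0.2, "A": 0.1},
            "C": {"D": 0.7, "A": 0.2, "B": 0.1},
            "D": {"A": 0.7, "B": 0.2, "C": 0.1},
        }
        model = ss.make_ground_truth(
            {
                "alphabet": list("ABCD"),
                "transitions": {"": {s: 0.25 for s in "ABCD"}, **rows},
            }
        )
        seqs = _simulate(model, 4000, 9)
        tree = fit_pst(seqs, STRICT)
        assert_tree_invariants(tree)
        assert tree.depth == 1
        for lab, row in rows.items():
            node = tree.nodes[(lab,)]
            tot = sum(node.raw_counts.values())
            for s, p in row.items():
                assert abs(node.raw_counts.get(s, 0) / tot - p) < 0.02

    def test_long_range_rule_recovered(self):
        """Entry phrase determines the exit from a shared corridor three
        phrases later: the tree grows depth-3 branches ending in the
        corridor's last phrase that predict the two distinct exits."""
        model = ss.make_ground_truth(
            {
                "alphabet": list("TUBDKJFG"),
                "transitions": {
                    "": {"T": 0.2, "U": 0.2, "F": 0.3, "G": 0.3},
                    "T": {"B": 0.75, "F": 0.25},
                    "U": {"B": 0.75, "G": 0.25},
                    "B": {"D": 0.8, "F": 0.1, "G": 0.1},
                    "D": {"K": 0.4, "J": 0.4, "F": 0.2},
                    "F": {"G": 0.5, "T": 0.25, "U": 0.25},
                    "G": {"F": 0.5, "T": 0.25, "U": 0.25},
                    "K": {"F": 0.5, "G": 0.5},
                    "J": {"F": 0.5, "G": 0.5},
                    "T B D": {"K": 0.75, "F": 0.25},
                    "U B D": {"J": 0.75, "F": 0.25},
                },
            }
        )
        seqs = _simulate(model, 4000, 12)
        tree = fit_pst(seqs, STRICT)
        assert_tree_invariants(tree)
        tbd, ubd = ("T", "B", "D"), ("U", "B", "D")
        assert tbd in tree.nodes and ubd in tree.nodes
        assert max(
            tree.nodes[tbd].smoothed_probs,
            key=tree.nodes[tbd].smoothed_probs.get,
        ) == "K"
        assert max(
            tree.nodes[ubd].smoothed_probs,
            key=tree.nodes[ubd].smoothed_probs.get,
        ) == "J"

    def test_monotone_in_p_min(self, two_ctx):
        """Node set at smaller p_min is a superset of that at larger."""
        _, corpus = two_ctx
        seqs = ss.corpus_to_sequences(corpus)
        small = fit_pst(seqs, PSTParams(p_min=0.004, r=1.2, alpha=0.05))
        large = fit_pst(seqs, PSTParams(p_min=0.04, r=1.2, alpha=0.05))
        assert set(large.nodes) <= set(small.nodes)

    def test_empty_input_and_root_only_edge_cases(self):
        with pytest.raises(PSTError):
            fit_pst([], STRICT)
        tree = fit_pst([("A", "B", "A", "B")], PSTParams(p_min=1.0, r=2.0))
        assert tree.depth == 0  # nothing passes the gate: root-only


class TestNLL:
    def test_uniform_root_exactly_two_bits(self):
        counts = {(): {s: 25.0 for s in "ABCD"}}
        tree = fit_pst_from_counts(
            counts, 100, "ABCD", PSTParams(p_min=1.0, r=2.0)
        )
        # smoothing fixed point: 0.25*(1-4g)+g == 0.25 exactly
        assert pst_nll(tree, [("A", "C", "B", "D")]) == pytest.approx(2.0)

    def test_training_gain_over_root_model(self, two_ctx):
        _, corpus = two_ctx
        seqs = ss.corpus_to_sequences(corpus)
        tree = fit_pst(seqs, STRICT)
        root_only = fit_pst(seqs, PSTParams(p_min=1.0, r=1.55))
        assert pst_nll(tree, seqs) <= pst_nll(root_only, seqs) + 1e-12

    def test_unknown_symbol_rejected(self, two_ctx):
        _, corpus = two_ctx
        tree = fit_pst(ss.corpus_to_sequences(corpus), STRICT)
        with pytest.raises(PSTError, match="ZZZ"):
            pst_nll(tree, [("ZZZ",)])

    def test_matches_brute_force_evaluator(self, recovery_truth,
                                           recovery_corpus):
        """Oracle equivalence: the suffix-walk evaluator equals a naive
        all-suffixes evaluator to 1e-9 bits/phrase."""
        seqs = [
            tuple(s) for s in ss.corpus_to_sequences(recovery_corpus)
        ][:300]
        tree = fit_pst(seqs, recovery_truth.fit_params)
        assert abs(pst_nll(tree, seqs) - brute_force_nll(tree, seqs)) < 1e-9

    def test_cross_entropy_converges_to_model_entropy(self):
        """Sequences generated from the tree itself: NLL approaches the
        model's per-phrase entropy (computed by exact state propagation
        through the equivalent PFA)."""
        from songsyntax.pfa import generate_from_pfa, pst_to_pfa

        rows = {
            "A": {"B": 0.8, "C": 0.2},
            "B": {"C": 0.7, "A": 0.3},
            "C": {"A": 0.6, "B": 0.4},
        }
        model = ss.make_ground_truth(
            {"alphabet": list("ABC"),
             "transitions": {"": {s: 1 / 3 for s in "ABC"}, **rows}}
        )
        tree = fit_pst(_simulate(model, 2000, 1), STRICT)
        pfa = pst_to_pfa(tree)
        length = 12
        seqs = generate_from_pfa(pfa, 3000, length, seed=5)
        # expected bits/phrase by propagating the state distribution
        state_p = {pfa.start: 1.0}
        expected = 0.0
        for _t in range(length):
            step = {}
            for s, w in state_p.items():
                ent = -sum(
                    p * math.log2(p)
                    for p in pfa.emissions[s].values()
                    if p > 0
                )
                expected += w * ent
                for sym, p in pfa.emissions[s].items():
                    if p > 0:
                        t2 = pfa.step(s, sym)
                        step[t2] = step.get(t2, 0.0) + w * p
            state_p = step
        expected /= length
        assert abs(pst_nll(tree, seqs) - expected) < 0.02


class TestCrossValidation:
    def test_depth0_generator_selects_depth0(self):
        model = ss.make_ground_truth(
            {
                "alphabet": list("ABCDE"),
                "transitions": {"": {s: 0.2 for s in "ABCDE"}},
            }
        )
        seqs = _simulate(model, 300, 2)
        # evidence thresholds scaled to the small per-context counts at
        # this corpus size (see docs/methods.md)
        rep = crossvalidate_pst(
            seqs,
            param_grid(p_min=(0.05, 0.02), r=(2.5,), alpha=(0.2,)),
            k_folds=5,
            repeats=1,
            seed=0,
        )
        assert (rep.table["max_depth"] == 0).all()

    def test_same_seed_identical_report(self, two_ctx):
        _, corpus = two_ctx
        seqs = ss.corpus_to_sequences(corpus)[:200]
        grid = param_grid(p_min=(0.05, 0.01), r=(1.3,))
        a = crossvalidate_pst(seqs, grid, k_folds=5, repeats=2, seed=9)
        b = crossvalidate_pst(seqs, grid, k_folds=5, repeats=2, seed=9)
        assert a.table.equals(b.table)
        assert a.selected == b.selected

    def test_folds_partition_songs(self, two_ctx):
        _, corpus = two_ctx
        seqs = ss.corpus_to_sequences(corpus)[:50]
        with pytest.raises(PSTError):
            crossvalidate_pst(seqs[:5], param_grid(), k_folds=10)
        rep = crossvalidate_pst(
            seqs, param_grid(p_min=(0.05,)), k_folds=5, repeats=1, seed=1
        )
        assert rep.table["fold"].nunique() == 5

    def test_empty_grid_rejected(self, two_ctx):
        _, corpus = two_ctx
        with pytest.raises(PSTError):
            crossvalidate_pst(
                ss.corpus_to_sequences(corpus), [], k_folds=5
            )


class TestChunkCollapse:
    def test_no_internal_nodes_identity(self):
        rows = {
            "A": {"B": 0.8, "C": 0.2},
            "B": {"C": 0.7, "A": 0.3},
            "C": {"A": 0.6, "B": 0.4},
        }
        model = ss.make_ground_truth(
            {"alphabet": list("ABC"),
             "transitions": {"": {s: 1 / 3 for s in "ABC"}, **rows}}
        )
        seqs = _simulate(model, 800, 4)
        tree = fit_pst(seqs, STRICT)
        assert not any(n.is_internal for n in tree.nodes.values())
        res = collapse_internal_nodes(tree, seqs)
        assert res.chunks == [] and res.percent_nll_change == 0.0
        assert res.depth_after == res.depth_before

    def test_block_generator_collapses_depth_4_to_2(self):
        gt = ss.chunk_block_model(seed=5)
        seqs = _simulate(gt.model, 1500, 6, max_phrases=80)
        tree = fit_pst(seqs, gt.fit_params)
        assert tree.depth == 4
        res = collapse_internal_nodes(tree, seqs)
        assert "(" + "".join(gt.block) + ")" in res.chunk_symbols
        assert res.depth_after == 2
        assert res.percent_nll_change < 1.0

    def test_chunk_expansion_is_lossless(self):
        gt = ss.chunk_block_model(seed=5)
        seqs = _simulate(gt.model, 400, 8, max_phrases=80)
        tree = fit_pst(seqs, gt.fit_params)
        res = collapse_internal_nodes(tree, seqs)
        assert res.expand() == seqs


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, two_ctx):
        _, corpus = two_ctx
        seqs = ss.corpus_to_sequences(corpus)
        tree = fit_pst(seqs, STRICT)
        back = ss.PST.from_json(tree.to_json())
        assert set(back.nodes) == set(tree.nodes)
        assert pst_nll(back, seqs) == pytest.approx(pst_nll(tree, seqs))

    def test_dot_output_mentions_contexts(self, two_ctx):
        _, corpus = two_ctx
        tree = fit_pst(ss.corpus_to_sequences(corpus), STRICT)
        dot = tree.to_dot()
        assert dot.startswith("digraph") and '"root"' in dot


class TestModelFacade:
    def test_model_fit_results_summary(self, two_ctx):
        _, corpus = two_ctx
        res = ss.PSTModel(corpus, STRICT).fit()
        assert res.train_nll > 0
        s = res.summary()
        assert "max depth" in s and "bits/phrase" in s
        pfa = res.to_pfa()
        assert len(pfa.states) >= 1

    def test_param_overrides(self, two_ctx):
        _, corpus = two_ctx
        m = ss.PSTModel(corpus, STRICT, p_min=0.5)
        assert m.params.p_min == 0.5 and m.params.r == STRICT.r
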