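"""Ground-truth model construction, corpus sampling, and contour rendering."""

import math
import warnings

import numpy as np
import pytest

import songsyntax as ss
from songsyntax.simulate import (
    EOS,
    ModelError,
    implied_context_statistics,
    make_ground_truth,
)


class TestMakeGroundTruth:
    def test_uniform_depth0(self):
        model = make_ground_truth(
            {
                "alphabet": ["A", "B", "C", "D"],
                "transitions": {
                    "": {s: 0.25 for s in "ABCD"},
                },
            }
        )
        dist = model.context_model[()]
        assert dist[EOS] == pytest.approx(0.125)
        for s in "ABCD":
            assert dist[s] == pytest.approx(0.25 * 0.875)

    def test_long_range_rule_spec(self):
        """A depth-3 rule (the entry phrase determines the exit three
        phrases later) can be declared directly."""
        base = {s: 1 / 6 for s in "TUBDKJ"}
        model = make_ground_truth(
            {
                "alphabet": list("TUBDKJ"),
                "transitions": {
                    "": base,
                    "T B D": {"K": 0.9, "T": 0.05, "U": 0.05},
                    "U B D": {"J": 0.9, "T": 0.05, "U": 0.05},
                },
            }
        )
        assert model.context_model[("T", "B", "D")]["K"] == pytest.approx(
            0.9 * 0.875
        )
        assert model.context_model[("U", "B", "D")]["J"] == pytest.approx(
            0.9 * 0.875
        )

    def test_bad_probability_sum_rejected(self):
        with pytest.raises(ModelError, match="sums to"):
            make_ground_truth(
                {
                    "alphabet": ["A", "B"],
                    "transitions": {"": {"A": 0.5, "B": 0.3}},
                }
            )


class TestSimulateCorpus:
    def test_deterministic_given_seed(self, two_ctx):
        model, _ = two_ctx
        cfg = ss.SimulationConfig(n_songs=40, seed=123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ss.simulate_corpus(model, cfg)
            b = ss.simulate_corpus(model, cfg)
        assert a.to_json() == b.to_json()

    def test_alternating_deterministic_model(self):
        model = make_ground_truth(
            {
                "alphabet": ["A", "B"],
                "transitions": {
                    "": {"A": 1.0},
                    "A": {"B": 1.0},
                    "B": {"A": 1.0},
                },
                "eos_probability": 0.2,
            }
        )
        corpus = ss.simulate_corpus(
            model, ss.SimulationConfig(n_songs=50, seed=0, min_phrases=2)
        )
        for seq in ss.corpus_to_sequences(corpus):
            assert seq == ["A", "B"] * (len(seq) // 2) + ["A"] * (
                len(seq) % 2
            )

    def test_depth0_symbol_frequencies(self):
        """Uniform depth-0 model: empirical frequencies within 3 binomial
        SE of uniform."""
        model = make_ground_truth(
            {
                "alphabet": list("ABCD"),
                "transitions": {"": {s: 0.25 for s in "ABCD"}},
            }
        )
        corpus = ss.simulate_corpus(
            model, ss.SimulationConfig(n_songs=200, seed=4)
        )
        from collections import Counter

        counts = Counter(
            s for seq in ss.corpus_to_sequences(corpus) for s in seq
        )
        n = sum(counts.values())
        se = math.sqrt(0.25 * 0.75 / n)
        for s in "ABCD":
            assert abs(counts[s] / n - 0.25) < 3 * se

    def test_phrase_durations_positive_and_lognormal_scale(self, two_ctx):
        _, corpus = two_ctx
        durs = [p.duration for s in corpus.songs for p in s.phrases]
        assert min(durs) > 0
        # median near the configured 1.35 s
        assert abs(float(np.median(durs)) - 1.35) < 0.1

    def test_duration_decoupled_from_syllable_duration(self):
        """Default generator: no correlation between per-phrase duration
        and syllable duration (|r| < 0.2 over >= 20 types)."""
        model = ss.default_model(seed=2)
        assert len(model.alphabet) >= 20
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corpus = ss.simulate_corpus(
                model, ss.SimulationConfig(n_songs=400, seed=8)
            )
        r, _p = ss.duration_syllable_correlation(
            ss.phrase_records(corpus), model.syllable_duration
        )
        assert abs(r) < 0.2

    def test_large_sample_context_recovery(self, two_ctx):
        """Empirical conditionals at the model's contexts converge to the
        implied population values (L_inf < 0.03 at 5000 songs)."""
        model, _ = two_ctx
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corpus = ss.simulate_corpus(
                model, ss.SimulationConfig(n_songs=5000, seed=17)
            )
        seqs = [tuple(s) for s in ss.corpus_to_sequences(corpus)]
        from songsyntax.pst import context_counts

        counts, n_pos = context_counts(seqs, l_max=2)
        implied, total = implied_context_statistics(model, max_len=2)
        for ctx in model.context_model:
            emp = counts[ctx]
            emp_tot = sum(emp.values())
            imp = implied[ctx]
            imp_tot = sum(imp.values())
            for s in model.alphabet:
                err = abs(
                    emp.get(s, 0) / emp_tot - imp.get(s, 0.0) / imp_tot
                )
                assert err < 0.03, (ctx, s, err)

    def test_syllable_repeat_counts_implied(self, two_ctx):
        model, corpus = two_ctx
        for song in corpus.songs[:20]:
            for p in song.phrases:
                repeats = max(
                    1, round(p.duration / model.syllable_duration[p.label])
                )
                assert repeats >= 1


class TestRecoveryFactory:
    def test_declared_nodes_are_suffix_closed(self, recovery_truth):
        nodes = recovery_truth.nodes
        for ctx in nodes:
            if ctx:
                assert ctx[1:] in nodes

    def test_implied_statistics_are_proper(self, recovery_truth):
        gt = recovery_truth
        uni = {
            s: gt.implied_counts[()][s] / gt.implied_positions
            for s in gt.model.alphabet
        }
        assert abs(sum(uni.values()) - 1) < 1e-9
        assert min(uni.values()) >= 0.035  # all conditionals estimable


class TestSimulateContours:
    def test_no_jitter_no_dropout_identical(self, two_ctx):
        model, _ = two_ctx
        model.jitter_scale = 0.0
        model.dropout = 0.0
        lab = model.alphabet[0]
        imgs = ss.simulate_contours(model, lab, 5, seed=3)
        model.jitter_scale, model.dropout = 1.5, 0.05
        assert all((im.pixels == imgs[0].pixels).all() for im in imgs)
        assert imgs[0].pixels.sum() > 0

    def test_full_dropout_all_zero(self, two_ctx):
        model, _ = two_ctx
        model.dropout = 1.0
        try:
            imgs = ss.simulate_contours(model, model.alphabet[0], 3, seed=1)
        finally:
            model.dropout = 0.05
        assert all(im.pixels.sum() == 0 for im in imgs)

    def test_missing_template_errors(self, two_ctx):
        model, _ = two_ctx
        with pytest.raises(ModelError, match="template"):
            ss.simulate_contours(model, "no-such-label", 3)

    def test_group_shift_separates_groups(self, two_ctx):
        """Template shift: cross-group d' exceeds within-group d'."""
        model, _ = two_ctx
        lab = model.alphabet[0]
        a = ss.simulate_contours(model, lab, 80, seed=1, group="a")
        b = ss.simulate_contours(model, lab, 80, seed=2, group="b")
        c = ss.simulate_contours(
            model, lab, 80, group_shift=(0, 10), seed=3, group="c"
        )
        within = ss.dprime(
            ss.similarity_scores(a, ss.spectral_density(b)),
            ss.similarity_scores(b, ss.spectral_density(b)),
        )
        cross = ss.dprime(
            ss.similarity_scores(a, ss.spectral_density(b)),
            ss.similarity_scores(c, ss.spectral_density(b)),
        )
        assert cross > within
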