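"""Tercile discretization, contingency tables, and the Monte Carlo
Fisher-Freeman-Halton test against exact enumeration oracles."""

import math
import warnings
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import songsyntax as ss
from songsyntax.contingency import (
    ContingencyError,
    ContingencyTable,
    _log_table_probability,
    build_md_table,
    discretize_terciles,
    ffh_test,
    transition_vs_repetition,
)


def exact_ffh_2x2(tab: np.ndarray) -> float:
    """Exact two-sided Fisher p by enumeration over all margin-consistent
    2x2 tables (probability-ordering convention)."""
    r = tab.sum(1)
    c = tab.sum(0)
    obs = _log_table_probability(tab)
    p = 0.0
    for a in range(min(r[0], c[0]) + 1):
        t = np.array([[a, r[0] - a], [c[0] - a, r[1] - (c[0] - a)]])
        if (t < 0).any():
            continue
        lp = _log_table_probability(t)
        if lp <= obs + 1e-9:
            p += math.exp(lp)
    return p


class TestTerciles:
    def test_six_values(self):
        assert discretize_terciles([1, 2, 3, 4, 5, 6]).tolist() == [
            0, 0, 1, 1, 2, 2,
        ]

    def test_all_equal_warns_lower_bin(self):
        with pytest.warns(UserWarning, match="degenerate"):
            bins = discretize_terciles([2.0] * 10)
        assert (bins == 0).all()

    def test_lognormal_draws_balanced(self):
        """Quantile oracle: 3000 draws put ~1000 in each bin."""
        rng = np.random.default_rng(0)
        d = rng.lognormal(0.3, 0.2, 3000)
        counts = Counter(discretize_terciles(d).tolist())
        for b in (0, 1, 2):
            assert abs(counts[b] - 1000) <= 2  # continuous data: ties rare

    def test_too_few_values(self):
        with pytest.raises(ContingencyError):
            discretize_terciles([1.0, 2.0])


class TestBuildTable:
    def test_degenerate_single_cell_flagged(self):
        recs = [
            ss.PhraseRecord("B", 1.0 + 0.01 * i, "A", "C", 1, f"s{i}")
            for i in range(12)
        ]
        table = build_md_table(recs, "B", "MD(path_in,path_out)")
        assert table.degenerate

    def test_total_conserved(self, two_ctx):
        _, corpus = two_ctx
        recs = ss.phrase_records(corpus)
        lab = max(
            corpus.alphabet,
            key=lambda l: sum(r.label == l for r in recs),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_md_table(recs, lab, "MD(path_in,path_out)")
        usable = sum(
            1
            for r in recs
            if r.label == lab
            and r.prev_label != ss.BOUNDARY
            and r.next_label != ss.BOUNDARY
        )
        assert table.total == usable

    def test_min_count_skip_warns(self):
        recs = [
            ss.PhraseRecord("B", 1.0, "A", "C", 1, "s0"),
            ss.PhraseRecord("B", 1.2, "A", "D", 1, "s1"),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            assert build_md_table(recs, "B", "MD(dur,path_out)") is None

    def test_duration_coupled_rule_concentrates_table(self):
        """Generator rule short->C, long->D shows up as mass on the
        (low tercile, C) and (high tercile, D) cells."""
        corpus = ss.duration_coupled_corpus(seed=3, n_songs=300)
        recs = ss.phrase_records(corpus)
        table = build_md_table(recs, "B", "MD(dur,path_out)")
        counts = {
            (r, c): int(table.counts[i, j])
            for i, r in enumerate(table.row_labels)
            for j, c in enumerate(table.col_labels)
        }
        on_rule = counts.get(("T0", "C"), 0) + counts.get(("T2", "D"), 0)
        off_rule = counts.get(("T0", "D"), 0) + counts.get(("T2", "C"), 0)
        assert on_rule > 5 * max(off_rule, 1)
        res = ffh_test(table, n_randomizations=20_000, seed=0)
        assert res.p_value < 0.001


class TestFFH:
    def test_diagonal_table_matches_closed_form(self):
        """[[10,0],[0,10]]: exact p = 2 / C(20,10)."""
        table = ContingencyTable(
            np.array([[10, 0], [0, 10]]), ["r0", "r1"], ["c0", "c1"]
        )
        res = ffh_test(table, n_randomizations=200_000, seed=11)
        p_exact = 2 / math.comb(20, 10)
        se = math.sqrt(p_exact * (1 - p_exact) / 200_000)
        assert abs(res.p_value - p_exact) < 3 * se + 1 / 200_000

    def test_modal_table_p_near_one(self):
        table = ContingencyTable(
            np.array([[5, 5], [5, 5]]), ["r0", "r1"], ["c0", "c1"]
        )
        p_exact = exact_ffh_2x2(table.counts)
        res = ffh_test(table, n_randomizations=50_000, seed=2)
        assert p_exact > 0.9
        assert abs(res.p_value - p_exact) < 0.02

    def test_degenerate_single_row(self):
        table = ContingencyTable(
            np.array([[3, 4, 5], [0, 0, 0]]), ["r0", "r1"], list("abc")
        )
        res = ffh_test(table, n_randomizations=100, seed=0)
        assert res.degenerate and res.p_value == 1.0

    def test_agrees_with_enumeration_on_random_tables(self):
        """Monte Carlo within 3 SE of exhaustive enumeration, 2x2 tables."""
        rng = np.random.default_rng(5)
        n_rand = 30_000
        for _ in range(8):
            while True:
                tab = rng.integers(0, 8, (2, 2))
                if (
                    10 <= tab.sum() <= 40
                    and (tab.sum(0) > 0).all()
                    and (tab.sum(1) > 0).all()
                ):
                    break
            ct = ContingencyTable(tab, ["a", "b"], ["x", "y"])
            res = ffh_test(ct, n_randomizations=n_rand,
                           seed=int(rng.integers(2**31)))
            pe = exact_ffh_2x2(tab)
            se = math.sqrt(max(pe * (1 - pe), 1e-12) / n_rand)
            assert abs(res.p_value - pe) < 3 * se + 2 / n_rand, tab

    def test_margins_preserved_by_sampler(self):
        """Every Monte Carlo table has exactly the observed margins."""
        tab = np.array([[6, 2, 1], [0, 5, 3], [2, 2, 4]])
        dist = stats.random_table(tab.sum(1), tab.sum(0))
        samples = dist.rvs(200, random_state=np.random.default_rng(0))
        assert (samples.sum(axis=2) == tab.sum(1)).all()
        assert (samples.sum(axis=1) == tab.sum(0)).all()

    def test_p_value_never_zero_and_reproducible(self):
        table = ContingencyTable(
            np.array([[20, 0], [0, 20]]), ["r0", "r1"], ["c0", "c1"]
        )
        a = ffh_test(table, n_randomizations=5000, seed=3)
        b = ffh_test(table, n_randomizations=5000, seed=3)
        assert a.p_value == b.p_value
        assert a.p_value >= 1 / 5001


class TestMutualDependenceFacade:
    def test_model_fit_summary(self):
        corpus = ss.duration_coupled_corpus(seed=1, n_songs=200)
        res = ss.MutualDependence(corpus, "B", "MD(dur,path_out)").fit(
            n_randomizations=5000, seed=0
        )
        assert res.p_value < 0.01
        assert "MD(dur,path_out)" in res.summary()


class TestTransitionVsRepetition:
    @staticmethod
    def _corpus_with_decay(p_by_k, n_songs=400, seed=0):
        """Songs X g X g X g ... where P(next=G | k-th X) is programmed."""
        rng = np.random.default_rng(seed)
        songs = []
        for i in range(n_songs):
            labs = []
            for k, p in enumerate(p_by_k):
                labs.append("X")
                labs.append("G" if rng.random() < p else "S")
            t = 0.0
            phrases = []
            sid = f"s{i:04d}"
            for lab in labs:
                phrases.append(ss.PhraseAnnotation(t, t + 1.0, lab, sid))
                t += 1.05
            songs.append(ss.Song(sid, phrases))
        return ss.Corpus(songs=songs)

    def test_programmed_decay_detected(self):
        corpus = self._corpus_with_decay([0.9, 0.6, 0.35])
        table = transition_vs_repetition(corpus, "X")
        assert table.modal_next == "G"
        assert table.classification == "strictly decreasing"

    def test_occurrence_independent_homogeneous(self):
        """Chi-square homogeneity across occurrence index not rejected."""
        corpus = self._corpus_with_decay([0.6, 0.6, 0.6], seed=3)
        table = transition_vs_repetition(corpus, "X")
        mat = np.array(
            [
                [e["counts"].get("G", 0), e["counts"].get("S", 0)]
                for e in table.per_k
            ]
        )
        _chi, p, _dof, _exp = stats.chi2_contingency(mat)
        assert p > 0.01

    def test_per_k_counts_conserved(self):
        corpus = self._corpus_with_decay([0.5, 0.5])
        table = transition_vs_repetition(corpus, "X")
        for e in table.per_k:
            n_songs_with_k = sum(
                1
                for song in corpus.songs
                if [p.label for p in song.phrases].count("X") >= e["k"]
            )
            assert e["n"] == n_songs_with_k


class TestDurationSyllableCorrelation:
    def test_proportional_gives_r_one(self):
        syl = {"A": 0.05, "B": 0.1, "C": 0.2}
        recs = [
            ss.PhraseRecord(lab, 10 * syl[lab], "A", "B", 0, "s")
            for lab in "ABC" for _ in range(5)
        ]
        r, p = ss.duration_syllable_correlation(recs, syl)
        assert r == pytest.approx(1.0)

    def test_too_few_labels(self):
        recs = [
            ss.PhraseRecord("A", 1.0, "B", "B", 0, "s"),
            ss.PhraseRecord("B", 2.0, "A", "A", 1, "s"),
        ]
        with pytest.raises(ContingencyError):
            ss.duration_syllable_correlation(recs, {"A": 0.1, "B": 0.2})
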