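"""Mutual-dependence tests between phrase duration and song path.

For each phrase type Y (the *center* label), a phrase triple X-Y-Z asks three
questions: does the duration of Y depend on the entry path X
(``MD(dur,path_in)``), on the exit path Z (``MD(dur,path_out)``), and does X
predict Z given Y (``MD(path_in,path_out)``)?  Durations are discretized by
terciles; each question becomes an R x C contingency table tested for
independence with the Fisher-Freeman-Halton test — the generalisation of
Fisher's exact test to arbitrary tables — evaluated by Monte Carlo: tables
are sampled from the fixed-margins (multivariate hypergeometric) null and
the p-value is the add-one fraction of samples whose conditional probability
is at most that of the observed table (the probability-ordering, two-sided
convention).

This module also carries the simple-pattern (adaptation) test — does a
transition probability change with the number of times its source phrase has
occurred in the song? — and the phrase-vs-syllable duration correlation.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .annotations import BOUNDARY, Corpus, PhraseRecord, phrase_records

__all__ = [
    "ContingencyTable",
    "MDResult",
    "discretize_terciles",
    "build_md_table",
    "ffh_test",
    "MutualDependence",
    "md_report",
    "transition_vs_repetition",
    "RepetitionTable",
    "duration_syllable_correlation",
]

MD_TESTS = ("MD(dur,path_in)", "MD(dur,path_out)", "MD(path_in,path_out)")


class ContingencyError(ValueError):
    pass


def discretize_terciles(durations: Sequence[float]) -> np.ndarray:
    """Tercile bin (0, 1, 2) of each duration.

    Cut points are the empirical 1/3 and 2/3 quantiles; values equal to a
    cut point go to the lower bin.
    """
    d = np.asarray(durations, float)
    if d.size < 3:
        raise ContingencyError("need at least 3 durations for terciles")
    q1, q2 = np.quantile(d, [1 / 3, 2 / 3])
    if q1 == q2:
        if np.all(d == d[0]):
            warnings.warn("degenerate duration spread: all values equal")
            return np.zeros(d.size, dtype=int)
    bins = np.where(d <= q1, 0, np.where(d <= q2, 1, 2))
    return bins.astype(int)


@dataclass
class ContingencyTable:
    """R x C counts with labeled factors; margins are derived."""

    counts: np.ndarray
    row_labels: list
    col_labels: list
    center_label: str = ""
    test_name: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ContingencyError("counts must be 2-D")
        if (c < 0).any():
            raise ContingencyError("counts must be non-negative")
        if c.sum() < 1:
            raise ContingencyError("table total must be >= 1")
        self.counts = c.astype(np.int64)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def drop_empty(self) -> "ContingencyTable":
        rows = self.row_margins > 0
        cols = self.col_margins > 0
        return ContingencyTable(
            counts=self.counts[np.ix_(rows, cols)],
            row_labels=[l for l, k in zip(self.row_labels, rows) if k],
            col_labels=[l for l, k in zip(self.col_labels, cols) if k],
            center_label=self.center_label,
            test_name=self.test_name,
        )

    @property
    def degenerate(self) -> bool:
        t = self.drop_empty()
        return t.counts.shape[0] < 2 or t.counts.shape[1] < 2

    @classmethod
    def from_factors(
        cls,
        row_factor: Sequence,
        col_factor: Sequence,
        center_label: str = "",
        test_name: str = "",
    ) -> "ContingencyTable":
        rows = sorted(set(row_factor), key=str)
        cols = sorted(set(col_factor), key=str)
        ri = {v: i for i, v in enumerate(rows)}
        ci = {v: i for i, v in enumerate(cols)}
        counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
        for rv, cv in zip(row_factor, col_factor):
            counts[ri[rv], ci[cv]] += 1
        return cls(counts, rows, cols, center_label, test_name)


def build_md_table(
    records: Sequence[PhraseRecord],
    center_label: str,
    test_name: str,
    min_count: int = 10,
    include_boundary: bool = False,
    tercile_scope: str = "per-type",
) -> ContingencyTable | None:
    """Contingency table for one mutual-dependence test at one center label.

    Boundary-marker neighbours are excluded by default: song edges are not
    phrase choices.  Duration terciles are computed per phrase type by
    default (``tercile_scope="global"`` uses corpus-wide cut points instead).
    Returns None (with a warning) when fewer than ``min_count`` observations
    survive the exclusions.
    """
    if test_name not in MD_TESTS:
        raise ContingencyError(
            f"unknown test {test_name!r}; expected one of {MD_TESTS}"
        )
    center = [r for r in records if r.label == center_label]
    if not center:
        raise ContingencyError(f"center label {center_label!r} not found")
    need_prev = test_name in ("MD(dur,path_in)", "MD(path_in,path_out)")
    need_next = test_name in ("MD(dur,path_out)", "MD(path_in,path_out)")
    if not include_boundary:
        if need_prev:
            center = [r for r in center if r.prev_label != BOUNDARY]
        if need_next:
            center = [r for r in center if r.next_label != BOUNDARY]
    if len(center) < max(min_count, 3):
        warnings.warn(
            f"{test_name} at {center_label!r}: only {len(center)} usable "
            f"observations (< {min_count}); skipped"
        )
        return None

    if test_name == "MD(path_in,path_out)":
        rows = [r.prev_label for r in center]
        cols = [r.next_label for r in center]
    else:
        if tercile_scope == "per-type":
            bins = discretize_terciles([r.duration for r in center])
        elif tercile_scope == "global":
            all_d = [r.duration for r in records]
            q1, q2 = np.quantile(np.asarray(all_d), [1 / 3, 2 / 3])
            d = np.asarray([r.duration for r in center])
            bins = np.where(d <= q1, 0, np.where(d <= q2, 1, 2)).astype(int)
        else:
            raise ContingencyError(
                f"unknown tercile_scope {tercile_scope!r}"
            )
        rows = [f"T{b}" for b in bins]
        cols = [
            r.next_label if test_name == "MD(dur,path_out)" else r.prev_label
            for r in center
        ]
    table = ContingencyTable.from_factors(
        rows, cols, center_label=center_label, test_name=test_name
    ).drop_empty()
    if table.degenerate:
        warnings.warn(
            f"{test_name} at {center_label!r}: degenerate "
            f"{table.counts.shape} table"
        )
    return table


# ---------------------------------------------------------------------------
# Fisher-Freeman-Halton Monte Carlo test


def _log_table_probability(counts: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given its
    margins (the FFH test statistic)."""
    counts = np.asarray(counts, dtype=np.int64)
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


@dataclass
class MDResult:
    """Monte Carlo Fisher-Freeman-Halton test result."""

    test_name: str
    center_label: str
    statistic: float  # log probability of the observed table given margins
    p_value: float
    n_randomizations: int
    seed: int
    table: ContingencyTable | None = None
    degenerate: bool = False
    n_obs: int = 0

    def summary(self) -> str:
        flag = " (degenerate: no dependence testable)" if self.degenerate else ""
        return (
            f"{self.test_name} @ {self.center_label!r}: "
            f"p = {self.p_value:.3g} "
            f"(log table prob {self.statistic:.3f}, n = {self.n_obs}, "
            f"{self.n_randomizations} randomizations){flag}"
        )


def ffh_test(
    table: ContingencyTable,
    n_randomizations: int = 100_000,
    seed: int = 0,
    batch: int = 20_000,
) -> MDResult:
    """Fisher-Freeman-Halton exact test, evaluated by Monte Carlo.

    Tables are sampled from the fixed-margins null (Patefield's algorithm,
    via scipy's ``random_table``) and the two-sided p-value is the add-one
    fraction whose conditional probability is as small or smaller than the
    observed table's:  p = (1 + #{P(T*) <= P(obs)}) / (1 + n_randomizations).
    Empty rows/columns are dropped first; a table with a single row or
    column after dropping is flagged degenerate with p = 1.
    """
    if n_randomizations < 1:
        raise ContingencyError("n_randomizations must be >= 1")
    t = table.drop_empty()
    if t.degenerate:
        return MDResult(
            test_name=table.test_name,
            center_label=table.center_label,
            statistic=_log_table_probability(t.counts),
            p_value=1.0,
            n_randomizations=n_randomizations,
            seed=seed,
            table=t,
            degenerate=True,
            n_obs=t.total,
        )
    obs_logp = _log_table_probability(t.counts)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(t.row_margins, t.col_margins)

    # the margin terms of log P(T) are fixed by the null, so only the cell
    # term sum(gammaln(n_ij + 1)) needs evaluating per sample
    obs_cell = gammaln(t.counts + 1).sum()

    extreme = 0
    remaining = n_randomizations
    while remaining > 0:
        m = min(batch, remaining)
        samples = dist.rvs(m, random_state=rng)
        cell_terms = gammaln(samples + 1).sum(axis=(1, 2))
        # smaller probability <=> larger cell term
        extreme += int(np.sum(cell_terms >= obs_cell - 1e-9))
        remaining -= m
    p = (1 + extreme) / (1 + n_randomizations)
    return MDResult(
        test_name=table.test_name,
        center_label=table.center_label,
        statistic=obs_logp,
        p_value=float(p),
        n_randomizations=n_randomizations,
        seed=seed,
        table=t,
        degenerate=False,
        n_obs=t.total,
    )


class MutualDependence:
    """Mutual-dependence model for one center label and test.

    Statsmodels-style facade: construct from a corpus or phrase records,
    ``fit()`` runs the Monte Carlo FFH test and returns an :class:`MDResult`.
    """

    def __init__(
        self,
        data: Corpus | Sequence[PhraseRecord],
        center_label: str,
        test_name: str,
        min_count: int = 10,
        include_boundary: bool = False,
        tercile_scope: str = "per-type",
    ):
        records = (
            phrase_records(data) if isinstance(data, Corpus) else list(data)
        )
        self.center_label = center_label
        self.test_name = test_name
        self.table = build_md_table(
            records,
            center_label,
            test_name,
            min_count=min_count,
            include_boundary=include_boundary,
            tercile_scope=tercile_scope,
        )

    def fit(self, n_randomizations: int = 100_000, seed: int = 0) -> MDResult:
        if self.table is None:
            raise ContingencyError(
                f"too few observations for {self.test_name} at "
                f"{self.center_label!r}"
            )
        return ffh_test(self.table, n_randomizations, seed)


def md_report(
    corpus: Corpus,
    tests: Sequence[str] = MD_TESTS,
    n_randomizations: int = 100_000,
    alpha: float = 0.001,
    min_count: int = 10,
    seed: int = 0,
    tercile_scope: str = "per-type",
):
    """Run mutual-dependence tests for every phrase type; tabulate results.

    Reports per-test p-values at significance level ``alpha`` (no
    multiple-testing correction is applied; the number of tests run is part
    of the report).  Returns a pandas DataFrame.
    """
    import pandas as pd

    records = phrase_records(corpus)
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(corpus.alphabet):
        for test in tests:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = build_md_table(
                    records,
                    label,
                    test,
                    min_count=min_count,
                    tercile_scope=tercile_scope,
                )
            if table is None:
                rows.append(
                    {
                        "center_label": label,
                        "test": test,
                        "n_obs": 0,
                        "p_value": float("nan"),
                        "significant": False,
                        "status": "skipped",
                    }
                )
                continue
            res = ffh_test(
                table, n_randomizations, seed=int(rng.integers(2**31))
            )
            rows.append(
                {
                    "center_label": label,
                    "test": test,
                    "n_obs": res.n_obs,
                    "p_value": res.p_value,
                    "significant": (not res.degenerate)
                    and res.p_value < alpha,
                    "status": "degenerate" if res.degenerate else "ok",
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["n_tests_run"] = int((df["status"] != "skipped").sum())
    df.attrs["alpha"] = alpha
    return df


# ---------------------------------------------------------------------------
# simple-pattern (adaptation) test


@dataclass
class RepetitionTable:
    """Next-phrase distributions by occurrence index of a source phrase."""

    from_label: str
    modal_next: str
    per_k: list[dict]  # k, n, counts, modal probability
    classification: str  # strictly increasing / strictly decreasing / non-monotonic
    min_n: int

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "k": e["k"],
                    "n": e["n"],
                    "p_modal": e["p_modal"],
                    **{f"p({s})": p for s, p in e["probs"].items()},
                }
                for e in self.per_k
            ]
        )


def transition_vs_repetition(
    corpus: Corpus, from_label: str, min_n: int = 5
) -> RepetitionTable:
    """Does the modal transition probability from a phrase change with its
    repetition number within the song?

    For the k-th occurrence of ``from_label`` in each song, the empirical
    next-phrase distribution is tabulated; the modal transition (the overall
    most frequent next phrase) is then classified as strictly increasing,
    strictly decreasing, or non-monotonic across occurrence indices with at
    least ``min_n`` observations.
    """
    per_k_counts: dict[int, Counter] = defaultdict(Counter)
    any_multi = False
    for song in corpus.songs:
        labels = song.labels()
        k = 0
        for i, lab in enumerate(labels):
            if lab != from_label:
                continue
            k += 1
            if i + 1 < len(labels):
                per_k_counts[k][labels[i + 1]] += 1
        if k >= 2:
            any_multi = True
    if not per_k_counts:
        raise ContingencyError(
            f"label {from_label!r} never followed by another phrase"
        )
    if not any_multi:
        warnings.warn(
            f"no song contains {from_label!r} twice; repetition table empty"
        )

    overall: Counter = Counter()
    for c in per_k_counts.values():
        overall.update(c)
    modal = overall.most_common(1)[0][0]

    per_k = []
    for k in sorted(per_k_counts):
        c = per_k_counts[k]
        n = sum(c.values())
        per_k.append(
            {
                "k": k,
                "n": n,
                "counts": dict(c),
                "probs": {s: v / n for s, v in c.items()},
                "p_modal": c.get(modal, 0) / n,
            }
        )

    usable = [e["p_modal"] for e in per_k if e["n"] >= min_n]
    if len(usable) < 2:
        classification = "insufficient data"
    else:
        diffs = np.diff(usable)
        if np.all(diffs > 0):
            classification = "strictly increasing"
        elif np.all(diffs < 0):
            classification = "strictly decreasing"
        else:
            classification = "non-monotonic"
    return RepetitionTable(
        from_label=from_label,
        modal_next=modal,
        per_k=per_k,
        classification=classification,
        min_n=min_n,
    )


# ---------------------------------------------------------------------------
# duration vs syllable-length correlation


def duration_syllable_correlation(
    records: Sequence[PhraseRecord],
    syllable_durations: Mapping[str, float],
) -> tuple[float, float]:
    """Pearson correlation between each phrase's duration and the duration
    of its underlying syllable type, with a two-sided p-value."""
    labels = {r.label for r in records}
    if len(labels) < 3:
        raise ContingencyError(
            "need phrases of at least 3 types for a meaningful correlation"
        )
    missing = labels - set(syllable_durations)
    if missing:
        raise ContingencyError(
            f"no syllable duration for labels: {sorted(missing)}"
        )
    x = np.array([syllable_durations[r.label] for r in records])
    y = np.array([r.duration for r in records])
    if x.size < 3:
        raise ContingencyError("need at least 3 phrases")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ContingencyError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
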