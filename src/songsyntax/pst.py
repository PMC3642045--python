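"""Prediction suffix trees (variable-order Markov models) over phrase sequences.

A prediction suffix tree (PST) stores a set of *contexts* — suffixes of the
recent past, most-recent symbol last — each carrying a next-symbol
distribution.  Prediction uses the deepest context matching the history, so
the model is a collection of Markov chains of varying order, one branch per
phrase type.  Learning follows the classic grow-from-the-root scheme: a
candidate context is kept only if it occurs often enough (frequency at least
``p_min`` of all phrase positions) and changes the prediction relative to its
one-shorter suffix by at least a multiplicative factor ``r`` for some symbol
with conditional probability at least ``alpha``.  Ancestors of retained
contexts are added as *internal* nodes: they connect the leaves to the trunk
without earning their place, and maximal runs of them can be collapsed into
monolithic sequence "chunks" (:func:`collapse_internal_nodes`).

Counting never crosses song boundaries; contexts are truncated at song start
(no artificial start symbol).  All likelihoods are in bits (log base 2) and,
unless stated otherwise, averaged per phrase.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PSTParams",
    "PSTNode",
    "PST",
    "PSTError",
    "context_counts",
    "fit_pst",
    "fit_pst_from_counts",
    "pst_nll",
    "crossvalidate_pst",
    "CVReport",
    "collapse_internal_nodes",
    "ChunkCollapseResult",
    "param_grid",
    "PSTModel",
    "PSTResults",
]

Context = tuple[str, ...]
LOG2 = math.log(2.0)


class PSTError(ValueError):
    pass


@dataclass(frozen=True)
class PSTParams:
    """Learning parameters.

    p_min
        Minimum context frequency (fraction of phrase positions) for a
        context to be considered.
    r
        Growth ratio: a context is retained when some next-symbol probability
        changes by a factor >= r (or <= 1/r) relative to its parent suffix.
    gamma_min
        Smoothing floor; every smoothed probability is at least this.
    alpha
        Minimum conditional probability a symbol must reach in the candidate
        context for its ratio to count as evidence.
    l_max
        Maximum context length (tree depth cap).
    """

    p_min: float = 0.007
    r: float = 1.05
    gamma_min: float = 0.001
    alpha: float = 0.0
    l_max: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.p_min <= 1:
            raise PSTError("p_min must be in (0, 1]")
        if not self.r > 1:
            raise PSTError("growth ratio r must exceed 1")
        if not 0 <= self.gamma_min < 1:
            raise PSTError("gamma_min must be in [0, 1)")
        if not 0 <= self.alpha < 1:
            raise PSTError("alpha must be in [0, 1)")
        if self.l_max < 0:
            raise PSTError("l_max must be >= 0")


@dataclass
class PSTNode:
    context: Context
    raw_counts: dict[str, float]
    smoothed_probs: dict[str, float]
    frequency: float
    is_internal: bool = False

    @property
    def raw_probs(self) -> dict[str, float]:
        tot = sum(self.raw_counts.values())
        return {s: c / tot for s, c in self.raw_counts.items()}


@dataclass
class PST:
    alphabet: tuple[str, ...]
    nodes: dict[Context, PSTNode]
    params: PSTParams

    def __post_init__(self) -> None:
        if () not in self.nodes:
            raise PSTError("PST must contain the root (empty context)")
        for ctx in self.nodes:
            if len(ctx) >= 1 and ctx[1:] not in self.nodes:
                raise PSTError(f"suffix closure violated at context {ctx}")

    @property
    def depth(self) -> int:
        return max(len(c) for c in self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def deepest_context(self, history: Sequence[str]) -> Context:
        """Longest suffix of ``history`` that is a node (the active context).

        Because the tree is suffix-closed the search can extend one symbol at
        a time and stop at the first miss.
        """
        h = tuple(history)
        ctx: Context = ()
        for l in range(1, min(len(h), self.depth) + 1):
            cand = h[len(h) - l :]
            if cand in self.nodes:
                ctx = cand
            else:
                break
        return ctx

    def predict(self, history: Sequence[str]) -> dict[str, float]:
        """Smoothed next-symbol distribution given a history."""
        return self.nodes[self.deepest_context(history)].smoothed_probs

    def leaves(self) -> list[Context]:
        non_leaf = {c[1:] for c in self.nodes if c}
        return [c for c in self.nodes if c not in non_leaf or c == ()]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "songsyntax-pst",
                "version": 1,
                "alphabet": list(self.alphabet),
                "params": vars(self.params) | {},
                "nodes": [
                    {
                        "context": list(n.context),
                        "raw_counts": n.raw_counts,
                        "smoothed_probs": n.smoothed_probs,
                        "frequency": n.frequency,
                        "is_internal": n.is_internal,
                    }
                    for n in self.nodes.values()
                ],
            },
            ensure_ascii=False,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PST":
        doc = json.loads(text)
        if doc.get("format") != "songsyntax-pst":
            raise PSTError("not a songsyntax PST document")
        params = PSTParams(**doc["params"])
        nodes = {}
        for nd in doc["nodes"]:
            ctx = tuple(nd["context"])
            nodes[ctx] = PSTNode(
                context=ctx,
                raw_counts=dict(nd["raw_counts"]),
                smoothed_probs=dict(nd["smoothed_probs"]),
                frequency=nd["frequency"],
                is_internal=nd["is_internal"],
            )
        return cls(tuple(doc["alphabet"]), nodes, params)

    def to_dot(self, max_edges_per_node: int = 4) -> str:
        """GraphViz DOT rendering: one graph node per context, sized by
        frequency, labeled with its top next-symbol probabilities."""
        lines = [
            "digraph pst {",
            '  graph [layout=twopi, ranksep=1.5, overlap=false];',
            "  node [shape=circle, style=filled, fillcolor=lightgray];",
        ]

        def nid(ctx: Context) -> str:
            return '"%s"' % ("·".join(ctx) if ctx else "root")

        for ctx, node in sorted(self.nodes.items(), key=lambda kv: kv[0]):
            top = sorted(
                node.smoothed_probs.items(), key=lambda kv: -kv[1]
            )[:max_edges_per_node]
            label = ("".join(ctx) if ctx else "root") + "\\n" + " ".join(
                f"{s}:{p:.2f}" for s, p in top
            )
            width = 0.3 + 2.0 * math.sqrt(node.frequency)
            style = "dashed" if node.is_internal else "solid"
            lines.append(
                f"  {nid(ctx)} [label=\"{label}\", width={width:.2f}, "
                f"style=\"filled,{style}\"];"
            )
            if ctx:
                lines.append(f"  {nid(ctx[1:])} -> {nid(ctx)};")
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# counting and learning


def _as_tuples(sequences: Iterable[Sequence[str]]) -> list[tuple[str, ...]]:
    seqs = [tuple(s) for s in sequences]
    if not seqs or all(len(s) == 0 for s in seqs):
        raise PSTError("no phrase sequences given")
    return seqs


def context_counts(
    sequences: Iterable[Sequence[str]], l_max: int
) -> tuple[dict[Context, dict[str, float]], int]:
    """Next-symbol counts for every within-song context up to length l_max.

    A context of length l is *active* at phrase position t of a song when the
    l symbols before t equal it; counting starts fresh in every song (no
    cross-song windows) and contexts are truncated at song start.  Returns
    ``(counts, n_positions)`` where n_positions is the total phrase count.
    """
    counts: dict[Context, dict[str, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    n_positions = 0
    for song in _as_tuples(sequences):
        n = len(song)
        n_positions += n
        for t in range(n):
            sym = song[t]
            for l in range(0, min(t, l_max) + 1):
                counts[song[t - l : t]][sym] += 1.0
    return {c: dict(d) for c, d in counts.items()}, n_positions


def fit_pst_from_counts(
    counts: Mapping[Context, Mapping[str, float]],
    n_positions: float,
    alphabet: Sequence[str],
    params: PSTParams,
) -> PST:
    """Build a PST from (possibly expected/weighted) context counts.

    This is the learning core shared by :func:`fit_pst` (empirical counts)
    and by analytic large-sample analyses that supply expected counts.
    """
    alphabet = tuple(sorted(set(alphabet)))
    k = len(alphabet)
    if k == 0:
        raise PSTError("empty alphabet")
    if params.gamma_min * k >= 1:
        raise PSTError(
            f"|alphabet| * gamma_min = {k * params.gamma_min:.3f} must be < 1"
        )
    totals = {c: sum(d.values()) for c, d in counts.items()}

    retained: set[Context] = set()
    for ctx, d in counts.items():
        l = len(ctx)
        if l == 0 or l > params.l_max:
            continue
        if totals[ctx] / n_positions < params.p_min:
            continue
        parent = ctx[1:]
        tot_c = totals[ctx]
        tot_p = totals[parent]
        for sym, c in d.items():
            p_child = c / tot_c
            if p_child <= 0 or p_child < params.alpha:
                continue
            p_parent = counts[parent].get(sym, 0.0) / tot_p
            if p_parent == 0:
                retained.add(ctx)  # symbol unseen in parent mix: maximal gain
                break
            ratio = p_child / p_parent
            if ratio >= params.r or ratio <= 1.0 / params.r:
                retained.add(ctx)
                break

    keep: set[Context] = {()}
    for ctx in retained:
        for l in range(len(ctx) + 1):
            keep.add(ctx[l:])

    gamma = params.gamma_min
    nodes: dict[Context, PSTNode] = {}
    for ctx in keep:
        d = counts.get(ctx, {})
        tot = sum(d.values())
        if tot == 0:
            raise PSTError(f"retained context {ctx} has no observations")
        smoothed = {
            s: (d.get(s, 0.0) / tot) * (1.0 - k * gamma) + gamma
            for s in alphabet
        }
        nodes[ctx] = PSTNode(
            context=ctx,
            raw_counts=dict(d),
            smoothed_probs=smoothed,
            frequency=tot / n_positions,
            is_internal=(ctx != () and ctx not in retained),
        )
    return PST(alphabet=alphabet, nodes=nodes, params=params)


def fit_pst(
    sequences: Iterable[Sequence[str]], params: PSTParams | None = None
) -> PST:
    """Learn a prediction suffix tree from phrase sequences."""
    params = params or PSTParams()
    seqs = _as_tuples(sequences)
    alphabet = sorted({s for song in seqs for s in song})
    counts, n_pos = context_counts(seqs, params.l_max)
    return fit_pst_from_counts(counts, n_pos, alphabet, params)


# ---------------------------------------------------------------------------
# likelihood


def pst_nll(
    pst: PST, sequences: Iterable[Sequence[str]], total: bool = False
) -> float:
    """Average negative log-likelihood in bits per phrase.

    Each phrase position is scored with the smoothed distribution of the
    deepest matching context; ``total=True`` returns summed bits instead of
    the per-phrase average.
    """
    seqs = _as_tuples(sequences)
    known = set(pst.alphabet)
    bits = 0.0
    n = 0
    for song in seqs:
        for sym in song:
            if sym not in known:
                raise PSTError(f"symbol {sym!r} not in the model alphabet")
        for t, sym in enumerate(song):
            ctx = pst.deepest_context(song[max(0, t - pst.depth) : t])
            p = pst.nodes[ctx].smoothed_probs[sym]
            bits -= math.log(p) / LOG2
            n += 1
    return bits if total else bits / n


# ---------------------------------------------------------------------------
# cross-validation


def param_grid(
    p_min: Sequence[float] = (0.007,),
    r: Sequence[float] = (1.05,),
    gamma_min: Sequence[float] = (0.001,),
    alpha: Sequence[float] = (0.0,),
    l_max: Sequence[int] = (8,),
) -> list[PSTParams]:
    """Cartesian grid of learning parameters (p_min is the primary axis)."""
    grid = [
        PSTParams(p_min=p, r=rr, gamma_min=g, alpha=a, l_max=l)
        for p in p_min
        for rr in r
        for g in gamma_min
        for a in alpha
        for l in l_max
    ]
    if not grid:
        raise PSTError("empty parameter grid")
    return grid


@dataclass
class CVReport:
    """Per-fold train/test NLL over a parameter grid, with model selection."""

    table: "object"  # pandas DataFrame; one row per (repeat, fold, params)
    grid: list[PSTParams]
    selected: PSTParams
    selection: str = "min"

    def by_params(self):
        """Mean and quartiles of train/test NLL and mean max depth per
        parameter setting."""
        import pandas as pd

        df = self.table
        rows = []
        for i, p in enumerate(self.grid):
            sub = df[df["param_index"] == i]
            rows.append(
                {
                    "p_min": p.p_min,
                    "r": p.r,
                    "gamma_min": p.gamma_min,
                    "alpha": p.alpha,
                    "l_max": p.l_max,
                    "train_nll_mean": sub["train_nll"].mean(),
                    "test_nll_mean": sub["test_nll"].mean(),
                    "test_nll_q25": sub["test_nll"].quantile(0.25),
                    "test_nll_q75": sub["test_nll"].quantile(0.75),
                    "test_nll_se": sub["test_nll"].sem(),
                    "depth_mean": sub["max_depth"].mean(),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        bp = self.by_params()
        lines = [
            f"PST cross-validation ({self.table['repeat'].nunique()} repeats x "
            f"{self.table['fold'].nunique()} folds, selection={self.selection})",
            bp.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
                columns=[
                    "p_min",
                    "train_nll_mean",
                    "test_nll_mean",
                    "test_nll_q25",
                    "test_nll_q75",
                    "depth_mean",
                ],
            ),
            f"selected: p_min={self.selected.p_min}, r={self.selected.r}, "
            f"gamma_min={self.selected.gamma_min}, l_max={self.selected.l_max}",
        ]
        return "\n".join(lines)


def crossvalidate_pst(
    sequences: Iterable[Sequence[str]],
    grid: Sequence[PSTParams],
    k_folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    selection: str = "min",
) -> CVReport:
    """Song-level k-fold cross-validation of PST parameters.

    Folds partition songs (never phrases), repeated with fresh splits.  The
    selected parameter set minimises mean test NLL; ties and the
    ``selection="one_se"`` option prefer the largest p_min (simpler trees)
    within one standard error of the minimum.
    """
    import pandas as pd

    seqs = _as_tuples(sequences)
    if len(seqs) < k_folds:
        raise PSTError(f"need at least k_folds={k_folds} songs")
    grid = list(grid)
    if not grid:
        raise PSTError("empty parameter grid")
    max_l = max(p.l_max for p in grid)
    alphabet = sorted({s for song in seqs for s in song})
    rng = np.random.default_rng(seed)

    rows = []
    for rep in range(repeats):
        order = rng.permutation(len(seqs))
        folds = np.array_split(order, k_folds)
        for fold_i, test_idx in enumerate(folds):
            test_set = set(int(i) for i in test_idx)
            train = [s for i, s in enumerate(seqs) if i not in test_set]
            test = [s for i, s in enumerate(seqs) if i in test_set]
            counts, n_pos = context_counts(train, max_l)
            for pi, params in enumerate(grid):
                tree = fit_pst_from_counts(counts, n_pos, alphabet, params)
                rows.append(
                    {
                        "repeat": rep,
                        "fold": fold_i,
                        "param_index": pi,
                        "p_min": params.p_min,
                        "train_nll": pst_nll(tree, train),
                        "test_nll": pst_nll(tree, test),
                        "max_depth": tree.depth,
                    }
                )
    df = pd.DataFrame(rows)

    mean_test = df.groupby("param_index")["test_nll"].mean()
    se_test = df.groupby("param_index")["test_nll"].sem()
    best = mean_test.idxmin()
    if selection == "one_se":
        cutoff = mean_test[best] + se_test[best]
        ok = [i for i in mean_test.index if mean_test[i] <= cutoff]
    elif selection == "min":
        ok = [
            i
            for i in mean_test.index
            if math.isclose(mean_test[i], mean_test[best], rel_tol=1e-12)
        ]
    else:
        raise PSTError(f"unknown selection rule {selection!r}")
    chosen = max(ok, key=lambda i: grid[i].p_min)
    return CVReport(
        table=df, grid=grid, selected=grid[chosen], selection=selection
    )


# ---------------------------------------------------------------------------
# chunk collapse


def _chunk_symbol(parts: Context) -> str:
    inner = (
        "".join(parts)
        if all(len(p) == 1 for p in parts)
        else "+".join(parts)
    )
    return f"({inner})"


@dataclass
class ChunkCollapseResult:
    """Outcome of collapsing internal-node runs into sequence chunks."""

    chunks: list[Context]
    chunk_symbols: list[str]
    chunked_pst: PST
    chunked_sequences: list[tuple[str, ...]]
    depth_before: int
    depth_after: int
    nll_total_before: float
    nll_total_after: float
    nll_per_phrase_before: float
    nll_per_token_after: float
    percent_nll_change: float

    def expand(
        self, sequences: Iterable[Sequence[str]] | None = None
    ) -> list[tuple[str, ...]]:
        """Map chunked sequences back to the original symbols (lossless)."""
        mapping = dict(zip(self.chunk_symbols, self.chunks))
        out = []
        for song in sequences if sequences is not None else self.chunked_sequences:
            expanded: list[str] = []
            for sym in song:
                expanded.extend(mapping.get(sym, (sym,)))
            out.append(tuple(expanded))
        return out

    def summary(self) -> str:
        chunk_desc = (
            ", ".join(self.chunk_symbols) if self.chunk_symbols else "(none)"
        )
        return (
            f"chunks: {chunk_desc}\n"
            f"depth: {self.depth_before} -> {self.depth_after}\n"
            f"total NLL: {self.nll_total_before:.1f} -> "
            f"{self.nll_total_after:.1f} bits "
            f"({self.percent_nll_change:.3f}% change)"
        )


def _retokenize(
    song: tuple[str, ...], chunks: Sequence[Context]
) -> tuple[str, ...]:
    out: list[str] = []
    i = 0
    n = len(song)
    while i < n:
        for ch in chunks:  # longest first
            l = len(ch)
            if song[i : i + l] == ch:
                out.append(_chunk_symbol(ch))
                i += l
                break
        else:
            out.append(song[i])
            i += 1
    return tuple(out)


def collapse_internal_nodes(
    pst: PST, sequences: Iterable[Sequence[str]]
) -> ChunkCollapseResult:
    """Collapse maximal runs of internal nodes into composite chunk symbols.

    Each maximal root-to-leaf run of internal nodes identifies a phrase block
    that carries no predictive information of its own; the block (the full
    context string of the deepest internal node in the run) becomes a single
    chunk symbol.  Sequences are re-tokenised (greedy, longest chunk first)
    and a new PST with the same parameters is fitted on chunk symbols.  The
    percent NLL change is measured on total corpus bits — the only scale on
    which the two tokenisations are directly comparable — evaluated on the
    provided sequences.
    """
    seqs = _as_tuples(sequences)
    nll_before_total = pst_nll(pst, seqs, total=True)
    n_phrases = sum(len(s) for s in seqs)

    internal = {c for c, n in pst.nodes.items() if n.is_internal}
    has_internal_child = {
        c[1:] for c in internal if len(c) >= 1 and c[1:] in internal
    }
    chunk_ctxs = sorted(
        {c for c in internal if c not in has_internal_child and len(c) >= 2},
        key=len,
        reverse=True,
    )

    if not chunk_ctxs:
        return ChunkCollapseResult(
            chunks=[],
            chunk_symbols=[],
            chunked_pst=pst,
            chunked_sequences=seqs,
            depth_before=pst.depth,
            depth_after=pst.depth,
            nll_total_before=nll_before_total,
            nll_total_after=nll_before_total,
            nll_per_phrase_before=nll_before_total / n_phrases,
            nll_per_token_after=nll_before_total / n_phrases,
            percent_nll_change=0.0,
        )

    chunked = [_retokenize(s, chunk_ctxs) for s in seqs]
    chunked_tree = fit_pst(chunked, pst.params)
    nll_after_total = pst_nll(chunked_tree, chunked, total=True)
    n_tokens = sum(len(s) for s in chunked)
    return ChunkCollapseResult(
        chunks=list(chunk_ctxs),
        chunk_symbols=[_chunk_symbol(c) for c in chunk_ctxs],
        chunked_pst=chunked_tree,
        chunked_sequences=chunked,
        depth_before=pst.depth,
        depth_after=chunked_tree.depth,
        nll_total_before=nll_before_total,
        nll_total_after=nll_after_total,
        nll_per_phrase_before=nll_before_total / n_phrases,
        nll_per_token_after=nll_after_total / n_tokens,
        percent_nll_change=100.0
        * abs(nll_after_total - nll_before_total)
        / nll_before_total,
    )


# ---------------------------------------------------------------------------
# model/results facade


class PSTModel:
    """Prediction-suffix-tree model of a phrase-sequence corpus.

    Parameters
    ----------
    data
        A :class:`songsyntax.annotations.Corpus` or a list of symbol
        sequences (one per song).
    params
        :class:`PSTParams`; keyword overrides (``p_min=...`` etc.) are also
        accepted.
    """

    def __init__(self, data, params: PSTParams | None = None, **overrides):
        from .annotations import Corpus, corpus_to_sequences

        if isinstance(data, Corpus):
            self.sequences = [tuple(s) for s in corpus_to_sequences(data)]
        else:
            self.sequences = _as_tuples(data)
        base = params or PSTParams()
        self.params = replace(base, **overrides) if overrides else base
        self.alphabet = tuple(
            sorted({s for song in self.sequences for s in song})
        )

    @classmethod
    def from_corpus(cls, corpus, params: PSTParams | None = None, **kw):
        return cls(corpus, params=params, **kw)

    def fit(self) -> "PSTResults":
        tree = fit_pst(self.sequences, self.params)
        return PSTResults(self, tree)

    def crossvalidate(
        self,
        grid: Sequence[PSTParams] | None = None,
        k_folds: int = 10,
        repeats: int = 3,
        seed: int = 0,
        selection: str = "min",
    ) -> CVReport:
        grid = grid or param_grid(
            p_min=(0.05, 0.02, 0.007, 0.003, 0.001),
            r=(self.params.r,),
            gamma_min=(self.params.gamma_min,),
            alpha=(self.params.alpha,),
            l_max=(self.params.l_max,),
        )
        return crossvalidate_pst(
            self.sequences,
            grid,
            k_folds=k_folds,
            repeats=repeats,
            seed=seed,
            selection=selection,
        )


class PSTResults:
    """Fitted PST with likelihoods, diagnostics, and derived models."""

    def __init__(self, model: PSTModel, tree: PST):
        self.model = model
        self.tree = tree
        self.params = tree.params
        self.train_nll = pst_nll(tree, model.sequences)

    def nll(self, sequences=None, total: bool = False) -> float:
        seqs = self.model.sequences if sequences is None else sequences
        return pst_nll(self.tree, seqs, total=total)

    def to_pfa(self):
        from .pfa import pst_to_pfa

        return pst_to_pfa(self.tree)

    def collapse_chunks(self, sequences=None) -> ChunkCollapseResult:
        seqs = self.model.sequences if sequences is None else sequences
        return collapse_internal_nodes(self.tree, seqs)

    def summary(self) -> str:
        t = self.tree
        n_internal = sum(n.is_internal for n in t.nodes.values())
        deep = sorted(t.nodes, key=len, reverse=True)[:8]
        lines = [
            "Prediction suffix tree",
            f"  alphabet size:   {len(t.alphabet)}",
            f"  songs / phrases: {len(self.model.sequences)} / "
            f"{sum(len(s) for s in self.model.sequences)}",
            f"  nodes:           {len(t)} ({n_internal} internal)",
            f"  max depth:       {t.depth}",
            f"  params:          p_min={t.params.p_min} r={t.params.r} "
            f"gamma_min={t.params.gamma_min} alpha={t.params.alpha} "
            f"l_max={t.params.l_max}",
            f"  train NLL:       {self.train_nll:.4f} bits/phrase",
            "  deepest contexts: "
            + ", ".join("".join(c) or "root" for c in deep),
        ]
        return "\n".join(lines)
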