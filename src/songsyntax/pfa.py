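"""Probabilistic finite automata derived from prediction suffix trees.

A PST predicts from the deepest context matching the full history; a PFA is
the equivalent *first-order* machine whose states are context strings.  For
the state-update rule ``next(s, sym) = longest suffix of s+sym that is a
state`` to reproduce the PST's predictions exactly, the state set must be
closed under removal of the most-recent symbol (so no information about the
deeper past can be lost in a single step).  We therefore take as states all
tree contexts plus their temporal prefixes, assign each state the prediction
of its deepest tree-context suffix, and prune to the states reachable from
the start (empty-history) state.  Likelihood under the PFA then equals the
PST likelihood on every sequence, to rounding error.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pst import PST, Context, LOG2, PSTError, _as_tuples

__all__ = [
    "PFA",
    "PrunedPFA",
    "pst_to_pfa",
    "prune_pfa",
    "generate_from_pfa",
    "count_states",
    "pfa_nll",
]


class PFAError(ValueError):
    pass


@dataclass
class PFA:
    """First-order automaton over context states.

    ``emissions[s]`` is the next-symbol distribution at state ``s``;
    ``transitions[(s, sym)]`` is the successor state.  ``start`` is the
    empty-history state used at the beginning of every song.
    """

    alphabet: tuple[str, ...]
    states: list[Context]
    emissions: dict[Context, dict[str, float]]
    transitions: dict[tuple[Context, str], Context]
    start: Context = ()
    state_frequency: dict[Context, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, dist in self.emissions.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-9:
                raise PFAError(f"emissions at state {s} sum to {tot}")
            for sym, p in dist.items():
                if p > 0 and (s, sym) not in self.transitions:
                    raise PFAError(f"missing transition for ({s}, {sym})")

    def __len__(self) -> int:
        return len(self.states)

    def step(self, state: Context, sym: str) -> Context:
        return self.transitions[(state, sym)]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "songsyntax-pfa",
                "version": 1,
                "alphabet": list(self.alphabet),
                "start": list(self.start),
                "states": [list(s) for s in self.states],
                "emissions": [
                    {"state": list(s), "probs": d}
                    for s, d in self.emissions.items()
                ],
                "transitions": [
                    {"state": list(s), "symbol": sym, "next": list(t)}
                    for (s, sym), t in self.transitions.items()
                ],
                "state_frequency": [
                    {"state": list(s), "frequency": f}
                    for s, f in self.state_frequency.items()
                ],
            },
            ensure_ascii=False,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PFA":
        doc = json.loads(text)
        if doc.get("format") != "songsyntax-pfa":
            raise PFAError("not a songsyntax PFA document")
        return cls(
            alphabet=tuple(doc["alphabet"]),
            states=[tuple(s) for s in doc["states"]],
            emissions={
                tuple(e["state"]): dict(e["probs"])
                for e in doc["emissions"]
            },
            transitions={
                (tuple(t["state"]), t["symbol"]): tuple(t["next"])
                for t in doc["transitions"]
            },
            start=tuple(doc["start"]),
            state_frequency={
                tuple(e["state"]): e["frequency"]
                for e in doc.get("state_frequency", [])
            },
        )

    def to_dot(
        self, min_probability: float = 0.0, hidden: set | None = None
    ) -> str:
        """DOT rendering; edge width proportional to transition probability.
        Edges below ``min_probability`` (or in ``hidden``) are omitted."""
        hidden = hidden or set()

        def nid(s: Context) -> str:
            return '"%s"' % ("".join(s) if s else "start")

        lines = [
            "digraph pfa {",
            "  rankdir=LR;",
            "  node [shape=ellipse, style=filled, fillcolor=lightyellow];",
        ]
        for s in self.states:
            lines.append(f"  {nid(s)};")
        for (s, sym), t in sorted(self.transitions.items()):
            p = self.emissions[s].get(sym, 0.0)
            if p < min_probability or (s, sym) in hidden:
                continue
            lines.append(
                f"  {nid(s)} -> {nid(t)} [label=\"{sym}:{p:.2f}\", "
                f"penwidth={0.3 + 4.0 * p:.2f}];"
            )
        lines.append("}")
        return "\n".join(lines)


def pst_to_pfa(pst: PST) -> PFA:
    """Convert a PST to an exactly likelihood-equivalent PFA.

    States are the tree contexts closed under temporal prefixes, pruned to
    those reachable from the start state.
    """
    closure: set[Context] = set()
    for ctx in pst.nodes:
        for i in range(len(ctx) + 1):
            closure.add(ctx[:i])

    def next_state(s: Context, sym: str) -> Context:
        cand = s + (sym,)
        for l in range(len(cand), -1, -1):
            if cand[len(cand) - l :] in closure:
                return cand[len(cand) - l :]
        return ()

    # breadth-first reachability from the start state
    reachable: set[Context] = {()}
    queue: deque[Context] = deque([()])
    transitions: dict[tuple[Context, str], Context] = {}
    emissions: dict[Context, dict[str, float]] = {}
    while queue:
        s = queue.popleft()
        dist = pst.nodes[pst.deepest_context(s)].smoothed_probs
        emissions[s] = dict(dist)
        for sym, p in dist.items():
            if p <= 0:
                continue
            t = next_state(s, sym)
            transitions[(s, sym)] = t
            if t not in reachable:
                reachable.add(t)
                queue.append(t)

    states = sorted(reachable, key=lambda c: (len(c), c))
    state_freq = {
        s: pst.nodes[s].frequency for s in states if s in pst.nodes
    }
    return PFA(
        alphabet=pst.alphabet,
        states=states,
        emissions=emissions,
        transitions=transitions,
        start=(),
        state_frequency=state_freq,
    )


def pfa_nll(
    pfa: PFA, sequences: Iterable[Sequence[str]], total: bool = False
) -> float:
    """Negative log-likelihood (bits/phrase, or total bits) under the PFA.

    Every song starts in the start state; symbols drive state transitions.
    """
    bits = 0.0
    n = 0
    for song in _as_tuples(sequences):
        state = pfa.start
        for sym in song:
            p = pfa.emissions[state].get(sym, 0.0)
            if p <= 0:
                raise PFAError(
                    f"symbol {sym!r} has zero probability at state {state}"
                )
            bits -= math.log(p) / LOG2
            state = pfa.step(state, sym)
            n += 1
    return bits if total else bits / n


@dataclass
class PrunedPFA:
    """Rendering-only view of a PFA with low-probability edges hidden.

    Pruning is for visualization: hidden edges stay in the underlying model
    (no renormalization), and likelihood queries are refused because the
    visible graph is not a probability model.
    """

    base: PFA
    threshold: float
    hidden: set[tuple[Context, str]]

    @property
    def n_hidden(self) -> int:
        return len(self.hidden)

    def nll(self, *args, **kwargs):
        raise PFAError(
            "pruned PFA is a visualization object; score likelihoods with "
            "the unpruned PFA"
        )

    def to_dot(self) -> str:
        return self.base.to_dot(hidden=self.hidden)


def prune_pfa(pfa: PFA, threshold: float) -> PrunedPFA:
    """Mark transition edges with emission probability < threshold as hidden."""
    if not 0 <= threshold < 1:
        raise PFAError("pruning threshold must be in [0, 1)")
    hidden = {
        (s, sym)
        for (s, sym) in pfa.transitions
        if pfa.emissions[s].get(sym, 0.0) < threshold
    }
    # a state whose outgoing edges are all hidden renders disconnected
    for s in pfa.states:
        out = [sym for sym in pfa.emissions[s] if pfa.emissions[s][sym] > 0]
        if out and all((s, sym) in hidden for sym in out):
            import warnings

            warnings.warn(
                f"state {s} has no visible outgoing edges at threshold "
                f"{threshold}; rendering will be disconnected"
            )
            break
    return PrunedPFA(base=pfa, threshold=threshold, hidden=hidden)


def generate_from_pfa(
    pfa: PFA,
    n_songs: int,
    length_model,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Sample symbol sequences from a PFA.

    ``length_model`` is either an integer (fixed song length), a sequence of
    per-song lengths, or a callable ``rng -> int``.  (PFAs built from PSTs
    carry no end-of-song outcome — contexts are truncated at song edges — so
    the stopping rule is supplied externally.)
    """
    rng = np.random.default_rng(seed)
    if isinstance(length_model, int):
        lengths = [length_model] * n_songs
    elif callable(length_model):
        lengths = [int(length_model(rng)) for _ in range(n_songs)]
    else:
        lengths = [int(x) for x in length_model]
        if len(lengths) != n_songs:
            raise PFAError("length list must have n_songs entries")

    # precompute per-state sampling tables
    tables: dict[Context, tuple[list[str], np.ndarray]] = {}
    for s, dist in pfa.emissions.items():
        syms = [sym for sym, p in dist.items() if p > 0]
        probs = np.array([dist[sym] for sym in syms])
        tables[s] = (syms, np.cumsum(probs / probs.sum()))

    songs: list[tuple[str, ...]] = []
    for length in lengths:
        if length < 1:
            raise PFAError("song length must be >= 1")
        state = pfa.start
        song: list[str] = []
        for _ in range(length):
            syms, cdf = tables[state]
            sym = syms[int(np.searchsorted(cdf, rng.random(), side="right"))]
            song.append(sym)
            state = pfa.step(state, sym)
        songs.append(tuple(song))
    return songs


@dataclass
class PFASummary:
    n_states: int
    n_symbols: int
    n_edges: int
    threshold: float


def count_states(pfa: PFA, threshold: float = 0.0) -> PFASummary:
    """State/symbol/edge counts.

    ``n_states`` counts the recurrent machine: states with at least one
    incoming transition (the start state is transient unless it is the only
    state).  ``n_edges`` counts transitions with emission probability >=
    threshold among those states.
    """
    incoming = set(pfa.transitions.values())
    if len(pfa.states) == 1:
        core = set(pfa.states)
    else:
        core = {s for s in pfa.states if s in incoming}
    n_edges = sum(
        1
        for (s, sym) in pfa.transitions
        if s in core and pfa.emissions[s].get(sym, 0.0) >= threshold
    )
    return PFASummary(
        n_states=len(core),
        n_symbols=len(pfa.alphabet),
        n_edges=n_edges,
        threshold=threshold,
    )
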