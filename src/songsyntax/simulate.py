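"""Synthetic phrased-song generator with fully known ground truth.

Every analysis stage in this package is validated by parameter recovery on
corpora drawn from a :class:`GroundTruthModel`: a variable-order context
model over phrase types (each context's probability vector includes an
explicit end-of-song outcome), a context-dependent lognormal phrase-duration
model, per-type syllable durations that are decoupled from phrase durations
by construction, and per-type contour templates from which jittered binary
time-frequency images are rendered.

The defaults emulate the study conditions the analyses are designed for:
17-35 phrase types per subject, syllable durations of 0.028-0.480 s, phrase
durations with a median near 1.35 s independent of syllable duration, and
songs of roughly 5-15 s (about eight phrases at the default end-of-song
probability of 1/8).

Because a phrase is *defined* as a maximal run of one syllable type, a
symbol can never follow itself; sampling renormalises away any declared
self-transition mass (models built by the factories here declare none, so
for them sampling follows the declared vectors exactly).  The analytic
counterpart :func:`implied_context_statistics` propagates the exact position
distribution of the sampler — including song-start truncation and the
end-of-song rule — and yields the infinite-corpus expected context counts
against which fitted models can be compared without sampling noise.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import BOUNDARY, Corpus, PhraseAnnotation, Song
from .pst import PSTParams, fit_pst_from_counts
from .spectral import ContourImage

__all__ = [
    "EOS",
    "GroundTruthModel",
    "SimulationConfig",
    "make_ground_truth",
    "simulate_corpus",
    "simulate_contours",
    "implied_context_statistics",
    "default_templates",
    "default_model",
    "random_recovery_model",
    "RecoveryGroundTruth",
    "chunk_block_model",
    "ChunkGroundTruth",
    "two_context_model",
    "duration_coupled_corpus",
]

#: End-of-song outcome key inside context probability vectors.
EOS = "$"

Context = tuple[str, ...]

_PROB_TOL = 1e-6


class ModelError(ValueError):
    pass


@dataclass
class GroundTruthModel:
    """Fully specified generative model of phrased songs."""

    alphabet: list[str]
    context_model: dict[Context, dict[str, float]]
    duration_model: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # (label, prev or "*") -> (mu_log_seconds, sigma_log)
    syllable_duration: dict[str, float] = field(default_factory=dict)
    contour_templates: dict[str, list[np.ndarray]] = field(
        default_factory=dict
    )
    jitter_scale: float = 1.5
    dropout: float = 0.05
    grid_shape: tuple[int, int] = (48, 96)  # (T, F) pixels
    time_step: float = 0.002
    freq_step: float = 100.0
    syllable_range: tuple[float, float] = (0.028, 0.480)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def max_context_length(self) -> int:
        return max(len(c) for c in self.context_model)

    def validate(self) -> None:
        if not self.alphabet:
            raise ModelError("empty alphabet")
        if BOUNDARY in self.alphabet or EOS in self.alphabet:
            raise ModelError("alphabet contains a reserved symbol")
        if () not in self.context_model:
            raise ModelError("context model must define the empty context")
        syms = set(self.alphabet)
        for ctx, dist in self.context_model.items():
            unknown = set(dist) - syms - {EOS}
            if unknown:
                raise ModelError(f"context {ctx}: unknown symbols {unknown}")
            if set(ctx) - syms:
                raise ModelError(f"context {ctx} uses unknown symbols")
            total = sum(dist.values())
            if abs(total - 1.0) > _PROB_TOL:
                raise ModelError(
                    f"probability vector at context {ctx} sums to "
                    f"{total:.8f} (no silent renormalization is done)"
                )
            if any(p < 0 for p in dist.values()):
                raise ModelError(f"negative probability at context {ctx}")
        for key, (mu, sigma) in self.duration_model.items():
            if sigma < 0:
                raise ModelError(f"negative sigma_log for {key}")
        lo, hi = self.syllable_range
        for lab, d in self.syllable_duration.items():
            if not (lo <= d <= hi):
                raise ModelError(
                    f"syllable duration {d} s for {lab!r} outside "
                    f"[{lo}, {hi}] s"
                )


@dataclass
class SimulationConfig:
    """Corpus-level simulation settings."""

    n_songs: int
    seed: int = 0
    min_phrases: int = 1
    max_phrases: int = 60
    gap: float = 0.05  # inter-phrase silent gap, seconds

    def __post_init__(self) -> None:
        if self.n_songs < 1:
            raise ModelError("n_songs must be >= 1")
        if not 1 <= self.min_phrases <= self.max_phrases:
            raise ModelError("need 1 <= min_phrases <= max_phrases")


_DEFAULT_MU = math.log(1.35)  # median phrase duration ~1.35 s
_DEFAULT_SIGMA = 0.2


def make_ground_truth(spec: Mapping) -> GroundTruthModel:
    """Build a validated :class:`GroundTruthModel` from a plain mapping.

    Expected keys: ``alphabet`` (list of symbols); ``transitions`` mapping a
    context key (symbols joined by spaces, ``""`` for the root) to a
    next-symbol probability mapping, which may include the end-of-song
    outcome ``"$"`` explicitly — otherwise ``eos_probability`` (default
    0.125) is folded into every vector; optional ``durations`` mapping
    ``"label|prev"`` (``"*"`` wildcards) to ``{"median_s":…, "sigma_log":…}``;
    optional ``syllable_durations``; optional ``jitter``
    (``{"scale":…, "dropout":…}``).  Unspecified duration contexts inherit
    the wildcard entry; probability vectors off by more than 1e-6 raise.
    """
    spec = dict(spec)
    alphabet = list(spec["alphabet"])
    eos_p = float(spec.get("eos_probability", 0.125))
    ctx_model: dict[Context, dict[str, float]] = {}
    for key, dist in spec["transitions"].items():
        ctx = tuple(key.split()) if isinstance(key, str) else tuple(key)
        dist = {str(s): float(p) for s, p in dist.items()}
        if EOS not in dist:
            total = sum(dist.values())
            if abs(total - 1.0) > _PROB_TOL:
                raise ModelError(
                    f"transitions[{key!r}] sums to {total:.8f}"
                )
            dist = {s: p * (1 - eos_p) for s, p in dist.items()}
            dist[EOS] = eos_p
        ctx_model[ctx] = dist

    durations: dict[tuple[str, str], tuple[float, float]] = {
        ("*", "*"): (_DEFAULT_MU, _DEFAULT_SIGMA)
    }
    for key, entry in spec.get("durations", {}).items():
        lab, _, prev = key.partition("|")
        prev = prev or "*"
        mu = math.log(float(entry.get("median_s", math.exp(_DEFAULT_MU))))
        sigma = float(entry.get("sigma_log", _DEFAULT_SIGMA))
        durations[(lab, prev)] = (mu, sigma)

    syl = spec.get("syllable_durations")
    if syl is None:
        syl = _spread_syllable_durations(alphabet)
    jitter = dict(spec.get("jitter", {}))
    templates = spec.get("contour_templates")
    if templates is None:
        templates = default_templates(alphabet)
    return GroundTruthModel(
        alphabet=alphabet,
        context_model=ctx_model,
        duration_model=durations,
        syllable_duration=dict(syl),
        contour_templates=templates,
        jitter_scale=float(jitter.get("scale", 1.5)),
        dropout=float(jitter.get("dropout", 0.05)),
    )


def _spread_syllable_durations(
    alphabet: Sequence[str], lo: float = 0.028, hi: float = 0.480
) -> dict[str, float]:
    """Log-spaced syllable durations assigned in alphabet order (any
    relation to phrase durations is broken separately by the factories)."""
    n = len(alphabet)
    vals = np.exp(np.linspace(math.log(lo), math.log(hi), max(n, 2)))[:n]
    return {lab: float(v) for lab, v in zip(alphabet, vals)}


# ---------------------------------------------------------------------------
# sampling


class _Emitter:
    """Shared resolution/caching of context distributions for sampling and
    for the analytic propagation (identical semantics by construction)."""

    def __init__(self, model: GroundTruthModel):
        self.model = model
        self.max_len = model.max_context_length
        self._resolve_cache: dict[Context, Context] = {}
        self._dist_cache: dict[tuple[Context, str | None, bool], list] = {}

    def resolve(self, state: Context) -> Context:
        """Longest declared suffix of the history (always resolves: the
        empty context is mandatory)."""
        key = state[-self.max_len :] if self.max_len else ()
        if key in self._resolve_cache:
            return self._resolve_cache[key]
        ctx: Context = ()
        for l in range(len(key), -1, -1):
            if key[len(key) - l :] in self.model.context_model:
                ctx = key[len(key) - l :]
                break
        self._resolve_cache[key] = ctx
        return ctx

    def emissions(
        self, state: Context, no_eos: bool
    ) -> list[tuple[str | None, float]]:
        """(symbol, probability) pairs; symbol None denotes end-of-song.

        Any declared mass on repeating the most recent symbol is
        redistributed proportionally over the other symbols (phrases cannot
        follow themselves); with ``no_eos`` the end-of-song mass is likewise
        redistributed (minimum-length clamp).
        """
        ctx = self.resolve(state)
        prev = state[-1] if state else None
        key = (ctx, prev, no_eos)
        if key in self._dist_cache:
            return self._dist_cache[key]
        dist = dict(self.model.context_model[ctx])
        eos = dist.pop(EOS, 0.0)
        if prev is not None and dist.get(prev, 0.0) > 0:
            m = dist.pop(prev)
            s = sum(dist.values())
            if s <= 0:
                raise ModelError(
                    f"context {ctx} emits only its own last symbol"
                )
            dist = {sym: p * (s + m) / s for sym, p in dist.items()}
        elif prev is not None:
            dist.pop(prev, None)
        if no_eos:
            s = sum(dist.values())
            if s <= 0:
                raise ModelError(
                    f"context {ctx} has no continuation but the song is "
                    "below its minimum length"
                )
            pairs = [(sym, p / s) for sym, p in dist.items() if p > 0]
        else:
            pairs = [(sym, p) for sym, p in dist.items() if p > 0]
            if eos > 0:
                pairs.append((None, eos))
        self._dist_cache[key] = pairs
        return pairs


def _duration_params(
    model: GroundTruthModel, label: str, prev: str | None
) -> tuple[float, float]:
    dm = model.duration_model
    for key in ((label, prev or "*"), (label, "*"), ("*", "*")):
        if key in dm:
            return dm[key]
    return (_DEFAULT_MU, _DEFAULT_SIGMA)


def simulate_corpus(
    model: GroundTruthModel, cfg: SimulationConfig
) -> Corpus:
    """Draw a corpus: symbols from the context model (longest matching
    suffix), durations from the context-dependent lognormal model, onsets
    tiled with a fixed inter-phrase gap.  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    em = _Emitter(model)
    cdf_cache: dict = {}
    used_contexts: set[Context] = set()

    songs: list[Song] = []
    for i in range(cfg.n_songs):
        history: list[str] = []
        while True:
            state = tuple(history[-max(em.max_len, 1) :])
            used_contexts.add(em.resolve(state))
            no_eos = len(history) < cfg.min_phrases
            key = (em.resolve(state), state[-1] if state else None, no_eos)
            if key not in cdf_cache:
                pairs = em.emissions(state, no_eos)
                syms = [s for s, _ in pairs]
                cdf = np.cumsum([p for _, p in pairs])
                cdf_cache[key] = (syms, cdf / cdf[-1])
            syms, cdf = cdf_cache[key]
            sym = syms[int(np.searchsorted(cdf, rng.random(), side="right"))]
            if sym is None:
                break
            history.append(sym)
            if len(history) >= cfg.max_phrases:
                break
        t = 0.0
        phrases = []
        prev: str | None = None
        song_id = f"s{i:05d}"
        for lab in history:
            mu, sigma = _duration_params(model, lab, prev)
            dur = float(rng.lognormal(mu, sigma))
            phrases.append(PhraseAnnotation(t, t + dur, lab, song_id))
            t += dur + cfg.gap
            prev = lab
        songs.append(Song(song_id=song_id, phrases=phrases))

    unreached = set(model.context_model) - used_contexts
    if unreached:
        warnings.warn(
            f"{len(unreached)} declared contexts were never active "
            f"(e.g. {sorted(unreached, key=len)[-1]})"
        )
    return Corpus(songs=songs, subject_id="synthetic")


def implied_context_statistics(
    model: GroundTruthModel,
    max_len: int,
    min_phrases: int = 1,
    max_phrases: int = 60,
    mass_tol: float = 1e-12,
) -> tuple[dict[Context, dict[str, float]], float]:
    """Exact expected context counts per song in the infinite-corpus limit.

    Propagates the distribution over histories position by position with the
    same emission semantics as :func:`simulate_corpus` (no-repeat rule,
    minimum-length clamp, hard stop at ``max_phrases``).  Returns
    ``(counts, n_positions)`` where ``counts[ctx][sym]`` is the expected
    number of positions per song at which ``ctx`` is the active suffix and
    ``sym`` follows, for every context up to length ``max_len``; and
    ``n_positions`` is the expected number of phrases per song.  Ratios of
    these counts are the population conditionals that an infinitely large
    fitted model would converge to.
    """
    em = _Emitter(model)
    track = max(max_len, em.max_len, 1)
    states: dict[Context, float] = {(): 1.0}
    state_counts: dict[Context, dict[str, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for t in range(max_phrases):
        new_states: dict[Context, float] = defaultdict(float)
        no_eos = t < min_phrases
        for s, w in states.items():
            if w <= mass_tol:
                continue
            sc = state_counts[s]
            for sym, p in em.emissions(s, no_eos):
                if sym is None:
                    continue
                wp = w * p
                sc[sym] += wp
                new_states[(s + (sym,))[-track:]] += wp
        if not new_states:
            break
        states = new_states

    counts: dict[Context, dict[str, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for s, d in state_counts.items():
        for l in range(0, min(len(s), max_len) + 1):
            tgt = counts[s[len(s) - l :]]
            for sym, v in d.items():
                tgt[sym] += v
    out = {c: dict(d) for c, d in counts.items()}
    total = sum(out[()].values())
    return out, total


# ---------------------------------------------------------------------------
# contour images


def default_templates(
    labels: Sequence[str],
    grid_shape: tuple[int, int] = (48, 96),
    seed: int = 0,
) -> dict[str, list[np.ndarray]]:
    """Per-type contour templates: a fundamental frequency sweep plus a
    fainter parallel band, distinct per label."""
    T, F = grid_shape
    templates: dict[str, list[np.ndarray]] = {}
    for j, lab in enumerate(sorted(labels)):
        rng = np.random.default_rng([seed, j])
        t = np.linspace(3, T - 4, 12)
        f0 = rng.uniform(0.25, 0.7) * F
        amp = rng.uniform(0.05, 0.2) * F
        k = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * math.pi)
        f = f0 + amp * np.sin(2 * math.pi * k * t / T + phase)
        sweep = np.column_stack([t, np.clip(f, 2, F - 3)])
        band = np.column_stack(
            [t, np.clip(f * rng.uniform(0.45, 0.6), 2, F - 3)]
        )
        templates[lab] = [sweep, band]
    return templates


def _rasterize(polylines: Sequence[np.ndarray], shape) -> np.ndarray:
    img = np.zeros(shape, dtype=np.uint8)
    for line in polylines:
        pts = np.asarray(line, float)
        for (t0, f0), (t1, f1) in zip(pts[:-1], pts[1:]):
            n = int(2 * max(abs(t1 - t0), abs(f1 - f0))) + 2
            ti = np.clip(
                np.round(np.linspace(t0, t1, n)).astype(int), 0, shape[0] - 1
            )
            fi = np.clip(
                np.round(np.linspace(f0, f1, n)).astype(int), 0, shape[1] - 1
            )
            img[ti, fi] = 1
    return img


def simulate_contours(
    model: GroundTruthModel,
    label: str,
    n: int,
    group_shift: tuple[float, float] | None = None,
    seed: int = 0,
    group: str = "",
) -> list[ContourImage]:
    """Jittered binary contour images for ``n`` renditions of one syllable.

    Each rendition displaces the template polylines by a smooth random field
    (Gaussian-filtered white noise scaled to ``jitter_scale`` pixels) and
    then drops set pixels independently with probability ``dropout``.
    ``group_shift`` applies a deterministic (time, frequency) pixel offset
    to the template first — the device for constructing acoustically
    distinct groups.
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    template = model.contour_templates.get(label)
    if not template:
        raise ModelError(f"no contour template for label {label!r}")
    T, F = model.grid_shape
    rng = np.random.default_rng(seed)
    base = [np.asarray(line, float).copy() for line in template]
    if group_shift is not None:
        dt, df = group_shift
        base = [line + np.array([dt, df]) for line in base]

    images = []
    for _ in range(n):
        if model.jitter_scale > 0:
            fields = []
            for _axis in range(2):
                noise = rng.standard_normal((T, F))
                smooth = gaussian_filter(noise, sigma=min(T, F) / 6)
                sd = smooth.std()
                fields.append(
                    smooth / sd * model.jitter_scale if sd > 0 else smooth
                )
            lines = []
            for line in base:
                ti = np.clip(np.round(line[:, 0]).astype(int), 0, T - 1)
                fi = np.clip(np.round(line[:, 1]).astype(int), 0, F - 1)
                disp = np.column_stack(
                    [fields[0][ti, fi], fields[1][ti, fi]]
                )
                lines.append(line + disp)
        else:
            lines = base
        img = _rasterize(lines, (T, F))
        if model.dropout > 0:
            img = img * (rng.random((T, F)) >= model.dropout)
        images.append(
            ContourImage(
                pixels=img.astype(np.uint8),
                time_step=model.time_step,
                freq_step=model.freq_step,
                label=label,
                group=group,
            )
        )
    return images


# ---------------------------------------------------------------------------
# reference generators (the study conditions for parameter-recovery tests)


def _spread(
    rng: np.random.Generator,
    fixed: Mapping[str, float],
    over: Sequence[str],
    mass: float,
) -> dict[str, float]:
    """Fixed probabilities plus random positive weights summing to ``mass``."""
    d = dict(fixed)
    if mass < -1e-12:
        raise ModelError("negative spread mass")
    if over and mass > 0:
        w = rng.uniform(0.5, 1.5, len(over))
        w = w / w.sum() * mass
        for s, wi in zip(over, w):
            d[s] = d.get(s, 0.0) + float(wi)
    return d


def _fold_eos(dist: Mapping[str, float], eos_p: float) -> dict[str, float]:
    out = {s: p * (1 - eos_p) for s, p in dist.items() if p > 0}
    out[EOS] = eos_p
    return out


@dataclass
class RecoveryGroundTruth:
    """A random depth-3 ground-truth tree with its analytically verified
    minimal context set and the fit parameters it was verified under."""

    model: GroundTruthModel
    nodes: frozenset[Context]
    leaves: tuple[Context, Context]
    fit_params: PSTParams
    implied_counts: dict[Context, dict[str, float]]
    implied_positions: float


def random_recovery_model(
    seed: int,
    n_symbols: int = 10,
    max_tries: int = 300,
) -> RecoveryGroundTruth:
    """Random depth-3 ground truth over ``n_symbols`` phrase types built for
    exact context recovery.

    The motif is the long-range rule of interest: two entry types route into
    a shared two-phrase corridor (entry -> m -> a) and the transition *out*
    of the corridor depends on which entry was taken three phrases earlier
    (distinct signal symbols, contrast >= 0.3).  Singles have strongly
    distinct next-symbol distributions (dominant transitions ~0.93) so every
    depth-1 context is genuinely informative, and all generating contexts
    are frequent (>= several times the p_min frequency gate).

    Candidate models are checked *analytically* (via
    :func:`implied_context_statistics`): the retention rule applied to the
    infinite-corpus statistics must recover exactly the declared node set,
    with margin (the same check passes at r scaled up and down by 15%), and
    every symbol must be frequent enough for its conditionals to be
    estimable; otherwise the model is redrawn.
    """
    if n_symbols < 8:
        raise ModelError("recovery motif needs at least 8 symbols")
    fit_params = PSTParams(
        p_min=0.007, r=1.55, gamma_min=0.001, alpha=0.12, l_max=8
    )
    symbols = [chr(ord("A") + i) for i in range(n_symbols)]

    for attempt in range(max_tries):
        rng = np.random.default_rng([seed, attempt])
        perm = [symbols[i] for i in rng.permutation(n_symbols)]
        u1, u2, m, a, g1, g2 = perm[:6]
        generics = perm[6:]
        others = generics + [g1, g2]  # everyone but entries, m, a
        tiny = 0.002

        src = [others[i] for i in rng.permutation(len(others))]
        half = len(src) // 2
        t_map = {z: u1 for z in src[:half]} | {z: u2 for z in src[half:]}
        t_map[u1] = generics[int(rng.integers(len(generics)))]
        t_map[u2] = generics[int(rng.integers(len(generics)))]

        dists: dict[str, dict[str, float]] = {}
        for z in others:
            p_dom = float(rng.uniform(0.91, 0.95))
            fixed = {t_map[z]: p_dom, m: tiny, a: tiny}
            over = [s for s in symbols if s not in fixed and s != z]
            dists[z] = _spread(rng, fixed, over, 1 - sum(fixed.values()))
        for u in (u1, u2):
            p_m = float(rng.uniform(0.62, 0.68))
            p_dom2 = float(rng.uniform(0.14, 0.18))
            fixed = {m: p_m, t_map[u]: p_dom2, a: tiny}
            over = [s for s in symbols if s not in fixed and s != u]
            dists[u] = _spread(rng, fixed, over, 1 - sum(fixed.values()))
        p_a = float(rng.uniform(0.78, 0.84))
        fixed = {a: p_a, m: 0.0}
        over = [s for s in symbols if s not in (m, a)]
        dists[m] = _spread(rng, {a: p_a}, over, 1 - p_a)

        leaves: dict[str, dict[str, float]] = {}
        for u, g in ((u1, g1), (u2, g2)):
            p_g = float(rng.uniform(0.82, 0.86))
            fixed = {g: p_g, m: tiny}
            over = [s for s in symbols if s not in fixed and s != a]
            leaves[u] = _spread(rng, fixed, over, 1 - sum(fixed.values()))
        dists[a] = {
            s: 0.5 * leaves[u1].get(s, 0.0) + 0.5 * leaves[u2].get(s, 0.0)
            for s in symbols
            if leaves[u1].get(s, 0.0) + leaves[u2].get(s, 0.0) > 0
        }

        p_u = float(rng.uniform(0.15, 0.19))
        root_fixed = {u1: p_u, u2: p_u, m: 0.01, a: 0.01, g1: 0.01, g2: 0.01}
        root = _spread(
            rng, root_fixed, generics, 1 - sum(root_fixed.values())
        )

        eos_p = 0.125
        context_model: dict[Context, dict[str, float]] = {
            (): _fold_eos(root, eos_p)
        }
        for z in symbols:
            context_model[(z,)] = _fold_eos(dists[z], eos_p)
        context_model[(u1, m, a)] = _fold_eos(leaves[u1], eos_p)
        context_model[(u2, m, a)] = _fold_eos(leaves[u2], eos_p)

        model = GroundTruthModel(
            alphabet=list(symbols),
            context_model=context_model,
            syllable_duration=_spread_syllable_durations(symbols),
            contour_templates=default_templates(symbols),
        )

        declared: set[Context] = {(), (m, a), (u1, m, a), (u2, m, a)}
        declared |= {(z,) for z in symbols}

        counts, total = implied_context_statistics(model, max_len=4)
        unigram = {
            s: counts[()].get(s, 0.0) / total for s in symbols
        }
        if min(unigram.values()) < 0.035:
            continue
        ok = True
        for r_test in (
            fit_params.r,
            fit_params.r * 1.15,
            1.0 + (fit_params.r - 1.0) / 1.6,
        ):
            params = PSTParams(
                p_min=fit_params.p_min,
                r=r_test,
                gamma_min=fit_params.gamma_min,
                alpha=fit_params.alpha,
                l_max=4,
            )
            tree = fit_pst_from_counts(counts, total, symbols, params)
            if set(tree.nodes) != declared:
                ok = False
                break
        if not ok:
            continue
        return RecoveryGroundTruth(
            model=model,
            nodes=frozenset(declared),
            leaves=((u1, m, a), (u2, m, a)),
            fit_params=fit_params,
            implied_counts=counts,
            implied_positions=total,
        )
    raise ModelError(
        f"no admissible recovery model found in {max_tries} tries"
    )


@dataclass
class ChunkGroundTruth:
    """Ground truth in which a three-phrase block always occurs as a unit
    inside a depth-4 rule (entry symbol determines the exit distribution)."""

    model: GroundTruthModel
    block: Context
    fit_params: PSTParams


def chunk_block_model(seed: int = 0) -> ChunkGroundTruth:
    """Generator for the chunk-collapse analysis.

    The block A->B->N is deterministic once entered from D or E, N occurs
    nowhere else, and the exit distribution after N depends on the symbol
    *preceding* the block (D favours K, E favours J): a genuine fourth-order
    rule whose intermediate contexts (BN, ABN) carry no information of their
    own and should collapse into the chunk (ABN).
    """
    rng = np.random.default_rng(seed)
    D, E, A, B, N, K, J = "D", "E", "A", "B", "N", "K", "J"
    generics = ["P", "Q", "R", "S", "T"]
    symbols = [D, E, A, B, N, K, J] + generics

    dists: dict[str, dict[str, float]] = {}
    root = _spread(rng, {D: 0.09, E: 0.09}, generics, 0.82)
    for ent in (D, E):
        over = [s for s in [D, E] + generics if s != ent]
        dists[ent] = _spread(rng, {A: 0.22}, over, 0.78)
    dists[A] = {B: 1.0}
    dists[B] = {N: 1.0}
    for ext in (K, J):
        dists[ext] = _spread(rng, {D: 0.25, E: 0.25}, generics, 0.50)
    for i, z in enumerate(generics):
        nxt = generics[(i + 1) % len(generics)]  # dominant generic cycle
        over = [s for s in generics if s not in (z, nxt)]
        dists[z] = _spread(
            rng, {nxt: 0.55, D: 0.06, E: 0.06}, over, 0.33
        )

    leaf_exit = {
        D: _spread(rng, {K: 0.86, J: 0.02}, generics, 0.12),
        E: _spread(rng, {J: 0.86, K: 0.02}, generics, 0.12),
    }
    # fallback for histories ending in N without a full block context
    # (unreachable by construction, but keeps resolution well-defined)
    dists[N] = {
        s: 0.5 * leaf_exit[D].get(s, 0.0) + 0.5 * leaf_exit[E].get(s, 0.0)
        for s in symbols
        if leaf_exit[D].get(s, 0.0) + leaf_exit[E].get(s, 0.0) > 0
    }

    eos_p = 0.06  # longer songs: the block rule recurs many phrases apart
    context_model: dict[Context, dict[str, float]] = {
        (): _fold_eos(root, eos_p)
    }
    for z in symbols:
        if z in (A, B):
            # the block is a monolithic unit: once entered it always
            # completes, so no end-of-song outcome mid-block
            context_model[(z,)] = dict(dists[z])
        else:
            context_model[(z,)] = _fold_eos(dists[z], eos_p)
    for ent in (D, E):
        context_model[(ent, A, B, N)] = _fold_eos(leaf_exit[ent], eos_p)

    model = GroundTruthModel(
        alphabet=symbols,
        context_model=context_model,
        syllable_duration=_spread_syllable_durations(symbols),
        contour_templates=default_templates(symbols),
    )
    fit_params = PSTParams(
        p_min=0.007, r=1.55, gamma_min=0.001, alpha=0.12, l_max=8
    )
    return ChunkGroundTruth(
        model=model, block=(A, B, N), fit_params=fit_params
    )


def two_context_model(seed: int = 0, n_symbols: int = 8) -> GroundTruthModel:
    """Depth-2 ground truth: two entries route into a shared phrase m and
    the transition out of m depends on the entry (second-order structure on
    top of strong first-order transitions)."""
    if n_symbols < 6:
        raise ModelError("need at least 6 symbols")
    symbols = [chr(ord("A") + i) for i in range(n_symbols)]
    rng = np.random.default_rng(seed)
    perm = [symbols[i] for i in rng.permutation(n_symbols)]
    u1, u2, m, g1, g2 = perm[:5]
    generics = perm[5:]
    others = generics + [g1, g2]
    tiny = 0.003

    src = [others[i] for i in rng.permutation(len(others))]
    half = (len(src) + 1) // 2
    t_map = {z: u1 for z in src[:half]} | {z: u2 for z in src[half:]}
    t_map[u1] = generics[int(rng.integers(len(generics)))]
    t_map[u2] = generics[int(rng.integers(len(generics)))]

    dists: dict[str, dict[str, float]] = {}
    for z in others:
        p_dom = float(rng.uniform(0.75, 0.85))
        fixed = {t_map[z]: p_dom, m: tiny}
        over = [s for s in symbols if s not in fixed and s != z]
        dists[z] = _spread(rng, fixed, over, 1 - sum(fixed.values()))
    for u in (u1, u2):
        p_m = float(rng.uniform(0.58, 0.64))
        fixed = {m: p_m, t_map[u]: 0.15}
        over = [s for s in symbols if s not in fixed and s != u]
        dists[u] = _spread(rng, fixed, over, 1 - sum(fixed.values()))

    leaves = {}
    for u, g in ((u1, g1), (u2, g2)):
        fixed = {g: float(rng.uniform(0.78, 0.82))}
        over = [s for s in symbols if s not in fixed and s != m]
        leaves[u] = _spread(rng, fixed, over, 1 - sum(fixed.values()))
    dists[m] = {
        s: 0.5 * leaves[u1].get(s, 0.0) + 0.5 * leaves[u2].get(s, 0.0)
        for s in symbols
        if leaves[u1].get(s, 0.0) + leaves[u2].get(s, 0.0) > 0
    }

    root_fixed = {u1: 0.16, u2: 0.16, m: 0.01}
    root = _spread(
        rng, root_fixed, others, 1 - sum(root_fixed.values())
    )

    eos_p = 0.125
    context_model: dict[Context, dict[str, float]] = {
        (): _fold_eos(root, eos_p)
    }
    for z in symbols:
        context_model[(z,)] = _fold_eos(dists[z], eos_p)
    context_model[(u1, m)] = _fold_eos(leaves[u1], eos_p)
    context_model[(u2, m)] = _fold_eos(leaves[u2], eos_p)

    return GroundTruthModel(
        alphabet=symbols,
        context_model=context_model,
        syllable_duration=_spread_syllable_durations(symbols),
        contour_templates=default_templates(symbols),
    )


def default_model(seed: int = 0, n_types: int = 24) -> GroundTruthModel:
    """Showcase model with realistic scale: ~24 phrase types, sparse random
    first-order transitions plus a handful of deeper rules, phrase-duration
    medians near 1.35 s with context-dependent shifts, and syllable
    durations decoupled from phrase durations by explicit orthogonalisation
    of the per-type duration medians against syllable duration."""
    rng = np.random.default_rng(seed)
    labels = [f"L{i:02d}" for i in range(n_types)]

    dists: dict[str, dict[str, float]] = {}
    for lab in labels:
        k = int(rng.integers(2, 5))
        succ = [
            labels[i]
            for i in rng.permutation(n_types)
            if labels[i] != lab
        ][:k]
        w = rng.dirichlet(np.full(k, 1.2))
        dists[lab] = {s: float(p) for s, p in zip(succ, w)}
    root_w = rng.dirichlet(np.full(n_types, 2.0))
    root = {lab: float(p) for lab, p in zip(labels, root_w)}

    eos_p = 0.125
    context_model: dict[Context, dict[str, float]] = {
        (): _fold_eos(root, eos_p)
    }
    for lab in labels:
        context_model[(lab,)] = _fold_eos(dists[lab], eos_p)
    # a few genuine depth-2 rules: the exit from a shared phrase depends on
    # the phrase before it
    shared = labels[0]
    entries = [lab for lab in labels if shared in dists[lab]][:2]
    exits = [lab for lab in labels[1:] if lab not in entries][:2]
    for ent, ex in zip(entries, exits):
        d = {ex: 0.7}
        over = [s for s in labels if s not in (ex, shared)]
        d = _spread(rng, d, over[:4], 0.3)
        context_model[(ent, shared)] = _fold_eos(d, eos_p)

    # durations: medians orthogonalised against syllable duration
    syl = _spread_syllable_durations(labels)
    order = rng.permutation(n_types)
    syl = {lab: syl[labels[i]] for lab, i in zip(labels, order)}
    log_syl = np.array([math.log(syl[lab]) for lab in labels])
    mu_raw = _DEFAULT_MU + rng.normal(0, 0.15, n_types)
    x = log_syl - log_syl.mean()
    beta = float(x @ (mu_raw - mu_raw.mean()) / (x @ x))
    mu = mu_raw - beta * x  # per-type medians uncorrelated with syllable dur
    duration_model: dict[tuple[str, str], tuple[float, float]] = {
        ("*", "*"): (_DEFAULT_MU, _DEFAULT_SIGMA)
    }
    for lab, mu_i in zip(labels, mu):
        duration_model[(lab, "*")] = (float(mu_i), _DEFAULT_SIGMA)
    # context-dependent duration shifts (duration depends on the previous
    # phrase type) on frequently co-occurring pairs
    frequent_pairs = [
        (prev, lab)
        for prev in labels
        for lab, p in dists[prev].items()
        if p >= 0.25
    ]
    order2 = rng.permutation(len(frequent_pairs))
    for idx in order2[: min(6, len(frequent_pairs))]:
        prev, lab = frequent_pairs[idx]
        base_mu, _s = duration_model[(lab, "*")]
        shift = float(rng.choice([-0.4, 0.4]))
        duration_model[(lab, prev)] = (base_mu + shift, _DEFAULT_SIGMA)

    return GroundTruthModel(
        alphabet=labels,
        context_model=context_model,
        duration_model=duration_model,
        syllable_duration=syl,
        contour_templates=default_templates(labels),
    )


def duration_coupled_corpus(
    seed: int = 0,
    n_songs: int = 200,
    center: str = "B",
    short_next: str = "C",
    long_next: str = "D",
    coupling: float = 0.95,
) -> Corpus:
    """Corpus in which the *duration* of the center phrase predicts the next
    phrase type: short renditions lead to ``short_next``, long ones to
    ``long_next`` (with probability ``coupling``).  The device for testing
    MD(dur,path_out) and duration-sorted barcodes."""
    rng = np.random.default_rng(seed)
    songs = []
    median = 1.0
    for i in range(n_songs):
        song_id = f"s{i:05d}"
        dur_b = float(rng.lognormal(math.log(median), 0.4))
        is_short = dur_b < median
        nxt = short_next if is_short else long_next
        if rng.random() > coupling:
            nxt = long_next if is_short else short_next
        t = 0.0
        phrases = []
        for lab, dur in (
            ("A", float(rng.lognormal(math.log(1.2), 0.2))),
            (center, dur_b),
            (nxt, float(rng.lognormal(math.log(1.1), 0.2))),
            ("E", float(rng.lognormal(math.log(1.0), 0.2))),
        ):
            phrases.append(PhraseAnnotation(t, t + dur, lab, song_id))
            t += dur + 0.05
        songs.append(Song(song_id=song_id, phrases=phrases))
    return Corpus(songs=songs, subject_id="duration-coupled")
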