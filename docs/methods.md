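# Methods

This note documents the statistical machinery in `songsyntax`, the design
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Data model

The unit of analysis is the **phrase**: a maximal run of repeats of one
syllable type, annotated as `(onset, offset, label)` in seconds with
half-open intervals `[onset, offset)`. A **song** is an ordered,
non-overlapping list of phrases; by definition two adjacent phrases cannot
share a label, so same-label adjacency in an input file is merged at parse
time. A **corpus** is one subject's songs. Song edges are marked with the
reserved boundary symbol `⊥`, which no model may emit. Combined-TSV input
is segmented by `song_id` only — annotations delimit songs, so no
silence-gap heuristic is applied. An explicit label-exclusion list handles
phrase types whose subtypes cannot be labeled consistently; no automatic
criterion is guessed.

## Mutual dependence tests

For each center phrase type Y, occurrences contribute a factor pair:

- `MD(dur,path_in)` — duration tercile × preceding label,
- `MD(dur,path_out)` — duration tercile × following label,
- `MD(path_in,path_out)` — preceding × following label.

Durations are discretized by empirical terciles, computed **per phrase
type** by default (a corpus-wide option exists): per-type cut points match
the per-type grouping of the duration analyses, since phrase types have
their own characteristic durations. Ties at a cut point go to the lower
bin. Boundary neighbours are excluded by default — a song edge is not a
phrase choice — with a flag to include them as a level. Tables with fewer
than 10 usable observations (configurable) are skipped and reported as
such.

Independence is tested with the Fisher–Freeman–Halton exact test: the
statistic is the multivariate hypergeometric probability of the table given
its margins, and the p-value is evaluated by Monte Carlo over tables drawn
from the fixed-margins null (Patefield's algorithm via
`scipy.stats.random_table`). We use the probability-ordering, two-sided
convention — sampled tables *as or less probable* than the observed one
count as extreme — and the add-one estimate
`p = (1 + #extreme) / (1 + N)`, which can never report zero and is exact in
the Monte Carlo sense. Ties in table probability are counted as extreme
(within 1e-9 in log-probability). Degenerate tables (a single non-empty row
or column) are flagged with p = 1. Significance summaries use α = 0.001
with no multiple-testing correction; the number of tests run is always part
of the report. The default 100,000 randomizations give a Monte Carlo SE
below 0.0016 everywhere; a million-randomization setting is available.

The **adaptation test** (`transition_vs_repetition`) tabulates the
next-phrase distribution after the k-th occurrence of a source phrase in
each song and classifies the modal transition's probability across k
(restricted to k with at least `min_n` observations) as strictly
increasing, strictly decreasing, or non-monotonic.

## Block entropy

`H_n` is the plug-in Shannon entropy (bits) of length-n windows pooled
**within songs only**; windows never cross song boundaries because songs
are the natural sequence unit. No bias correction is applied; instead the
block-count diagnostics (distinct blocks vs total windows) are reported so
undersampling at large n is visible. Controls:

- **zero-order**: pool all tokens across songs, permute, re-deal into the
  original song lengths (exactly preserves the token multiset, hence H_1);
  pooling across songs is the default because the zero-order null concerns
  occurrence probabilities of the corpus as a whole.
- **first-order**: per-song random Eulerian path on the bigram multigraph
  from the original start symbol (randomized Hierholzer), which preserves
  each song's bigram multiset and start symbol *exactly* — "preserves
  nearest-neighbour transitions" holds as a conservation law rather than
  approximately, and no fitting noise enters. Songs shorter than 3 phrases
  pass through unchanged. (Resampling songs from a fitted chain is the
  obvious alternative; exact conservation was preferred.)
- **maximum entropy**: `n·log2 |Σ|`.

Shuffle curves default to 100 randomizations with 5th–95th percentile
bands.

## Prediction suffix trees

Learning follows the classic grow-from-root scheme for variable-order
Markov models with parameters `(p_min, r, γ_min, α, L_max)`:

- a candidate context `s` (length ≤ `L_max`) must be active at a fraction
  ≥ `p_min` of phrase positions;
- it is retained iff some symbol σ with P̂(σ|s) ≥ α changes prediction
  relative to the parent suffix by ratio ≥ r or ≤ 1/r (the published
  algorithm's ratio test; the growth criterion is stated informally in the
  literature, and this is the interpretation implemented);
- ancestors of retained contexts are added with `is_internal=True` when
  they fail the test on their own strength (the flag is stored at fit time
  because internality is parameter-relative);
- smoothing `P(σ|s) = P̂(σ|s)(1 − |Σ|γ_min) + γ_min` bounds every
  probability away from zero.

Counting is within songs, with contexts truncated at song start — no
artificial start symbol, matching the collection-of-chains view of the
tree. Likelihood is reported in bits **per phrase** (the averaging
convention had to be fixed somewhere; per-phrase makes corpora of different
song lengths comparable), with each position scored by its deepest matching
context.

Library defaults are `p_min=0.007, r=1.05, γ_min=0.001, α=0, L_max=8`.
`p_min=0.007` is a conservative cross-validated choice for corpora of a few
tens of thousands of phrases; `r` and `γ_min` near their defaults have
little effect on test likelihood there, and depth caps at 8 comfortably
above observed structure. A caveat that matters in practice: at a given
corpus size, a context passing the frequency gate has of order
`p_min·N` observations, so its conditional probabilities carry binomial
noise of a few percent — a 5% ratio threshold (`r=1.05`) then admits
contexts on sampling noise alone. Wherever this package's own validation
requires *exact* context recovery (recovery tests, the chunk analysis), the
fits use evidence thresholds scaled to the corpus: `r≈1.55, α≈0.12`, chosen
a priori so that genuine contrasts (ratio ≥ 1.9 by construction) pass with
≥ 5σ margin while a spurious pass requires a ≥ 4σ fluctuation. These are
calibrations of the test's power at the synthetic study conditions, not
tuned constants.

**Cross-validation** is song-level k-fold (default 10), repeated (default
3) with fresh splits, over a `p_min` grid (optionally `r`, `γ_min`, `α`
axes). Reported per setting: mean train/test NLL, 25th/75th percentiles,
standard error, and mean max depth. Selection takes the test-NLL minimizer,
breaking ties toward the largest `p_min`; a one-standard-error rule
(largest `p_min` within one SE of the minimum) is available for
conservative selection.

**Chunk collapse.** Maximal root-to-leaf runs of internal nodes identify
phrase blocks with no predictive content of their own; each run collapses
to the full context string of its deepest internal node (so internal nodes
`BN, ABN` under a leaf `DABN` give the chunk `(ABN)`, and the leaf becomes
the order-2 context `D·(ABN)`). Sequences are re-tokenized greedily
(longest chunk first) — the mapping is lossless and inverted by
`ChunkCollapseResult.expand` — and a new tree is fitted with the same
parameters. The percent NLL change is computed on **total corpus bits**:
per-token averages are not comparable across tokenizations, while total
bits score the same songs under both models. Two honest artifacts of this
comparison are worth knowing: (i) block-internal emissions cost
`−log2` of near-one smoothed probabilities, and (ii) the root node predicts
with the global unigram, which shifts when block symbols merge; both scale
with the block's share of tokens. In the acceptance condition (blocks ~7%
of tokens in songs of ~17 phrases) the total change is 0.2–0.4%.

## PST → PFA conversion

The equivalent first-order machine needs states on which the update rule
`next(s, σ) = longest suffix of s+σ in S` never loses information about
the deeper past. The tree's node set is suffix-closed (oldest symbol
removable) but not prefix-closed in time; taking `S` = tree contexts plus
all their temporal prefixes makes the update exact, with each state
predicting via its deepest tree-context suffix. States are pruned to those
reachable from the empty-history start state. The conversion is validated
by the strongest property available: likelihood equality with the tree to
1e-9 bits/phrase on arbitrary sequences. Edge pruning for visualization
(default threshold 0.2) *hides* edges rather than deleting or
renormalizing — the pruned object refuses likelihood queries. State counts
report the recurrent machine (states with incoming edges; the start state
is transient unless it is the only state). Generation from a PFA needs an
external length rule (fixed, per-song list, or callable), since trees built
with context truncation carry no end-of-song outcome.

## Spectral density images and similarity

A contour image is a binary T×F matrix (one syllable rendition, pre-aligned
on onset; no warping). The spectral density image is the pixelwise mean
over renditions — the probability of finding a contour in each pixel. The
per-rendition similarity score is the cosine-normalized inner product with
the reference density (bounded in [0,1], equal to 1 for a contour identical
to a one-member reference, comparable across syllables); the raw inner
product is also exposed because it satisfies the exact group-mean identity
⟨D_A, D_B⟩ = mean over pairs ⟨C_i, C_j⟩, which the tests assert. When a
group is scored against its own density, leave-one-out densities are used
so self-inclusion does not inflate scores. Group comparisons report
two-sample KS p-values against the reference group (exact method below 30
renditions, asymptotic otherwise) and the full pairwise d′ table, with
pooled SD = sqrt of the size-weighted average of the two group variances.

## The synthetic generator

`GroundTruthModel` specifies: a context model (suffix → next-symbol
probabilities *including an explicit end-of-song outcome* — generation
needs a stopping rule, and making it part of each probability vector keeps
it context-dependent); lognormal phrase durations keyed by (label,
previous label) with wildcard fallback (positive, right-skewed, unimodal —
no particular family is canonical, and lognormal is the simplest with
those properties); per-type syllable durations in 0.028–0.480 s; and
per-type contour templates with smooth-field jitter plus pixel dropout.
Defaults emulate the study conditions: ~17–35 phrase types, duration
medians near 1.35 s (σ_log = 0.2, a calibration choice — no per-type
variance is canonical), songs averaging ~8 phrases (end-of-song
probability 1/8, clamped to 1–60 phrases), and syllable durations
*decoupled from phrase durations by construction* (the showcase model
orthogonalizes per-type duration medians against log syllable duration, so
the population correlation is exactly zero at the type level).

Because a phrase cannot follow itself by definition, sampling renormalizes
away any declared self-transition mass; the bundled generators declare
none, so their sampling follows the declared vectors exactly.

`implied_context_statistics` propagates the position distribution of the
sampler exactly (song-start truncation, minimum-length clamp, end-of-song
rule, no-repeat rule) and returns expected context counts per song — the
infinite-corpus limit of what a fitted model sees. This is the reference
for parameter-recovery checks, and it resolves an identifiability subtlety:
at a non-maximal context the observable conditional is a mixture over the
deeper generating contexts, so recovery is asserted against these *implied*
conditionals, not against raw declared vectors.

Three reference generators define the validation conditions:

- `random_recovery_model`: random depth-3 trees over 10 symbols built
  around the long-range motif (two entries → shared two-phrase corridor →
  entry-specific exits, contrasts ≥ 0.3, all generating contexts at several
  times the frequency gate, dominant single-context transitions ~0.93 so
  every conditional is estimable with SE ≪ 0.02 at 40k phrases). Candidate
  models are *analytically* screened: the retention rule applied to the
  implied statistics must recover exactly the declared node set, with
  margin (the same holds at r scaled ±15%), else the model is redrawn.
- `chunk_block_model`: a deterministic three-phrase block (entered from two
  entry types, ~7% of tokens) whose exit depends on the pre-block symbol; 
  block-internal transitions carry no end-of-song outcome (the block is
  monolithic by hypothesis). Songs average ~17 phrases.
- `two_context_model`: a depth-2 variant used for cross-validation shape
  and entropy-ordering checks.

What the generator does **not** emulate: real acoustic variability (no
audio is synthesized; contour jitter reproduces the *spread* structure of
density images, not spectro-temporal detail), annotation noise and
inter-observer disagreement, non-stationarity across a recording season,
and repertoire drift. Passing recovery tests therefore demonstrates
correctness of the estimators under the declared generative family, not
robustness to mis-annotation.

## Numerical choices and degenerate inputs

- Log base 2 throughout; likelihood comparisons use exact total bits where
  tokenizations differ.
- Probability vectors must sum to 1 within 1e-6 — construction errors are
  raised, never silently renormalized.
- Tercile ties go to the lower bin; all-equal durations trigger a
  degenerate-spread warning.
- Monte Carlo tie tolerance: 1e-9 in log table probability.
- Tree fitting with nothing past the frequency gate yields a valid
  root-only (depth-0) model; unknown symbols in scoring raise with the
  symbol named.
- All randomness uses explicit `numpy` generators; the pipeline derives
  named per-stage sub-seeds from the global seed by hashing, and identical
  configurations give byte-identical reports.

## Problem sizes

The validation suite runs at deliberately moderate scale: 5,000 songs
(~40,000 phrases) for exact context recovery across 10 random ground-truth
trees; 3,000 songs (~51,000 phrases) for the chunk analysis; 600 songs for
cross-validation shape; 100,000 Monte Carlo randomizations against exact
Fisher enumeration and 500 null tables for p-value uniformity; 60 seeds of
200-rendition contour groups for the d′ calibration. These sizes were
chosen so that every pass/fail margin is several standard errors wide under
the generators' declared contrasts.

## Known limitations

- The ratio retention test is one interpretation of the informally stated
  growth criterion; alternative information criteria (KL-gain thresholds)
  would differ at the margin.
- Plug-in entropy is biased downward at large n; diagnostics expose, but do
  not correct, undersampling.
- The chunk NLL comparison inherits the two tokenization artifacts noted
  above; with very frequent chunks the root-unigram term alone can exceed
  1% even when chunking is information-lossless.
- `MD` tests treat phrase occurrences as exchangeable across songs; serial
  correlation within songs is not modeled under the null beyond the fixed
  margins.
- PFA state counts depend on the fitted tree and therefore on corpus size
  and fit parameters; no claim is made that counts on synthetic corpora
  match any particular recorded repertoire.
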