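"""Spectral density images and contour-similarity statistics.

A syllable rendition is represented as a sparse binary time-frequency
*contour image*.  Averaging the binary images of all renditions of a syllable
gives the *spectral density image*: the per-pixel probability of finding a
contour there, a direct picture of acoustic variability.  Similarity between a
rendition and a group is the inner product between the rendition's contour
image and the group's density image; group separability is summarised by a
two-sample KS test on score distributions and by d', the difference of group
mean scores in units of the pooled standard deviation.

Two inner-product conventions are exposed:

* ``normalized=True`` (default): cosine-normalised score
  ``<C, D> / (||C|| * ||D||)`` in [0, 1], comparable across syllables.
* ``normalized=False``: raw inner product ``<C, D>``, which satisfies the
  identity  mean over pairs (i in A, j in B) of <C_i, C_j>  ==  <D_A, D_B>.

Images are assumed pre-aligned on syllable onset; no time warping is done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContourImage",
    "SpectralDensityImage",
    "SimilarityResult",
    "spectral_density",
    "similarity_scores",
    "dprime",
    "compare_groups",
]


class SpectralError(ValueError):
    pass


@dataclass
class ContourImage:
    """Binary time-frequency contour image of one syllable rendition.

    ``pixels`` is a T x F array of {0, 1}; axis metadata gives physical units
    (seconds per time pixel, Hz per frequency pixel).
    """

    pixels: np.ndarray
    time_step: float = 0.001
    freq_step: float = 100.0
    label: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        vals = np.unique(px)
        if not np.isin(vals, (0, 1)).all():
            raise SpectralError("contour image pixels must be 0/1")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_set(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SpectralDensityImage:
    """Pixelwise contour probability over N renditions of one syllable."""

    density: np.ndarray
    n_renditions: int
    label: str = ""
    group: str = ""
    time_step: float = 0.001
    freq_step: float = 100.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape  # type: ignore[return-value]


def _check_shapes(shapes: Iterable[tuple[int, int]]) -> tuple[int, int]:
    shapes = list(shapes)
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise SpectralError(
                f"contour image shapes differ: {s} vs {first}; "
                "no resampling is performed"
            )
    return first


def spectral_density(contours: Sequence[ContourImage]) -> SpectralDensityImage:
    """Pixelwise mean of binary contour images (the contour probability)."""
    if len(contours) == 0:
        raise SpectralError("need at least one contour image")
    _check_shapes(c.shape for c in contours)
    stack = np.stack([c.pixels for c in contours]).astype(float)
    return SpectralDensityImage(
        density=stack.mean(axis=0),
        n_renditions=len(contours),
        label=contours[0].label,
        group=contours[0].group,
        time_step=contours[0].time_step,
        freq_step=contours[0].freq_step,
    )


def similarity_scores(
    contours: Sequence[ContourImage],
    reference: SpectralDensityImage,
    normalized: bool = True,
) -> np.ndarray:
    """Similarity of each rendition to a reference density image.

    With ``normalized=True`` the score is the cosine between the contour and
    the density viewed as pixel vectors (1 for a contour identical to a
    one-member reference, 0 for disjoint support).  With ``normalized=False``
    the raw inner product is returned.
    """
    if len(contours) == 0:
        raise SpectralError("no contour images given")
    _check_shapes([c.shape for c in contours] + [reference.shape])
    ref = reference.density.ravel()
    ref_norm = float(np.linalg.norm(ref))
    if ref_norm == 0:
        raise SpectralError("reference density is all-zero; score undefined")
    scores = np.empty(len(contours))
    for i, c in enumerate(contours):
        v = c.pixels.ravel().astype(float)
        raw = float(v @ ref)
        if normalized:
            nv = float(np.linalg.norm(v))
            if nv == 0:
                raise SpectralError(
                    f"contour {i} is all-zero; similarity undefined"
                )
            scores[i] = raw / (nv * ref_norm)
        else:
            scores[i] = raw
    return scores


def dprime(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """|mean_a - mean_b| over the pooled standard deviation.

    The pooled SD is the square root of the size-weighted average of the two
    group variances; it is zero only for degenerate (constant) scores, which
    raises.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size < 2 or b.size < 2:
        raise SpectralError("each group needs at least 2 scores")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = np.sqrt((a.size * va + b.size * vb) / (a.size + b.size))
    if pooled == 0:
        raise SpectralError("zero pooled standard deviation (degenerate)")
    return float(abs(a.mean() - b.mean()) / pooled)


@dataclass
class SimilarityResult:
    """Per-group similarity scores against a reference group's density."""

    reference: str
    group_labels: list[str]
    scores: dict[str, np.ndarray]
    ks_p: dict[str, float]
    dprime_table: "np.ndarray"  # symmetric, zero diagonal, group order
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Similarity vs reference group {self.reference!r} "
            f"({len(self.group_labels)} groups)",
            f"{'group':>12} {'n':>5} {'mean':>8} {'sd':>8} {'KS p':>10}",
        ]
        for g in self.group_labels:
            ks = self.ks_p.get(g)
            ks_s = f"{ks:.3g}" if ks is not None else "--"
            lines.append(
                f"{g:>12} {len(self.scores[g]):>5} {self.means[g]:>8.4f} "
                f"{self.sds[g]:>8.4f} {ks_s:>10}"
            )
        return "\n".join(lines)


def compare_groups(
    groups: Mapping[str, Sequence[ContourImage]],
    reference_tag: str,
    normalized: bool = True,
    leave_one_out: bool = True,
    exact_ks_below: int = 30,
) -> SimilarityResult:
    """Score every group against the reference group's density image.

    The reference group is scored against itself with leave-one-out densities
    by default, so its own renditions do not inflate self-similarity.  Each
    non-reference group gets a two-sample KS p-value against the reference
    scores, and all group pairs get a d' entry.
    """
    if reference_tag not in groups:
        raise SpectralError(f"reference group {reference_tag!r} not present")
    usable = {}
    for tag, imgs in groups.items():
        if len(imgs) < 2:
            warnings.warn(f"group {tag!r} has < 2 renditions; excluded")
            continue
        usable[tag] = list(imgs)
    if reference_tag not in usable:
        raise SpectralError("reference group too small after exclusions")
    if len(usable) < 2:
        raise SpectralError("need at least 2 usable groups")

    ref_imgs = usable[reference_tag]
    ref_density = spectral_density(ref_imgs)
    scores: dict[str, np.ndarray] = {}
    for tag, imgs in usable.items():
        if tag == reference_tag and leave_one_out and len(imgs) > 1:
            n = len(imgs)
            total = np.stack([c.pixels for c in imgs]).astype(float).sum(0)
            vals = np.empty(n)
            for i, c in enumerate(imgs):
                loo = SpectralDensityImage(
                    density=(total - c.pixels) / (n - 1), n_renditions=n - 1
                )
                vals[i] = similarity_scores([c], loo, normalized=normalized)[0]
            scores[tag] = vals
        else:
            scores[tag] = similarity_scores(
                imgs, ref_density, normalized=normalized
            )

    tags = list(usable)
    ks_p: dict[str, float] = {}
    for tag in tags:
        if tag == reference_tag:
            continue
        n_min = min(len(scores[tag]), len(scores[reference_tag]))
        method = "exact" if n_min < exact_ks_below else "asymp"
        ks_p[tag] = float(
            stats.ks_2samp(
                scores[tag], scores[reference_tag], method=method
            ).pvalue
        )

    dp = np.zeros((len(tags), len(tags)))
    for i, a in enumerate(tags):
        for j, b in enumerate(tags):
            if i < j:
                dp[i, j] = dp[j, i] = dprime(scores[a], scores[b])

    return SimilarityResult(
        reference=reference_tag,
        group_labels=tags,
        scores=scores,
        ks_p=ks_p,
        dprime_table=dp,
        means={t: float(scores[t].mean()) for t in tags},
        sds={t: float(scores[t].std(ddof=1)) for t in tags},
    )
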