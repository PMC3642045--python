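"""Barcode plots and figure helpers.

A *barcode* summarises every occurrence of one phrase type: one row per
occurrence, the centered phrase starting at time zero, and the phrases sung
before (left) and after (right) drawn as bars colored by phrase type and
scaled by duration.  Sorting the rows by the centered phrase's duration or
by the preceding phrase type makes duration- and path-dependent rules
directly visible.  A scale square (2 s wide by 20 rows tall) flanks the
barcode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless by default; figures are saved, not shown
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Patch, Rectangle

from .annotations import BOUNDARY, Corpus

__all__ = [
    "BarcodeRow",
    "barcode_rows",
    "render_barcode",
    "plot_entropy_profile",
    "plot_cv_report",
]

SORT_MODES = ("by-duration", "by-prev-label", "by-occurrence")


@dataclass
class BarcodeRow:
    """One occurrence of the centered phrase with its flanking phrases."""

    song_id: str
    position_index: int
    center_duration: float
    prev_label: str
    left: list[tuple[str, float]]  # outermost first
    right: list[tuple[str, float]]


def barcode_rows(
    corpus: Corpus,
    center_label: str,
    sort_mode: str = "by-occurrence",
    window: int = 4,
) -> list[BarcodeRow]:
    """Collect and order barcode rows (the testable core of the plot)."""
    if center_label not in corpus.alphabet:
        raise ValueError(
            f"label {center_label!r} not in corpus alphabet "
            f"{sorted(corpus.alphabet)}"
        )
    if sort_mode not in SORT_MODES:
        raise ValueError(f"sort_mode must be one of {SORT_MODES}")
    rows: list[BarcodeRow] = []
    for song in corpus.songs:
        phrases = song.phrases
        for i, ph in enumerate(phrases):
            if ph.label != center_label:
                continue
            left = [
                (p.label, p.duration)
                for p in phrases[max(0, i - window) : i]
            ]
            right = [
                (p.label, p.duration) for p in phrases[i + 1 : i + 1 + window]
            ]
            rows.append(
                BarcodeRow(
                    song_id=song.song_id,
                    position_index=i,
                    center_duration=ph.duration,
                    prev_label=phrases[i - 1].label if i > 0 else BOUNDARY,
                    left=left,
                    right=right,
                )
            )
    if sort_mode == "by-duration":
        rows.sort(key=lambda r: r.center_duration)
    elif sort_mode == "by-prev-label":
        rows.sort(key=lambda r: r.prev_label)
    return rows


def _label_colors(labels: Sequence[str]) -> dict[str, tuple]:
    cmap = plt.get_cmap("tab20")
    return {lab: cmap(i % 20) for i, lab in enumerate(sorted(labels))}


def render_barcode(
    corpus: Corpus,
    center_label: str,
    sort_mode: str = "by-duration",
    window: int = 4,
    center_color: str = "0.15",
):
    """Render a barcode figure; returns ``(figure, rows)``.

    The centered phrase is drawn in a neutral dark color starting at t=0;
    flanking phrases are colored by label.  The scale square at the left
    flank spans 2 seconds by 20 rows.
    """
    rows = barcode_rows(corpus, center_label, sort_mode, window)
    colors = _label_colors(corpus.alphabet)

    fig, ax = plt.subplots(
        figsize=(8, max(2.0, 0.06 * len(rows) + 1.0))
    )
    for y, row in enumerate(rows):
        t = 0.0
        for lab, dur in reversed(row.left):
            ax.add_patch(
                Rectangle(
                    (t - dur, y), dur, 0.9, color=colors[lab], linewidth=0
                )
            )
            t -= dur
        ax.add_patch(
            Rectangle(
                (0, y), row.center_duration, 0.9,
                color=center_color, linewidth=0,
            )
        )
        t = row.center_duration
        for lab, dur in row.right:
            ax.add_patch(
                Rectangle((t, y), dur, 0.9, color=colors[lab], linewidth=0)
            )
            t += dur

    xmin = min(
        (-sum(d for _, d in r.left) for r in rows), default=-1.0
    )
    xmax = max(
        (r.center_duration + sum(d for _, d in r.right) for r in rows),
        default=1.0,
    )
    # scale square: 2 s wide x 20 rows tall
    ax.add_patch(
        Rectangle(
            (xmin - 2.5, 0), 2.0, min(20, max(1, len(rows))),
            fill=False, edgecolor="k", linewidth=1.2,
        )
    )
    ax.set_xlim(xmin - 3.0, xmax + 0.5)
    ax.set_ylim(-1, len(rows) + 1)
    ax.set_xlabel("time relative to phrase onset (s)")
    ax.set_ylabel(f"occurrences of {center_label!r} ({sort_mode})")
    ax.set_yticks([])
    handles = [
        Patch(color=c, label=lab)
        for lab, c in sorted(colors.items())
        if lab != center_label
    ][:19]
    handles.insert(0, Patch(color=center_color, label=f"{center_label} (center)"))
    ax.legend(handles=handles, loc="upper right", fontsize=6, ncol=2)
    fig.tight_layout()
    return fig, rows


def plot_entropy_profile(profile):
    """Block entropy vs block size: data, shuffle controls with bands, and
    the maximum-entropy line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    n = profile.data.n
    ax.plot(n, profile.max_entropy.H, "k--", label="max entropy")
    for curve, color in (
        (profile.zero_order, "tab:green"),
        (profile.first_order, "tab:blue"),
    ):
        ax.plot(n, curve.H, color=color, label=curve.source)
        if curve.H_low is not None:
            ax.fill_between(
                n, curve.H_low, curve.H_high, color=color, alpha=0.25
            )
    ax.plot(n, profile.data.H, "m-o", label="data")
    ax.set_xlabel("block size n (phrases)")
    ax.set_ylabel("block entropy $H_n$ (bits)")
    ax.set_xticks(n)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_cv_report(report):
    """Train/test NLL (with quartiles) and mean tree depth vs p_min."""
    bp = report.by_params().sort_values("p_min", ascending=False)
    fig, (ax, ax2) = plt.subplots(
        2, 1, figsize=(5, 6), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]},
    )
    x = bp["p_min"].to_numpy()
    ax.plot(x, bp["train_nll_mean"], "o-", label="train")
    ax.errorbar(
        x,
        bp["test_nll_mean"],
        yerr=np.vstack(
            [
                bp["test_nll_mean"] - bp["test_nll_q25"],
                bp["test_nll_q75"] - bp["test_nll_mean"],
            ]
        ),
        fmt="s-",
        label="test",
        capsize=3,
    )
    ax.axvline(report.selected.p_min, color="k", ls=":", lw=1)
    ax.set_xscale("log")
    ax.invert_xaxis()
    ax.set_ylabel("NLL (bits/phrase)")
    ax.legend()
    ax2.plot(x, bp["depth_mean"], "k.-")
    ax2.set_xlabel(r"$p_{min}$ (decreasing)")
    ax2.set_ylabel("mean max depth")
    fig.tight_layout()
    return fig
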