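"""Phrase-level annotation I/O and corpus assembly.

A *phrase* is a run of repeats of one syllable type; songs are ordered lists of
labeled, timed phrases, and a corpus is the set of songs from one subject.  Two
plain-text dialects are supported:

``label-track``
    One song per file, tab-separated ``onset<TAB>offset<TAB>label`` lines with
    no header (Audacity label-track compatible).  Times in seconds.
``combined-tsv``
    A single table with header ``song_id\tonset\toffset\tlabel``; songs are
    segmented by ``song_id`` only (no silence-gap heuristic).

Adjacent phrases carrying the same label are merged at parse time: by
definition a phrase already spans all consecutive repeats of its syllable, so
same-label adjacency is an annotation artifact, not structure.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BOUNDARY",
    "AnnotationError",
    "PhraseAnnotation",
    "Song",
    "Corpus",
    "PhraseRecord",
    "read_annotations",
    "write_annotations",
    "corpus_to_sequences",
    "phrase_records",
    "records_frame",
]

#: Reserved marker for "no neighbouring phrase" (song edge).  Excluded from
#: every alphabet; downstream modules must treat it as non-emittable.
BOUNDARY = "⊥"  # ⊥

_OVERLAP_TOL = 1e-9


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent phrase annotations."""


@dataclass(frozen=True)
class PhraseAnnotation:
    """A single labeled, timed phrase.  Interval is half-open [onset, offset)."""

    onset: float
    offset: float
    label: str
    song_id: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise AnnotationError("phrase label must be non-empty")
        if self.label == BOUNDARY:
            raise AnnotationError(
                f"label {BOUNDARY!r} is reserved for song boundaries"
            )
        if not (math.isfinite(self.onset) and math.isfinite(self.offset)):
            raise AnnotationError(
                f"non-finite phrase interval [{self.onset}, {self.offset})"
            )
        if not self.offset > self.onset:
            raise AnnotationError(
                f"phrase offset must exceed onset, got [{self.onset}, "
                f"{self.offset}) for label {self.label!r}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Song:
    """An ordered, non-overlapping list of phrases from one rendition."""

    song_id: str
    phrases: list[PhraseAnnotation]

    def __post_init__(self) -> None:
        if not self.phrases:
            raise AnnotationError(f"song {self.song_id!r} has no phrases")
        for prev, cur in zip(self.phrases, self.phrases[1:]):
            if cur.onset < prev.onset:
                raise AnnotationError(
                    f"song {self.song_id!r}: phrases not sorted by onset"
                )
            if cur.onset < prev.offset - _OVERLAP_TOL:
                raise AnnotationError(
                    f"song {self.song_id!r}: phrases overlap at t={cur.onset}"
                )
            if cur.label == prev.label:
                raise AnnotationError(
                    f"song {self.song_id!r}: adjacent phrases share label "
                    f"{cur.label!r} (merge before constructing a Song)"
                )

    def labels(self) -> list[str]:
        return [p.label for p in self.phrases]

    def __len__(self) -> int:
        return len(self.phrases)


@dataclass
class Corpus:
    """All songs of one subject plus the observed phrase-type alphabet."""

    songs: list[Song]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.songs:
            raise AnnotationError("corpus has no songs")

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(p.label for s in self.songs for p in s.phrases)

    @property
    def n_phrases(self) -> int:
        return sum(len(s) for s in self.songs)

    def __len__(self) -> int:
        return len(self.songs)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format": "songsyntax-corpus",
            "version": 1,
            "subject_id": self.subject_id,
            "songs": [
                {
                    "song_id": s.song_id,
                    "phrases": [
                        [p.onset, p.offset, p.label] for p in s.phrases
                    ],
                }
                for s in self.songs
            ],
        }
        return json.dumps(doc, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Corpus":
        doc = json.loads(text)
        if doc.get("format") != "songsyntax-corpus":
            raise AnnotationError("not a songsyntax corpus document")
        songs = [
            Song(
                song_id=s["song_id"],
                phrases=[
                    PhraseAnnotation(on, off, lab, s["song_id"])
                    for on, off, lab in s["phrases"]
                ],
            )
            for s in doc["songs"]
        ]
        return cls(songs=songs, subject_id=doc.get("subject_id", ""))


@dataclass(frozen=True)
class PhraseRecord:
    """One phrase with its immediate context (the X,Y,Z roles of a triple)."""

    label: str
    duration: float
    prev_label: str
    next_label: str
    position_index: int
    song_id: str


# ---------------------------------------------------------------------------
# parsing


def _merge_adjacent(
    tuples: list[tuple[float, float, str]],
) -> list[tuple[float, float, str]]:
    """Merge runs of adjacent same-label phrases into one spanning phrase."""
    merged: list[tuple[float, float, str]] = []
    for on, off, lab in tuples:
        if merged and merged[-1][2] == lab:
            merged[-1] = (merged[-1][0], off, lab)
        else:
            merged.append((on, off, lab))
    return merged


def _parse_line(
    parts: list[str], path: str, lineno: int
) -> tuple[float, float, str]:
    try:
        on, off = float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise AnnotationError(
            f"{path}:{lineno}: cannot parse times from {parts[:2]!r}"
        ) from exc
    label = parts[2].strip()
    if not label:
        raise AnnotationError(f"{path}:{lineno}: empty phrase label")
    if off <= on:
        raise AnnotationError(
            f"{path}:{lineno}: offset {off} <= onset {on} for label {label!r}"
        )
    return on, off, label


def _song_from_tuples(
    song_id: str, tuples: list[tuple[float, float, str]]
) -> Song:
    tuples = sorted(tuples, key=lambda t: t[0])
    tuples = [tuple(t) for t in _merge_adjacent([list(t) for t in tuples])]  # type: ignore[misc]
    phrases = [
        PhraseAnnotation(on, off, lab, song_id) for on, off, lab in tuples
    ]
    return Song(song_id=song_id, phrases=phrases)


def read_annotations(
    paths: Sequence[str | Path] | str | Path,
    dialect: str = "label-track",
    subject_id: str = "",
    exclude_labels: Iterable[str] = (),
) -> Corpus:
    """Read phrase annotations into a :class:`Corpus`.

    Parameters
    ----------
    paths
        One path or a list of paths.  For ``label-track`` each file is one
        song; for ``combined-tsv`` the files are concatenated row-wise.
    dialect
        ``"label-track"`` or ``"combined-tsv"`` (see module docstring).
    exclude_labels
        Phrase types to drop entirely before assembling songs (the manual
        exclusion list for inconsistently labeled types).  A song that ends
        up empty after exclusion is skipped with a warning.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    excluded = set(exclude_labels)
    if dialect not in ("label-track", "combined-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    per_song: dict[str, list[tuple[float, float, str]]] = {}
    order: list[str] = []

    for path in paths:
        path = Path(path)
        lines = path.read_text(encoding="utf-8").splitlines()
        rows = [
            (i + 1, line) for i, line in enumerate(lines) if line.strip()
        ]
        if dialect == "label-track":
            if not rows:
                warnings.warn(f"empty annotation file skipped: {path}")
                continue
            song_id = path.stem
            tuples = []
            for lineno, line in rows:
                parts = line.split("\t")
                if len(parts) < 3:
                    raise AnnotationError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                tuples.append(_parse_line(parts, str(path), lineno))
            per_song.setdefault(song_id, []).extend(tuples)
            if song_id not in order:
                order.append(song_id)
        else:  # combined-tsv
            if not rows:
                warnings.warn(f"empty annotation file skipped: {path}")
                continue
            header_no, header = rows[0]
            cols = [c.strip() for c in header.split("\t")]
            expected = ["song_id", "onset", "offset", "label"]
            if cols != expected:
                raise AnnotationError(
                    f"{path}:{header_no}: expected header {expected}, got {cols}"
                )
            for lineno, line in rows[1:]:
                parts = line.split("\t")
                if len(parts) < 4:
                    raise AnnotationError(
                        f"{path}:{lineno}: expected 4 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                song_id = parts[0].strip()
                if not song_id:
                    raise AnnotationError(f"{path}:{lineno}: empty song_id")
                tup = _parse_line(parts[1:4], str(path), lineno)
                per_song.setdefault(song_id, []).append(tup)
                if song_id not in order:
                    order.append(song_id)

    songs = []
    for song_id in order:
        tuples = [t for t in per_song[song_id] if t[2] not in excluded]
        if not tuples:
            warnings.warn(f"song {song_id!r} empty after exclusions; skipped")
            continue
        songs.append(_song_from_tuples(song_id, tuples))
    if not songs:
        raise AnnotationError("no songs parsed from input")
    return Corpus(songs=songs, subject_id=subject_id)


def write_annotations(
    corpus: Corpus,
    target: str | Path,
    dialect: str = "label-track",
) -> list[Path]:
    """Write a corpus back to disk; inverse of :func:`read_annotations`.

    For ``label-track``, ``target`` is a directory receiving one
    ``<song_id>.txt`` per song; for ``combined-tsv``, ``target`` is a single
    file path.  Returns the written paths.
    """
    target = Path(target)
    written: list[Path] = []
    if dialect == "label-track":
        target.mkdir(parents=True, exist_ok=True)
        for song in corpus.songs:
            p = target / f"{song.song_id}.txt"
            p.write_text(
                "".join(
                    f"{ph.onset:.6f}\t{ph.offset:.6f}\t{ph.label}\n"
                    for ph in song.phrases
                ),
                encoding="utf-8",
            )
            written.append(p)
    elif dialect == "combined-tsv":
        target.parent.mkdir(parents=True, exist_ok=True)
        lines = ["song_id\tonset\toffset\tlabel"]
        for song in corpus.songs:
            for ph in song.phrases:
                lines.append(
                    f"{song.song_id}\t{ph.onset:.6f}\t{ph.offset:.6f}\t{ph.label}"
                )
        target.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(target)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return written


# ---------------------------------------------------------------------------
# derived views


def corpus_to_sequences(corpus: Corpus) -> list[list[str]]:
    """Symbol sequence (ordered phrase labels) of each song, in corpus order."""
    return [song.labels() for song in corpus.songs]


def phrase_records(corpus: Corpus) -> list[PhraseRecord]:
    """One context-annotated record per phrase (prev/next within-song only)."""
    records: list[PhraseRecord] = []
    for song in corpus.songs:
        n = len(song.phrases)
        for i, ph in enumerate(song.phrases):
            records.append(
                PhraseRecord(
                    label=ph.label,
                    duration=ph.duration,
                    prev_label=song.phrases[i - 1].label if i > 0 else BOUNDARY,
                    next_label=(
                        song.phrases[i + 1].label if i < n - 1 else BOUNDARY
                    ),
                    position_index=i,
                    song_id=song.song_id,
                )
            )
    return records


def records_frame(records: Sequence[PhraseRecord]):
    """Phrase records as a pandas DataFrame (one row per phrase)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "song_id": [r.song_id for r in records],
            "position_index": [r.position_index for r in records],
            "label": [r.label for r in records],
            "duration": [r.duration for r in records],
            "prev_label": [r.prev_label for r in records],
            "next_label": [r.next_label for r in records],
        }
    )
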