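"""Read and write narratives, span annotations, scores, and reports.

The interchange formats are deliberately plain: UTF-8 CSV (RFC 4180) or XLSX
for narratives, a segment-level CSV (one row per annotated span, ordered) for
annotations, and a flat CSV for per-narrative scores.  All reads collapse runs
of whitespace to single spaces, because transcripts arrive from heterogeneous
exports with inconsistent spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ConfigError, ConsistencyError, FormatError, ValidationError

INTERNAL = "internal"
EXTERNAL = "external"
CATEGORIES = (INTERNAL, EXTERNAL)

Category = Literal["internal", "external"]


def normalize_whitespace(text: str) -> str:
    """Collapse all runs of whitespace to single spaces and strip the ends."""
    return " ".join(str(text).split())


def _word_count(text: str) -> int:
    return len(text.split())


@dataclass(frozen=True)
class Narrative:
    """One participant narrative (a memory, simulation, or writing sample).

    ``dataset_id`` is the grouping key for leave-one-dataset-out evaluation;
    ``task`` (memory | future | writing | other) is carried as metadata only.
    """

    narrative_id: str
    text: str
    dataset_id: str = ""
    task: str = "other"

    @property
    def is_empty(self) -> bool:
        return not self.text.strip()


@dataclass(frozen=True)
class AnnotatedSegment:
    """A contiguous span manually tagged internal or external.

    ``detail_count`` is the number of manually scored details in the span;
    zero is legal (filler text inside a span).
    """

    text: str
    category: Category
    detail_count: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"segment category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.detail_count < 0:
            raise ValidationError("detail_count must be non-negative")

    @property
    def word_count(self) -> int:
        return _word_count(self.text)


@dataclass(frozen=True)
class AnnotatedNarrative:
    """A narrative plus its ordered spans and manual per-category totals.

    Invariants (enforced at construction): the totals equal the sums over the
    corresponding segments, and the concatenated segments reconstruct the
    narrative text up to whitespace normalization.
    """

    narrative: Narrative
    segments: tuple[AnnotatedSegment, ...]
    internal_details: int = field(default=-1)
    external_details: int = field(default=-1)
    internal_words: int = field(default=-1)
    external_words: int = field(default=-1)

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        sums = {
            "internal_details": sum(s.detail_count for s in segs if s.category == INTERNAL),
            "external_details": sum(s.detail_count for s in segs if s.category == EXTERNAL),
            "internal_words": sum(s.word_count for s in segs if s.category == INTERNAL),
            "external_words": sum(s.word_count for s in segs if s.category == EXTERNAL),
        }
        for name, value in sums.items():
            provided = getattr(self, name)
            if provided < 0:
                object.__setattr__(self, name, value)
            elif provided != value:
                raise ConsistencyError(
                    f"narrative {self.narrative.narrative_id!r}: provided {name}="
                    f"{provided} but recomputed {value} from segments"
                )
        joined = normalize_whitespace(" ".join(s.text for s in segs))
        if joined != normalize_whitespace(self.narrative.text):
            raise ValidationError(
                f"narrative {self.narrative.narrative_id!r}: segments do not "
                "reconstruct the narrative text"
            )

    @classmethod
    def from_segments(
        cls,
        narrative_id: str,
        segments: Iterable[AnnotatedSegment],
        dataset_id: str = "",
        task: str = "other",
    ) -> "AnnotatedNarrative":
        segs = tuple(segments)
        text = normalize_whitespace(" ".join(s.text for s in segs))
        return cls(Narrative(narrative_id, text, dataset_id, task), segs)

    @property
    def total_words(self) -> int:
        return self.internal_words + self.external_words


@dataclass(frozen=True)
class NarrativeScore:
    """Automated estimate of internal/external content in one narrative.

    Internal and external predicted word counts must sum to the narrative's
    total word count (conservation); ``flagged_empty`` marks narratives that
    were empty after preprocessing and scored (0, 0, 0).
    """

    narrative_id: str
    predicted_internal_words: float
    predicted_external_words: float
    total_words: int
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        if self.predicted_internal_words < 0 or self.predicted_external_words < 0:
            raise ValidationError("predicted word counts must be non-negative")
        total = self.predicted_internal_words + self.predicted_external_words
        tol = 1e-9 * max(self.total_words, 1)
        if not math.isclose(total, self.total_words, abs_tol=tol):
            raise ValidationError(
                f"narrative {self.narrative_id!r}: predicted internal + external "
                f"({total}) != total_words ({self.total_words})"
            )


# ---------------------------------------------------------------------------
# Narrative spreadsheets
# ---------------------------------------------------------------------------

_NARRATIVE_REQUIRED = ("narrative_id", "text")


def _read_table(path: str | Path, format: str | None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if format == "xlsx":
        return pd.read_excel(path, dtype=str)
    if format == "csv":
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    raise ConfigError(f"unknown narrative file format {format!r} (expected csv or xlsx)")


def read_narratives(
    path: str | Path, format: Literal["csv", "xlsx"] | None = None
) -> list[Narrative]:
    """Read narratives from a CSV or XLSX spreadsheet.

    Requires ``narrative_id`` and ``text`` columns; ``dataset_id`` defaults to
    the file stem and ``task`` to "other".  Rows whose text is empty after
    whitespace normalization are dropped.  Raises :class:`FormatError` for a
    missing required column and :class:`ValidationError` for duplicate ids.
    """
    path = Path(path)
    df = _read_table(path, format)
    df = df.fillna("")
    for col in _NARRATIVE_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"narrative file {path} is missing required column {col!r}")
    ids = [str(i) for i in df["narrative_id"]]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate narrative_id values: {dupes}")
    default_dataset = path.stem
    out: list[Narrative] = []
    for _, row in df.iterrows():
        text = normalize_whitespace(row["text"])
        if not text:
            continue
        out.append(
            Narrative(
                narrative_id=str(row["narrative_id"]),
                text=text,
                dataset_id=str(row.get("dataset_id", "") or default_dataset),
                task=str(row.get("task", "") or "other"),
            )
        )
    return out


def write_narratives(narratives: Sequence[Narrative], path: str | Path) -> None:
    pd.DataFrame(
        {
            "narrative_id": [n.narrative_id for n in narratives],
            "dataset_id": [n.dataset_id for n in narratives],
            "task": [n.task for n in narratives],
            "text": [n.text for n in narratives],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Segment-level annotations
# ---------------------------------------------------------------------------

_ANNOTATION_REQUIRED = ("narrative_id", "segment_index", "text", "category", "detail_count")


def read_annotations(
    path: str | Path, totals: str | Path | None = None
) -> list[AnnotatedNarrative]:
    """Read span annotations from a segment-level CSV.

    One row per span with columns ``narrative_id, segment_index, text,
    category, detail_count`` (optional ``dataset_id``, ``task``).  Segments are
    grouped by narrative and ordered by ``segment_index``; narrative totals are
    recomputed from the segments.  If ``totals`` points to a CSV with columns
    ``narrative_id, internal_details, external_details`` the recomputed totals
    are checked against it and a :class:`ConsistencyError` names any narrative
    that disagrees.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _ANNOTATION_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"annotation file {path} is missing required column {col!r}")
    df["segment_index"] = df["segment_index"].astype(int)
    df["detail_count"] = df["detail_count"].astype(int)
    bad = sorted(set(df["category"]) - set(CATEGORIES))
    if bad:
        raise ValidationError(f"unknown segment categories: {bad}")

    out: list[AnnotatedNarrative] = []
    for nid, group in df.groupby("narrative_id", sort=False):
        group = group.sort_values("segment_index")
        segs = [
            AnnotatedSegment(
                text=normalize_whitespace(r["text"]),
                category=r["category"],
                detail_count=int(r["detail_count"]),
            )
            for _, r in group.iterrows()
        ]
        dataset_id = str(group.iloc[0].get("dataset_id", "") or path.stem)
        task = str(group.iloc[0].get("task", "") or "other")
        out.append(AnnotatedNarrative.from_segments(str(nid), segs, dataset_id, task))

    if totals is not None:
        tdf = pd.read_csv(totals)
        by_id = {a.narrative.narrative_id: a for a in out}
        for _, row in tdf.iterrows():
            nid = str(row["narrative_id"])
            ann = by_id.get(nid)
            if ann is None:
                continue
            for col, attr in (
                ("internal_details", "internal_details"),
                ("external_details", "external_details"),
            ):
                if col in tdf.columns and int(row[col]) != getattr(ann, attr):
                    raise ConsistencyError(
                        f"narrative {nid!r}: provided {col}={int(row[col])} but "
                        f"segments sum to {getattr(ann, attr)}"
                    )
    return out


def write_annotations(annotated: Sequence[AnnotatedNarrative], path: str | Path) -> None:
    rows = []
    for ann in annotated:
        for idx, seg in enumerate(ann.segments):
            rows.append(
                {
                    "narrative_id": ann.narrative.narrative_id,
                    "dataset_id": ann.narrative.dataset_id,
                    "task": ann.narrative.task,
                    "segment_index": idx,
                    "text": seg.text,
                    "category": seg.category,
                    "detail_count": seg.detail_count,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def write_scores(scores: Sequence[NarrativeScore], path: str | Path) -> None:
    """Write scores as CSV (narrative_id, predicted internal/external, total)."""
    pd.DataFrame(
        {
            "narrative_id": [s.narrative_id for s in scores],
            "predicted_internal_words": [s.predicted_internal_words for s in scores],
            "predicted_external_words": [s.predicted_external_words for s in scores],
            "total_words": [s.total_words for s in scores],
        }
    ).to_csv(path, index=False)


def read_scores(path: str | Path) -> list[NarrativeScore]:
    df = pd.read_csv(path)
    for col in ("narrative_id", "predicted_internal_words", "predicted_external_words", "total_words"):
        if col not in df.columns:
            raise FormatError(f"score file {path} is missing required column {col!r}")
    return [
        NarrativeScore(
            narrative_id=str(r["narrative_id"]),
            predicted_internal_words=float(r["predicted_internal_words"]),
            predicted_external_words=float(r["predicted_external_words"]),
            total_words=int(r["total_words"]),
        )
        for _, r in df.iterrows()
    ]
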