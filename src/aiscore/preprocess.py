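"""Turn raw narrative text into clean, ordered sentences; training-time filters.

The scoring pipeline operates sentence by sentence, so sentence boundary
detection matters: transcripts with sparse punctuation collapse into run-on
"sentences" that mix episodic and non-episodic content, which is the dominant
failure mode of automated scoring.  The default splitter is rule-based
(terminal punctuation plus an abbreviation list); an alternative boundary
backend can be plugged in via the ``splitter`` argument wherever sentences are
produced.

A "word" throughout the package is a whitespace-delimited token; punctuation
stays attached to its token, and hyphens/em-dashes do not split tokens.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Pattern, Sequence

from .corpus_io import AnnotatedNarrative, normalize_whitespace
from .errors import ConfigError

__all__ = [
    "Sentence",
    "strip_prompts",
    "split_sentences",
    "word_count",
    "sentence_detail_counts",
    "filter_long_sentences",
    "DEFAULT_ABBREVIATIONS",
]


@dataclass(frozen=True)
class Sentence:
    """One sentence of a narrative, at its 0-based position."""

    narrative_id: str
    index: int
    text: str
    word_count: int

    @classmethod
    def make(cls, narrative_id: str, index: int, text: str) -> "Sentence":
        return cls(narrative_id, index, text, word_count(text))


def word_count(text: str) -> int:
    """Number of whitespace-delimited tokens; empty or blank text counts 0."""
    return len(text.split())


def strip_prompts(text: str, prompts: Sequence[str | Pattern[str]]) -> str:
    """Remove researcher prompts (e.g., "tell me more about that") from text.

    Prompts are user-supplied literal strings or compiled regex patterns; every
    occurrence is removed and surrounding whitespace collapsed.  With an empty
    prompt list the text is returned unchanged.  Zero matches is not an error.
    """
    if not prompts:
        return text
    out = text
    for prompt in prompts:
        if isinstance(prompt, str):
            out = out.replace(prompt, " ")
        else:
            out = prompt.sub(" ", out)
    return normalize_whitespace(out)


# Tokens ending in a period that do not terminate a sentence.  Lowercased,
# trailing closing quotes/brackets stripped before lookup.  Single capital
# initials ("J.") are handled separately.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr.", "mr.", "mrs.", "ms.", "prof.", "rev.", "gen.", "sen.", "st.",
        "jr.", "sr.", "vs.", "etc.", "e.g.", "i.e.", "cf.", "al.", "approx.",
        "appt.", "dept.", "est.", "fig.", "no.", "p.m.", "a.m.", "u.s.",
        "u.k.", "inc.", "ltd.", "co.", "mt.", "ave.", "blvd.",
    }
)

_TERMINATORS = (".", "!", "?", "…")
_CLOSERS = "\"')]’”"
_INITIAL_RE = re.compile(r"^[A-Z]\.$")
_NUMBER_RE = re.compile(r"^\d+\.$")


def _core(token: str) -> str:
    return token.rstrip(_CLOSERS)


def _ends_sentence(token: str, abbreviations: frozenset[str]) -> bool:
    core = _core(token)
    if not core or not core.endswith(_TERMINATORS):
        return False
    if core.endswith("."):
        if core.lower() in abbreviations:
            return False
        if _INITIAL_RE.match(core) or _NUMBER_RE.match(core):
            return False
    return True


def split_sentences(
    text: str,
    narrative_id: str = "",
    abbreviations: Iterable[str] | None = None,
) -> list[Sentence]:
    """Split whitespace-normalized text into non-overlapping, in-order sentences.

    Boundaries occur after a token ending in terminal punctuation (., !, ?, …)
    unless the token is a known abbreviation, a single capital initial, or a
    bare number.  Text with no terminal punctuation yields one sentence;
    empty text yields an empty list (a signal, not an exception).  The
    concatenation of the returned sentences reconstructs the input up to
    whitespace.
    """
    abbrev = DEFAULT_ABBREVIATIONS if abbreviations is None else frozenset(
        a.lower() for a in abbreviations
    )
    tokens = text.split()
    if not tokens:
        return []
    sentences: list[Sentence] = []
    current: list[str] = []
    for token in tokens:
        current.append(token)
        if _ends_sentence(token, abbrev):
            sentences.append(Sentence.make(narrative_id, len(sentences), " ".join(current)))
            current = []
    if current:
        sentences.append(Sentence.make(narrative_id, len(sentences), " ".join(current)))
    return sentences


Splitter = Callable[[str, str], list[Sentence]]


def _default_splitter(text: str, narrative_id: str = "") -> list[Sentence]:
    return split_sentences(text, narrative_id)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _segment_word_ranges(annotated: AnnotatedNarrative) -> list[tuple[int, int]]:
    ranges = []
    pos = 0
    for seg in annotated.segments:
        n = seg.word_count
        ranges.append((pos, pos + n))
        pos += n
    return ranges


def sentence_word_ranges(sentences: Sequence[Sentence]) -> list[tuple[int, int]]:
    """Token-index ranges [start, end) of each sentence within its narrative."""
    ranges = []
    pos = 0
    for s in sentences:
        ranges.append((pos, pos + s.word_count))
        pos += s.word_count
    return ranges


def sentence_detail_counts(
    annotated: AnnotatedNarrative,
    sentences: Sequence[Sentence] | None = None,
) -> list[tuple[int, int]]:
    """Per-sentence (internal, external) manual detail counts.

    A sentence's count in each category is the sum over the annotation spans it
    overlaps; a span crossing a sentence boundary contributes its detail count
    prorated by word overlap, rounded half-up per (span, sentence) pair.  The
    per-pair rounding means totals are conserved only when spans do not cross
    boundaries; the filter contracts account for this.
    """
    if sentences is None:
        sentences = split_sentences(
            normalize_whitespace(annotated.narrative.text), annotated.narrative.narrative_id
        )
    seg_ranges = _segment_word_ranges(annotated)
    sent_ranges = sentence_word_ranges(sentences)
    counts: list[tuple[int, int]] = []
    for s_start, s_end in sent_ranges:
        internal = external = 0
        for seg, (g_start, g_end) in zip(annotated.segments, seg_ranges):
            overlap = min(s_end, g_end) - max(s_start, g_start)
            if overlap <= 0 or g_end == g_start:
                continue
            share = _round_half_up(seg.detail_count * overlap / (g_end - g_start))
            if seg.category == "internal":
                internal += share
            else:
                external += share
        counts.append((internal, external))
    return counts


def filter_long_sentences(
    sentences_with_counts: Sequence[tuple[Sentence, int, int]],
    max_details: int = 8,
) -> tuple[
    list[tuple[Sentence, int, int]],
    list[tuple[Sentence, int, int]],
    dict[str, tuple[int, int]],
]:
    """Drop training/validation sentences with more than ``max_details`` details.

    Sentences carrying more than eight manually scored details are almost
    always run-ons from transcripts missing punctuation, so they are removed
    from annotated corpora before labeling.  Input items are
    ``(sentence, internal_details, external_details)``; the removal threshold
    applies to the sum.  Returns ``(retained, removed, adjustments)`` where
    ``adjustments`` maps narrative_id to the (internal, external) details
    removed with its dropped sentences, so validation totals can be updated.
    Scoring-time pipelines never call this filter.
    """
    if max_details < 1:
        raise ConfigError(f"max_details must be >= 1, got {max_details}")
    retained: list[tuple[Sentence, int, int]] = []
    removed: list[tuple[Sentence, int, int]] = []
    adjustments: dict[str, tuple[int, int]] = {}
    for item in sentences_with_counts:
        sentence, internal, external = item
        if internal + external > max_details:
            removed.append(item)
            prev = adjustments.get(sentence.narrative_id, (0, 0))
            adjustments[sentence.narrative_id] = (prev[0] + internal, prev[1] + external)
        else:
            retained.append(item)
    return retained, removed, adjustments
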