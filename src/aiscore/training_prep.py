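"""Build the four-class labeled sentence set and balance the classes.

Each sentence of an annotated narrative is labeled by the fraction of its
words that fall inside internal (episodic) spans, then binned into one of four
proportion classes — 0%, 50%, 75%, or 100% internal content — which are the
empirical clusters these fractions form in manually scored interview data.
Training sets are balanced by upsampling minority classes with replacement so
the classifier cannot exploit base rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import AnnotatedNarrative, normalize_whitespace
from .errors import ConfigError, DataError
from .preprocess import (
    Sentence,
    filter_long_sentences,
    sentence_detail_counts,
    sentence_word_ranges,
    split_sentences,
)

__all__ = [
    "ProportionClass",
    "CLASS_ORDER",
    "LabeledSentence",
    "compute_internal_fraction",
    "bin_fraction",
    "label_narrative",
    "prepare_training_sentences",
    "balance_classes",
]


class ProportionClass(str, Enum):
    """Sentence label: the proportion of its content that is internal."""

    P0 = "P0"
    P50 = "P50"
    P75 = "P75"
    P100 = "P100"

    @property
    def internal_fraction(self) -> float:
        return _CENTERS[self]


_CENTERS = {
    ProportionClass.P0: 0.0,
    ProportionClass.P50: 0.5,
    ProportionClass.P75: 0.75,
    ProportionClass.P100: 1.0,
}

#: Classes in increasing order of internal content; ties in nearest-center
#: binning and in argmax prediction resolve toward the later (higher) class.
CLASS_ORDER: tuple[ProportionClass, ...] = (
    ProportionClass.P0,
    ProportionClass.P50,
    ProportionClass.P75,
    ProportionClass.P100,
)


@dataclass(frozen=True)
class LabeledSentence:
    """A sentence with its true internal-content fraction and binned class."""

    sentence: Sentence
    internal_fraction: float
    cls: ProportionClass


def bin_fraction(fraction: float) -> ProportionClass:
    """Map an internal-content fraction to the nearest proportion class.

    Nearest of the four class centers {0, .5, .75, 1}; a tie between two
    centers goes to the higher (more internal) class.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"fraction must be in [0, 1], got {fraction}")
    best = CLASS_ORDER[0]
    best_dist = abs(fraction - best.internal_fraction)
    for cls in CLASS_ORDER[1:]:
        dist = abs(fraction - cls.internal_fraction)
        if dist <= best_dist:  # <= : ties resolve to the higher class
            best, best_dist = cls, dist
    return best


def _word_categories(annotated: AnnotatedNarrative) -> np.ndarray:
    """Boolean per-token mask over the narrative: True where internal."""
    flags: list[bool] = []
    for seg in annotated.segments:
        flags.extend([seg.category == "internal"] * seg.word_count)
    return np.asarray(flags, dtype=bool)


def compute_internal_fraction(
    sentence: Sentence,
    annotated: AnnotatedNarrative,
    token_offset: int | None = None,
) -> float:
    """Fraction of a sentence's words that fall inside internal spans.

    ``token_offset`` is the sentence's starting token index within the
    narrative; if omitted it is derived from the sentence's ``index`` by
    re-splitting the narrative text.  Zero-word sentences are undefined and
    must be excluded upstream.
    """
    if sentence.word_count == 0:
        raise DataError("internal fraction is undefined for a zero-word sentence")
    if token_offset is None:
        sentences = split_sentences(
            normalize_whitespace(annotated.narrative.text), sentence.narrative_id
        )
        if sentence.index >= len(sentences):
            raise DataError(
                f"sentence index {sentence.index} outside narrative "
                f"{annotated.narrative.narrative_id!r}"
            )
        token_offset = sentence_word_ranges(sentences)[sentence.index][0]
    mask = _word_categories(annotated)
    window = mask[token_offset : token_offset + sentence.word_count]
    if len(window) != sentence.word_count:
        raise DataError(
            f"sentence extends past narrative {annotated.narrative.narrative_id!r}"
        )
    return float(window.sum()) / sentence.word_count


def label_narrative(annotated: AnnotatedNarrative) -> list[LabeledSentence]:
    """Split an annotated narrative into sentences and label each one."""
    sentences = split_sentences(
        normalize_whitespace(annotated.narrative.text), annotated.narrative.narrative_id
    )
    mask = _word_categories(annotated)
    out: list[LabeledSentence] = []
    for (start, end), sent in zip(sentence_word_ranges(sentences), sentences):
        if sent.word_count == 0:
            continue
        fraction = float(mask[start:end].sum()) / sent.word_count
        out.append(LabeledSentence(sent, fraction, bin_fraction(fraction)))
    return out


def prepare_training_sentences(
    annotated: Iterable[AnnotatedNarrative],
    max_details: int = 8,
    seed: int = 0,
    balance: bool = True,
) -> list[LabeledSentence]:
    """Full training-data preparation: label, filter run-ons, balance.

    Labels every sentence of every narrative, removes sentences carrying more
    than ``max_details`` manual details (run-ons from unpunctuated
    transcripts), then upsamples minority classes to the majority count.
    """
    labeled: list[LabeledSentence] = []
    for ann in annotated:
        sentences = split_sentences(
            normalize_whitespace(ann.narrative.text), ann.narrative.narrative_id
        )
        counts = sentence_detail_counts(ann, sentences)
        with_counts = [(s, c[0], c[1]) for s, c in zip(sentences, counts)]
        retained, _, _ = filter_long_sentences(with_counts, max_details=max_details)
        kept = {(item[0].index) for item in retained}
        for ls in label_narrative(ann):
            if ls.sentence.index in kept:
                labeled.append(ls)
    if balance:
        labeled = balance_classes(labeled, seed=seed)
    return labeled


def balance_classes(
    labeled: Sequence[LabeledSentence],
    seed: int = 0,
    classes: Sequence[ProportionClass] | None = None,
) -> list[LabeledSentence]:
    """Upsample minority classes with replacement to the majority class count.

    Every original element is retained; additions are drawn with replacement
    from the existing members of each minority class, in fixed label order
    from a single seeded RNG stream, so the result is deterministic given the
    seed.  Raises :class:`DataError` if a required class has no members.
    """
    required = tuple(classes) if classes is not None else CLASS_ORDER
    groups: dict[ProportionClass, list[LabeledSentence]] = {c: [] for c in required}
    for ls in labeled:
        if ls.cls in groups:
            groups[ls.cls].append(ls)
    empty = [c.value for c in required if not groups[c]]
    if empty:
        raise DataError(f"cannot upsample empty classes: {empty}")
    target = max(len(g) for g in groups.values())
    rng = np.random.default_rng(seed)
    out = list(labeled)
    for cls in (c for c in CLASS_ORDER if c in groups):
        members = groups[cls]
        deficit = target - len(members)
        if deficit > 0:
            picks = rng.integers(0, len(members), size=deficit)
            out.extend(members[i] for i in picks)
    return out
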