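"""Generate annotated interview-like narratives with known structure.

The scored interview datasets this pipeline was designed for are private, so
every stage is validated on a synthetic corpus whose ground truth is known by
construction.  Sentences are composed from two disjoint template vocabularies
— an "internal" lexicon (past-tense, perceptual, event-specific words) and an
"external" lexicon (habitual/semantic words) — so that each sentence hits an
exact internal-content fraction in {0, .5, .75, 1}.  Manual detail counts are
generated as a noisy linear function of segment word counts, deliberately
encoding the empirical near-proxy relationship between detail counts and word
counts (r ~ .86-.98 in scored interview data) as the generative assumption.

Realism is a non-goal: template text keeps class separability controllable so
that classifier-recovery tests measure the pipeline, not the encoder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import AnnotatedNarrative, AnnotatedSegment
from .errors import ConfigError
from .training_prep import ProportionClass

__all__ = [
    "DatasetSpec",
    "GeneratorConfig",
    "generate_corpus",
    "shuffle_labels",
    "INTERNAL_LEXICON",
    "EXTERNAL_LEXICON",
]

# Past-tense / perceptual / event-specific vocabulary (episodic content).
INTERNAL_LEXICON: tuple[str, ...] = (
    "yesterday", "sand", "waves", "sunlight", "laughed", "grabbed", "tasted",
    "salty", "breeze", "jacket", "blue", "boat", "dock", "morning", "ran",
    "shouted", "glimpsed", "warm", "rain", "umbrella", "stumbled", "kitchen",
    "candles", "flickered", "whispered", "gravel", "path", "sunset", "crimson",
    "coat", "smelled", "coffee", "spilled", "bench", "pigeons", "scarf",
    "slipped", "ice", "gleamed", "window", "hummed", "melody", "wooden",
    "stairs", "creaked", "lantern", "glowing", "fog", "harbour", "bells",
    "rang", "twice", "noticed", "freckles", "gasped", "suddenly", "dripping",
    "velvet", "curtain", "trembled",
)

# Habitual / semantic / metacognitive vocabulary (non-episodic content).
EXTERNAL_LEXICON: tuple[str, ...] = (
    "generally", "usually", "people", "believe", "beaches", "popular",
    "summers", "tend", "crowded", "history", "families", "often", "visit",
    "tradition", "knowledge", "always", "enjoy", "vacations", "typically",
    "weather", "seasons", "climate", "regions", "famous", "culture",
    "societies", "value", "education", "cities", "grow", "economies",
    "depend", "tourism", "research", "shows", "humans", "prefer", "routines",
    "habits", "form", "slowly", "opinions", "differ", "widely", "experts",
    "argue", "statistics", "suggest", "populations", "change", "countries",
    "maintain", "customs", "communities", "gather", "annually", "markets",
    "operate", "daily", "institutions",
)

_TERMINATORS = (".", ".", ".", ".", "!", "?")  # mostly periods, as in prose


@dataclass(frozen=True)
class DatasetSpec:
    """One synthetic dataset: its id, task tag, and class mixing weights."""

    dataset_id: str
    class_mix: dict = field(
        default_factory=lambda: {
            ProportionClass.P0: 0.35,
            ProportionClass.P50: 0.10,
            ProportionClass.P75: 0.10,
            ProportionClass.P100: 0.45,
        }
    )
    task: str = "memory"

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"class_mix weights for {self.dataset_id!r} must sum to 1, got {total}"
            )
        if any(w < 0 for w in self.class_mix.values()):
            raise ConfigError("class_mix weights must be non-negative")


def default_datasets() -> list[DatasetSpec]:
    """Three emulated study datasets with mildly different class mixes."""
    return [
        DatasetSpec(
            "memories_a",
            {
                ProportionClass.P0: 0.30,
                ProportionClass.P50: 0.10,
                ProportionClass.P75: 0.10,
                ProportionClass.P100: 0.50,
            },
            task="memory",
        ),
        DatasetSpec(
            "simulations_b",
            {
                ProportionClass.P0: 0.35,
                ProportionClass.P50: 0.10,
                ProportionClass.P75: 0.10,
                ProportionClass.P100: 0.45,
            },
            task="future",
        ),
        DatasetSpec(
            "writing_c",
            {
                ProportionClass.P0: 0.40,
                ProportionClass.P50: 0.10,
                ProportionClass.P75: 0.10,
                ProportionClass.P100: 0.40,
            },
            task="writing",
        ),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-corpus parameters.

    ``n_narratives`` is per dataset.  ``sentences_per_narrative`` sets the
    sentence-count scale: pure-class (P0/P100) sentence counts are drawn
    independently per narrative with expectation weight x mean, while
    mixed-class (P50/P75) counts are held at their rounded expectation — this
    keeps per-narrative internal and external totals nearly independent
    across narratives, matching the validation property of scored interview
    data.  ``details_per_word_rate`` and ``proxy_noise_sd`` control the
    detail-count model ``round(rate x words + N(0, sd))`` clipped at zero;
    the defaults land the detail/word correlation in the .86-.98 band.
    ``punctuation_dropout`` deletes each sentence terminator with the given
    probability, emulating unpunctuated transcription.
    """

    n_narratives: int = 100
    datasets: tuple[DatasetSpec, ...] = field(
        default_factory=lambda: tuple(default_datasets())
    )
    sentences_per_narrative: tuple[int, int] = (6, 12)
    words_per_segment: tuple[int, int] = (4, 12)
    details_per_word_rate: float = 0.3
    proxy_noise_sd: float = 0.45
    punctuation_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_narratives < 1:
            raise ConfigError("n_narratives must be positive")
        lo, hi = self.sentences_per_narrative
        wlo, whi = self.words_per_segment
        if lo > hi or lo < 1 or wlo > whi or wlo < 1:
            raise ConfigError("ranges must be non-empty with positive bounds")
        if self.details_per_word_rate <= 0:
            raise ConfigError("details_per_word_rate must be positive")
        if self.proxy_noise_sd < 0:
            raise ConfigError("proxy_noise_sd must be non-negative")
        if not 0.0 <= self.punctuation_dropout <= 1.0:
            raise ConfigError("punctuation_dropout must be in [0, 1]")
        if not self.datasets:
            raise ConfigError("at least one dataset spec is required")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _chunk(rng: np.random.Generator, lexicon: Sequence[str], n_words: int) -> str:
    return " ".join(rng.choice(lexicon, size=n_words))


def _sentence_segments(
    rng: np.random.Generator, cls: ProportionClass, config: GeneratorConfig
) -> list[tuple[str, str]]:
    """(text, category) parts of one sentence hitting the class fraction exactly."""
    wlo, whi = config.words_per_segment
    if cls is ProportionClass.P0:
        return [(_chunk(rng, EXTERNAL_LEXICON, int(rng.integers(wlo, whi + 1))), "external")]
    if cls is ProportionClass.P100:
        return [(_chunk(rng, INTERNAL_LEXICON, int(rng.integers(wlo, whi + 1))), "internal")]
    # Mixed-class sentences use fixed segment sizes so that their equal/3:1
    # word split adds no cross-category covariance: internal and external
    # totals then covary across narratives only through sampling noise,
    # matching the near-zero misclassification correlations of manually
    # scored interview data.  Sizes sit at the words_per_segment midpoint so
    # every segment honours the configured range.
    mean = (wlo + whi) / 2.0
    if cls is ProportionClass.P50:
        half = max(1, _round_half_up(mean))
        parts = [
            (_chunk(rng, INTERNAL_LEXICON, half), "internal"),
            (_chunk(rng, EXTERNAL_LEXICON, half), "external"),
        ]
    else:  # P75
        unit = max(1, min(_round_half_up(mean / 2), whi // 3 or 1))
        parts = [
            (_chunk(rng, INTERNAL_LEXICON, 3 * unit), "internal"),
            (_chunk(rng, EXTERNAL_LEXICON, unit), "external"),
        ]
    if rng.random() < 0.5:
        parts.reverse()
    return parts


def _class_counts(
    rng: np.random.Generator, spec: DatasetSpec, config: GeneratorConfig
) -> dict[ProportionClass, int]:
    """Per-narrative sentence counts: pure classes vary, mixed stay steady."""
    lo, hi = config.sentences_per_narrative
    mean = (lo + hi) / 2.0
    counts: dict[ProportionClass, int] = {}
    for cls in (ProportionClass.P0, ProportionClass.P100):
        w = spec.class_mix.get(cls, 0.0)
        c_lo = max(0, int(math.floor(w * lo)))
        c_hi = max(c_lo, int(math.ceil(w * hi)))
        counts[cls] = int(rng.integers(c_lo, c_hi + 1))
    for cls in (ProportionClass.P50, ProportionClass.P75):
        counts[cls] = _round_half_up(spec.class_mix.get(cls, 0.0) * mean)
    if sum(counts.values()) == 0:
        counts[ProportionClass.P100] = 1
    return counts


def _detail_count(rng: np.random.Generator, n_words: int, config: GeneratorConfig) -> int:
    raw = config.details_per_word_rate * n_words + rng.normal(0.0, config.proxy_noise_sd)
    return max(0, _round_half_up(raw))


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedNarrative]:
    """Generate ``n_narratives`` annotated narratives per configured dataset.

    Fully deterministic given ``config.seed``.  Every narrative satisfies the
    annotated-narrative invariants, and (with no punctuation dropout) every
    sentence's true internal fraction lies exactly on the class grid
    {0, .5, .75, 1}.
    """
    rng = np.random.default_rng(config.seed)
    corpus: list[AnnotatedNarrative] = []
    for spec in config.datasets:
        for i in range(config.n_narratives):
            narrative_id = f"{spec.dataset_id}-{i:04d}"
            counts = _class_counts(rng, spec, config)
            classes: list[ProportionClass] = []
            for cls, n in counts.items():
                classes.extend([cls] * n)
            rng.shuffle(classes)  # interleave classes within the narrative
            segments: list[AnnotatedSegment] = []
            for cls in classes:
                parts = _sentence_segments(rng, cls, config)
                if rng.random() >= config.punctuation_dropout:
                    text, cat = parts[-1]
                    parts[-1] = (text + rng.choice(_TERMINATORS), cat)
                for text, category in parts:
                    segments.append(
                        AnnotatedSegment(
                            text=text,
                            category=category,
                            detail_count=_detail_count(
                                rng, len(text.split()), config
                            ),
                        )
                    )
            corpus.append(
                AnnotatedNarrative.from_segments(
                    narrative_id, segments, dataset_id=spec.dataset_id, task=spec.task
                )
            )
    return corpus


def shuffle_labels(
    corpus: Iterable[AnnotatedNarrative], seed: int
) -> list[AnnotatedNarrative]:
    """Randomly permute span categories across the whole corpus.

    Text and word counts are untouched; only the internal/external tags move,
    so detail totals become decoupled from the text content.  Used to build
    null models for the independence checks.  Deterministic given ``seed``.
    """
    corpus = list(corpus)
    categories = [seg.category for ann in corpus for seg in ann.segments]
    rng = np.random.default_rng(seed)
    permuted = [categories[i] for i in rng.permutation(len(categories))]
    out: list[AnnotatedNarrative] = []
    pos = 0
    for ann in corpus:
        segs = []
        for seg in ann.segments:
            segs.append(replace(seg, category=permuted[pos]))
            pos += 1
        out.append(
            AnnotatedNarrative.from_segments(
                ann.narrative.narrative_id,
                segs,
                dataset_id=ann.narrative.dataset_id,
                task=ann.narrative.task,
            )
        )
    return out
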