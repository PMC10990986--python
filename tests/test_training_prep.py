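"""Fraction binning, sentence labeling, and class balancing."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aiscore import (
    AnnotatedNarrative,
    AnnotatedSegment,
    DataError,
    LabeledSentence,
    ProportionClass,
    balance_classes,
    bin_fraction,
    compute_internal_fraction,
    label_narrative,
)
from aiscore.errors import ConfigError
from aiscore.preprocess import Sentence, split_sentences
from aiscore.training_prep import CLASS_ORDER

CENTERS = {c: c.internal_fraction for c in CLASS_ORDER}


def brute_force_bin(fraction: float) -> ProportionClass:
    """Independent nearest-center search; ties resolved to the higher class."""
    best, best_d = None, None
    for cls in CLASS_ORDER:  # increasing internal order; later wins ties
        d = abs(fraction - CENTERS[cls])
        if best_d is None or d <= best_d:
            best, best_d = cls, d
    return best


class TestBinFraction:
    @pytest.mark.parametrize(
        "fraction, expected",
        [
            (0.5, ProportionClass.P50),
            (0.6, ProportionClass.P50),
            (0.25, ProportionClass.P50),  # tie with P0 -> higher class
            (0.625, ProportionClass.P75),  # tie with P50 -> higher class
            (0.875, ProportionClass.P100),  # tie with P75 -> higher class
            (0.1, ProportionClass.P0),
            (1.0, ProportionClass.P100),
        ],
    )
    def test_nearest_center_with_higher_ties(self, fraction, expected):
        assert bin_fraction(fraction) == expected

    def test_centers_are_fixed_points(self):
        for cls in CLASS_ORDER:
            assert bin_fraction(cls.internal_fraction) == cls

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bin_fraction(1.01)
        with pytest.raises(ConfigError):
            bin_fraction(-0.01)

    def test_matches_brute_force_on_grid(self):
        for k in range(10_001):
            f = k / 10_000
            assert bin_fraction(f) == brute_force_bin(f)


class TestComputeInternalFraction:
    def _ann(self):
        return AnnotatedNarrative.from_segments(
            "n1",
            [
                AnnotatedSegment("warm sand and salty waves rolled", "internal", 3),
                AnnotatedSegment("beaches are crowded.", "external", 1),
                AnnotatedSegment("People usually visit in summer.", "external", 2),
                AnnotatedSegment("I grabbed the blue umbrella today.", "internal", 2),
            ],
        )

    def test_mixed_sentence_fraction(self):
        ann = self._ann()
        sentences = split_sentences(ann.narrative.text, "n1")
        # first sentence: 6 internal words + 3 external words = 2/3 internal
        assert compute_internal_fraction(sentences[0], ann) == pytest.approx(6 / 9)

    def test_pure_sentences(self):
        ann = self._ann()
        sentences = split_sentences(ann.narrative.text, "n1")
        assert compute_internal_fraction(sentences[1], ann) == 0.0
        assert compute_internal_fraction(sentences[2], ann) == 1.0

    def test_zero_word_sentence_rejected(self):
        ann = self._ann()
        empty = Sentence("n1", 0, "", 0)
        with pytest.raises(DataError):
            compute_internal_fraction(empty, ann)

    def test_label_narrative_bins_fractions(self):
        ann = self._ann()
        labeled = label_narrative(ann)
        assert [ls.cls for ls in labeled] == [
            ProportionClass.P75,  # 2/3 internal is nearest .75
            ProportionClass.P0,
            ProportionClass.P100,
        ]


def _labeled(cls: ProportionClass, i: int) -> LabeledSentence:
    return LabeledSentence(
        Sentence("n", i, f"text {cls.value} {i}", 3), cls.internal_fraction, cls
    )


def _make(counts: dict[ProportionClass, int]) -> list[LabeledSentence]:
    out = []
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            out.append(_labeled(cls, i))
            i += 1
    return out


class TestBalanceClasses:
    def test_worked_example_10000_8000(self):
        labeled = _make(
            {
                ProportionClass.P100: 10_000,
                ProportionClass.P75: 8_000,
                ProportionClass.P50: 8_000,
                ProportionClass.P0: 8_000,
            }
        )
        balanced = balance_classes(labeled, seed=0)
        counts = Counter(ls.cls for ls in balanced)
        assert counts == {cls: 10_000 for cls in CLASS_ORDER}
        assert len(balanced) - len(labeled) == 3 * 2_000

    def test_already_balanced_is_identity(self):
        labeled = _make({cls: 5 for cls in CLASS_ORDER})
        assert balance_classes(labeled, seed=0) == labeled

    def test_restricted_classes(self):
        labeled = _make({ProportionClass.P0: 3, ProportionClass.P100: 1})
        balanced = balance_classes(
            labeled, seed=0, classes=[ProportionClass.P0, ProportionClass.P100]
        )
        counts = Counter(ls.cls for ls in balanced)
        assert counts[ProportionClass.P0] == 3
        assert counts[ProportionClass.P100] == 3
        assert len(balanced) == 6

    def test_empty_class_named_in_error(self):
        labeled = _make({ProportionClass.P0: 3, ProportionClass.P100: 1})
        with pytest.raises(DataError, match="P50"):
            balance_classes(labeled, seed=0)

    def test_deterministic_given_seed(self):
        labeled = _make({ProportionClass.P0: 7, ProportionClass.P50: 3,
                         ProportionClass.P75: 2, ProportionClass.P100: 5})
        assert balance_classes(labeled, seed=42) == balance_classes(labeled, seed=42)

    def test_additions_are_duplicates_and_originals_retained(self):
        labeled = _make({ProportionClass.P0: 6, ProportionClass.P50: 2,
                         ProportionClass.P75: 4, ProportionClass.P100: 3})
        balanced = balance_classes(labeled, seed=1)
        # every original element retained, in order, as a prefix
        assert balanced[: len(labeled)] == labeled
        # every addition is a duplicate of an existing member of its class
        originals = set(id(ls) for ls in labeled)
        for ls in balanced[len(labeled):]:
            assert id(ls) in originals

    @given(
        st.tuples(
            st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30)
        ),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_balanced_counts_property(self, counts, seed):
        labeled = _make(dict(zip(CLASS_ORDER, counts)))
        balanced = balance_classes(labeled, seed=seed)
        tally = Counter(ls.cls for ls in balanced)
        assert set(tally.values()) == {max(counts)}
        assert len(balanced) == 4 * max(counts)
        # distinct sentence identities unchanged
        assert {ls.sentence.text for ls in balanced} == {
            ls.sentence.text for ls in labeled
        }
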