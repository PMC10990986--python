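"""Quadrant reports, proxy validation, and leave-one-dataset-out folds."""

import warnings

import numpy as np
import pytest

from aiscore import (
    ConfigError,
    DatasetSpec,
    GeneratorConfig,
    NarrativeScore,
    OracleClassifier,
    ProportionClass,
    TrainConfig,
    ValidationError,
    generate_corpus,
    leave_one_dataset_out,
    proxy_validation,
    quadrant_report,
    score_corpus,
)
from aiscore.evaluation import pearson
from aiscore.training_prep import prepare_training_sentences


def _scores(ids, internal, external):
    """Build conserving scores with the given predicted-internal values."""
    out = []
    for i, a, b in zip(ids, internal, external):
        total = int(round(a + b))
        out.append(NarrativeScore(i, float(a), float(total - a), total))
    return out


def textbook_pearson(x, y):
    """Independent reference: covariance over product of standard deviations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestQuadrantReport:
    def test_truth_fed_as_predictions_gives_unit_diagonal(self):
        ids = ["a", "b", "c", "d"]
        truth = {i: (k + 1.0, 10.0 - k) for k, i in enumerate(ids)}
        scores = _scores(ids, [v[0] for v in truth.values()], [v[1] for v in truth.values()])
        report = quadrant_report(scores, truth)
        assert report.r_int_int == pytest.approx(1.0)
        assert report.r_ext_ext == pytest.approx(1.0)

    def test_hand_computable_linear_case(self):
        ids = ["a", "b", "c", "d"]
        truth = {i: (k + 1.0, 5.0) for k, i in enumerate(ids)}
        scores = _scores(ids, [2, 4, 6, 8], [3, 3, 3, 3])
        report = quadrant_report(scores, truth)
        assert report.r_int_int == pytest.approx(1.0)
        assert report.r_ext_ext is None  # both columns constant -> undefined

    def test_agrees_with_textbook_pearson(self):
        rng = np.random.default_rng(17)
        ids = [str(i) for i in range(50)]
        ti, te = rng.normal(10, 3, 50), rng.normal(8, 2, 50)
        pi, pe = rng.normal(20, 5, 50), rng.normal(15, 4, 50)
        truth = {i: (a, b) for i, a, b in zip(ids, ti, te)}
        scores = _scores(ids, np.abs(pi), np.abs(pe))
        report = quadrant_report(scores, truth)
        assert report.r_int_int == pytest.approx(
            textbook_pearson(ti, np.abs(pi)), abs=1e-12
        )
        assert report.r_ext_int == pytest.approx(
            textbook_pearson(te, np.abs(pi)), abs=1e-12
        )
        assert report.r2_int_int == pytest.approx(report.r_int_int**2, abs=1e-12)

    def test_misaligned_ids_rejected(self):
        scores = _scores(["a", "b", "c"], [1, 2, 3], [3, 2, 1])
        with pytest.raises(ValidationError):
            quadrant_report(scores, {"a": (1, 1), "b": (2, 2), "x": (3, 3)})

    def test_permuted_truth_breaks_all_correlations(self):
        """Null model: pairing each narrative's predictions with a randomly
        permuted narrative's manual counts (the permutation-test null) drives
        all four quadrant correlations to the n=500 null band."""
        config = GeneratorConfig(
            n_narratives=500, datasets=(DatasetSpec("null_ds"),), seed=99
        )
        corpus = generate_corpus(config)
        oracle = OracleClassifier(prepare_training_sentences(corpus, balance=False))
        scores = score_corpus([a.narrative for a in corpus], oracle)
        ids = [a.narrative.narrative_id for a in corpus]
        permuted = np.random.default_rng(100).permutation(len(ids))
        truth = {
            ids[i]: (
                corpus[j].internal_details,
                corpus[j].external_details,
            )
            for i, j in enumerate(permuted)
        }
        report = quadrant_report(scores, truth)
        for r in (report.r_int_int, report.r_ext_ext, report.r_int_ext, report.r_ext_int):
            assert abs(r) < 0.15


class TestProxyValidation:
    def test_perfect_linearity_gives_unit_r(self, small_corpus):
        # details exactly 10 x words
        from aiscore import AnnotatedNarrative, AnnotatedSegment

        anns = []
        rng = np.random.default_rng(4)
        for i in range(5):
            n_int = int(rng.integers(3, 9))
            n_ext = int(rng.integers(3, 9))
            anns.append(
                AnnotatedNarrative.from_segments(
                    f"n{i}",
                    [
                        AnnotatedSegment(" ".join(["sand"] * n_int), "internal", 10 * n_int),
                        AnnotatedSegment(" ".join(["facts"] * n_ext), "external", 10 * n_ext),
                    ],
                    dataset_id="lin",
                )
            )
        reports, _ = proxy_validation(anns)
        assert reports[0].r_internal == pytest.approx(1.0)
        assert reports[0].r_external == pytest.approx(1.0)

    def test_default_generator_lands_in_band(self):
        corpus = generate_corpus(GeneratorConfig(n_narratives=200, seed=3))
        reports, summary = proxy_validation(corpus)
        for report in reports:
            assert 0.86 <= report.r_internal <= 0.98
            assert 0.86 <= report.r_external <= 0.98
        # cross-check the pooled summary with an independent routine
        for r in reports:
            sub = [a for a in corpus if a.narrative.dataset_id == r.dataset_id]
            assert r.r_internal == pytest.approx(
                textbook_pearson(
                    [a.internal_details for a in sub], [a.internal_words for a in sub]
                ),
                abs=1e-12,
            )

    def test_two_narrative_group_undefined(self, small_corpus):
        reports, summary = proxy_validation(small_corpus[:2])
        assert reports[0].r_internal is None
        assert reports[0].r_external is None


@pytest.fixture(scope="module")
def folds(medium_corpus):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return leave_one_dataset_out(medium_corpus, TrainConfig(seed=11))


class TestLeaveOneDatasetOut:
    def test_one_fold_per_dataset(self, folds):
        assert sorted(f.dataset_id for f in folds) == [
            "memories_a",
            "simulations_b",
            "writing_c",
        ]

    def test_fold_isolation(self, folds, medium_corpus):
        ids_by_dataset = {}
        for ann in medium_corpus:
            ids_by_dataset.setdefault(ann.narrative.dataset_id, set()).add(
                ann.narrative.narrative_id
            )
        for fold in folds:
            held_out = ids_by_dataset[fold.dataset_id]
            assert held_out.isdisjoint(fold.train_narrative_ids)
            assert fold.dataset_id not in fold.train_dataset_ids

    def test_subgroups_reported_separately(self):
        mix = {
            ProportionClass.P0: 0.35,
            ProportionClass.P50: 0.10,
            ProportionClass.P75: 0.10,
            ProportionClass.P100: 0.45,
        }
        datasets = (
            DatasetSpec("plain_a", dict(mix), task="memory"),
            DatasetSpec("plain_b", dict(mix), task="memory"),
            DatasetSpec("ages_young", dict(mix), task="young"),
        )
        corpus = generate_corpus(
            GeneratorConfig(n_narratives=30, datasets=datasets, seed=6)
        )
        # tag half of ages_young narratives as a second subgroup
        retagged = []
        for i, ann in enumerate(corpus):
            if ann.narrative.dataset_id == "ages_young" and i % 2:
                retagged.append(
                    type(ann).from_segments(
                        ann.narrative.narrative_id,
                        ann.segments,
                        dataset_id="ages_young",
                        task="old",
                    )
                )
            else:
                retagged.append(ann)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            folds = leave_one_dataset_out(retagged, TrainConfig(seed=6))
        age_folds = [f for f in folds if f.dataset_id == "ages_young"]
        assert sorted(f.subgroup for f in age_folds) == ["old", "young"]

    def test_all_protected_rejected(self, small_corpus):
        datasets = {a.narrative.dataset_id for a in small_corpus}
        with pytest.raises(ConfigError):
            leave_one_dataset_out(small_corpus, TrainConfig(), protected=datasets)

    def test_protected_dataset_never_trained_on(self, small_corpus):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            folds = leave_one_dataset_out(
                small_corpus, TrainConfig(seed=2), protected={"writing_c"}
            )
        protected = [f for f in folds if f.dataset_id == "writing_c"]
        assert protected and all(f.protected for f in protected)
        for fold in protected:
            assert "writing_c" not in fold.train_dataset_ids
            assert fold.model_source == "all"
        unprotected = [f for f in folds if not f.protected]
        assert sorted(f.dataset_id for f in unprotected) == ["memories_a", "simulations_b"]

    def test_punctuation_dropout_degrades_diagonal(self):
        """Removing sentence terminators strictly reduces both diagonal
        correlations at the same seed (the unpunctuated-transcript effect)."""
        base = GeneratorConfig(n_narratives=60, seed=13)
        degraded = GeneratorConfig(n_narratives=60, seed=13, punctuation_dropout=0.8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            folds_base = leave_one_dataset_out(generate_corpus(base), TrainConfig(seed=13))
            folds_drop = leave_one_dataset_out(
                generate_corpus(degraded), TrainConfig(seed=13)
            )
        r_base = np.mean([f.report.r_int_int for f in folds_base])
        r_drop = np.mean([f.report.r_int_int for f in folds_drop])
        assert r_drop < r_base
        e_base = np.mean([f.report.r_ext_ext for f in folds_base])
        e_drop = np.mean([f.report.r_ext_ext for f in folds_drop])
        assert e_drop < e_base


class TestPearson:
    def test_undefined_for_constant_or_short_input(self):
        assert pearson([1, 1, 1], [1, 2, 3]) == (None, None)
        assert pearson([1, 2], [1, 2]) == (None, None)

    def test_two_sided_p_from_t_transform(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = pearson(x, y)
        from scipy import stats

        t = r * np.sqrt(28 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=28), rel=1e-9)
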