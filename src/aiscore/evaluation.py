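"""Validation design: proxy checks, four-quadrant reports, leave-one-dataset-out.

The four-quadrant report is the core validity argument for automated interview
scoring: predicted internal content should correlate with manual internal
detail counts, predicted external with manual external counts, and the two
cross (misclassification) correlations should be near zero.  The proxy report
establishes the premise that word counts track detail counts nearly perfectly
within each dataset.  Leave-one-dataset-out cross-validation holds out entire
studies so generalization is measured across tasks and populations rather
than across participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classifier import TrainConfig, train
from .corpus_io import AnnotatedNarrative, NarrativeScore
from .errors import ConfigError, ValidationError
from .scoring import score_corpus
from .training_prep import prepare_training_sentences

__all__ = [
    "QuadrantReport",
    "ProxyReport",
    "FoldResult",
    "pearson",
    "proxy_validation",
    "quadrant_report",
    "leave_one_dataset_out",
]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None]:
    """Pearson r with a two-sided p-value from the t transform (n - 2 df).

    Returns ``(None, None)`` — an explicit undefined marker, never a silent
    zero or NaN — when fewer than 3 pairs are available or either variable is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class QuadrantReport:
    """The 2x2 of correlations between predicted content and manual details.

    ``r_int_int`` — manual internal details vs. predicted internal words
    (quadrant a); ``r_ext_ext`` — manual external vs. predicted external (b);
    ``r_int_ext`` — manual internal vs. predicted external, i.e.
    internal-as-external misclassification (c); ``r_ext_int`` — the converse
    (d).  ``None`` marks an undefined correlation (constant column or n < 3).
    """

    r_int_int: float | None
    r_ext_ext: float | None
    r_int_ext: float | None
    r_ext_int: float | None
    p_int_int: float | None
    p_ext_ext: float | None
    p_int_ext: float | None
    p_ext_int: float | None
    n: int

    def _r2(self, r: float | None) -> float | None:
        return None if r is None else r * r

    @property
    def r2_int_int(self) -> float | None:
        return self._r2(self.r_int_int)

    @property
    def r2_ext_ext(self) -> float | None:
        return self._r2(self.r_ext_ext)

    @property
    def r2_int_ext(self) -> float | None:
        return self._r2(self.r_int_ext)

    @property
    def r2_ext_int(self) -> float | None:
        return self._r2(self.r_ext_int)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r_int_int": self.r_int_int,
            "r_ext_ext": self.r_ext_ext,
            "r_int_ext": self.r_int_ext,
            "r_ext_int": self.r_ext_int,
            "p_int_int": self.p_int_int,
            "p_ext_ext": self.p_ext_ext,
            "p_int_ext": self.p_int_ext,
            "p_ext_int": self.p_ext_int,
            "r2_int_int": self.r2_int_int,
            "r2_ext_ext": self.r2_ext_ext,
            "r2_int_ext": self.r2_int_ext,
            "r2_ext_int": self.r2_ext_int,
        }


@dataclass(frozen=True)
class ProxyReport:
    """Detail-count vs. word-count correlations for one dataset."""

    dataset_id: str
    r_internal: float | None
    r_external: float | None
    n: int


def proxy_validation(
    annotated: Iterable[AnnotatedNarrative],
) -> tuple[list[ProxyReport], dict]:
    """Correlate manual detail counts with annotated word counts per dataset.

    Returns the per-dataset reports and a summary with the range and mean of
    the defined correlations per category.  Groups where a correlation is
    undefined (fewer than 3 narratives or a constant variable) carry ``None``
    and are excluded from the summary.
    """
    groups: dict[str, list[AnnotatedNarrative]] = {}
    for ann in annotated:
        groups.setdefault(ann.narrative.dataset_id, []).append(ann)
    reports: list[ProxyReport] = []
    for dataset_id in sorted(groups):
        anns = groups[dataset_id]
        r_int, _ = pearson(
            [a.internal_details for a in anns], [a.internal_words for a in anns]
        )
        r_ext, _ = pearson(
            [a.external_details for a in anns], [a.external_words for a in anns]
        )
        reports.append(ProxyReport(dataset_id, r_int, r_ext, len(anns)))

    def summarize(values: list[float | None]) -> dict:
        defined = [v for v in values if v is not None]
        if not defined:
            return {"min": None, "max": None, "mean": None}
        return {
            "min": min(defined),
            "max": max(defined),
            "mean": float(np.mean(defined)),
        }

    summary = {
        "internal": summarize([r.r_internal for r in reports]),
        "external": summarize([r.r_external for r in reports]),
    }
    return reports, summary


def quadrant_report(
    scores: Sequence[NarrativeScore],
    truth: Mapping[str, tuple[float, float]] | Sequence[AnnotatedNarrative],
) -> QuadrantReport:
    """Four-quadrant correlation report of predictions against manual counts.

    ``truth`` maps narrative_id to (internal_details, external_details), or is
    a sequence of annotated narratives from which that mapping is taken.  The
    ids must align one-to-one with the scores.
    """
    if not isinstance(truth, Mapping):
        truth = {
            a.narrative.narrative_id: (a.internal_details, a.external_details)
            for a in truth
        }
    score_ids = [s.narrative_id for s in scores]
    if set(score_ids) != set(truth) or len(score_ids) != len(set(score_ids)):
        missing = sorted(set(score_ids) ^ set(truth))
        raise ValidationError(f"scores and truth ids do not align 1:1: {missing[:10]}")
    pred_int = [s.predicted_internal_words for s in scores]
    pred_ext = [s.predicted_external_words for s in scores]
    true_int = [truth[i][0] for i in score_ids]
    true_ext = [truth[i][1] for i in score_ids]
    r_ii, p_ii = pearson(true_int, pred_int)
    r_ee, p_ee = pearson(true_ext, pred_ext)
    r_ie, p_ie = pearson(true_int, pred_ext)
    r_ei, p_ei = pearson(true_ext, pred_int)
    return QuadrantReport(
        r_int_int=r_ii,
        r_ext_ext=r_ee,
        r_int_ext=r_ie,
        r_ext_int=r_ei,
        p_int_int=p_ii,
        p_ext_ext=p_ee,
        p_int_ext=p_ie,
        p_ext_int=p_ei,
        n=len(scores),
    )


@dataclass(frozen=True)
class FoldResult:
    """One leave-one-dataset-out evaluation record.

    ``train_narrative_ids``/``train_dataset_ids`` form the training manifest
    used to assert fold isolation; ``subgroup`` is the task tag when a held-out
    dataset is evaluated per task, else ``None``; ``protected`` marks datasets
    never used for training.
    """

    dataset_id: str
    subgroup: str | None
    report: QuadrantReport
    train_dataset_ids: tuple[str, ...]
    train_narrative_ids: tuple[str, ...]
    protected: bool = False
    model_source: str = ""


def _subgroups(anns: list[AnnotatedNarrative]) -> dict[str | None, list[AnnotatedNarrative]]:
    tasks = sorted({a.narrative.task for a in anns})
    if len(tasks) <= 1:
        return {None: anns}
    return {t: [a for a in anns if a.narrative.task == t] for t in tasks}


def _evaluate(
    model,
    anns: list[AnnotatedNarrative],
    dataset_id: str,
    train_ds: tuple[str, ...],
    train_ids: tuple[str, ...],
    protected: bool,
    model_source: str,
) -> list[FoldResult]:
    results = []
    for subgroup, members in _subgroups(anns).items():
        scores = score_corpus([a.narrative for a in members], model)
        report = quadrant_report(scores, members)
        results.append(
            FoldResult(
                dataset_id=dataset_id,
                subgroup=subgroup,
                report=report,
                train_dataset_ids=train_ds,
                train_narrative_ids=train_ids,
                protected=protected,
                model_source=model_source,
            )
        )
    return results


def leave_one_dataset_out(
    corpus: Iterable[AnnotatedNarrative],
    config: TrainConfig,
    protected: Iterable[str] = (),
    max_details: int = 8,
    protected_model: str = "all",
) -> list[FoldResult]:
    """Leave-one-dataset-out cross-validation of the full scoring pipeline.

    For each non-protected dataset: prepare (label, filter, balance) the
    sentences of the remaining non-protected datasets, train a classifier,
    score the held-out narratives, and report one quadrant record per
    (dataset, task subgroup).  Protected datasets — scored with guidelines the
    model was never trained on — are never used for training; they are
    evaluated against a model trained on all non-protected data
    (``protected_model="all"``, the default) or against every fold's model
    (``"fold"``); the choice is recorded in each result's ``model_source``.
    """
    corpus = list(corpus)
    protected = set(protected)
    by_dataset: dict[str, list[AnnotatedNarrative]] = {}
    for ann in corpus:
        by_dataset.setdefault(ann.narrative.dataset_id, []).append(ann)
    eligible = [d for d in sorted(by_dataset) if d not in protected]
    if not eligible:
        raise ConfigError("the protected set covers every dataset; nothing to train on")
    if len(eligible) < 2:
        raise ConfigError(
            "leave-one-dataset-out requires at least 2 non-protected datasets"
        )
    if protected_model not in {"all", "fold"}:
        raise ConfigError(f"protected_model must be 'all' or 'fold', got {protected_model!r}")

    results: list[FoldResult] = []
    for fold_idx, held in enumerate(eligible):
        train_ds = tuple(d for d in eligible if d != held)
        train_anns = [a for d in train_ds for a in by_dataset[d]]
        train_ids = tuple(a.narrative.narrative_id for a in train_anns)
        labeled = prepare_training_sentences(
            train_anns, max_details=max_details, seed=config.seed + fold_idx
        )
        model = train(labeled, config)
        results.extend(
            _evaluate(
                model,
                by_dataset[held],
                held,
                train_ds,
                train_ids,
                protected=False,
                model_source=f"fold:{held}",
            )
        )
        if protected_model == "fold":
            for pdataset in sorted(protected & set(by_dataset)):
                results.extend(
                    _evaluate(
                        model,
                        by_dataset[pdataset],
                        pdataset,
                        train_ds,
                        train_ids,
                        protected=True,
                        model_source=f"fold:{held}",
                    )
                )

    if protected_model == "all" and protected & set(by_dataset):
        train_anns = [a for d in eligible for a in by_dataset[d]]
        train_ids = tuple(a.narrative.narrative_id for a in train_anns)
        labeled = prepare_training_sentences(
            train_anns, max_details=max_details, seed=config.seed + len(eligible)
        )
        model = train(labeled, config)
        for pdataset in sorted(protected & set(by_dataset)):
            results.extend(
                _evaluate(
                    model,
                    by_dataset[pdataset],
                    pdataset,
                    tuple(eligible),
                    train_ids,
                    protected=True,
                    model_source="all",
                )
            )
    return results
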