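"""Four-class sentence classifier behind a backend-agnostic interface.

The contribution of the pipeline is the label scheme and the aggregation, not
any particular encoder, so the classifier is an abstraction with pluggable
backends:

* ``count-logistic`` (default) — token-count features with a multinomial
  logistic-regression head.  CPU-only, bit-deterministic under a fixed seed,
  and sufficient wherever the internal/external lexicons are separable.
* ``transformer:<model>`` — a pretrained transformer encoder with a single
  linear classification head, fine-tuned with cross-entropy.  Requires the
  optional ``transformers``/``torch`` dependencies.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) so it composes with sklearn pipelines and
model selection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, DataError
from .preprocess import Sentence
from .training_prep import CLASS_ORDER, LabeledSentence, ProportionClass

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SentenceClassifier",
    "OracleClassifier",
    "train",
    "predict_class",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    """Fine-tuning configuration.

    Defaults follow the reference fine-tuning recipe: three epochs, batch size
    16 for training and 64 for evaluation, 500 warmup steps, 0.01 weight
    decay, accuracy as the training evaluation criterion, and the framework's
    default 5e-5 initial learning rate with linear decay.  The lightweight
    backend consumes ``epochs``, ``seed`` and ``holdout_fraction``; the batch,
    warmup and decay settings drive the transformer backend.
    """

    epochs: int = 3
    train_batch_size: int = 16
    eval_batch_size: int = 64
    warmup_steps: int = 500
    weight_decay: float = 0.01
    learning_rate: float = 5e-5
    max_seq_length: int = 128
    backbone: str = "count-logistic"
    seed: int = 0
    holdout_fraction: float = 0.1
    eval_metric: str = field(default="accuracy")

    def __post_init__(self) -> None:
        for name in ("epochs", "train_batch_size", "eval_batch_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.warmup_steps < 0 or self.weight_decay < 0:
            raise ConfigError("warmup_steps and weight_decay must be non-negative")
        if self.eval_metric != "accuracy":
            raise ConfigError("eval_metric is fixed to 'accuracy'")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ConfigError("holdout_fraction must be in (0, 1)")


def _as_labels(y: Sequence[ProportionClass | str]) -> np.ndarray:
    out = []
    for v in y:
        out.append(ProportionClass(v).value)
    return np.asarray(out, dtype=object)


def _argmax_prefer_higher(proba: np.ndarray) -> np.ndarray:
    """Column-wise argmax with exact ties resolved to the highest column.

    Columns are ordered by increasing internal content, so preferring the last
    tied column prefers the more internal class.
    """
    ncol = proba.shape[1]
    return ncol - 1 - np.argmax(proba[:, ::-1], axis=1)


class _CountLogisticBackend:
    """Token-count features + multinomial logistic regression.

    Counts are L1-normalized per sentence (term frequencies): the label is a
    proportion, so relative token frequencies carry the signal and sentence
    length does not confound the mixed classes.  The weight-decay convention
    assumes O(1) features, while term frequencies scale as 1/length, so the
    ridge strength is corrected by the squared mean training-sentence length
    (equivalent to rescaling the features, with better optimizer
    conditioning).
    """

    tag = "count-logistic"

    def __init__(self, config: TrainConfig):
        self.config = config
        self.vectorizer = TfidfVectorizer(
            lowercase=True,
            token_pattern=r"(?u)\b\w[\w'’-]*\b",
            use_idf=False,
            norm="l1",
        )
        self.model = LogisticRegression(
            C=1.0 / max(config.weight_decay, 1e-12),
            solver="lbfgs",
            warm_start=True,
            max_iter=1000,
        )

    def fit_epochs(self, texts, labels, eval_texts, eval_labels):
        scale = float(np.mean([len(t.split()) for t in texts]))
        self.model.C = scale * scale / max(self.config.weight_decay, 1e-12)
        X = self.vectorizer.fit_transform(texts)
        X_eval = self.vectorizer.transform(eval_texts) if len(eval_texts) else None
        history = []
        for epoch in range(self.config.epochs):
            self.model.fit(X, labels)
            if X_eval is not None:
                acc = float(np.mean(self.model.predict(X_eval) == eval_labels))
            else:
                acc = float("nan")
            history.append(acc)
            logger.info("epoch %d: eval accuracy %.4f", epoch + 1, acc)
        return history

    def predict_proba(self, texts):
        X = self.vectorizer.transform(texts)
        return self.model.predict_proba(X), list(self.model.classes_)


class _TransformerBackend:
    """Pretrained transformer encoder + single linear classification head.

    Fine-tuned with cross-entropy via the huggingface ``Trainer``; single
    sentences are tokenized with truncation at ``max_seq_length`` tokens
    (truncation events are logged).  Requires the optional ``transformers``
    and ``torch`` dependencies.
    """

    tag = "transformer"

    def __init__(self, config: TrainConfig, model_name: str):
        try:
            import torch  # noqa: F401
            from transformers import (
                AutoModelForSequenceClassification,
                AutoTokenizer,
            )
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigError(
                f"backbone {config.backbone!r} requires the optional "
                "'transformers' and 'torch' dependencies (pip install aiscore[transformer])"
            ) from exc
        self.config = config
        self.model_name = model_name
        self._tokenizer_cls = AutoTokenizer
        self._model_cls = AutoModelForSequenceClassification
        self.tokenizer = None
        self.model = None
        self.label_order: list[str] = []

    def fit_epochs(self, texts, labels, eval_texts, eval_labels):  # pragma: no cover
        import torch
        from transformers import Trainer, TrainingArguments, set_seed

        set_seed(self.config.seed)
        self.label_order = [c.value for c in CLASS_ORDER if c.value in set(labels)]
        label2id = {l: i for i, l in enumerate(self.label_order)}
        self.tokenizer = self._tokenizer_cls.from_pretrained(self.model_name)
        self.model = self._model_cls.from_pretrained(
            self.model_name,
            num_labels=len(self.label_order),
            id2label={i: l for l, i in label2id.items()},
            label2id=label2id,
        )

        def encode(batch_texts, batch_labels):
            enc = self.tokenizer(
                list(batch_texts),
                truncation=True,
                max_length=self.config.max_seq_length,
                padding=True,
                return_tensors="pt",
            )
            n_trunc = int((enc["attention_mask"].sum(dim=1) >= self.config.max_seq_length).sum())
            if n_trunc:
                logger.info("%d inputs truncated at %d tokens", n_trunc, self.config.max_seq_length)
            items = []
            for i in range(len(batch_texts)):
                item = {k: v[i] for k, v in enc.items()}
                item["labels"] = torch.tensor(label2id[batch_labels[i]])
                items.append(item)
            return items

        train_ds = encode(texts, labels)
        eval_ds = encode(eval_texts, eval_labels) if len(eval_texts) else None
        args = TrainingArguments(
            output_dir="transformer_finetune",
            num_train_epochs=self.config.epochs,
            per_device_train_batch_size=self.config.train_batch_size,
            per_device_eval_batch_size=self.config.eval_batch_size,
            warmup_steps=self.config.warmup_steps,
            weight_decay=self.config.weight_decay,
            learning_rate=self.config.learning_rate,
            eval_strategy="epoch" if eval_ds else "no",
            logging_strategy="epoch",
            seed=self.config.seed,
            report_to=[],
        )

        def metrics(pred):
            acc = float(np.mean(np.argmax(pred.predictions, axis=1) == pred.label_ids))
            return {"accuracy": acc}

        trainer = Trainer(
            model=self.model,
            args=args,
            train_dataset=train_ds,
            eval_dataset=eval_ds,
            compute_metrics=metrics,
        )
        trainer.train()
        history = [
            log["eval_accuracy"] for log in trainer.state.log_history if "eval_accuracy" in log
        ]
        return history or [float("nan")]

    def predict_proba(self, texts):  # pragma: no cover
        import torch

        enc = self.tokenizer(
            list(texts),
            truncation=True,
            max_length=self.config.max_seq_length,
            padding=True,
            return_tensors="pt",
        )
        with torch.no_grad():
            logits = self.model(**enc).logits
        proba = torch.softmax(logits, dim=1).numpy()
        return proba, list(self.label_order)


def _make_backend(config: TrainConfig):
    if config.backbone == "count-logistic":
        return _CountLogisticBackend(config)
    if config.backbone.startswith("transformer:"):
        return _TransformerBackend(config, config.backbone.split(":", 1)[1])
    raise ConfigError(
        f"unknown backbone {config.backbone!r}; expected 'count-logistic' "
        "or 'transformer:<model-name>'"
    )


class SentenceClassifier(ClassifierMixin, BaseEstimator):
    """Four-class internal-content proportion classifier for sentences.

    Parameters mirror :class:`TrainConfig`.  ``fit`` expects ``X`` as a
    sequence of sentence strings and ``y`` as proportion-class labels (either
    :class:`ProportionClass` members or their string values).  Prediction ties
    resolve toward the more internal class.

    Attributes set by ``fit``: ``classes_`` (labels present, in increasing
    internal-content order), ``backend_`` (the fitted backend),
    ``history_`` (held-out accuracy per epoch), ``n_features_in_``.
    """

    def __init__(
        self,
        backbone: str = "count-logistic",
        epochs: int = 3,
        train_batch_size: int = 16,
        eval_batch_size: int = 64,
        warmup_steps: int = 500,
        weight_decay: float = 0.01,
        learning_rate: float = 5e-5,
        max_seq_length: int = 128,
        seed: int = 0,
        holdout_fraction: float = 0.1,
    ):
        self.backbone = backbone
        self.epochs = epochs
        self.train_batch_size = train_batch_size
        self.eval_batch_size = eval_batch_size
        self.warmup_steps = warmup_steps
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.max_seq_length = max_seq_length
        self.seed = seed
        self.holdout_fraction = holdout_fraction

    # -- configuration ----------------------------------------------------
    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            train_batch_size=self.train_batch_size,
            eval_batch_size=self.eval_batch_size,
            warmup_steps=self.warmup_steps,
            weight_decay=self.weight_decay,
            learning_rate=self.learning_rate,
            max_seq_length=self.max_seq_length,
            backbone=self.backbone,
            seed=self.seed,
            holdout_fraction=self.holdout_fraction,
        )

    @classmethod
    def from_config(cls, config: TrainConfig) -> "SentenceClassifier":
        d = asdict(config)
        d.pop("eval_metric")
        return cls(**d)

    # -- estimator API -----------------------------------------------------
    def fit(self, X: Sequence[str], y: Sequence[ProportionClass | str]):
        texts = [str(t) for t in X]
        labels = _as_labels(y)
        if len(texts) != len(labels):
            raise DataError("X and y have different lengths")
        if len(texts) == 0:
            raise DataError("cannot fit on an empty training set")
        present = set(labels)
        if len(present) < 2:
            raise DataError(
                f"training data must contain at least 2 classes, got {sorted(present)}"
            )
        counts = {c: int(np.sum(labels == c)) for c in sorted(present)}
        if len(set(counts.values())) > 1:
            warnings.warn(
                f"training classes are not balanced (counts {counts}); "
                "the model may learn base rates",
                UserWarning,
                stacklevel=2,
            )
        config = self._config()
        backend = _make_backend(config)

        # Held-out split for the per-epoch accuracy log; stratified when every
        # class can contribute at least one example to each side.
        min_count = min(counts.values())
        if min_count >= 2 and len(texts) * config.holdout_fraction >= len(present):
            tr_texts, ev_texts, tr_labels, ev_labels = train_test_split(
                texts,
                labels,
                test_size=config.holdout_fraction,
                random_state=config.seed,
                stratify=labels,
            )
        else:
            tr_texts, ev_texts, tr_labels, ev_labels = texts, [], labels, np.array([])

        self.history_ = backend.fit_epochs(tr_texts, tr_labels, ev_texts, ev_labels)
        self.backend_ = backend
        order = {c.value: i for i, c in enumerate(CLASS_ORDER)}
        self.classes_ = np.asarray(sorted(present, key=order.__getitem__), dtype=object)
        self.n_features_in_ = len(texts)
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        """Class probabilities aligned to ``classes_``; rows sum to one."""
        check_is_fitted(self, "backend_")
        texts = [str(t) for t in X]
        for t in texts:
            if not t.strip():
                raise DataError("cannot classify an empty sentence; filter upstream")
        raw, raw_labels = self.backend_.predict_proba(texts)
        col = {l: i for i, l in enumerate(raw_labels)}
        proba = np.zeros((len(texts), len(self.classes_)))
        for j, cls in enumerate(self.classes_):
            if cls in col:
                proba[:, j] = raw[:, col[cls]]
        proba /= proba.sum(axis=1, keepdims=True)
        return proba

    def predict(self, X: Sequence[str]) -> np.ndarray:
        proba = self.predict_proba(X)
        idx = _argmax_prefer_higher(proba)
        return self.classes_[idx]


class OracleClassifier:
    """Upper-bound reference scorer: returns the binned true fraction.

    Built from labeled sentences, it looks predictions up by sentence text and
    is used to validate the aggregation pipeline independently of any trained
    model.  It supports the same ``predict``/``predict_proba`` surface on
    sentences it has seen; unseen text raises :class:`DataError`.
    """

    def __init__(self, labeled: Sequence[LabeledSentence]):
        self._lookup: dict[str, ProportionClass] = {
            ls.sentence.text: ls.cls for ls in labeled
        }
        self.classes_ = np.asarray([c.value for c in CLASS_ORDER], dtype=object)

    def fit(self, X=None, y=None):  # pragma: no cover - lookup needs no fitting
        return self

    def _one(self, text: str) -> ProportionClass:
        try:
            return self._lookup[text]
        except KeyError:
            raise DataError(f"oracle has no label for sentence {text!r}") from None

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.asarray([self._one(t).value for t in X], dtype=object)

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        proba = np.zeros((len(X), len(self.classes_)))
        for i, t in enumerate(X):
            proba[i, list(self.classes_).index(self._one(t).value)] = 1.0
        return proba


# ---------------------------------------------------------------------------
# Functional wrappers and persistence
# ---------------------------------------------------------------------------


def train(labeled: Sequence[LabeledSentence], config: TrainConfig) -> SentenceClassifier:
    """Train a sentence classifier on (balanced) labeled sentences."""
    clf = SentenceClassifier.from_config(config)
    texts = [ls.sentence.text for ls in labeled]
    labels = [ls.cls for ls in labeled]
    return clf.fit(texts, labels)


def predict_class(
    model, sentence: Sentence | str
) -> tuple[ProportionClass, dict[ProportionClass, float]]:
    """Classify one sentence; returns (argmax class, probability vector)."""
    text = sentence.text if isinstance(sentence, Sentence) else str(sentence)
    if not text.strip():
        raise DataError("cannot classify an empty sentence; filter upstream")
    proba = model.predict_proba([text])[0]
    labels = [ProportionClass(c) for c in model.classes_]
    idx = int(_argmax_prefer_higher(proba[None, :])[0])
    return labels[idx], dict(zip(labels, (float(p) for p in proba)))


_MANIFEST = "manifest.json"
_PAYLOAD = "model.joblib"


def save_model(model: SentenceClassifier, directory: str | Path) -> None:
    """Persist a fitted classifier to a directory with a metadata manifest."""
    check_is_fitted(model, "backend_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "backend": model.backend_.tag,
        "config": asdict(model._config()),
        "label_map": [str(c) for c in model.classes_],
    }
    (directory / _MANIFEST).write_text(json.dumps(manifest, indent=2))
    joblib.dump(model, directory / _PAYLOAD)


def load_model(directory: str | Path) -> SentenceClassifier:
    directory = Path(directory)
    manifest_path = directory / _MANIFEST
    if not manifest_path.exists():
        raise ConfigError(f"{directory} does not contain a model manifest")
    return joblib.load(directory / _PAYLOAD)
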