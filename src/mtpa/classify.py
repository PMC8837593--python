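"""Per-connection task-vs-rest decoding from temporal connectivity patterns.

Each region pair gets its own L2-regularised linear logistic classifier.
Features are either the T framewise coefficients of the pair's dynamic
connectivity series or the single static correlation value. Subjects are
split 70/30 (grouped, so a subject's task and rest samples never straddle
the split); 10-fold grouped cross-validation on the training partition
provides an overfitting check and out-of-fold probability estimates.
Labels: task = 1, rest = 0; predicted label is 1 iff probability >= 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .fls import DfcTensor

__all__ = [
    "SplitSpec",
    "ConnectionDataset",
    "ClassifierModel",
    "ConnectionResult",
    "split_subjects",
    "fit_logistic",
    "predict_proba",
    "cross_validate",
    "run_all_connections",
    "datasets_from_dfc",
    "datasets_from_static",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    n_folds: int = 10
    seed: int = 0
    group_by_subject: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


@dataclass
class ConnectionDataset:
    """Samples for one connection: one task and one rest row per subject."""

    connection: tuple[int, int]
    features: np.ndarray  # samples x features
    labels: np.ndarray  # 1 = task, 0 = rest
    subjects: np.ndarray  # subject id per sample

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        for sid in np.unique(self.subjects):
            m = self.subjects == sid
            if sorted(self.labels[m].tolist()) != [0, 1]:
                raise ValueError(f"subject {sid} must contribute exactly one task and one rest sample")


@dataclass(frozen=True)
class ClassifierModel:
    weights: np.ndarray
    intercept: float
    reg_strength: float


@dataclass
class ConnectionResult:
    connection: tuple[int, int]
    cv_accuracy: float
    test_accuracy: float
    subjects: np.ndarray  # per sample
    labels: np.ndarray
    in_test: np.ndarray  # bool per sample
    proba: np.ndarray  # task probability per sample
    predicted: np.ndarray


def split_subjects(subject_ids, spec: SplitSpec) -> tuple[list, list]:
    """Disjoint, exhaustive 70/30 subject partition (floor on train size)."""
    if not spec.group_by_subject:
        raise ValueError("ungrouped splitting is rejected: it leaks subjects across partitions")
    ids = list(dict.fromkeys(subject_ids))
    if len(ids) < 10:
        raise ValueError(f"need at least 10 subjects, got {len(ids)}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    n_train = math.floor(spec.train_fraction * len(ids))
    train = [ids[k] for k in order[:n_train]]
    test = [ids[k] for k in order[n_train:]]
    return train, test


def fit_logistic(features: np.ndarray, labels: np.ndarray, reg_strength: float = 1.0) -> ClassifierModel:
    """Minimise 0.5||w||^2 + C * sum_i log(1 + exp(-y_i (w.x_i + b))).

    The intercept is unpenalised. Callers are expected to have
    standardised features with training-set statistics.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the training data")
    clf = LogisticRegression(C=reg_strength, solver="lbfgs", tol=1e-8, max_iter=10_000)
    clf.fit(np.atleast_2d(features), labels)
    return ClassifierModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        reg_strength=reg_strength,
    )


def predict_proba(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """P(task) = sigmoid(w.x + b) per row."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.weights.size:
        raise ValueError(
            f"feature length {x.shape[1]} does not match model ({model.weights.size})"
        )
    z = x @ model.weights + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


class _Scaler:
    """Per-feature z-scoring frozen on training statistics."""

    def __init__(self, x: np.ndarray):
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self.sd = np.where(sd < 1e-12, 1.0, sd)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def _subject_folds(subjects: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    ids = list(dict.fromkeys(subjects.tolist()))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [np.array([ids[k] for k in chunk]) for chunk in np.array_split(order, n_folds) if len(chunk)]


def cross_validate(
    dataset: ConnectionDataset, spec: SplitSpec, reg_strength: float = 1.0
) -> tuple[float, np.ndarray]:
    """Grouped k-fold CV: mean fold accuracy and out-of-fold probabilities."""
    folds = _subject_folds(dataset.subjects, spec.n_folds, spec.seed)
    oof = np.full(dataset.labels.shape, np.nan)
    accs = []
    for fold_ids in folds:
        held = np.isin(dataset.subjects, fold_ids)
        if len(np.unique(dataset.labels[~held])) < 2:
            log.warning("skipping CV fold with a single training class")
            continue
        scale = _Scaler(dataset.features[~held])
        model = fit_logistic(scale(dataset.features[~held]), dataset.labels[~held], reg_strength)
        p = predict_proba(model, scale(dataset.features[held]))
        oof[held] = p
        accs.append(float(np.mean((p >= 0.5).astype(int) == dataset.labels[held])))
    if not accs:
        raise ValueError("no usable CV fold")
    return float(np.mean(accs)), oof


def _evaluate_connection(
    dataset: ConnectionDataset, train_ids, test_ids, spec: SplitSpec, reg_strength: float
) -> ConnectionResult:
    in_test = np.isin(dataset.subjects, test_ids)
    tr = ~in_test
    train_set = ConnectionDataset(
        connection=dataset.connection,
        features=dataset.features[tr],
        labels=dataset.labels[tr],
        subjects=dataset.subjects[tr],
    )
    cv_acc, oof = cross_validate(train_set, spec, reg_strength)
    scale = _Scaler(dataset.features[tr])
    model = fit_logistic(scale(dataset.features[tr]), dataset.labels[tr], reg_strength)
    p_test = predict_proba(model, scale(dataset.features[in_test]))
    proba = np.empty(dataset.labels.shape)
    proba[tr] = oof
    proba[in_test] = p_test
    predicted = (proba >= 0.5).astype(int)
    test_acc = float(np.mean(predicted[in_test] == dataset.labels[in_test]))
    return ConnectionResult(
        connection=dataset.connection,
        cv_accuracy=cv_acc,
        test_accuracy=test_acc,
        subjects=dataset.subjects.copy(),
        labels=dataset.labels.copy(),
        in_test=in_test,
        proba=proba,
        predicted=predicted,
    )


def _paired_subjects(samples: dict[tuple[str, str], np.ndarray]) -> list[str]:
    ids = list(dict.fromkeys(sid for sid, _ in samples))
    keep = []
    for sid in ids:
        if (sid, "task") in samples and (sid, "rest") in samples:
            keep.append(sid)
        else:
            log.warning("subject %s lacks a condition; dropped", sid)
    return keep


def datasets_from_dfc(tensors: list[DfcTensor]):
    """Yield one ConnectionDataset per pair from per-recording DFC stacks."""
    samples = {(t.subject_id, t.condition): t for t in tensors}
    keep = _paired_subjects(samples)
    if not keep:
        raise ValueError("no subject has both conditions")
    ref = samples[(keep[0], "task")]
    subjects = np.repeat(keep, 2)
    labels = np.tile([1, 0], len(keep))
    for row, pair in enumerate(ref.pairs):
        feats = np.empty((2 * len(keep), ref.n_frames))
        for s, sid in enumerate(keep):
            feats[2 * s] = samples[(sid, "task")].beta[row]
            feats[2 * s + 1] = samples[(sid, "rest")].beta[row]
        yield ConnectionDataset(
            connection=(int(pair[0]), int(pair[1])),
            features=feats,
            labels=labels,
            subjects=subjects,
        )


def datasets_from_static(static_results: list[tuple[str, str, np.ndarray, np.ndarray]]):
    """Same as ``datasets_from_dfc`` for 1-D static-correlation features.

    ``static_results`` rows are (subject_id, condition, r_vector, pairs).
    """
    samples = {(sid, cond): vec for sid, cond, vec, _ in static_results}
    pairs = static_results[0][3]
    keep = _paired_subjects(samples)
    if not keep:
        raise ValueError("no subject has both conditions")
    subjects = np.repeat(keep, 2)
    labels = np.tile([1, 0], len(keep))
    for row, pair in enumerate(pairs):
        feats = np.empty((2 * len(keep), 1))
        for s, sid in enumerate(keep):
            feats[2 * s, 0] = samples[(sid, "task")][row]
            feats[2 * s + 1, 0] = samples[(sid, "rest")][row]
        yield ConnectionDataset(
            connection=(int(pair[0]), int(pair[1])),
            features=feats,
            labels=labels,
            subjects=subjects,
        )


def run_all_connections(
    datasets, spec: SplitSpec, reg_strength: float = 1.0
) -> list[ConnectionResult]:
    """Train/evaluate every connection with one shared subject split."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no connection datasets supplied")
    train_ids, test_ids = split_subjects(datasets[0].subjects, spec)
    return [
        _evaluate_connection(ds, train_ids, test_ids, spec, reg_strength) for ds in datasets
    ]
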