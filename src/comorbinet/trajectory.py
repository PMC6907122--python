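"""Trajectory-based disease-occurrence prediction.

Visit trajectories are turned into a supervised dataset: for an index visit
v of a patient with at least two visits, the features are the diseases seen
at visits strictly before v (the target excluded), and the label is whether
the target disease occurs at v.  Balanced benchmarks are evaluated with four
classifier families under stratified, patient-grouped 10-fold
cross-validation, and risk diseases are ranked from model coefficients /
impurity importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

MODEL_NAMES = ("lr", "svm", "rf", "nn")


@dataclass(frozen=True)
class TrajectoryDataset:
    """Binary past-disease feature matrix with per-visit labels.

    ``X[i, f] = 1`` iff feature disease ``f`` appeared at any visit strictly
    before instance i's index visit; ``y[i] = 1`` iff the target occurs at
    the index visit.  ``provenance[i]`` is ``(patient_id, visit_index)``.
    """

    feature_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    provenance: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), len(self.feature_names)):
            raise ValueError("X shape inconsistent with labels / feature names")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X entries must be binary")

    @property
    def groups(self) -> np.ndarray:
        return np.array([p for p, _ in self.provenance])


@dataclass(frozen=True)
class BenchmarkSpec:
    """Requested class sizes for a balanced benchmark."""

    target_disease: str
    n_positive: int
    n_negative: int
    sampling_seed: int = 0


@dataclass
class EvaluationReport:
    """Cross-validated metrics plus final models fitted on the full benchmark."""

    metrics: pd.DataFrame
    fold_metrics: pd.DataFrame
    fitted: dict[str, object] = field(default_factory=dict)


def build_dataset(
    profiles: Sequence,
    target_disease: str | set[str] | frozenset[str],
) -> TrajectoryDataset:
    """Build the supervised dataset for one target disease (or a code set).

    Only patients with >= 2 visits contribute.  Each eligible index visit
    v >= 2 yields one instance; a patient contributes at most one positive
    instance (first target occurrence) and no instances after it, so the
    post-onset tail cannot leak into the negatives.
    """
    targets = frozenset([target_disease]) if isinstance(target_disease, str) else frozenset(target_disease)
    all_codes: set[str] = set()
    for prof in profiles:
        all_codes |= prof.disease_set
    feature_names = tuple(sorted(all_codes - targets))
    if not any(targets & prof.disease_set for prof in profiles):
        warnings.warn(
            f"target {sorted(targets)} absent from all records: every label is 0",
            stacklevel=2,
        )
    col = {c: i for i, c in enumerate(feature_names)}
    rows: list[np.ndarray] = []
    labels: list[int] = []
    provenance: list[tuple[str, int]] = []
    for prof in profiles:
        if prof.n_visits < 2:
            continue
        history: set[str] = set(prof.visit_sequence[0])
        for v in range(1, prof.n_visits):
            visit = prof.visit_sequence[v]
            x = np.zeros(len(feature_names), dtype=np.uint8)
            for c in history - targets:
                x[col[c]] = 1
            label = int(bool(targets & visit))
            rows.append(x)
            labels.append(label)
            provenance.append((prof.patient_id, v))
            if label == 1:
                break  # one positive per patient; drop the post-onset tail
            history |= visit
    X = np.vstack(rows) if rows else np.zeros((0, len(feature_names)), dtype=np.uint8)
    return TrajectoryDataset(
        feature_names=feature_names,
        X=X,
        y=np.array(labels, dtype=np.int64),
        provenance=tuple(provenance),
    )


def assemble_benchmark(dataset: TrajectoryDataset, spec: BenchmarkSpec) -> TrajectoryDataset:
    """Sample a balanced benchmark: requested positives plus random negatives.

    Deterministic given ``spec.sampling_seed``.  Raises a ``ValueError``
    naming the deficient class when the pool is too small.
    """
    rng = np.random.default_rng(spec.sampling_seed)
    pos_idx = np.flatnonzero(dataset.y == 1)
    neg_idx = np.flatnonzero(dataset.y == 0)
    if len(pos_idx) < spec.n_positive:
        raise ValueError(
            f"insufficient positive instances: requested {spec.n_positive}, available {len(pos_idx)}"
        )
    if len(neg_idx) < spec.n_negative:
        raise ValueError(
            f"insufficient negative instances: requested {spec.n_negative}, available {len(neg_idx)}"
        )
    take_pos = np.sort(rng.choice(pos_idx, size=spec.n_positive, replace=False))
    take_neg = np.sort(rng.choice(neg_idx, size=spec.n_negative, replace=False))
    take = np.concatenate([take_pos, take_neg])
    return TrajectoryDataset(
        feature_names=dataset.feature_names,
        X=dataset.X[take],
        y=dataset.y[take],
        provenance=tuple(dataset.provenance[i] for i in take),
    )


def default_models(seed: int = 0, *, hidden_layer_size: int = 64) -> dict[str, object]:
    """The four classifier families with their published settings.

    LR: L2 penalty, regularization intensity 1.  SVM: linear kernel, error
    penalty 10.  RF: 180 trees, bootstrap, OOB scoring, Gini impurity.
    NN: two hidden layers, learning rate 0.001, at most 200 iterations,
    mini-batch training.
    """
    return {
        # default penalty is L2; intensity C=1
        "lr": LogisticRegression(C=1.0, max_iter=2000, random_state=seed),
        "svm": LinearSVC(C=10.0, max_iter=5000, random_state=seed),
        "rf": RandomForestClassifier(
            n_estimators=180,
            bootstrap=True,
            oob_score=True,
            criterion="gini",
            random_state=seed,
            n_jobs=1,
        ),
        "nn": MLPClassifier(
            hidden_layer_sizes=(hidden_layer_size, hidden_layer_size),
            learning_rate_init=0.001,
            max_iter=200,
            batch_size="auto",
            random_state=seed,
        ),
    }


def train_evaluate(
    benchmark: TrajectoryDataset,
    models: Mapping[str, object] | None = None,
    *,
    n_folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified, patient-grouped k-fold cross-validation of the model suite.

    Reports mean and standard deviation of precision, recall and F1 on the
    positive class over folds, and refits each model on the full benchmark
    for feature-importance extraction.
    """
    if len(np.unique(benchmark.y)) < 2:
        raise ValueError("benchmark must contain both classes")
    if models is None:
        models = default_models(seed)
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    X, y, groups = benchmark.X.astype(np.float64), benchmark.y, benchmark.groups
    splits = list(splitter.split(X, y, groups))
    for k, (train, test) in enumerate(splits):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(
                f"fold {k} is single-class; use fewer folds or a larger benchmark"
            )
    fold_rows = []
    fitted: dict[str, object] = {}
    for name, proto in models.items():
        for k, (train, test) in enumerate(splits):
            model = clone(proto)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter
                model.fit(X[train], y[train])
            pred = model.predict(X[test])
            prec, rec, f1, _ = precision_recall_fscore_support(
                y[test], pred, average="binary", zero_division=0
            )
            fold_rows.append((name, k, prec, rec, f1))
        final = clone(proto)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(X, y)
        fitted[name] = final
    fold_metrics = pd.DataFrame(
        fold_rows, columns=["model", "fold", "precision", "recall", "f1"]
    )
    agg = fold_metrics.groupby("model")[["precision", "recall", "f1"]].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    metrics = agg.reset_index()
    return EvaluationReport(metrics=metrics, fold_metrics=fold_metrics, fitted=fitted)


def extract_risk_features(
    fitted: Mapping[str, object],
    feature_names: Sequence[str],
    k: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per-model top-k risk diseases.

    Linear models are ranked by coefficient magnitude (sign retained);
    forests by impurity importance.  Models without per-feature scores
    (the neural network) are skipped.
    """
    if k > len(feature_names):
        warnings.warn(
            f"k={k} exceeds the {len(feature_names)} features; returning all", stacklevel=2
        )
        k = len(feature_names)
    out: dict[str, pd.DataFrame] = {}
    for name, model in fitted.items():
        if hasattr(model, "coef_"):
            scores = np.asarray(model.coef_).ravel()
            order = np.argsort(-np.abs(scores), kind="stable")
        elif hasattr(model, "feature_importances_"):
            scores = np.asarray(model.feature_importances_)
            order = np.argsort(-scores, kind="stable")
        else:
            continue
        top = order[:k]
        out[name] = pd.DataFrame(
            {
                "disease": [feature_names[i] for i in top],
                "score": scores[top],
            }
        )
    return out
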