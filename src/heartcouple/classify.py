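"""Classification of normal vs abnormal recordings from coupling features.

Wraps the multiscale-kernel CNN (see :mod:`heartcouple._mscnn`), the
confusion-matrix metrics (accuracy, precision, sensitivity, specificity,
F1, reported as percentages) and the repeated stratified 70/30 split
evaluation protocol. Feature selection (ReliefF) is fitted on the training
portion of each split only, so selection never sees test-fold values.
A thin harness over standard scikit-learn estimators (logistic regression,
SVM, decision tree, k-NN, Gaussian naive Bayes) is provided for
comparison runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn import base as skbase
from sklearn.model_selection import train_test_split

from ._mscnn import MultiScaleCNN
from .selection import FeatureMatrix, relieff_weights, select_top


@dataclass
class CnnConfig:
    """Hyperparameters of the multiscale CNN. ``kernel_sizes`` must include 1."""

    kernel_sizes: tuple[int, ...] = (1, 3, 5)
    filters_per_branch: int = 16
    conv_layers_per_branch: int = 2
    pool_size: int = 2
    fc_units: int = 32
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if 1 not in tuple(self.kernel_sizes):
            raise ValueError("kernel_sizes must include 1")
        if self.conv_layers_per_branch != 2:
            raise ValueError("conv_layers_per_branch is fixed at 2")
        for name in ("filters_per_branch", "pool_size", "fc_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class Metrics:
    """Confusion-derived metrics in percent; NaN where undefined."""

    acc: float
    pr: float
    se: float
    sp: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"acc": self.acc, "pr": self.pr, "se": self.se, "sp": self.sp, "f1": self.f1}


@dataclass
class EvalReport:
    """Aggregate of a repeated-split evaluation."""

    confusion: dict[str, int]  # summed over repeats: tp, fp, fn, tn
    acc: float
    pr: float
    se: float
    sp: float
    f1: float
    n_repeats: int
    per_repeat: list[dict] = field(default_factory=list)
    positive_label: str = "abnormal"

    def to_json(self, path: str | Path, config_hash: str | None = None) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "confusion": self.confusion,
            "metrics": {"acc": self.acc, "pr": self.pr, "se": self.se, "sp": self.sp, "f1": self.f1},
            "n_repeats": self.n_repeats,
            "positive_label": self.positive_label,
            "per_repeat": self.per_repeat,
        }
        if config_hash is not None:
            payload["config_hash"] = config_hash
        path.write_text(json.dumps(payload, indent=1))
        return path

    def confusion_table(self) -> str:
        c = self.confusion
        pos, neg = self.positive_label, "other"
        lines = [
            f"{'':>12} {'pred ' + pos:>14} {'pred ' + neg:>14}",
            f"{'true ' + pos:>12} {c['tp']:>14d} {c['fn']:>14d}",
            f"{'true ' + neg:>12} {c['fp']:>14d} {c['tn']:>14d}",
        ]
        return "\n".join(lines)


def build_model(n_features: int, n_classes: int, cfg: CnnConfig) -> MultiScaleCNN:
    """Instantiate the multiscale CNN with seeded parameter initialization."""
    return MultiScaleCNN(n_features, n_classes, cfg)


def train(model: MultiScaleCNN, x_train: np.ndarray, y_train: np.ndarray, cfg: CnnConfig):
    """Train with mini-batch Adam on the cross-entropy objective.

    ``y_train`` holds integer class indices. The per-epoch loss history is
    attached to the model as ``loss_history``.
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    history = model.fit(
        np.asarray(x_train, dtype=float),
        y_train,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        seed=cfg.seed,
    )
    model.loss_history = history
    return model


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    """Acc/Pr/Se/Sp/F1 (percent) from confusion counts; NaN if undefined."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    acc = ratio(tp + tn, tp + tn + fp + fn, "acc")
    pr = ratio(tp, tp + fp, "pr")
    se = ratio(tp, tp + fn, "se")
    sp = ratio(tn, fp + tn, "sp")
    if math.isnan(pr) or math.isnan(se) or (pr + se) == 0:
        undefined.append("f1")
        f1 = math.nan
    else:
        f1 = 2 * pr * se / (pr + se)
    return Metrics(acc=acc, pr=pr, se=se, sp=sp, f1=f1, undefined=tuple(undefined))


def baseline_classifiers() -> dict:
    """Standard comparison estimators (delegating to scikit-learn)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "logistic_regression": LogisticRegression(max_iter=2000),
        "svm": SVC(),
        "decision_tree": DecisionTreeClassifier(random_state=0),
        "knn": KNeighborsClassifier(),
        "naive_bayes": GaussianNB(),
    }


def _derived_seed(seed: int, repeat: int) -> int:
    return (seed * 100003 + repeat * 7919 + 1) % (2**31 - 1)


def evaluate(
    features: FeatureMatrix,
    selection_fraction: float = 0.6,
    k_neighbors: int = 10,
    cnn_cfg: CnnConfig | None = None,
    classifier: str | object = "cnn",
    n_repeats: int = 20,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified-split evaluation of the full selection+classification stage.

    Per repeat: a stratified ``train_fraction`` split with a repeat-derived
    seed; ReliefF weights fitted on the training fold only; the top
    ``selection_fraction`` of features kept; features standardized with
    training-fold statistics; the classifier trained and scored on the test
    fold. The confusion matrix is summed over repeats and metrics are means
    of the per-repeat metrics. ``classifier`` is ``"cnn"`` or any
    scikit-learn estimator (cloned per repeat).
    """
    cnn_cfg = cnn_cfg or CnnConfig()
    classes = features.classes
    if len(classes) != 2:
        raise ValueError(f"binary evaluation requires 2 classes, got {classes}")
    positive = "abnormal" if "abnormal" in classes else classes[1]
    y_all = (features.labels == positive).astype(int)

    total = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    per_repeat: list[dict] = []
    for rep in range(n_repeats):
        rs = _derived_seed(seed, rep)
        idx_train, idx_test = train_test_split(
            np.arange(features.n_samples),
            train_size=train_fraction,
            stratify=features.labels,
            random_state=rs,
        )
        train_fm = features.subset(rows=idx_train)
        weights = relieff_weights(train_fm, k_neighbors=k_neighbors, seed=rs)
        sel = select_top(weights, selection_fraction)
        kept = sel.kept

        x_train = features.values[np.ix_(idx_train, kept)]
        x_test = features.values[np.ix_(idx_test, kept)]
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_train - mu) / sd
        x_test = (x_test - mu) / sd
        y_train = y_all[idx_train]
        y_test = y_all[idx_test]

        if classifier == "cnn":
            ks = tuple(k for k in cnn_cfg.kernel_sizes if k <= len(kept))
            cfg = replace(cnn_cfg, kernel_sizes=ks, seed=rs)
            model = build_model(len(kept), 2, cfg)
            train(model, x_train, y_train, cfg)
            y_pred = model.predict(x_test)
        else:
            est = skbase.clone(classifier)
            if "random_state" in est.get_params():
                est.set_params(random_state=rs)
            est.fit(x_train, y_train)
            y_pred = np.asarray(est.predict(x_test))

        tp = int(np.sum((y_pred == 1) & (y_test == 1)))
        fp = int(np.sum((y_pred == 1) & (y_test == 0)))
        fn = int(np.sum((y_pred == 0) & (y_test == 1)))
        tn = int(np.sum((y_pred == 0) & (y_test == 0)))
        for key, val in zip(("tp", "fp", "fn", "tn"), (tp, fp, fn, tn)):
            total[key] += val
        met = metrics_from_confusion(tp, fp, fn, tn)
        per_repeat.append(
            {
                **met.as_dict(),
                "confusion": [tp, fp, fn, tn],
                "kept": [int(k) for k in kept],
                "test_idx": [int(i) for i in idx_test],
            }
        )

    means = {
        key: float(np.nanmean([r[key] for r in per_repeat])) for key in ("acc", "pr", "se", "sp", "f1")
    }
    return EvalReport(
        confusion=total,
        acc=means["acc"],
        pr=means["pr"],
        se=means["se"],
        sp=means["sp"],
        f1=means["f1"],
        n_repeats=n_repeats,
        per_repeat=per_repeat,
        positive_label=positive,
    )
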