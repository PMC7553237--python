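"""Cross-validation, classification metrics, and ablation experiments.

Metrics follow the one-vs-all scheme: for each class A,

    per-class accuracy (recall form) = #(samples of A predicted as A) / #A
    precision (PPV)  = TP / (TP + FP)
    sensitivity      = TP / (TP + FN)
    specificity      = TN / (TN + FP)
    F1               = 2 * precision * recall / (precision + recall)

The report exposes the recall-form per-class accuracy and the PPV under
both names because the two are conflated in common usage. Undefined
metrics (empty denominator) are NA — never coerced to 0 — and excluded
from medians.

The confusion-matrix convention is cell (j, i) = number of class-i
samples classified as class j, i.e. columns are true classes and rows
predicted classes in the serialised table; in memory the DataFrame is
true x predicted for ease of indexing.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, ExpressionMatrix, FoldError
from .cnn import PredictionResult, TrainedClassifier, predict

__all__ = [
    "MetricsReport",
    "CVSchedule",
    "make_folds",
    "compute_metrics",
    "topk_accuracy",
    "cross_validate",
    "ablation_remove_named",
    "ablation_remove_random",
    "save_confusion_heatmap",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    confusion: pd.DataFrame  # true x predicted, shared label order
    overall_accuracy: float
    per_class: pd.DataFrame  # indexed by class
    topk_accuracy: dict[int, float] = field(default_factory=dict)

    def to_json(self, path: Optional[os.PathLike | str] = None) -> str:
        payload = {
            "overall_accuracy": self.overall_accuracy,
            "topk_accuracy": {str(k): v for k, v in sorted(self.topk_accuracy.items())},
            "n_samples": int(self.confusion.to_numpy().sum()),
            "classes": list(self.confusion.index),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path: os.PathLike | str) -> None:
        self.per_class.to_csv(path, sep="\t")

    def confusion_to_tsv(self, path: os.PathLike | str) -> None:
        # serialised convention: cell (j, i) = class i samples predicted as j
        out = self.confusion.T
        out.index.name = "predicted\\true"
        out.to_csv(path, sep="\t")


def compute_metrics(
    confusion: pd.DataFrame,
    probability_matrix: Optional[np.ndarray] = None,
    true_labels: Optional[Sequence[str]] = None,
    class_order: Optional[Sequence[str]] = None,
    k_values: Sequence[int] = (1, 5),
) -> MetricsReport:
    """One-vs-all metrics from a labelled square confusion matrix.

    ``confusion`` is true x predicted with identical row/column labels.
    When a probability matrix (samples x class_order) and true labels are
    supplied, top-k accuracies are added for each ``k``.
    """
    if confusion.shape[0] != confusion.shape[1]:
        raise ConfigError("confusion matrix must be square")
    if list(confusion.index) != list(confusion.columns):
        raise ConfigError("confusion matrix rows/columns must share one label order")
    C = confusion.to_numpy(dtype=np.int64)
    if (C < 0).any():
        raise ConfigError("confusion entries must be non-negative")
    total = C.sum()
    if total == 0:
        raise ConfigError("empty confusion matrix")
    overall = float(np.trace(C) / total)

    rows = []
    for i, cls in enumerate(confusion.index):
        tp = C[i, i]
        fn = C[i, :].sum() - tp
        fp = C[:, i].sum() - tp
        tn = total - tp - fn - fp

        def ratio(num, den):
            return float(num / den) if den > 0 else np.nan

        precision = ratio(tp, tp + fp)
        recall = ratio(tp, tp + fn)
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = np.nan
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows.append(
            {
                "class": cls,
                "n": int(tp + fn),
                "per_class_accuracy": recall,  # recall-form printed formula
                "precision": precision,
                "ppv": precision,
                "sensitivity": recall,
                "specificity": ratio(tn, tn + fp),
                "f1": f1,
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")

    topk: dict[int, float] = {}
    if probability_matrix is not None and true_labels is not None:
        order = list(class_order if class_order is not None else confusion.index)
        for k in k_values:
            topk[int(k)] = topk_accuracy(probability_matrix, true_labels, order, k)
    return MetricsReport(
        confusion=confusion.copy(),
        overall_accuracy=overall,
        per_class=per_class,
        topk_accuracy=topk,
    )


def topk_accuracy(
    probs: np.ndarray,
    true_labels: Sequence[str],
    class_order: Sequence[str],
    k: int,
) -> float:
    """Fraction of samples whose true class ranks in the top k.

    Ties in probability are broken by class-order position (stable
    ranking), matching prediction.
    """
    probs = np.asarray(probs)
    k = min(k, probs.shape[1])
    order = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    pos = {c: i for i, c in enumerate(class_order)}
    true_idx = np.array([pos[t] for t in true_labels])
    return float((order == true_idx[:, None]).any(axis=1).mean())


def confusion_from_predictions(
    true_labels: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str],
) -> pd.DataFrame:
    order = list(class_order)
    pos = {c: i for i, c in enumerate(order)}
    C = np.zeros((len(order), len(order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted):
        C[pos[t], pos[p]] += 1
    return pd.DataFrame(C, index=order, columns=order)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVSchedule:
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ConfigError("cross-validation needs k >= 2")


def make_folds(labels: np.ndarray, schedule: CVSchedule) -> list[np.ndarray]:
    """Test-fold index arrays partitioning the sample set.

    Stratified folds (the default) keep every class represented in every
    fold, which small classes need for defined per-class metrics; plain
    random folds are available via ``stratified=False``.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    y = np.asarray(labels, dtype=object)
    n = len(y)
    if schedule.k > n:
        raise FoldError(f"k={schedule.k} exceeds {n} samples")
    if schedule.stratified:
        counts = pd.Series(y).value_counts()
        small = counts[counts < schedule.k]
        if len(small):
            raise FoldError(
                f"class(es) smaller than k={schedule.k}: {dict(small)} — "
                "reduce k, drop the class, or use stratified=False"
            )
        splitter = StratifiedKFold(n_splits=schedule.k, shuffle=True, random_state=schedule.seed)
        return [te for _, te in splitter.split(np.zeros(n), y.astype(str))]
    splitter = KFold(n_splits=schedule.k, shuffle=True, random_state=schedule.seed)
    return [te for _, te in splitter.split(np.zeros(n))]


def cross_validate(
    X: ExpressionMatrix,
    labels: Optional[np.ndarray] = None,
    pipeline_factory: Callable[[], object] = None,
    schedule: CVSchedule = CVSchedule(),
    k_values: Sequence[int] = (1, 5),
) -> tuple[MetricsReport, pd.DataFrame]:
    """k-fold cross-validation of an end-to-end pipeline.

    ``pipeline_factory()`` must return an object with
    ``fit(X_train, y_train)`` and
    ``predict_proba(X_test) -> (probs, class_order)``; feature selection
    happens inside ``fit``, so with a re-selecting pipeline the panel is
    chosen per fold (no leakage). Returns the pooled-confusion metrics
    report (with top-k accuracies) and a per-fold log.
    """
    if pipeline_factory is None:
        raise ConfigError("pipeline_factory is required")
    y = np.asarray(X.labels if labels is None else labels, dtype=object)
    if y.shape != (X.n_samples,):
        raise ConfigError("labels must align with samples")
    class_order = sorted(set(y))
    folds = make_folds(y, schedule)

    all_true: list[str] = []
    all_pred: list[str] = []
    all_probs: list[np.ndarray] = []
    fold_rows = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(X.n_samples), test_idx)
        pipe = pipeline_factory()
        pipe.fit(X.subset_samples(train_idx), y[train_idx])
        probs, fold_order = pipe.predict_proba(X.subset_samples(test_idx))
        # re-align the fold's class order onto the global one
        aligned = np.zeros((probs.shape[0], len(class_order)))
        for j, c in enumerate(fold_order):
            aligned[:, class_order.index(c)] = probs[:, j]
        pred = [class_order[j] for j in
                np.argsort(-aligned, axis=1, kind="stable")[:, 0]]
        truth = list(y[test_idx])
        all_true.extend(truth)
        all_pred.extend(pred)
        all_probs.append(aligned)
        acc = float(np.mean([p == t for p, t in zip(pred, truth)]))
        fold_rows.append({"fold": f, "n_test": len(test_idx), "accuracy": acc})

    confusion = confusion_from_predictions(all_true, all_pred, class_order)
    report = compute_metrics(
        confusion,
        probability_matrix=np.vstack(all_probs),
        true_labels=all_true,
        class_order=class_order,
        k_values=k_values,
    )
    return report, pd.DataFrame(fold_rows)


# ---------------------------------------------------------------------------
# Ablation experiments
# ---------------------------------------------------------------------------

def _metrics_for(clf: TrainedClassifier, X: ExpressionMatrix, y: np.ndarray,
                 zero_genes: Sequence[str] = (),
                 k_values: Sequence[int] = (1, 5)) -> MetricsReport:
    res = predict(clf, X, missing_policy="impute_zero", zero_genes=zero_genes)
    class_order = clf.class_order
    pred = [r[0] for r in res.ranked_labels]
    order = sorted(set(list(y) + class_order))
    confusion = confusion_from_predictions(list(y), pred, order)
    probs = res.probabilities.to_numpy()
    return compute_metrics(confusion, probs, list(y), class_order, k_values=k_values)


def ablation_remove_named(
    clf: TrainedClassifier,
    X_eval: ExpressionMatrix,
    labels: Optional[np.ndarray] = None,
    gene_list: Sequence[str] = (),
) -> dict:
    """Zero a named gene set at prediction and compare with baseline.

    Emulates the loss of diagnostic marker genes (e.g. an IHC panel
    analogue): the listed panel genes are zero-imputed after
    standardisation, metrics recomputed, and the paired deltas reported.
    """
    y = np.asarray(X_eval.labels if labels is None else labels, dtype=object)
    baseline = _metrics_for(clf, X_eval, y)
    ablated = _metrics_for(clf, X_eval, y, zero_genes=gene_list)
    return {
        "baseline": baseline,
        "ablated": ablated,
        "delta_overall_accuracy": ablated.overall_accuracy - baseline.overall_accuracy,
        "delta_topk": {
            k: ablated.topk_accuracy.get(k, np.nan) - baseline.topk_accuracy.get(k, np.nan)
            for k in baseline.topk_accuracy
        },
        "n_genes_removed": len([g for g in gene_list if g in clf.feature_set.genes]),
    }


def ablation_remove_random(
    clf: TrainedClassifier,
    X_eval: ExpressionMatrix,
    labels: Optional[np.ndarray] = None,
    k_values: Sequence[int] = (5, 10, 20, 50, 200),
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy under random removal of k panel genes, repeated.

    For each k, ``n_repeats`` seeded random panel subsets are zeroed at
    prediction; per-k mean and sd of top-1 accuracy are reported. ``k=0``
    rows reproduce the baseline exactly.
    """
    y = np.asarray(X_eval.labels if labels is None else labels, dtype=object)
    panel = list(clf.feature_set.genes)
    if max(k_values, default=0) > len(panel):
        raise ConfigError(
            f"cannot remove {max(k_values)} genes from a {len(panel)}-gene panel"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_values:
        accs = []
        for rep in range(n_repeats):
            if k == 0:
                removed: list[str] = []
            else:
                removed = list(rng.choice(panel, size=k, replace=False))
            rep_metrics = _metrics_for(clf, X_eval, y, zero_genes=removed)
            accs.append(rep_metrics.overall_accuracy)
            if k == 0:
                break  # baseline is deterministic
        rows.append(
            {
                "k": int(k),
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "n_repeats": len(accs),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plotting (deliberately minimal)
# ---------------------------------------------------------------------------

def save_confusion_heatmap(report: MetricsReport, path: os.PathLike | str) -> None:
    """Grayscale confusion-matrix heatmap (true x predicted)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    C = report.confusion.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = C / C.sum(axis=1, keepdims=True)
    norm = np.nan_to_num(norm)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(norm, cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(C.shape[1]), report.confusion.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(C.shape[0]), report.confusion.index, fontsize=6)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, label="row fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
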