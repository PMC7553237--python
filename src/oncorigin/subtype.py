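"""Per-cancer random-forest molecular-subtype classifiers.

Once the tissue of origin is known, a second, per-cancer classifier
assigns the molecular subtype (e.g. basal-like / HER2-enriched /
luminal A / luminal B in breast cancer). Each model is a random forest
— 1000 bootstrap trees, 31 candidate features per split by default —
trained on the per-sample standardised expression of a subtype-selected
gene panel, with classification by majority vote across trees. The same
machinery serves pan-cancer subtype groups: they are just a different
label table.

The forests are sklearn ensembles behind this module's surface; vote
tallies are computed from per-tree hard predictions so that votes sum
to the number of trees.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core import (
    ConfigError,
    CorruptBundleError,
    ExpressionMatrix,
    InsufficientClassError,
)
from .features import FeatureSet
from .preprocessing import DEFAULT_LOG2_OFFSET, apply_preprocessing

__all__ = [
    "SubtypeModel",
    "train_subtype_rf",
    "predict_subtype",
    "train_pancancer_subtype_rf",
]

DEFAULT_N_TREES = 1000
DEFAULT_MTRY = 31


@dataclass
class SubtypeModel:
    """A fitted per-cancer (or pan-cancer) subtype forest."""

    cancer_type: str
    subtype_order: list[str]
    forest: RandomForestClassifier
    feature_set: FeatureSet
    preprocessing: dict
    n_trees: int
    mtry: int
    oob_accuracy: Optional[float] = None


def _prepare_training_matrix(
    X: ExpressionMatrix,
    feature_set: Optional[FeatureSet],
    log2_offset: float,
) -> tuple[np.ndarray, FeatureSet]:
    if feature_set is None:
        if X.scale != "standardized":
            raise ConfigError(
                "without a feature_set, training expects an already standardized, "
                f"panel-aligned matrix (got scale={X.scale!r})"
            )
        fs = FeatureSet(
            genes=list(X.gene_ids),
            per_gene=pd.DataFrame(
                {
                    "gene_id": X.gene_ids,
                    "chromosome": None,
                    "start": np.nan,
                    "source_classes": "",
                    "median_difference": np.nan,
                    "p_value": np.nan,
                }
            ),
        )
        return X.values, fs
    Xp = apply_preprocessing(X, feature_set, offset=log2_offset, missing_policy="error")
    return Xp.values, feature_set


def train_subtype_rf(
    X: ExpressionMatrix,
    subtype_labels: Optional[np.ndarray] = None,
    cancer_type: str = "",
    n_trees: int = DEFAULT_N_TREES,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
    bootstrap: bool = True,
    feature_set: Optional[FeatureSet] = None,
    log2_offset: float = DEFAULT_LOG2_OFFSET,
) -> SubtypeModel:
    """Fit a subtype forest for one cancer type.

    ``X`` is either an already standardised panel-aligned matrix, or any
    scale together with ``feature_set`` (the subtype panel), in which
    case the stored preprocessing pipeline is applied. ``mtry`` clips to
    the panel size with a warning when the panel is smaller. The
    out-of-bag accuracy is recorded when bootstrapping.
    """
    y = np.asarray(X.labels if subtype_labels is None else subtype_labels, dtype=object)
    if y.shape != (X.n_samples,):
        raise InsufficientClassError("subtype labels must align with samples")
    subtypes = sorted(set(y))
    if len(subtypes) < 2:
        raise InsufficientClassError(
            f"need >= 2 subtypes, got {len(subtypes)} ({subtypes})"
        )
    counts = {s: int((y == s).sum()) for s in subtypes}
    small = [s for s, c in counts.items() if c < 2]
    if small:
        raise InsufficientClassError(f"subtype(s) with < 2 samples: {small}")
    values, fs = _prepare_training_matrix(X, feature_set, log2_offset)
    n_features = values.shape[1]
    if n_features < 1:
        raise ConfigError("subtype training needs at least one feature")
    eff_mtry = mtry
    if mtry > n_features:
        warnings.warn(
            f"mtry={mtry} exceeds panel size {n_features}; clipping", stacklevel=2
        )
        eff_mtry = n_features
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=eff_mtry,
        bootstrap=bootstrap,
        oob_score=bootstrap,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny cohorts can leave some samples never out-of-bag
        warnings.simplefilter("ignore", UserWarning)
        forest.fit(values, y.astype(str))
    oob = float(forest.oob_score_) if bootstrap else None
    return SubtypeModel(
        cancer_type=cancer_type,
        subtype_order=subtypes,
        forest=forest,
        feature_set=fs,
        preprocessing={"log2_offset": log2_offset, "ddof": 0, "scale_over": "panel"},
        n_trees=n_trees,
        mtry=eff_mtry,
        oob_accuracy=oob,
    )


def train_pancancer_subtype_rf(
    X: ExpressionMatrix,
    pan_subtype_labels: Optional[np.ndarray] = None,
    group_name: str = "pan",
    **kwargs,
) -> SubtypeModel:
    """Pan-cancer subtype forest: identical machinery, pan-group labels."""
    return train_subtype_rf(
        X, pan_subtype_labels, cancer_type=group_name, **kwargs
    )


def predict_subtype(
    model: SubtypeModel,
    X: ExpressionMatrix,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Majority-vote subtype calls with per-subtype vote fractions.

    Returns a DataFrame (index sample_id) with ``predicted_subtype``, a
    ``tie`` flag (ties resolved to the first subtype in subtype order),
    and one vote-fraction column per subtype; fractions sum to 1.
    """
    Xp = apply_preprocessing(
        X,
        model.feature_set,
        offset=model.preprocessing.get("log2_offset", DEFAULT_LOG2_OFFSET),
        missing_policy=missing_policy,
        ddof=model.preprocessing.get("ddof", 0),
    )
    values = Xp.values
    classes = list(model.forest.classes_)
    col = {s: j for j, s in enumerate(model.subtype_order)}
    # trees inside a forest predict in the encoded (0..K-1) label space
    class_to_col = np.array([col[str(c)] for c in classes])
    counts = np.zeros((values.shape[0], len(model.subtype_order)), dtype=np.int64)
    for tree in model.forest.estimators_:
        pred = tree.predict(values)
        if np.issubdtype(np.asarray(pred).dtype, np.number):
            cols = class_to_col[pred.astype(int)]
        else:
            cols = np.array([col[str(s)] for s in pred])
        np.add.at(counts, (np.arange(values.shape[0]), cols), 1)
    assert counts.sum(axis=1).min() == counts.sum(axis=1).max() == len(
        model.forest.estimators_
    )
    fractions = counts / counts.sum(axis=1, keepdims=True)
    best = fractions.argmax(axis=1)  # argmax takes the first maximum: tie rule
    ties = (fractions == fractions.max(axis=1, keepdims=True)).sum(axis=1) > 1
    out = pd.DataFrame(
        {
            "predicted_subtype": [model.subtype_order[j] for j in best],
            "tie": ties,
        },
        index=Xp.sample_ids,
    )
    for j, s in enumerate(model.subtype_order):
        out[f"vote_{s}"] = fractions[:, j]
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Bundle helpers used by core.save_model_bundle
# ---------------------------------------------------------------------------

def save_subtype_model(model: SubtypeModel, directory: Path) -> dict:
    joblib.dump(model.forest, directory / "forest.joblib")
    model.feature_set.to_tsv(directory / "features.tsv")
    return {
        "kind": "subtype_rf",
        "cancer_type": model.cancer_type,
        "subtype_order": list(model.subtype_order),
        "n_trees": model.n_trees,
        "mtry": model.mtry,
        "oob_accuracy": model.oob_accuracy,
        "preprocessing": model.preprocessing,
        "feature_genes": list(model.feature_set.genes),
        "files": {"forest": "forest.joblib", "features": "features.tsv"},
    }


def load_subtype_model(directory: Path, manifest: dict) -> SubtypeModel:
    for key in ("subtype_order", "preprocessing", "files"):
        if key not in manifest:
            raise CorruptBundleError(f"manifest missing {key!r}")
    files = manifest["files"]
    fpath = directory / files.get("forest", "forest.joblib")
    gpath = directory / files.get("features", "features.tsv")
    if not fpath.exists() or not gpath.exists():
        raise CorruptBundleError(f"bundle component missing in {directory}")
    forest = joblib.load(fpath)
    return SubtypeModel(
        cancer_type=manifest.get("cancer_type", ""),
        subtype_order=list(manifest["subtype_order"]),
        forest=forest,
        feature_set=FeatureSet.from_tsv(gpath),
        preprocessing=dict(manifest["preprocessing"]),
        n_trees=int(manifest.get("n_trees", DEFAULT_N_TREES)),
        mtry=int(manifest.get("mtry", DEFAULT_MTRY)),
        oob_accuracy=manifest.get("oob_accuracy"),
    )
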