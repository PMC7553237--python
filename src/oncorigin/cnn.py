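"""1-D convolutional tissue-of-origin classifiers.

Two architectures over the same chromosomally ordered feature-gene
vector:

* **1D-Inception** — several parallel convolutional branches with
  different kernel sizes (each branch 1-3 conv layers, its own max-pool
  window and dropout keep-probability), concatenated and fed into two
  128-node fully connected layers and a softmax output. Parallel kernels
  of different sizes let a small gene panel expose patterns at several
  genomic scales at once.
* **1D-CNN baseline** — one conv layer (32 filters of length 4), one
  max-pool, four 64-node FC layers, softmax.

Convolutions are valid (no padding), stride 1, so the concatenation
width is a deterministic function of the config, which the builder
reports. Activations are ReLU throughout; dropout is parameterised as
keep-probability and applied after pooling and after each hidden FC
layer. Training is Adam (default batch 32, learning rate 0.001) on
categorical cross-entropy with Xavier-normal initialisation, fully
seeded.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .core import (
    ConfigError,
    CorruptBundleError,
    DivergenceError,
    ExpressionMatrix,
    LabelError,
)
from .features import FeatureSet, select_features
from .preprocessing import DEFAULT_LOG2_OFFSET, apply_preprocessing

__all__ = [
    "ConvLayerSpec",
    "BranchSpec",
    "InceptionConfig",
    "CNN1DConfig",
    "TrainHyperparams",
    "TRAIN_PRESETS",
    "default_inception_config",
    "default_cnn1d_config",
    "build_inception",
    "build_cnn1d",
    "TrainedClassifier",
    "train",
    "predict",
    "PredictionResult",
    "OriginClassifierPipeline",
    "hyperparameter_search",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvLayerSpec:
    kernel_size: int
    n_filters: int


@dataclass(frozen=True)
class BranchSpec:
    """One parallel convolutional module: 1-3 conv layers, then pool/dropout."""

    conv_layers: tuple[ConvLayerSpec, ...]
    pool_window: int = 1
    keep_prob: float = 1.0


def _validate_branch(branch: BranchSpec, input_length: int, where: str) -> int:
    """Validate one branch and return its flattened output width."""
    if not (1 <= len(branch.conv_layers) <= 3):
        raise ConfigError(f"{where}: conv module must have 1-3 layers, got {len(branch.conv_layers)}")
    length = input_length
    for spec in branch.conv_layers:
        if spec.kernel_size < 1 or spec.n_filters < 1:
            raise ConfigError(f"{where}: kernel_size and n_filters must be >= 1")
        if spec.kernel_size > length:
            raise ConfigError(
                f"{where}: kernel_size {spec.kernel_size} exceeds remaining length {length}"
            )
        length = length - spec.kernel_size + 1
    if branch.pool_window < 1:
        raise ConfigError(f"{where}: pool window must be >= 1")
    pooled = length // branch.pool_window
    if pooled < 1:
        raise ConfigError(f"{where}: pool window {branch.pool_window} exceeds conv output {length}")
    if not (0.0 < branch.keep_prob <= 1.0):
        raise ConfigError(f"{where}: keep_prob must be in (0, 1]")
    return pooled * branch.conv_layers[-1].n_filters


@dataclass(frozen=True)
class InceptionConfig:
    """Declarative 1D-Inception architecture.

    ``concat_width()`` reports the size of the concatenation layer — a
    deterministic function of the config under valid convolutions.
    """

    branches: tuple[BranchSpec, ...]
    n_classes: int
    input_length: int
    fc_layers: tuple[int, ...] = (128, 128)
    fc_keep_prob: float = 1.0

    def __post_init__(self):
        if len(self.branches) < 2:
            raise ConfigError("an inception config needs >= 2 parallel branches")
        self._validate_common()

    def _validate_common(self):
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.input_length < 1:
            raise ConfigError("input_length must be >= 1")
        if any(w < 1 for w in self.fc_layers):
            raise ConfigError("fc layer widths must be >= 1")
        if not (0.0 < self.fc_keep_prob <= 1.0):
            raise ConfigError("fc_keep_prob must be in (0, 1]")
        for i, b in enumerate(self.branches):
            _validate_branch(b, self.input_length, f"branch {i}")

    def concat_width(self) -> int:
        return sum(
            _validate_branch(b, self.input_length, f"branch {i}")
            for i, b in enumerate(self.branches)
        )

    def to_dict(self) -> dict:
        return {
            "kind": "inception",
            "branches": [
                {
                    "conv_layers": [[s.kernel_size, s.n_filters] for s in b.conv_layers],
                    "pool_window": b.pool_window,
                    "keep_prob": b.keep_prob,
                }
                for b in self.branches
            ],
            "n_classes": self.n_classes,
            "input_length": self.input_length,
            "fc_layers": list(self.fc_layers),
            "fc_keep_prob": self.fc_keep_prob,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InceptionConfig":
        return cls(
            branches=tuple(
                BranchSpec(
                    conv_layers=tuple(ConvLayerSpec(int(k), int(f)) for k, f in b["conv_layers"]),
                    pool_window=int(b.get("pool_window", 1)),
                    keep_prob=float(b.get("keep_prob", 1.0)),
                )
                for b in d["branches"]
            ),
            n_classes=int(d["n_classes"]),
            input_length=int(d["input_length"]),
            fc_layers=tuple(int(w) for w in d.get("fc_layers", (128, 128))),
            fc_keep_prob=float(d.get("fc_keep_prob", 1.0)),
        )


@dataclass(frozen=True)
class CNN1DConfig(InceptionConfig):
    """Single-branch 1D-CNN baseline (32 filters of length 4, 4x64 FC)."""

    def __post_init__(self):
        if len(self.branches) != 1:
            raise ConfigError("the 1D-CNN baseline has exactly one conv branch")
        self._validate_common()

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["kind"] = "cnn1d"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CNN1DConfig":
        base = InceptionConfig.from_dict.__func__(cls, d)  # type: ignore[attr-defined]
        return base


def default_inception_config(input_length: int, n_classes: int) -> InceptionConfig:
    """Shipped default: branches of 1/2/3 conv layers with kernels {1},
    {3,3}, {5,5,5}, 16 filters each, pools {1,2,2}, keep {1.0,0.8,0.8},
    two 128-node FC layers. Fully overridable via config files; the
    builder reports the resulting concatenation width."""
    return InceptionConfig(
        branches=(
            BranchSpec((ConvLayerSpec(1, 16),), pool_window=1, keep_prob=1.0),
            BranchSpec((ConvLayerSpec(3, 16), ConvLayerSpec(3, 16)), pool_window=2, keep_prob=0.8),
            BranchSpec(
                (ConvLayerSpec(5, 16), ConvLayerSpec(5, 16), ConvLayerSpec(5, 16)),
                pool_window=2,
                keep_prob=0.8,
            ),
        ),
        n_classes=n_classes,
        input_length=input_length,
    )


def default_cnn1d_config(input_length: int, n_classes: int) -> CNN1DConfig:
    """Baseline defaults: 32 filters of length 4, one max-pool (window 2),
    no dropout, four 64-node FC layers."""
    return CNN1DConfig(
        branches=(BranchSpec((ConvLayerSpec(4, 32),), pool_window=2, keep_prob=1.0),),
        n_classes=n_classes,
        input_length=input_length,
        fc_layers=(64, 64, 64, 64),
        fc_keep_prob=1.0,
    )


@dataclass(frozen=True)
class TrainHyperparams:
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 500
    optimizer: str = "adam"
    weight_init: str = "xavier_normal"
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.weight_init not in ("xavier_normal", "default"):
            raise ConfigError(f"unknown weight_init {self.weight_init!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainHyperparams":
        return cls(**{k: d[k] for k in
                      ("batch_size", "learning_rate", "epochs", "optimizer",
                       "weight_init", "seed") if k in d})


#: Named training schedules. ``combined`` is the full-scale schedule for
#: the inception model on large cohorts; ``baseline_1dcnn`` the tuned
#: baseline schedule; ``desk`` a short schedule sized for the synthetic
#: desk-scale benchmarks.
TRAIN_PRESETS: dict[str, TrainHyperparams] = {
    "combined": TrainHyperparams(batch_size=32, learning_rate=1e-3, epochs=500),
    "baseline_1dcnn": TrainHyperparams(batch_size=32, learning_rate=0.02, epochs=200),
    "desk": TrainHyperparams(batch_size=32, learning_rate=1e-3, epochs=40),
}


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class _Net:
    """Parallel conv branches -> concat -> FC stack -> logits."""

    def __init__(self, config: InceptionConfig, rng: np.random.Generator,
                 init: str = "xavier_normal"):
        self.config = config
        self.branches: list[nn.Sequential] = []
        widths = []
        for i, b in enumerate(config.branches):
            layers: list[nn.Layer] = []
            channels = 1
            for spec in b.conv_layers:
                layers.append(nn.Conv1D(spec.kernel_size, channels, spec.n_filters, rng, init))
                layers.append(nn.ReLU())
                channels = spec.n_filters
            layers.append(nn.MaxPool1D(b.pool_window))
            layers.append(nn.Dropout(b.keep_prob))
            layers.append(nn.Flatten())
            self.branches.append(nn.Sequential(layers))
            widths.append(_validate_branch(b, config.input_length, f"branch {i}"))
        self._branch_widths = widths
        self.concat_width = sum(widths)
        fc_layers: list[nn.Layer] = []
        n_in = self.concat_width
        for w in config.fc_layers:
            fc_layers.append(nn.Dense(n_in, w, rng, init))
            fc_layers.append(nn.ReLU())
            fc_layers.append(nn.Dropout(config.fc_keep_prob))
            n_in = w
        fc_layers.append(nn.Dense(n_in, config.n_classes, rng, init))
        self.fc = nn.Sequential(fc_layers)

    def forward(self, X: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        x = X[:, :, None]  # (B, L, 1)
        outs = [b.forward(x, train, rng) for b in self.branches]
        self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        concat = np.concatenate(outs, axis=1)
        return self.fc.forward(concat, train, rng)

    def backward(self, dlogits: np.ndarray) -> None:
        dconcat = self.fc.backward(dlogits)
        for branch, dpart in zip(self.branches, np.split(dconcat, self._split, axis=1)):
            branch.backward(dpart)

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, b in enumerate(self.branches):
            out.update(b.named_params(f"branch{i}."))
        out.update(self.fc.named_params("fc."))
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, b in enumerate(self.branches):
            out.update(b.named_grads(f"branch{i}."))
        out.update(self.fc.named_grads("fc."))
        return out

    def set_params(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if set(state) != set(params):
            raise CorruptBundleError("weight state does not match architecture")
        for k, v in params.items():
            v[...] = state[k]

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused at eval (no dropout)
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits = self.forward(X[start:start + batch_size], train=False, rng=rng)
            out.append(nn.softmax(logits))
        return np.vstack(out)


def build_inception(config: InceptionConfig, seed: int = 0,
                    init: str = "xavier_normal") -> tuple[_Net, int]:
    """Build an untrained inception network; returns (net, concat_width)."""
    net = _Net(config, np.random.default_rng(seed), init)
    return net, net.concat_width


def build_cnn1d(config: CNN1DConfig, seed: int = 0,
                init: str = "xavier_normal") -> tuple[_Net, int]:
    """Build the untrained single-branch baseline; returns (net, concat_width)."""
    if not isinstance(config, CNN1DConfig):
        raise ConfigError("build_cnn1d expects a CNN1DConfig")
    net = _Net(config, np.random.default_rng(seed), init)
    return net, net.concat_width


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A fitted network bundled with everything prediction needs."""

    config: InceptionConfig
    net: _Net
    feature_set: FeatureSet
    class_order: list[str]
    preprocessing: dict
    hyperparams: TrainHyperparams
    training_log: pd.DataFrame  # epoch, train_loss, val_loss


def train(
    net: _Net,
    X_train: ExpressionMatrix,
    labels: Optional[np.ndarray] = None,
    hp: TrainHyperparams = TRAIN_PRESETS["combined"],
    validation_fraction: float = 0.1,
    feature_set: Optional[FeatureSet] = None,
    class_order: Optional[Sequence[str]] = None,
    preprocessing: Optional[dict] = None,
) -> TrainedClassifier:
    """Train a network on a standardised, panel-aligned matrix.

    Minimises categorical cross-entropy with the configured optimiser;
    records per-epoch train/validation loss; a fixed ``hp.seed``
    reproduces shuffling and dropout exactly. Non-finite loss raises
    :class:`DivergenceError` with the epoch index.
    """
    if X_train.scale != "standardized":
        raise ConfigError(f"training expects standardized input, got scale={X_train.scale!r}")
    y_raw = np.asarray(X_train.labels if labels is None else labels, dtype=object)
    if y_raw.shape != (X_train.n_samples,):
        raise LabelError("labels must align with training samples")
    order = list(class_order) if class_order is not None else sorted(set(y_raw))
    pos = {c: i for i, c in enumerate(order)}
    unknown = sorted({c for c in y_raw if c not in pos})
    if unknown:
        raise LabelError(f"label(s) outside class order: {unknown[:5]}")
    if len(order) != net.config.n_classes:
        raise LabelError(
            f"{len(order)} classes in data but network outputs {net.config.n_classes}"
        )
    if feature_set is not None and list(X_train.gene_ids) != list(feature_set.genes):
        raise ConfigError("training matrix columns must follow the feature-set order")

    y = np.array([pos[c] for c in y_raw])
    X = X_train.values
    rng = np.random.default_rng(hp.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(n * validation_fraction))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ConfigError("validation_fraction leaves no training samples")
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    params = net.params()
    if hp.optimizer == "adam":
        opt = nn.Adam(params, lr=hp.learning_rate)
    else:
        opt = nn.SGD(params, lr=hp.learning_rate)

    log = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(hp.epochs):
        idx = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(idx), hp.batch_size):
            batch = idx[start:start + hp.batch_size]
            logits = net.forward(Xtr[batch], train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, ytr[batch])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            net.backward(dlogits)
            opt.step(net.grads())
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if len(Xval):
            vlogits = net.forward(Xval, train=False, rng=rng)
            val_loss, _ = nn.softmax_cross_entropy(vlogits, yval)
        else:
            val_loss = train_loss
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise DivergenceError(epoch)
        log["epoch"].append(epoch)
        log["train_loss"].append(train_loss)
        log["val_loss"].append(float(val_loss))

    fs = feature_set if feature_set is not None else FeatureSet(
        genes=list(X_train.gene_ids),
        per_gene=pd.DataFrame(
            {
                "gene_id": X_train.gene_ids,
                "chromosome": None,
                "start": np.nan,
                "source_classes": "",
                "median_difference": np.nan,
                "p_value": np.nan,
            }
        ),
    )
    prep = dict(preprocessing or {})
    prep.setdefault("log2_offset", DEFAULT_LOG2_OFFSET)
    prep.setdefault("ddof", 0)
    prep.setdefault("scale_over", "panel")
    return TrainedClassifier(
        config=net.config,
        net=net,
        feature_set=fs,
        class_order=order,
        preprocessing=prep,
        hyperparams=hp,
        training_log=pd.DataFrame(log),
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    probabilities: pd.DataFrame  # samples x class_order
    ranked_labels: list[list[str]]  # per sample, best first

    def top_labels(self, k: int = 1) -> list[list[str]]:
        return [r[:k] for r in self.ranked_labels]

    def to_frame(self, k: int = 5) -> pd.DataFrame:
        out = pd.DataFrame(
            {f"top{i + 1}": [r[i] if i < len(r) else "" for r in self.ranked_labels]
             for i in range(min(k, self.probabilities.shape[1]))},
            index=self.probabilities.index,
        )
        return pd.concat([out, self.probabilities], axis=1)


def _rank(probs: np.ndarray, class_order: list[str]) -> list[list[str]]:
    # stable argsort on -p breaks ties by class_order position
    order = np.argsort(-probs, axis=1, kind="stable")
    return [[class_order[j] for j in row] for row in order]


def predict(
    clf: TrainedClassifier,
    X: ExpressionMatrix,
    missing_policy: str = "error",
    zero_genes: Sequence[str] = (),
) -> PredictionResult:
    """Predict class probabilities and ranked labels for any input scale.

    Raw TPM or log2 input is passed through the classifier's stored
    preprocessing contract (log2 offset, panel subset, per-sample
    standardisation); already-standardised input is aligned only.
    ``zero_genes`` zeroes the listed panel genes after preprocessing —
    the mechanism of the gene-ablation robustness experiments.
    """
    Xp = apply_preprocessing(
        X,
        clf.feature_set,
        offset=clf.preprocessing.get("log2_offset", DEFAULT_LOG2_OFFSET),
        missing_policy=missing_policy,
        ddof=clf.preprocessing.get("ddof", 0),
    )
    values = Xp.values
    if len(zero_genes):
        index = {g: i for i, g in enumerate(clf.feature_set.genes)}
        hit = [index[g] for g in zero_genes if g in index]
        absent = [g for g in zero_genes if g not in index]
        if absent:
            warnings.warn(f"{len(absent)} gene(s) to zero are not in the panel", stacklevel=2)
        if hit:
            values = values.copy()
            values[:, hit] = 0.0
    probs = clf.net.predict_proba(values)
    pf = pd.DataFrame(probs, index=Xp.sample_ids, columns=clf.class_order)
    return PredictionResult(probabilities=pf, ranked_labels=_rank(probs, clf.class_order))


# ---------------------------------------------------------------------------
# End-to-end pipeline (used by cross-validation and the CLI)
# ---------------------------------------------------------------------------

class OriginClassifierPipeline:
    """Feature selection + preprocessing + network training as one unit.

    ``fit`` expects a log2-scale (or TPM) labelled matrix; it selects the
    panel (unless a fixed :class:`FeatureSet` is supplied), standardises,
    builds the network from the config factory, and trains.
    """

    def __init__(
        self,
        n_per_class: int = 40,
        alpha: float = 1e-3,
        annotation: Optional[pd.DataFrame] = None,
        config_factory: Callable[[int, int], InceptionConfig] = default_inception_config,
        hp: TrainHyperparams = TRAIN_PRESETS["desk"],
        feature_set: Optional[FeatureSet] = None,
        log2_offset: float = DEFAULT_LOG2_OFFSET,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.n_per_class = n_per_class
        self.alpha = alpha
        self.annotation = annotation
        self.config_factory = config_factory
        self.hp = hp
        self.fixed_feature_set = feature_set
        self.log2_offset = log2_offset
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.classifier: Optional[TrainedClassifier] = None

    def fit(self, X: ExpressionMatrix, y: Optional[np.ndarray] = None) -> "OriginClassifierPipeline":
        from .preprocessing import log2_transform  # local to avoid cycles

        if X.scale == "tpm":
            X = log2_transform(X, self.log2_offset)
        labels = np.asarray(X.labels if y is None else y, dtype=object)
        if self.fixed_feature_set is not None:
            fs = self.fixed_feature_set
        else:
            fs = select_features(
                X, labels, n_per_class=self.n_per_class, alpha=self.alpha,
                annotation=self.annotation,
            )
        Xs = apply_preprocessing(X, fs, offset=self.log2_offset, missing_policy="error")
        config = self.config_factory(len(fs), len(sorted(set(labels))))
        hp = dataclasses.replace(self.hp, seed=self.seed)
        net, _ = build_inception(config, seed=self.seed) if not isinstance(
            config, CNN1DConfig
        ) else build_cnn1d(config, seed=self.seed)
        self.classifier = train(
            net, Xs, labels, hp=hp,
            validation_fraction=self.validation_fraction,
            feature_set=fs,
            preprocessing={"log2_offset": self.log2_offset, "ddof": 0, "scale_over": "panel"},
        )
        return self

    def predict_proba(self, X: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
        if self.classifier is None:
            raise ConfigError("pipeline is not fitted")
        res = predict(self.classifier, X, missing_policy="impute_zero")
        return res.probabilities.to_numpy(), self.classifier.class_order


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

def hyperparameter_search(
    space: Sequence[tuple[InceptionConfig, TrainHyperparams]],
    X: ExpressionMatrix,
    labels: Optional[np.ndarray] = None,
    k_inner: int = 3,
    seed: int = 0,
    mode: str = "grid",
    n_random: Optional[int] = None,
) -> tuple[tuple[InceptionConfig, TrainHyperparams], pd.DataFrame]:
    """Score candidate (architecture, schedule) pairs by inner-CV accuracy.

    ``mode='grid'`` scores the whole declared space; ``'random'`` scores a
    seeded sample of ``n_random`` candidates. Returns the best candidate
    (ties to the earliest) and the full (candidate, score) log.
    """
    from sklearn.model_selection import StratifiedKFold

    if len(space) == 0:
        raise ConfigError("empty hyperparameter space")
    candidates = list(space)
    if mode == "random":
        k = min(n_random or len(candidates), len(candidates))
        pick = np.random.default_rng(seed).choice(len(candidates), size=k, replace=False)
        candidates = [candidates[i] for i in sorted(pick)]
    elif mode != "grid":
        raise ConfigError(f"unknown search mode {mode!r}")

    y = np.asarray(X.labels if labels is None else labels, dtype=object)
    rows = []
    best_idx, best_score = 0, -np.inf
    for ci, (config, hp) in enumerate(candidates):
        skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
        correct = total = 0
        for tr, te in skf.split(X.values, y):
            Xtr = X.subset_samples(tr)
            net, _ = build_inception(config, seed=seed)
            clf = train(net, Xtr, y[tr], hp=dataclasses.replace(hp, seed=seed),
                        validation_fraction=0.0)
            probs = clf.net.predict_proba(X.values[te])
            pred = [clf.class_order[j] for j in probs.argmax(axis=1)]
            correct += int(sum(p == t for p, t in zip(pred, y[te])))
            total += len(te)
        score = correct / total
        rows.append({"candidate": ci, "config": config.to_dict(), "hp": hp.to_dict(),
                     "score": score})
        if score > best_score:
            best_idx, best_score = ci, score
    return candidates[best_idx], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle (de)serialisation helpers used by core.save_model_bundle
# ---------------------------------------------------------------------------

def save_trained_classifier(clf: TrainedClassifier, directory: Path) -> dict:
    np.savez(directory / "weights.npz", **clf.net.params())
    clf.feature_set.to_tsv(directory / "features.tsv")
    clf.training_log.to_csv(directory / "training_log.csv", index=False)
    return {
        "kind": "cnn",
        "config": clf.config.to_dict(),
        "hyperparams": clf.hyperparams.to_dict(),
        "class_order": list(clf.class_order),
        "preprocessing": clf.preprocessing,
        "feature_genes": list(clf.feature_set.genes),
        "files": {"weights": "weights.npz", "features": "features.tsv",
                  "training_log": "training_log.csv"},
    }


def load_trained_classifier(directory: Path, manifest: dict) -> TrainedClassifier:
    for key in ("config", "class_order", "preprocessing", "files"):
        if key not in manifest:
            raise CorruptBundleError(f"manifest missing {key!r}")
    files = manifest["files"]
    wpath = directory / files.get("weights", "weights.npz")
    fpath = directory / files.get("features", "features.tsv")
    if not wpath.exists() or not fpath.exists():
        raise CorruptBundleError(f"bundle component missing in {directory}")
    cfg_dict = manifest["config"]
    cls = CNN1DConfig if cfg_dict.get("kind") == "cnn1d" else InceptionConfig
    config = cls.from_dict(cfg_dict)
    net = _Net(config, np.random.default_rng(0))
    with np.load(wpath) as state:
        net.set_params({k: state[k] for k in state.files})
    fs = FeatureSet.from_tsv(fpath)
    log_path = directory / files.get("training_log", "training_log.csv")
    log = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame(
        columns=["epoch", "train_loss", "val_loss"]
    )
    return TrainedClassifier(
        config=config,
        net=net,
        feature_set=fs,
        class_order=list(manifest["class_order"]),
        preprocessing=dict(manifest["preprocessing"]),
        hyperparams=TrainHyperparams.from_dict(manifest.get("hyperparams", {})),
        training_log=log,
    )
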