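"""Core data model and file I/O.

Expression matrices, gene annotations, sample label tables, and model
bundle (de)serialisation. Everything downstream — preprocessing, feature
selection, the convolutional classifiers, the subtype forests — consumes
the types defined here.

Conventions
-----------
* In memory, expression matrices are samples x genes (float64). On disk
  the default dialect is genes-as-rows (first column gene IDs, header row
  sample IDs), the common expression-matrix layout; a flag overrides.
* Chromosomes are normalised to the ``chr1``..``chr22``, ``chrX``,
  ``chrY``, ``chrM`` universe and sort in that karyotype order; unknown
  names are kept but sort after the universe. Starts are 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OncoriginError",
    "ParseError",
    "IdentifierCollisionError",
    "EmptyInputError",
    "ScaleError",
    "DomainError",
    "FlaggedSampleError",
    "MissingFeatureError",
    "InsufficientClassError",
    "NoFeaturesError",
    "ConfigError",
    "LabelError",
    "DivergenceError",
    "FoldError",
    "CorruptBundleError",
    "CHROMOSOME_UNIVERSE",
    "normalize_chromosome",
    "chromosome_rank",
    "ExpressionMatrix",
    "load_expression",
    "write_expression",
    "load_annotation",
    "write_annotation",
    "load_labels",
    "write_labels",
    "save_model_bundle",
    "load_model_bundle",
    "file_sha256",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OncoriginError(Exception):
    """Base class for all package errors."""


class ParseError(OncoriginError):
    """A file could not be parsed (non-numeric cell, bad column, ...)."""


class IdentifierCollisionError(ParseError):
    """Duplicate gene or sample identifiers."""


class EmptyInputError(ParseError):
    """A matrix or table with no rows/columns."""


class ScaleError(OncoriginError):
    """An operation received data on the wrong value scale."""


class DomainError(OncoriginError):
    """A value outside the mathematical domain of an operation."""


class FlaggedSampleError(OncoriginError):
    """Samples that cannot be processed (e.g. zero variance).

    Carries the offending sample ids so clinical single-sample use fails
    loudly and informatively rather than propagating NaNs.
    """

    def __init__(self, sample_ids: Sequence[str], reason: str = "zero variance"):
        self.sample_ids = list(sample_ids)
        super().__init__(
            f"{len(self.sample_ids)} sample(s) flagged ({reason}): "
            + ", ".join(self.sample_ids[:10])
            + ("..." if len(self.sample_ids) > 10 else "")
        )


class MissingFeatureError(OncoriginError):
    """Required feature genes absent from an input matrix."""

    def __init__(self, genes: Sequence[str]):
        self.genes = list(genes)
        super().__init__(
            f"{len(self.genes)} feature gene(s) missing from input: "
            + ", ".join(self.genes[:10])
            + ("..." if len(self.genes) > 10 else "")
        )


class InsufficientClassError(OncoriginError):
    """A class/subtype with too few samples for the requested statistic."""


class NoFeaturesError(OncoriginError):
    """Feature selection produced an empty panel."""


class ConfigError(OncoriginError):
    """Invalid architecture / hyperparameter / generator configuration."""


class LabelError(OncoriginError):
    """A label outside the declared class order."""


class DivergenceError(OncoriginError):
    """Training loss became NaN/Inf."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")


class FoldError(OncoriginError):
    """A cross-validation schedule that cannot be realised."""


class CorruptBundleError(OncoriginError):
    """A model bundle directory with missing or inconsistent components."""


# ---------------------------------------------------------------------------
# Chromosome universe
# ---------------------------------------------------------------------------

CHROMOSOME_UNIVERSE: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
)

_CHROM_RANK = {name: i for i, name in enumerate(CHROMOSOME_UNIVERSE)}


def normalize_chromosome(name: str) -> str:
    """Normalise a chromosome name into the declared universe.

    Accepts names with or without the ``chr`` prefix and maps ``MT`` to
    ``chrM``. Names outside the universe are returned prefixed but
    otherwise untouched.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() == "MT":
        s = "M"
    if s.upper() in ("X", "Y", "M"):
        s = s.upper()
    return f"chr{s}"


def chromosome_rank(name: str) -> int:
    """Sort rank of a (normalised or raw) chromosome name.

    Universe chromosomes rank 0..24 in karyotype order; anything else
    ranks after the whole universe.
    """
    return _CHROM_RANK.get(normalize_chromosome(name), len(CHROMOSOME_UNIVERSE))


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

VALID_SCALES = ("tpm", "log2", "standardized")


@dataclass
class ExpressionMatrix:
    """A samples x genes expression matrix with a value-scale tag.

    Parameters
    ----------
    values
        float array of shape ``(n_samples, n_genes)``.
    sample_ids, gene_ids
        Unique identifiers matching the matrix dimensions.
    scale
        One of ``tpm`` (non-negative), ``log2``, ``standardized``
        (each row zero mean / unit population variance).
    labels
        Optional per-sample class labels, aligned with ``sample_ids``.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    scale: str = "tpm"
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParseError("expression values must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, m = self.values.shape
        if n == 0 or m == 0:
            raise EmptyInputError("empty expression matrix")
        if len(self.sample_ids) != n:
            raise ParseError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.gene_ids) != m:
            raise ParseError(f"{len(self.gene_ids)} gene ids for {m} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if self.scale not in VALID_SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.scale == "tpm" and np.any(self.values < 0):
            raise DomainError("scale='tpm' requires non-negative values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n,):
                raise ParseError("labels must align with sample_ids")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        """Row subset by positional index, carrying labels along."""
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            scale=self.scale,
            labels=None if self.labels is None else self.labels[idx],
        )

    def with_labels(self, label_table: pd.DataFrame) -> "ExpressionMatrix":
        """Attach class labels from a label table (sample_id, class_label)."""
        mapping = dict(zip(label_table["sample_id"].astype(str), label_table["class_label"]))
        missing = [s for s in self.sample_ids if s not in mapping]
        if missing:
            raise LabelError(f"{len(missing)} sample(s) missing from label table: {missing[:5]}")
        labels = np.array([mapping[s] for s in self.sample_ids], dtype=object)
        return dataclasses.replace(self, labels=labels)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise IdentifierCollisionError(
            f"duplicate {kind} identifier(s): " + ", ".join(sorted(set(dups))[:10])
        )


# ---------------------------------------------------------------------------
# Matrix / table I/O
# ---------------------------------------------------------------------------

def _sep_for(path: os.PathLike | str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_expression(
    path: os.PathLike | str,
    orientation: str = "genes_as_rows",
    scale: str = "tpm",
) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix.

    ``orientation='genes_as_rows'`` (default dialect: first column gene
    IDs, header sample IDs) or ``'samples_as_rows'``. The result is
    always samples x genes in memory.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyInputError(f"empty expression matrix in {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise IdentifierCollisionError(f"duplicate row identifier(s) in {path}: {dup}")
    if pd.Index(df.columns).duplicated().any():
        dup = [c for c in df.columns if list(df.columns).count(c) > 1][:5]
        raise IdentifierCollisionError(f"duplicate column identifier(s) in {path}: {dup}")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        where = f"column {col!r}" + (f", row {row[0]!r}" if len(row) else "")
        raise ParseError(f"non-numeric cell in {path} ({where})")
    if orientation == "genes_as_rows":
        df = df.T
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        scale=scale,
    )


def write_expression(
    X: ExpressionMatrix,
    path: os.PathLike | str,
    orientation: str = "genes_as_rows",
) -> None:
    """Write a matrix in the on-disk dialect (lossless round-trip)."""
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    df = X.to_frame()
    if orientation == "genes_as_rows":
        df = df.T
        df.index.name = "gene_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def load_annotation(path: os.PathLike | str) -> pd.DataFrame:
    """Read a BED-like gene annotation table.

    Columns: gene_id, chromosome, start[, end] (end ignored). Chromosome
    names are normalised into the declared universe; starts are 0-based
    and must be non-negative.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=0)
    required = {"gene_id", "chromosome", "start"}
    if not required.issubset(df.columns):
        # headerless BED-like fallback: first three columns
        df = pd.read_csv(path, sep=_sep_for(path), header=None)
        if df.shape[1] < 3:
            raise ParseError(f"annotation {path} needs columns gene_id, chromosome, start")
        df = df.iloc[:, :3]
        df.columns = ["gene_id", "chromosome", "start"]
    df = df[["gene_id", "chromosome", "start"]].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    start = pd.to_numeric(df["start"], errors="coerce")
    if start.isna().any():
        raise ParseError(f"non-numeric start coordinate in {path}")
    if (start < 0).any():
        bad = df.loc[start < 0, "gene_id"].iloc[0]
        raise ParseError(f"negative start coordinate for gene {bad!r} in {path}")
    df["start"] = start.astype(np.int64)
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise IdentifierCollisionError(f"duplicate gene_id {dup!r} in annotation {path}")
    return df.reset_index(drop=True)


def write_annotation(ann: pd.DataFrame, path: os.PathLike | str) -> None:
    ann[["gene_id", "chromosome", "start"]].to_csv(path, sep=_sep_for(path), index=False)


def load_labels(path: os.PathLike | str) -> pd.DataFrame:
    """Read a sample label table (sample_id, class_label[, subtype_label])."""
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if "sample_id" not in df.columns or "class_label" not in df.columns:
        df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
        if df.shape[1] < 2:
            raise ParseError(f"label table {path} needs sample_id and class_label columns")
        cols = ["sample_id", "class_label"] + (["subtype_label"] if df.shape[1] > 2 else [])
        df = df.iloc[:, : len(cols)]
        df.columns = cols
    keep = ["sample_id", "class_label"] + (
        ["subtype_label"] if "subtype_label" in df.columns else []
    )
    df = df[keep].copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise IdentifierCollisionError(f"duplicate sample_id {dup!r} in {path}")
    if df["class_label"].isna().any() or (df["class_label"].astype(str).str.len() == 0).any():
        raise ParseError(f"empty class_label in {path}")
    return df.reset_index(drop=True)


def write_labels(labels: pd.DataFrame, path: os.PathLike | str) -> None:
    labels.to_csv(path, sep=_sep_for(path), index=False)


def file_sha256(path: os.PathLike | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------
# A bundle is a directory:
#   manifest.json   kind, config, hyperparams, class order, preprocessing
#                   contract, feature list — everything human-readable
#   features.tsv    the FeatureSet contract file
#   weights.npz     (cnn) network parameter arrays
#   forest.joblib   (subtype_rf) fitted sklearn forest
#   training_log.csv (cnn) per-epoch train/validation loss

MANIFEST_NAME = "manifest.json"


def save_model_bundle(model, directory: os.PathLike | str) -> dict:
    """Serialise a trained classifier (CNN or subtype RF) to a directory.

    Returns the manifest dict. The bundle is self-describing: reloading
    restores a model whose predictions match the original to 1e-6.
    """
    from . import cnn as _cnn
    from . import subtype as _subtype

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, _cnn.TrainedClassifier):
        manifest = _cnn.save_trained_classifier(model, directory)
    elif isinstance(model, _subtype.SubtypeModel):
        manifest = _subtype.save_subtype_model(model, directory)
    else:
        raise ConfigError(f"cannot bundle object of type {type(model).__name__}")
    with open(directory / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_model_bundle(directory: os.PathLike | str):
    """Restore a model saved with :func:`save_model_bundle`."""
    from . import cnn as _cnn
    from . import subtype as _subtype

    directory = Path(directory)
    mpath = directory / MANIFEST_NAME
    if not mpath.exists():
        raise CorruptBundleError(f"no {MANIFEST_NAME} in {directory}")
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as e:
        raise CorruptBundleError(f"unreadable manifest in {directory}: {e}") from e
    kind = manifest.get("kind")
    if kind == "cnn":
        return _cnn.load_trained_classifier(directory, manifest)
    if kind == "subtype_rf":
        return _subtype.load_subtype_model(directory, manifest)
    raise CorruptBundleError(f"unknown bundle kind {kind!r} in {directory}")
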