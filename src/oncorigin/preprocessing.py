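"""Expression preprocessing: log2 transform and per-sample standardisation.

The classifiers consume a per-sample standardised representation:
log2(TPM + offset), restricted to the feature panel, then each sample
scaled to zero mean and unit population variance across the panel.
Per-sample scaling is what makes trained models transferable across
profiling platforms — any per-sample affine distortion of the log
expression (a*x + b, a > 0) is removed exactly.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING

import numpy as np

from .core import (
    DomainError,
    ExpressionMatrix,
    FlaggedSampleError,
    MissingFeatureError,
    ScaleError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureSet

__all__ = [
    "log2_transform",
    "per_sample_standardize",
    "subset_and_align",
    "apply_preprocessing",
]

DEFAULT_LOG2_OFFSET = 1.0


def log2_transform(X: ExpressionMatrix, offset: float = DEFAULT_LOG2_OFFSET) -> ExpressionMatrix:
    """log2(value + offset) on a TPM-scale matrix.

    The pseudocount ``offset`` must be positive; it is recorded in model
    bundles so prediction reuses the training value.
    """
    if X.scale != "tpm":
        raise ScaleError(f"log2_transform expects scale='tpm', got {X.scale!r}")
    if offset <= 0:
        raise DomainError(f"offset must be > 0, got {offset}")
    if np.any(X.values < 0):
        raise DomainError("negative expression value in TPM matrix")
    return dataclasses.replace(X, values=np.log2(X.values + offset), scale="log2")


def per_sample_standardize(X: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Scale every sample row to zero mean and unit variance.

    Population variance (``ddof=0``) by default; ``ddof=1`` gives the
    sample-variance convention (negligible difference at panel sizes of
    several hundred genes). Rows with zero variance raise
    :class:`FlaggedSampleError` — never silent NaNs.
    """
    if X.scale != "log2":
        raise ScaleError(f"per_sample_standardize expects scale='log2', got {X.scale!r}")
    if X.n_genes < 2:
        raise DomainError("standardisation needs at least 2 genes per sample")
    mean = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=ddof, keepdims=True)
    zero = np.where(sd[:, 0] == 0)[0]
    if len(zero):
        raise FlaggedSampleError([X.sample_ids[i] for i in zero])
    return dataclasses.replace(X, values=(X.values - mean) / sd, scale="standardized")


def subset_and_align(
    X: ExpressionMatrix,
    features: "FeatureSet | list[str]",
    missing_policy: str = "error",
) -> ExpressionMatrix:
    """Reorder columns to exactly the feature-set order.

    Genes absent from ``X`` raise :class:`MissingFeatureError` under
    ``missing_policy='error'`` or become all-zero columns under
    ``'impute_zero'`` (zero is the per-sample mean in standardised
    space, making the imputation neutral). The input's own gene order
    never matters.
    """
    genes = list(getattr(features, "genes", features))
    if len(genes) == 0:
        raise MissingFeatureError([])
    if missing_policy not in ("error", "impute_zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    index = X.gene_index()
    missing = [g for g in genes if g not in index]
    if missing and missing_policy == "error":
        raise MissingFeatureError(missing)
    out = np.zeros((X.n_samples, len(genes)), dtype=np.float64)
    present = [(j, index[g]) for j, g in enumerate(genes) if g in index]
    if present:
        cols_out, cols_in = map(np.array, zip(*present))
        out[:, cols_out] = X.values[:, cols_in]
    return dataclasses.replace(X, values=out, gene_ids=genes)


def apply_preprocessing(
    X: ExpressionMatrix,
    features: "FeatureSet | list[str]",
    offset: float = DEFAULT_LOG2_OFFSET,
    missing_policy: str = "error",
    ddof: int = 0,
) -> ExpressionMatrix:
    """Full inference-time pipeline: log2 → subset to panel → standardise.

    Accepts TPM, log2, or already-standardised input and applies only the
    remaining steps. Standardisation is computed over the *present* panel
    genes; genes imputed under ``'impute_zero'`` are filled with 0 (the
    per-sample mean) afterwards, so a missing gene never distorts the
    scaling of the observed ones.
    """
    if X.scale == "standardized":
        return subset_and_align(X, features, missing_policy=missing_policy)
    if X.scale == "tpm":
        X = log2_transform(X, offset=offset)
    genes = list(getattr(features, "genes", features))
    index = X.gene_index()
    missing = [g for g in genes if g not in index]
    if missing and missing_policy == "error":
        raise MissingFeatureError(missing)
    present = [g for g in genes if g in index]
    if len(present) < 2:
        raise MissingFeatureError(missing)
    sub = subset_and_align(X, present, missing_policy="error")
    std = per_sample_standardize(sub, ddof=ddof)
    if not missing:
        return std
    return subset_and_align(std, genes, missing_policy="impute_zero")
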