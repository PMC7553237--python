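"""Feature-gene selection by class-wise median difference.

For every (gene, class) pair the statistic is

    median_difference = median(in-class log2 expression)
                        - median(out-of-class log2 expression)

with a two-sample significance gate (two-sided Wilcoxon rank-sum by
default; medians rather than means for robustness to extreme values).
Per class, genes passing ``p < alpha`` are ranked by |median_difference|
and the top N taken; the per-class sets are merged, de-duplicated, and
ordered by chromosomal coordinates — the order the 1D convolutions see.

Selection runs on log2 (pre-standardisation) values: per-sample
standardisation would distort cross-sample medians.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CHROMOSOME_UNIVERSE,
    ExpressionMatrix,
    InsufficientClassError,
    NoFeaturesError,
    ScaleError,
    chromosome_rank,
)

__all__ = [
    "FeatureSet",
    "class_median_differences",
    "select_features",
    "select_subtype_features",
]

DEFAULT_ALPHA = 1e-3
TESTS = ("wilcoxon", "welch")


# ---------------------------------------------------------------------------
# FeatureSet
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """An ordered gene panel with its selection provenance.

    ``genes`` is the chromosomally ordered panel; ``per_gene`` has one
    row per gene (gene_id, chromosome, start, source_classes,
    median_difference, p_value) where the statistics belong to the
    strongest source class. This table, serialised as TSV, is the
    contract between training and prediction.
    """

    genes: list[str]
    per_gene: pd.DataFrame
    n_per_class: Optional[int] = None
    alpha: float = DEFAULT_ALPHA
    test: str = "wilcoxon"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("FeatureSet genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    # -- serialisation (TSV contract file) --------------------------------
    def to_tsv(self, path: os.PathLike | str) -> None:
        df = self.per_gene.copy()
        df.attrs = {}
        header = f"#n_per_class={self.n_per_class}\talpha={self.alpha!r}\ttest={self.test}\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: os.PathLike | str) -> "FeatureSet":
        with open(path) as fh:
            first = fh.readline()
            meta: dict[str, str] = {}
            if first.startswith("#"):
                for kv in first[1:].strip().split("\t"):
                    k, _, v = kv.partition("=")
                    meta[k] = v
                df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
        npc = meta.get("n_per_class", "None")
        return cls(
            genes=df["gene_id"].tolist(),
            per_gene=df,
            n_per_class=None if npc == "None" else int(npc),
            alpha=float(meta.get("alpha", DEFAULT_ALPHA)),
            test=meta.get("test", "wilcoxon"),
        )


# ---------------------------------------------------------------------------
# Per-class statistics
# ---------------------------------------------------------------------------

def _two_sample_p(inside: np.ndarray, outside: np.ndarray, test: str) -> np.ndarray:
    """Two-sided p-values per gene column for in-class vs out-of-class."""
    if test == "wilcoxon":
        res = stats.mannwhitneyu(
            inside, outside, axis=0, alternative="two-sided", method="asymptotic"
        )
        return np.asarray(res.pvalue)
    if test == "welch":
        res = stats.ttest_ind(inside, outside, axis=0, equal_var=False)
        return np.asarray(res.pvalue)
    raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")


def class_median_differences(
    X: ExpressionMatrix,
    labels: Optional[np.ndarray] = None,
    test: str = "wilcoxon",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median differences and p-values for every (gene, class) pair.

    Returns ``(median_diff, p_values)`` as genes x classes DataFrames.
    Requires log2-scale input, >= 2 classes, and >= 2 samples per class.
    """
    if X.scale != "log2":
        raise ScaleError(f"selection runs on log2 values, got scale={X.scale!r}")
    y = np.asarray(X.labels if labels is None else labels, dtype=object)
    if y.shape != (X.n_samples,):
        raise InsufficientClassError("labels must align with samples")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise InsufficientClassError("need at least 2 classes")
    md = np.empty((X.n_genes, len(classes)))
    pv = np.empty_like(md)
    for j, c in enumerate(classes):
        mask = y == c
        n_in = int(mask.sum())
        if n_in < 2 or (len(y) - n_in) < 2:
            raise InsufficientClassError(f"class {c!r} has too few samples ({n_in})")
        inside = X.values[mask]
        outside = X.values[~mask]
        md[:, j] = np.median(inside, axis=0) - np.median(outside, axis=0)
        with warnings.catch_warnings():
            # constant genes yield zero-variance warnings; their p is 1/NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            pv[:, j] = _two_sample_p(inside, outside, test)
    pv = np.where(np.isfinite(pv), pv, 1.0)
    md_df = pd.DataFrame(md, index=X.gene_ids, columns=classes)
    pv_df = pd.DataFrame(pv, index=X.gene_ids, columns=classes)
    return md_df, pv_df


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _rank_class(md: pd.Series, pv: pd.Series, alpha: float) -> pd.DataFrame:
    """Genes passing the gate for one class, best first.

    Rank by |median_difference| descending; ties broken by smaller
    p-value, then lexicographic gene_id (determinism).
    """
    passing = pv.index[pv < alpha]
    df = pd.DataFrame(
        {
            "gene_id": passing,
            "median_difference": md.loc[passing].to_numpy(),
            "p_value": pv.loc[passing].to_numpy(),
        }
    )
    df["abs_md"] = df["median_difference"].abs()
    df = df.sort_values(
        ["abs_md", "p_value", "gene_id"], ascending=[False, True, True], kind="mergesort"
    )
    return df.drop(columns="abs_md").reset_index(drop=True)


def _chromosomal_order(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chromosome universe rank, start, gene_id).

    Genes without annotation sort after the universe, lexicographically.
    """
    key = per_gene.assign(
        _rank=per_gene["chromosome"].map(
            lambda c: chromosome_rank(c) if isinstance(c, str) and c else len(CHROMOSOME_UNIVERSE)
        ),
        _start=per_gene["start"].fillna(np.iinfo(np.int64).max),
    )
    key = key.sort_values(["_rank", "_start", "gene_id"], kind="mergesort")
    return key.drop(columns=["_rank", "_start"]).reset_index(drop=True)


def _build_feature_set(
    chosen: dict[str, pd.DataFrame],
    annotation: Optional[pd.DataFrame],
    n_per_class: Optional[int],
    alpha: float,
    test: str,
) -> FeatureSet:
    rows: dict[str, dict] = {}
    for cls in sorted(chosen):
        for _, r in chosen[cls].iterrows():
            g = str(r["gene_id"])
            if g not in rows:
                rows[g] = {
                    "gene_id": g,
                    "source_classes": [cls],
                    "median_difference": r["median_difference"],
                    "p_value": r["p_value"],
                }
            else:
                rows[g]["source_classes"].append(cls)
                if abs(r["median_difference"]) > abs(rows[g]["median_difference"]):
                    rows[g]["median_difference"] = r["median_difference"]
                    rows[g]["p_value"] = r["p_value"]
    if not rows:
        raise NoFeaturesError(f"no gene passed p < {alpha} in any class")
    per_gene = pd.DataFrame(rows.values())
    per_gene["source_classes"] = per_gene["source_classes"].map(",".join)
    if annotation is not None:
        ann = annotation.set_index("gene_id")
        covered = per_gene["gene_id"].isin(ann.index)
        if not covered.all():
            missing = per_gene.loc[~covered, "gene_id"].tolist()
            warnings.warn(
                f"{len(missing)} selected gene(s) lack chromosomal annotation and "
                f"sort last: {missing[:5]}",
                stacklevel=3,
            )
        per_gene["chromosome"] = per_gene["gene_id"].map(ann["chromosome"])
        per_gene["start"] = per_gene["gene_id"].map(ann["start"])
    else:
        per_gene["chromosome"] = None
        per_gene["start"] = np.nan
    per_gene = _chromosomal_order(per_gene)
    per_gene = per_gene[
        ["gene_id", "chromosome", "start", "source_classes", "median_difference", "p_value"]
    ]
    return FeatureSet(
        genes=per_gene["gene_id"].tolist(),
        per_gene=per_gene,
        n_per_class=n_per_class,
        alpha=alpha,
        test=test,
    )


def select_features(
    X: ExpressionMatrix,
    labels: Optional[np.ndarray] = None,
    n_per_class: int = 40,
    alpha: float = DEFAULT_ALPHA,
    annotation: Optional[pd.DataFrame] = None,
    test: str = "wilcoxon",
) -> FeatureSet:
    """Top-N differentially expressed genes per class, merged and ordered.

    Per class: genes with ``p < alpha`` ranked by absolute median
    difference, top ``n_per_class`` taken (default 40; 10 gives a small
    panel). The per-class sets are unioned, de-duplicated, and ordered
    chromosomally. A class contributing nothing triggers a warning; all
    classes empty raises :class:`NoFeaturesError`.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    md, pv = class_median_differences(X, labels, test=test)
    chosen: dict[str, pd.DataFrame] = {}
    for cls in md.columns:
        ranked = _rank_class(md[cls], pv[cls], alpha)
        if ranked.empty:
            warnings.warn(f"class {cls!r}: no gene passed p < {alpha}", stacklevel=2)
        chosen[cls] = ranked.head(n_per_class)
    return _build_feature_set(chosen, annotation, n_per_class, alpha, test)


def select_subtype_features(
    X: ExpressionMatrix,
    subtype_labels: Optional[np.ndarray] = None,
    alpha: float = DEFAULT_ALPHA,
    annotation: Optional[pd.DataFrame] = None,
    test: str = "wilcoxon",
    n_per_subtype: Optional[int] = None,
) -> FeatureSet:
    """Subtype-vs-rest selection within a single cancer type.

    Same statistic and gate as :func:`select_features`, but by default
    *all* genes passing ``p < alpha`` per subtype are pooled (no top-N
    cap unless ``n_per_subtype`` is given).
    """
    md, pv = class_median_differences(X, subtype_labels, test=test)
    chosen: dict[str, pd.DataFrame] = {}
    for sub in md.columns:
        ranked = _rank_class(md[sub], pv[sub], alpha)
        if ranked.empty:
            warnings.warn(f"subtype {sub!r}: no gene passed p < {alpha}", stacklevel=2)
        chosen[sub] = ranked if n_per_subtype is None else ranked.head(n_per_subtype)
    return _build_feature_set(chosen, annotation, n_per_subtype, alpha, test)
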