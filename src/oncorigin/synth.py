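"""Synthetic TPM-like expression cohorts with planted structure.

Generates multi-class cohorts the whole pipeline can be exercised on:
log-normal baseline expression (Gaussian in log2 space), class marker
genes shifted by a configurable log2 effect in their class, optional
within-class subtype (or pan-cancer subtype) markers, class imbalance,
chromosomal gene coordinates, and per-sample rescaling to a fixed
library sum mimicking TPM. Everything is driven by one seed.

This module exists to make the tool testable without consortium data;
it emulates the statistical structure the selection statistic assumes
(class-specific median shifts), not the full complexity of real RNA-seq.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CHROMOSOME_UNIVERSE,
    ConfigError,
    ExpressionMatrix,
)

__all__ = [
    "SubtypeSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_expression",
    "make_benchmark",
    "BENCHMARK_PRESETS",
]


@dataclass(frozen=True)
class SubtypeSpec:
    """Within-class (or pan-cancer) subtype structure.

    ``pan=True`` draws subtype labels from one shared universe across
    classes (pan-cancer groups); otherwise each class gets its own
    subtype label set.
    """

    n_subtypes: int = 4
    markers_per_subtype: int = 10
    effect: float = 2.0
    pan: bool = False


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Effects and noise are in log2 units: a marker's in-class median is
    shifted by ``effect_size`` over baseline, against per-gene Gaussian
    noise of sd ``noise_sd`` — so ``effect_size = 3 * noise_sd`` plants
    a 3-standard-deviation signal.
    """

    n_classes: int = 8
    samples_per_class: Union[int, tuple[int, ...]] = 200
    n_genes: int = 2000
    markers_per_class: int = 10
    effect_size: float = 3.0
    subtypes: Optional[SubtypeSpec] = None
    noise_sd: float = 1.0
    baseline_mean: float = 4.0
    baseline_sd: float = 2.0
    library_size: float = 1_000_000.0
    seed: int = 0

    def class_sizes(self) -> list[int]:
        if isinstance(self.samples_per_class, int):
            return [self.samples_per_class] * self.n_classes
        sizes = list(self.samples_per_class)
        if len(sizes) != self.n_classes:
            raise ConfigError(
                f"{len(sizes)} class sizes for {self.n_classes} classes"
            )
        return sizes

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if any(s < 2 for s in self.class_sizes()):
            raise ConfigError("every class needs at least 2 samples")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.markers_per_class < 0 or self.effect_size < 0:
            raise ConfigError("markers_per_class and effect_size must be >= 0")
        need = self.markers_per_class * self.n_classes
        if self.subtypes is not None:
            sub = self.subtypes
            if sub.n_subtypes < 2:
                raise ConfigError("need at least 2 subtypes")
            groups = 1 if sub.pan else self.n_classes
            need += sub.markers_per_subtype * sub.n_subtypes * groups
        if need > self.n_genes:
            raise ConfigError(
                f"marker genes required ({need}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0 or self.library_size <= 0:
            raise ConfigError("noise_sd and library_size must be positive")


@dataclass
class SyntheticDataset:
    """A generated cohort plus its ground truth."""

    expression: ExpressionMatrix  # scale=tpm, labels attached
    labels: pd.DataFrame  # sample_id, class_label[, subtype_label]
    class_markers: dict[str, list[str]]
    subtype_markers: dict[str, list[str]]
    annotation: pd.DataFrame  # gene_id, chromosome, start
    config: SyntheticConfig


def _gene_annotation(gene_ids: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Scatter genes across the chromosome universe with increasing starts."""
    chroms = rng.choice(len(CHROMOSOME_UNIVERSE), size=len(gene_ids))
    starts = rng.integers(0, 200_000_000, size=len(gene_ids))
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "chromosome": [CHROMOSOME_UNIVERSE[c] for c in chroms],
            "start": starts.astype(np.int64),
        }
    )


def simulate_expression(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a TPM-scale cohort with planted markers.

    Log2 expression = per-gene baseline + planted shifts + N(0, noise_sd);
    values are exponentiated and each sample rescaled to a constant
    library sum. Same config and seed => bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.class_sizes()
    n_samples = sum(sizes)
    classes = [f"C{i + 1:02d}" for i in range(cfg.n_classes)]
    y = np.repeat(classes, sizes)
    sample_ids = [f"sample_{i + 1:05d}" for i in range(n_samples)]
    # Entrez-style numeric identifiers
    gene_ids = [str(100_001 + i) for i in range(cfg.n_genes)]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    log2x = baseline[None, :] + rng.normal(0.0, cfg.noise_sd, size=(n_samples, cfg.n_genes))

    # plant class markers in disjoint gene blocks
    cursor = 0
    class_markers: dict[str, list[str]] = {}
    for c, cls in enumerate(classes):
        block = list(range(cursor, cursor + cfg.markers_per_class))
        cursor += cfg.markers_per_class
        class_markers[cls] = [gene_ids[g] for g in block]
        if block:
            log2x[np.ix_(y == cls, block)] += cfg.effect_size

    # optional subtype structure
    subtype_markers: dict[str, list[str]] = {}
    subtype_col: Optional[np.ndarray] = None
    if cfg.subtypes is not None:
        sub = cfg.subtypes
        subtype_col = np.empty(n_samples, dtype=object)
        if sub.pan:
            sub_names = [f"S{j + 1}" for j in range(sub.n_subtypes)]
            blocks = {}
            for name in sub_names:
                blocks[name] = list(range(cursor, cursor + sub.markers_per_subtype))
                cursor += sub.markers_per_subtype
                subtype_markers[name] = [gene_ids[g] for g in blocks[name]]
            assign = rng.integers(0, sub.n_subtypes, size=n_samples)
            for j, name in enumerate(sub_names):
                mask = assign == j
                subtype_col[mask] = name
                log2x[np.ix_(mask, blocks[name])] += sub.effect
        else:
            for cls in classes:
                mask_cls = y == cls
                idx_cls = np.where(mask_cls)[0]
                assign = rng.integers(0, sub.n_subtypes, size=len(idx_cls))
                for j in range(sub.n_subtypes):
                    name = f"{cls}_s{j + 1}"
                    block = list(range(cursor, cursor + sub.markers_per_subtype))
                    cursor += sub.markers_per_subtype
                    subtype_markers[name] = [gene_ids[g] for g in block]
                    rows = idx_cls[assign == j]
                    subtype_col[rows] = name
                    log2x[np.ix_(rows, block)] += sub.effect

    tpm = np.exp2(log2x)
    tpm *= cfg.library_size / tpm.sum(axis=1, keepdims=True)

    labels = pd.DataFrame({"sample_id": sample_ids, "class_label": y})
    if subtype_col is not None:
        labels["subtype_label"] = subtype_col
    X = ExpressionMatrix(
        values=tpm,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        scale="tpm",
        labels=np.asarray(y, dtype=object),
    )
    return SyntheticDataset(
        expression=X,
        labels=labels,
        class_markers=class_markers,
        subtype_markers=subtype_markers,
        annotation=_gene_annotation(gene_ids, rng),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

def _imbalanced_sizes(n_classes: int = 32, smallest: int = 12, largest: int = 96) -> tuple[int, ...]:
    """Log-spaced class sizes echoing the skew of real pan-cancer cohorts."""
    sizes = np.round(np.logspace(np.log10(smallest), np.log10(largest), n_classes)).astype(int)
    return tuple(int(s) for s in sizes)


#: Named fixture configurations used throughout the test and acceptance
#: suites. ``origin8`` is the desk-scale tissue-of-origin benchmark;
#: ``origin32_imbalanced`` mirrors the many-class, skewed-size regime;
#: ``subtype4`` a 4-subtype single cancer; ``pangroup`` shared subtype
#: labels spanning several cancers.
BENCHMARK_PRESETS: dict[str, SyntheticConfig] = {
    "origin8": SyntheticConfig(
        n_classes=8, samples_per_class=200, n_genes=2000,
        markers_per_class=10, effect_size=3.0, noise_sd=1.0, seed=8801,
    ),
    "origin32_imbalanced": SyntheticConfig(
        n_classes=32, samples_per_class=_imbalanced_sizes(), n_genes=3000,
        markers_per_class=10, effect_size=3.0, noise_sd=1.0, seed=3201,
    ),
    "subtype4": SyntheticConfig(
        n_classes=2, samples_per_class=150, n_genes=1500,
        markers_per_class=10, effect_size=3.0, noise_sd=1.0, seed=4401,
        subtypes=SubtypeSpec(n_subtypes=4, markers_per_subtype=15, effect=2.5, pan=False),
    ),
    "pangroup": SyntheticConfig(
        n_classes=3, samples_per_class=120, n_genes=1500,
        markers_per_class=10, effect_size=3.0, noise_sd=1.0, seed=5501,
        subtypes=SubtypeSpec(n_subtypes=4, markers_per_subtype=15, effect=2.5, pan=True),
    ),
}


def make_benchmark(preset: str, seed: Optional[int] = None) -> SyntheticDataset:
    """Generate a named benchmark fixture (optionally reseeded)."""
    if preset not in BENCHMARK_PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; available: {sorted(BENCHMARK_PRESETS)}"
        )
    cfg = BENCHMARK_PRESETS[preset]
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return simulate_expression(cfg)
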