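# Methods

## Problem and model

`oncorigin` classifies the tissue of origin of a tumour from its bulk
RNA expression profile, and then — within a predicted cancer type —
its molecular subtype. The design targets the clinical setting of
cancer of unknown primary (CUP), where a single archival sample must be
classified on its own, possibly profiled on a different platform than
the training cohort.

The pipeline has four stages, run in this order:

1. **log2 transform.** TPM values become `log2(TPM + c)` with
   pseudocount `c = 1` by default. The pseudocount is stored in every
   model bundle so prediction always reuses the training value.
2. **Feature-gene selection.** For every gene and class, the statistic
   is the difference between the median log2 expression in-class and
   out-of-class, gated by a two-sided Wilcoxon rank-sum test at
   `p < 0.001`. Medians rather than means are used for robustness to
   expression outliers. Per class the genes passing the gate are ranked
   by absolute median difference (ties: smaller p, then gene id) and the
   top N kept (N = 40 default, 10 for a compact panel). The per-class
   sets are merged and de-duplicated, and the union panel is ordered by
   chromosomal coordinates (karyotype order chr1..chr22, X, Y, M;
   0-based starts). Chromosomal order gives the 1-D convolutions a
   stable, biologically meaningful axis.
3. **Per-sample standardisation.** Each sample's panel vector is scaled
   to zero mean and unit population variance. Because the scaling is
   per sample, any per-sample affine distortion of log expression
   (`a·x + b`, `a > 0`) — the dominant form of platform and library-
   depth variation — is removed exactly. This is what lets a trained
   model transfer across profiling platforms, and it is verified as an
   exact invariance property in the tests.
4. **Classification.** A multi-branch 1-D inception network for tissue
   of origin; per-cancer random forests for molecular subtype.

### Order of operations

Selection runs on log2 values *before* standardisation (per-sample
scaling would distort cross-sample medians), and standardisation runs
over the *panel*, not the whole gene set. Standardising over the panel
was chosen because at prediction time only panel genes are guaranteed
present, and it makes 0 exactly the per-sample mean — so a missing gene
imputed as 0 is neutral rather than biased. The variance convention is
population (`÷n`); the sample convention (`÷(n−1)`) is exposed via
`ddof=1` and is negligible at panel sizes of several hundred genes.

### The 1-D inception network

Several parallel convolutional branches read the same ordered gene
vector. Each branch is a stack of 1–3 valid (no padding, stride 1)
1-D convolutions with ReLU, followed by a non-overlapping max-pool
(window 1 = no pooling) and dropout parameterised as keep-probability.
Branch outputs are flattened and concatenated, then passed through two
128-node fully connected ReLU layers and a softmax over the classes.
Kernels of different sizes let a small panel expose patterns at several
genomic scales simultaneously; a kernel-1 branch simply projects the
input forward.

The shipped default has three branches of 1, 2 and 3 conv layers with
kernel sizes {1}, {3,3}, {5,5,5}, 16 filters each, pool windows
{1,2,2} and keep-probabilities {1.0, 0.8, 0.8}. Every element is
overridable from a config file, and the builder always reports the
resulting concatenation width, which under valid convolution is a
deterministic function of the config.

The single-branch 1-D CNN baseline is one convolution of 32 filters of
length 4, one max-pool, no dropout, and four 64-node FC layers; its
tuned schedule is learning rate 0.02 for 200 epochs.

Training minimises categorical cross-entropy with Adam (batch 32,
learning rate 0.001 by default) from Xavier-normal initial weights.
There is no early stopping; the epoch count is configuration. Three
named schedules exist: `combined` (500 epochs — the full-cohort
schedule), `baseline_1dcnn` (200 epochs, lr 0.02), and `desk`
(40 epochs) — the schedule used for the synthetic desk-scale benchmarks,
where the planted signal is strong and training converges within a few
epochs (the loss curves in the logs confirm this).

The network is implemented directly on NumPy — valid 1-D convolution
via strided windows, analytic backprop, fused softmax/cross-entropy,
Adam/SGD — with every stochastic element (initialisation, shuffling,
dropout) keyed to a single seed, so a fixed seed reproduces training
bit-for-bit on the same platform. The analytic gradients are verified
against central finite differences in the test suite, and the
degenerate limit of the architecture (one branch, kernel 1, one filter,
no pooling, no hidden FC layers) is checked against a directly fitted
multinomial logistic regression: in that limit the network is exactly a
linear model of the inputs.

### Subtype random forests

Per cancer type, subtype-vs-rest selection (same statistic and gate,
but *all* genes passing `p < 0.001` pooled, no top-N cap) defines the
panel; a 1000-tree random forest with 31 candidate features per split
classifies by majority vote across trees. Vote tallies are computed
from per-tree hard predictions, so counts sum to the number of trees
and tie-breaks go to the first subtype in sorted order (flagged).
When a panel has fewer than 31 features, the per-split count clips to
the panel size with a warning. Out-of-bag accuracy is recorded when
bootstrapping. Pan-cancer subtype groups use the identical machinery
with a different label table. The forests are scikit-learn ensembles
behind this module's interface.

### Evaluation

Metrics are one-vs-all: precision (PPV), sensitivity (recall),
specificity, F1, plus overall and top-k accuracy (stable ranking; ties
broken by class-order position). The "per-class accuracy" printed by
the report is the recall-form quantity (class-A samples predicted A
over all class-A samples); because that phrase is used for PPV in some
conventions, the table carries both columns explicitly. Metrics with an
empty denominator are NA, never 0, and excluded from summaries.

Cross-validation is stratified 10-fold by default — plain random folds
can leave a small class absent from a training fold and make per-class
metrics undefined; a flag restores unstratified folds. Feature
selection runs inside the fold by default (no leakage); a fixed panel
can be supplied instead, and the choice is logged.

Robustness experiments zero panel genes at prediction time (the
imputation value is the per-sample mean, see above): a named set
(modelling the loss of common immunohistochemistry marker genes), and
random removals of k ∈ {5, 10, 20, 50, 200} genes repeated over seeds
with mean ± sd reported.

## Synthetic data

The generator plants the structure the selection statistic assumes:
per-gene baseline log2 expression drawn once from N(4, 2), i.i.d.
Gaussian noise of sd 1 log2 unit per sample, class markers shifted by a
configurable log2 effect in their class, optional within-class or
pan-cancer subtype markers, class imbalance, random chromosomal
coordinates, and per-sample rescaling to a constant library sum (the
fixed-sum property of TPM). Everything derives from one seed.

Named presets define the benchmark conditions:

| preset | shape | signal |
|---|---|---|
| `origin8` | 8 classes × 200 samples, 2000 genes | 10 markers/class, 3-sd effect |
| `origin32_imbalanced` | 32 classes, log-spaced sizes 12–96, 3000 genes | as above |
| `subtype4` | 2 cancers × ~150 samples, 4 subtypes each, 1500 genes | 15 markers/subtype, 2.5-sd effect |
| `pangroup` | 3 cancers, 4 shared pan-subtype groups | as subtype4 |

What the generator does *not* model: count-level sampling (no negative
binomial), gene–gene correlation beyond the shared library factor,
batch effects, heavy-tailed outliers, or contaminating normal tissue.
Passing benchmarks therefore demonstrates that the machinery is
correct and recovers planted signal at realistic sizes — not that real
cohorts of this size would reach the same accuracy.

## Numerical choices and edge cases

- Zero-variance samples are an error listing the offending sample ids,
  never silently dropped or NaN-propagated — single-sample clinical use
  must fail loudly.
- Non-negative TPM is enforced at construction; the log2 guard rejects
  double application via the scale tag.
- Wilcoxon p-values use the tie-corrected normal approximation with
  continuity correction (appropriate at cohort sizes; the test is
  pluggable, with Welch's t as the alternative, and is recorded in the
  feature-set file). No multiple-testing correction is applied by
  default (the gate is a raw p < 0.001); Benjamini–Hochberg is
  available but off by default.
- Ranking uses |median difference| so strongly down-regulated markers
  qualify; all ties break deterministically (p, then gene id).
- Genes missing from the chromosome annotation sort after the declared
  universe, lexicographically, with a warning — the network needs a
  total order and silent dropping would shrink the panel.
- Max-pooling drops the remainder when the window does not divide the
  length; dropout is inverted (scaled at train time).
- ReLU subgradient at exactly 0 is 0.

## Limitations

- The desk-scale schedule (40 epochs) is tuned to the synthetic
  benchmarks; full-cohort training uses the 500-epoch schedule and has
  not been exercised on consortium-scale data here.
- Identifier harmonisation across annotation namespaces is the
  caller's responsibility; the package matches gene ids as strings.
- Weight-level reproducibility is guaranteed on a fixed platform;
  across BLAS builds, ranking-level agreement is the contract.
- The NumPy engine is single-threaded by design and sized for panels of
  10²–10³ genes, not whole-transcriptome inputs.
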