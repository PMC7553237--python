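"""Feature selection against an independently coded brute-force oracle.

The oracle recomputes median differences by direct enumeration and the
rank-sum p-value from first principles (U statistic by pair counting,
tie-corrected normal approximation with continuity correction), without
touching the implementation under test.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import oncorigin as o
from oncorigin.core import InsufficientClassError, NoFeaturesError


# ---------------------------------------------------------------------------
# Oracle
# ---------------------------------------------------------------------------

def oracle_median_difference(inside, outside):
    inside, outside = sorted(inside), sorted(outside)

    def med(v):
        n = len(v)
        return v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])

    return med(inside) - med(outside)


def oracle_ranksum_p(x, y):
    """Two-sided Mann-Whitney p by pair counting + tie-corrected normal
    approximation with continuity correction."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    u1 = 0.0
    for a in x:
        for b in y:
            u1 += 1.0 if a > b else (0.5 if a == b else 0.0)
    u = max(u1, n1 * n2 - u1)
    mu = n1 * n2 / 2.0
    pooled = sorted(x + y)
    n = n1 + n2
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    z = (u - mu - 0.5) / np.sqrt(sigma2)
    return min(1.0, 2.0 * norm.sf(z))


def oracle_select(values, y, n_per_class, alpha):
    """Per class: gate at alpha, rank by |median diff| (ties: p, gene idx),
    take top N; union."""
    classes = sorted(set(y))
    union = set()
    for c in classes:
        rows = []
        for g in range(values.shape[1]):
            inside = values[np.array(y) == c, g]
            outside = values[np.array(y) != c, g]
            md = oracle_median_difference(list(inside), list(outside))
            p = oracle_ranksum_p(list(inside), list(outside))
            if p < alpha:
                rows.append((-abs(md), p, g))
        rows.sort()
        union |= {g for _, _, g in rows[:n_per_class]}
    return union


def make_log2(values, y=None):
    values = np.asarray(values, dtype=float)
    return o.ExpressionMatrix(
        values,
        [f"s{i}" for i in range(values.shape[0])],
        [f"g{j:02d}" for j in range(values.shape[1])],
        scale="log2",
        labels=None if y is None else np.asarray(y, dtype=object),
    )


# ---------------------------------------------------------------------------
# class_median_differences
# ---------------------------------------------------------------------------

class TestClassMedianDifferences:
    def test_identical_distribution_gives_zero_difference(self):
        v = np.tile(np.arange(3.0)[None, :], (6, 1))  # each gene constant
        X = make_log2(v, ["A", "A", "A", "B", "B", "B"])
        md, _ = o.class_median_differences(X)
        np.testing.assert_array_equal(md.to_numpy(), 0.0)

    def test_small_class_rejected(self):
        X = make_log2(np.ones((3, 2)), ["A", "B", "B"])
        with pytest.raises(InsufficientClassError):
            o.class_median_differences(X)

    def test_planted_shift_recovered_at_n50(self):
        rng = np.random.default_rng(21)
        n = 50
        base = rng.normal(4, 1, size=(2 * n, 20))
        base[:n, 0] += 5.0  # class A marker, +5 in log2 space
        X = make_log2(base, ["A"] * n + ["B"] * n)
        md, pv = o.class_median_differences(X)
        # sampling noise on a median difference at n=50 is well under 1
        assert abs(md.loc["g00", "A"] - 5.0) < 0.75
        assert pv.loc["g00", "A"] < 1e-10

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_toy_matrices(self, seed):
        """Seeded sweep over matrices <= 10 genes x 12 samples, including
        heavy ties from rounding."""
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(2, 11))
        n_per = int(rng.integers(2, 7))
        v = np.round(rng.normal(0, 2, size=(2 * n_per, n_genes)), 1)
        y = ["A"] * n_per + ["B"] * n_per
        X = make_log2(v, y)
        md, pv = o.class_median_differences(X)
        for g in range(n_genes):
            inside = list(v[:n_per, g])
            outside = list(v[n_per:, g])
            assert md.iloc[g]["A"] == oracle_median_difference(inside, outside)
            expected_p = oracle_ranksum_p(inside, outside)
            assert pv.iloc[g]["A"] == pytest.approx(expected_p, abs=1e-9)


# ---------------------------------------------------------------------------
# select_features
# ---------------------------------------------------------------------------

class TestSelectFeatures:
    def test_label_permutation_of_identical_samples_yields_nothing(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(12, 8))
        y = list("AB" * 6)  # labels carry no signal
        X = make_log2(v, y)
        with pytest.raises(NoFeaturesError):
            o.select_features(X, n_per_class=5)

    def test_planted_markers_recovered_exactly(self, tiny_ds, tiny_log2):
        fs = o.select_features(tiny_log2, n_per_class=8, annotation=tiny_ds.annotation)
        planted = {g for genes in tiny_ds.class_markers.values() for g in genes}
        assert set(fs.genes) == planted

    def test_union_bound(self, tiny_log2, tiny_ds):
        fs = o.select_features(tiny_log2, n_per_class=12, annotation=tiny_ds.annotation)
        assert len(fs) <= 12 * 4

    def test_selection_matches_oracle_end_to_end(self):
        rng = np.random.default_rng(99)
        v = np.round(rng.normal(0, 2, size=(12, 10)), 1)
        v[:6, :3] += 4.0
        y = ["A"] * 6 + ["B"] * 6
        X = make_log2(v, y)
        expected = oracle_select(v, y, n_per_class=2, alpha=0.01)
        fs = o.select_features(X, n_per_class=2, alpha=0.01)
        assert {int(g[1:]) for g in fs.genes} == expected

    def test_monotone_in_n_per_class(self, tiny_log2, tiny_ds):
        small = o.select_features(tiny_log2, n_per_class=4, annotation=tiny_ds.annotation)
        large = o.select_features(tiny_log2, n_per_class=8, annotation=tiny_ds.annotation)
        assert set(small.genes) <= set(large.genes)

    def test_invariant_to_sample_and_gene_order(self, tiny_log2, tiny_ds):
        rng = np.random.default_rng(7)
        ref = o.select_features(tiny_log2, n_per_class=6, annotation=tiny_ds.annotation)
        sp = rng.permutation(tiny_log2.n_samples)
        gp = rng.permutation(tiny_log2.n_genes)
        X2 = o.ExpressionMatrix(
            tiny_log2.values[np.ix_(sp, gp)],
            [tiny_log2.sample_ids[i] for i in sp],
            [tiny_log2.gene_ids[j] for j in gp],
            scale="log2",
            labels=tiny_log2.labels[sp],
        )
        out = o.select_features(X2, n_per_class=6, annotation=tiny_ds.annotation)
        assert out.genes == ref.genes

    def test_output_is_chromosomally_ordered(self, tiny_features):
        from oncorigin.core import chromosome_rank

        keys = [
            (chromosome_rank(c), s)
            for c, s in zip(tiny_features.per_gene["chromosome"],
                            tiny_features.per_gene["start"])
        ]
        assert keys == sorted(keys)

    def test_unannotated_genes_sort_last_with_warning(self, tiny_log2, tiny_ds):
        ann = tiny_ds.annotation[tiny_ds.annotation["gene_id"] != "100001"]
        with pytest.warns(UserWarning, match="annotation"):
            fs = o.select_features(tiny_log2, n_per_class=8, annotation=ann)
        assert fs.genes[-1] == "100001"  # a class-C01 marker, now unannotated

    def test_tsv_round_trip(self, tiny_features, tmp_path):
        p = tmp_path / "features.tsv"
        tiny_features.to_tsv(p)
        back = o.FeatureSet.from_tsv(p)
        assert back.genes == tiny_features.genes
        assert back.alpha == tiny_features.alpha
        assert back.n_per_class == tiny_features.n_per_class
        np.testing.assert_allclose(
            back.per_gene["median_difference"],
            tiny_features.per_gene["median_difference"],
        )


class TestSubtypeFeatures:
    def test_pooled_set_is_union_of_per_subtype_sets(self, subtype_ds):
        X, sub, _ = subtype_ds
        Xl = o.log2_transform(X)
        fs = o.select_subtype_features(Xl, sub)
        md, pv = o.class_median_differences(Xl, sub)
        union = set()
        for s in md.columns:
            union |= set(pv.index[pv[s] < fs.alpha])
        assert set(fs.genes) == union

    def test_planted_subtype_markers_recovered(self, subtype_ds):
        X, sub, ds = subtype_ds
        fs = o.select_subtype_features(o.log2_transform(X), sub)
        planted = {g for name, genes in ds.subtype_markers.items()
                   if name.startswith("C01") for g in genes}
        assert planted <= set(fs.genes)

    def test_identical_subtypes_give_no_features(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=(20, 10))
        sub = ["s1", "s2"] * 10
        X = make_log2(v, sub)
        with pytest.raises(NoFeaturesError):
            o.select_subtype_features(X)
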