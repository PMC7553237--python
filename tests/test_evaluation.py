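"""Metric formulas against a brute-force oracle, CV schedules, ablations."""

import itertools

import numpy as np
import pandas as pd
import pytest

import oncorigin as o
from oncorigin.core import FoldError
from oncorigin.evaluation import confusion_from_predictions


# ---------------------------------------------------------------------------
# Independent one-vs-all oracle
# ---------------------------------------------------------------------------

def oracle_metrics(C):
    """Plain-python one-vs-all metrics from an integer matrix (true x pred)."""
    C = [list(map(int, row)) for row in C]
    k = len(C)
    total = sum(map(sum, C))
    out = {"overall": sum(C[i][i] for i in range(k)) / total, "per_class": []}
    for i in range(k):
        tp = C[i][i]
        fn = sum(C[i]) - tp
        fp = sum(C[j][i] for j in range(k)) - tp
        tn = total - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp else None
        rec = tp / (tp + fn) if tp + fn else None
        spec = tn / (tn + fp) if tn + fp else None
        if prec is None or rec is None or (prec + rec) == 0:
            f1 = None
        else:
            f1 = 2 * prec * rec / (prec + rec)
        out["per_class"].append((prec, rec, spec, f1))
    return out


def frame(C, labels=None):
    k = len(C)
    labels = labels or [f"c{i}" for i in range(k)]
    return pd.DataFrame(np.asarray(C, dtype=np.int64), index=labels, columns=labels)


class TestComputeMetrics:
    def test_worked_three_class_example(self):
        rep = o.compute_metrics(frame([[5, 0, 0], [1, 4, 0], [0, 0, 5]]))
        assert rep.overall_accuracy == pytest.approx(14 / 15)
        assert rep.per_class.loc["c1", "sensitivity"] == pytest.approx(0.8)
        assert rep.per_class.loc["c0", "precision"] == pytest.approx(5 / 6)

    def test_perfect_diagonal_gives_all_ones(self):
        rep = o.compute_metrics(frame([[3, 0], [0, 7]]))
        assert rep.overall_accuracy == 1.0
        cols = ["per_class_accuracy", "precision", "sensitivity", "specificity", "f1"]
        assert (rep.per_class[cols] == 1.0).all().all()

    def test_exhaustive_2x2_sweep_matches_oracle(self):
        """Every 2x2 integer confusion table with total <= 12."""
        checked = 0
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if not 0 < a + b + c + d <= 12:
                continue
            rep = o.compute_metrics(frame([[a, b], [c, d]]))
            want = oracle_metrics([[a, b], [c, d]])
            assert rep.overall_accuracy == pytest.approx(want["overall"])
            for i, cls in enumerate(rep.confusion.index):
                prec, rec, spec, f1 = want["per_class"][i]
                row = rep.per_class.loc[cls]
                for got, exp in [(row["precision"], prec), (row["sensitivity"], rec),
                                 (row["specificity"], spec), (row["f1"], f1)]:
                    if exp is None:
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(exp)
            checked += 1
        assert checked > 1000

    def test_undefined_precision_is_na_not_zero(self):
        rep = o.compute_metrics(frame([[0, 2], [0, 3]]))
        assert np.isnan(rep.per_class.loc["c0", "precision"])
        assert rep.per_class.loc["c0", "sensitivity"] == 0.0

    def test_recall_form_accuracy_and_ppv_both_exposed(self):
        rep = o.compute_metrics(frame([[3, 1], [2, 4]]))
        assert (rep.per_class["per_class_accuracy"]
                == rep.per_class["sensitivity"]).all()
        assert (rep.per_class["ppv"] == rep.per_class["precision"]).all()

    def test_serialised_confusion_uses_predicted_by_true_convention(self, tmp_path):
        rep = o.compute_metrics(frame([[5, 0], [2, 3]], labels=["A", "B"]))
        p = tmp_path / "conf.tsv"
        rep.confusion_to_tsv(p)
        back = pd.read_csv(p, sep="\t", index_col=0)
        # cell (j, i): class i samples predicted as j -> B-true,A-pred = 2
        assert back.loc["A", "B"] == 2


class TestTopK:
    def test_monotone_and_saturating(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(6), size=40)
        order = [f"c{i}" for i in range(6)]
        true = [order[i] for i in rng.integers(0, 6, 40)]
        accs = [o.topk_accuracy(probs, true, order, k) for k in range(1, 7)]
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0


class TestFolds:
    def test_folds_partition_samples(self):
        y = np.array(["a"] * 25 + ["b"] * 15, dtype=object)
        folds = o.make_folds(y, o.CVSchedule(k=5, seed=3))
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(40))

    def test_stratified_keeps_classes_in_every_fold(self):
        y = np.array(["a"] * 30 + ["b"] * 10, dtype=object)
        for fold in o.make_folds(y, o.CVSchedule(k=5, seed=0)):
            assert set(y[fold]) == {"a", "b"}

    def test_class_smaller_than_k_gives_guidance(self):
        y = np.array(["a"] * 30 + ["b"] * 3, dtype=object)
        with pytest.raises(FoldError, match="stratified=False"):
            o.make_folds(y, o.CVSchedule(k=10))

    def test_unstratified_allows_small_classes(self):
        y = np.array(["a"] * 30 + ["b"] * 3, dtype=object)
        folds = o.make_folds(y, o.CVSchedule(k=10, stratified=False))
        assert sum(len(f) for f in folds) == 33


class _OraclePipeline:
    """Memorises the label of every sample id — a perfect predictor."""

    def fit(self, X, y):
        self.memory = dict(zip(X.sample_ids, y))
        self.order = sorted(set(y))
        return self

    def predict_proba(self, X):
        probs = np.zeros((X.n_samples, len(self.order)))
        for i, s in enumerate(X.sample_ids):
            probs[i, self.order.index(self.memory[s])] = 1.0
        return probs, self.order


class _MajorityPipeline:
    def fit(self, X, y):
        vals, counts = np.unique(np.asarray(y, dtype=str), return_counts=True)
        self.order = sorted(vals)
        self.major = vals[counts.argmax()]
        return self

    def predict_proba(self, X):
        probs = np.zeros((X.n_samples, len(self.order)))
        probs[:, self.order.index(self.major)] = 1.0
        return probs, self.order


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def labelled_matrix(self):
        rng = np.random.default_rng(44)
        y = np.array(["a"] * 30 + ["b"] * 18 + ["c"] * 12, dtype=object)
        return o.ExpressionMatrix(
            rng.gamma(2, 5, size=(60, 20)), [f"s{i}" for i in range(60)],
            [f"g{j}" for j in range(20)], scale="tpm", labels=y,
        )

    def test_oracle_pipeline_scores_one(self, labelled_matrix):
        # the oracle sees test labels via sample identity: accuracy 1 by design
        full = dict(zip(labelled_matrix.sample_ids, labelled_matrix.labels))

        class Oracle(_OraclePipeline):
            def fit(self, X, y):
                self.memory = full
                self.order = sorted(set(full.values()))
                return self

        rep, folds = o.cross_validate(labelled_matrix, pipeline_factory=Oracle,
                                      schedule=o.CVSchedule(k=5, seed=1))
        assert rep.overall_accuracy == 1.0
        assert (folds["accuracy"] == 1.0).all()

    def test_majority_predictor_scores_majority_fraction(self, labelled_matrix):
        rep, _ = o.cross_validate(labelled_matrix, pipeline_factory=_MajorityPipeline,
                                  schedule=o.CVSchedule(k=5, seed=1))
        assert rep.overall_accuracy == pytest.approx(30 / 60)

    def test_pooled_accuracy_is_sample_weighted_fold_mean(self, labelled_matrix):
        rep, folds = o.cross_validate(labelled_matrix, pipeline_factory=_MajorityPipeline,
                                      schedule=o.CVSchedule(k=4, seed=2))
        weighted = (folds["accuracy"] * folds["n_test"]).sum() / folds["n_test"].sum()
        assert rep.overall_accuracy == pytest.approx(weighted)


class TestAblation:
    def test_empty_gene_list_is_identity(self, trained_toy, tiny_ds):
        out = o.ablation_remove_named(trained_toy, tiny_ds.expression, gene_list=[])
        assert out["delta_overall_accuracy"] == 0.0
        assert out["n_genes_removed"] == 0

    def test_removing_entire_panel_collapses_predictions(self, trained_toy, tiny_ds):
        res = o.predict(trained_toy, tiny_ds.expression,
                        zero_genes=list(trained_toy.feature_set.genes))
        p = res.probabilities.to_numpy()
        # every sample sees the all-zeros input: identical output rows
        np.testing.assert_allclose(p, np.broadcast_to(p[0], p.shape), atol=1e-12)

    def test_random_sweep_seeded_and_k0_is_baseline(self, trained_toy, tiny_ds):
        base = o.ablation_remove_named(trained_toy, tiny_ds.expression, gene_list=[])
        sweep1 = o.ablation_remove_random(trained_toy, tiny_ds.expression,
                                          k_values=(0, 2, 5), n_repeats=3, seed=7)
        sweep2 = o.ablation_remove_random(trained_toy, tiny_ds.expression,
                                          k_values=(0, 2, 5), n_repeats=3, seed=7)
        pd.testing.assert_frame_equal(sweep1, sweep2)
        k0 = sweep1[sweep1["k"] == 0].iloc[0]
        assert k0["mean_accuracy"] == base["baseline"].overall_accuracy

    def test_k_exceeding_panel_rejected(self, trained_toy, tiny_ds):
        from oncorigin.core import ConfigError

        with pytest.raises(ConfigError):
            o.ablation_remove_random(trained_toy, tiny_ds.expression,
                                     k_values=(10**6,), n_repeats=1)
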