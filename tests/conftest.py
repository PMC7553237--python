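"""Shared fixtures: small synthetic cohorts and a trained toy classifier."""

import dataclasses

import numpy as np
import pytest

import oncorigin as o


@pytest.fixture(scope="session")
def tiny_ds():
    """4 classes x 30 samples, 300 genes, strong planted markers."""
    cfg = o.SyntheticConfig(
        n_classes=4, samples_per_class=30, n_genes=300,
        markers_per_class=8, effect_size=3.0, noise_sd=1.0, seed=101,
    )
    return o.simulate_expression(cfg)


@pytest.fixture(scope="session")
def tiny_log2(tiny_ds):
    return o.log2_transform(tiny_ds.expression)


@pytest.fixture(scope="session")
def tiny_features(tiny_ds, tiny_log2):
    return o.select_features(tiny_log2, n_per_class=8, annotation=tiny_ds.annotation)


@pytest.fixture(scope="session")
def trained_toy(tiny_ds, tiny_log2, tiny_features):
    """A converged small inception classifier on the tiny cohort."""
    Xs = o.apply_preprocessing(tiny_log2, tiny_features)
    cfg = o.default_inception_config(len(tiny_features), 4)
    net, _ = o.build_inception(cfg, seed=7)
    hp = dataclasses.replace(o.TRAIN_PRESETS["desk"], epochs=15, seed=7)
    return o.train(net, Xs, tiny_ds.expression.labels, hp=hp,
                   feature_set=tiny_features)


@pytest.fixture(scope="session")
def subtype_ds():
    """The 4-subtype single-cancer benchmark, restricted to one cancer."""
    ds = o.make_benchmark("subtype4")
    mask = np.where(ds.expression.labels == "C01")[0]
    X = ds.expression.subset_samples(mask)
    sub = ds.labels.set_index("sample_id").loc[X.sample_ids, "subtype_label"].to_numpy(object)
    return X, sub, ds
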