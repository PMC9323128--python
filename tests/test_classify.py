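"""Backbones, dataset splitting, head training, prediction, persistence."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from manoclass import classify as cl, preprocess as pp
from manoclass.types import IRPClass


# --- split_dataset ----------------------------------------------------------


def test_split_is_exact_in_rounding_free_case():
    items = list(range(100))
    tr, te, va = cl.split_dataset(items, (0.7, 0.15, 0.15), seed=0)
    assert (len(tr), len(te), len(va)) == (70, 15, 15)


def test_split_is_a_partition_and_stratified():
    rng = np.random.default_rng(1)
    labels = ["a"] * 40 + ["b"] * 30 + ["c"] * 30
    items = list(range(100))
    tr, te, va = cl.split_dataset(items, (0.6, 0.2, 0.2), seed=3, labels=labels)
    assert sorted(tr + te + va) == items
    assert not (set(tr) & set(te) or set(tr) & set(va) or set(te) & set(va))
    for part in (te, va):
        counts = {lab: sum(1 for i in part if labels[i] == lab) for lab in "abc"}
        assert counts == {"a": 8, "b": 6, "c": 6}


def test_split_deterministic_and_class_size_guard():
    items = list(range(30))
    labels = ["x"] * 15 + ["y"] * 15
    assert cl.split_dataset(items, seed=9, labels=labels) == cl.split_dataset(
        items, seed=9, labels=labels
    )
    with pytest.raises(ValueError):
        cl.split_dataset([1, 2, 3], labels=["x", "x", "y"])  # y has 1 < 3 splits


# --- backbones and feature extraction ---------------------------------------


def test_backbone_features_are_deterministic(tiny_backbone):
    rng = np.random.default_rng(0)
    tensor = pp.NormalizedTensor(
        rng.uniform(-1, 1, size=(299, 299, 3)).astype(np.float32),
        pp.ClassifierTarget.IRP,
    )
    f1 = cl.extract_features(tensor, tiny_backbone)
    f2 = cl.extract_features(tensor, tiny_backbone)
    assert np.array_equal(f1, f2)
    assert f1.shape == (tiny_backbone.feature_dim,)


def test_same_seed_rebuilds_identical_backbone():
    rng = np.random.default_rng(5)
    x = rng.uniform(-1, 1, size=(224, 224, 3)).astype(np.float32)
    a = cl.get_backbone(cl.BackboneSpec("tiny_test_cnn", seed=3)).extract(x)
    b = cl.get_backbone(cl.BackboneSpec("tiny_test_cnn", seed=3)).extract(x)
    assert np.array_equal(a, b)


def test_backbone_input_contracts():
    inc = cl.get_backbone(cl.BackboneSpec("inception_v3", seed=0))
    with pytest.raises(ValueError):
        inc.extract(np.zeros((224, 224, 3), np.float32))
    with pytest.raises(cl.PretrainedWeightsUnavailableError):
        cl.get_backbone(cl.BackboneSpec("densenet201", weights="imagenet"))
    with pytest.raises(ValueError):
        cl.BackboneSpec("resnet50")


# --- training ---------------------------------------------------------------


def _separable_data(seed=0, n=120, d=16):
    rng = np.random.default_rng(seed)
    X = np.r_[rng.normal(0, 1, (n // 2, d)), rng.normal(4, 1, (n // 2, d))]
    y = [IRPClass.NORMAL] * (n // 2) + [IRPClass.HIGH] * (n // 2)
    return X, y


def test_separable_features_train_to_high_accuracy():
    """Logistic regression reaches 1.0 on this data; the head must be close."""
    X, y = _separable_data()
    oracle = LogisticRegression().fit(X, [lab.value for lab in y])
    assert oracle.score(X, [lab.value for lab in y]) == 1.0
    clf = cl.train_classifier(
        X, y, cl.HeadConfig(2), cl.TrainConfig(epochs=20, seed=1),
        class_order=(IRPClass.NORMAL, IRPClass.HIGH),
    )
    assert clf.history["train_acc"][-1] >= 0.95
    assert clf.validation_report.accuracy >= 0.95


def test_training_without_stochastic_layers_is_reproducible():
    X, y = _separable_data(seed=2)
    kwargs = dict(
        head=cl.HeadConfig(2, dropout_rate=0.0),
        train_cfg=cl.TrainConfig(epochs=5, seed=7, shuffle_each_epoch=True),
        class_order=(IRPClass.NORMAL, IRPClass.HIGH),
    )
    a = cl.train_classifier(X, y, **kwargs)
    b = cl.train_classifier(X, y, **kwargs)
    assert np.array_equal(a.weight, b.weight) and np.array_equal(a.bias, b.bias)


def test_permuted_labels_give_chance_level_validation_accuracy():
    """Null-label experiment: accuracy within binomial 99% bounds of 0.5."""
    rng = np.random.default_rng(11)
    X = rng.normal(0, 1, (200, 16))
    y = [IRPClass.NORMAL, IRPClass.HIGH] * 100
    perm = rng.permutation(200)
    y = [y[i] for i in perm]
    clf = cl.train_classifier(
        X, y, cl.HeadConfig(2), cl.TrainConfig(epochs=15, seed=0),
        class_order=(IRPClass.NORMAL, IRPClass.HIGH),
    )
    n_val = clf.validation_report.total
    # 99% binomial bounds around chance for n_val trials
    half_width = 2.576 * np.sqrt(0.25 / n_val)
    assert abs(clf.validation_report.accuracy - 0.5) <= half_width + 1e-9


def test_single_class_dataset_rejected():
    X = np.zeros((10, 4))
    with pytest.raises(ValueError):
        cl.train_classifier(
            X, [IRPClass.HIGH] * 10, cl.HeadConfig(2), cl.TrainConfig(epochs=1)
        )


def test_history_and_validation_discipline():
    """Per-epoch train/test curves exist; validation is computed once, on the
    finalized classifier only."""
    X, y = _separable_data(seed=5)
    cfg = cl.TrainConfig(epochs=8, seed=2)
    clf = cl.train_classifier(
        X, y, cl.HeadConfig(2), cfg, class_order=(IRPClass.NORMAL, IRPClass.HIGH)
    )
    assert len(clf.history["train_loss"]) == 8
    assert len(clf.history["test_acc"]) == 8
    assert clf.validation_report is not None and clf.validation_report.total > 0


# --- prediction -------------------------------------------------------------


def test_probabilities_sum_to_one_and_argmax_consistency():
    X, y = _separable_data(seed=8)
    clf = cl.train_classifier(
        X, y, cl.HeadConfig(2), cl.TrainConfig(epochs=10, seed=3),
        class_order=(IRPClass.NORMAL, IRPClass.HIGH),
    )
    rng = np.random.default_rng(0)
    for _ in range(100):
        label, probs = clf.predict(rng.normal(0, 2, 16))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert (probs >= 0).all()
        assert label == clf.class_order[int(np.argmax(probs))]


def test_predict_checks_feature_width():
    X, y = _separable_data()
    clf = cl.train_classifier(
        X, y, cl.HeadConfig(2), cl.TrainConfig(epochs=2, seed=0),
        class_order=(IRPClass.NORMAL, IRPClass.HIGH),
    )
    with pytest.raises(ValueError):
        clf.predict_proba(np.zeros((1, 7)))


def test_save_load_round_trip_preserves_predictions(tmp_path):
    X, y = _separable_data(seed=13)
    clf = cl.train_classifier(
        X, y, cl.HeadConfig(2), cl.TrainConfig(epochs=10, seed=4),
        class_order=(IRPClass.NORMAL, IRPClass.HIGH),
    )
    clf.save(tmp_path / "model")
    reloaded = cl.TrainedClassifier.load(tmp_path / "model")
    assert reloaded.class_order == clf.class_order
    rng = np.random.default_rng(1)
    probes = rng.normal(0, 2, size=(50, 16))
    assert np.array_equal(clf.predict_proba(probes), reloaded.predict_proba(probes))
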