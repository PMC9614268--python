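"""Dual-channel construction, input adapters, CNN training contracts, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcdiff import (
    ChannelLayout,
    DualChannelFeature,
    TrainConfig,
    adapt_input,
    build_dual_channel,
    evaluate,
    stratified_split,
    train_classifier,
)
from fcdiff.tlnn import (
    channel_norm_stats,
    metrics_from_confusion,
    normalize_channels,
    resize_bilinear,
)


def _blob_features(rng, n_per_class=20, side=2, sep=1.0):
    feats = []
    for i in range(2 * n_per_class):
        lab = "p" if i < n_per_class else "c"
        mu = sep if lab == "p" else -sep
        feats.append(
            DualChannelFeature(f"s{i}", rng.normal(mu, 0.5, size=(side, side, 2)), lab)
        )
    return feats


class TestBuildDualChannel:
    def test_layout_mechanics(self):
        lay = ChannelLayout(2, [0, 1, 2, 3])
        feats = build_dual_channel(
            {"a": np.array([1.0, 2, 3, 4])},
            {"a": np.array([5.0, 6, 7, 8])},
            (lay, lay),
            {"a": "p"},
        )
        np.testing.assert_array_equal(feats[0].tensor[..., 0], [[1, 2], [3, 4]])
        np.testing.assert_array_equal(feats[0].tensor[..., 1], [[5, 6], [7, 8]])

    def test_missing_subject_rejected(self):
        lay = ChannelLayout(1, [0])
        with pytest.raises(KeyError):
            build_dual_channel({"a": np.array([1.0])}, {}, (lay, lay), {"a": "p"})

    def test_training_normalization_stats(self, rng):
        feats = _blob_features(rng, n_per_class=50, side=4)
        stats = channel_norm_stats(feats)
        normed = normalize_channels(feats, stats)
        stack = np.stack([f.tensor for f in normed])
        np.testing.assert_allclose(stack.mean(axis=(0, 1, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(stack.std(axis=(0, 1, 2)), 1.0, atol=1e-10)


class TestAdaptInput:
    def test_tiny_is_identity_up_to_axis_order(self, rng):
        t = rng.normal(size=(5, 5, 2))
        out = adapt_input(t, "tiny")
        np.testing.assert_array_equal(out, np.moveaxis(t, -1, 0))

    @pytest.mark.parametrize("backbone", ["vgg16", "resnet50"])
    def test_constant_channels_stay_constant(self, backbone):
        t = np.zeros((6, 6, 2))
        t[..., 0] = 3.5
        t[..., 1] = -1.25
        out = adapt_input(t, backbone)
        assert out.shape == (3, 32, 32)
        np.testing.assert_allclose(out[0], 3.5, atol=1e-12)
        np.testing.assert_allclose(out[1], -1.25, atol=1e-12)
        np.testing.assert_allclose(out[2], (3.5 - 1.25) / 2, atol=1e-12)

    def test_bilinear_round_trip_on_ramp(self):
        h, w = 22, 22
        ramp = np.add.outer(np.linspace(0, 1, h), np.linspace(0, 2, w))
        up = resize_bilinear(ramp, 32, 32)
        back = resize_bilinear(up, h, w)
        assert np.abs(back - ramp).max() < 0.05

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            adapt_input(np.zeros((2, 2, 2)), "alexnet")


class TestTraining:
    def test_separable_blobs_learned(self, rng):
        feats = _blob_features(rng)
        cfg = TrainConfig(backbone="tiny", fcl_neurons=64, epochs=30, seed=1)
        model, hist = train_classifier(feats, cfg, positive_label="p")
        assert hist.accuracy.iloc[-1] >= 0.95
        assert list(hist.columns) == ["epoch", "loss", "accuracy"]

    def test_freeze_leaves_backbone_untouched(self, rng):
        feats = _blob_features(rng)
        cfg = TrainConfig(backbone="tiny", strategy="freeze", fcl_neurons=32, epochs=5, seed=2)
        rng_init = np.random.default_rng(cfg.seed)
        from fcdiff.tlnn import Classifier

        ref = Classifier(cfg, in_channels=2, rng=rng_init)
        before = [p.copy() for p in ref.backbone_params()]
        model, _ = train_classifier(feats, cfg, positive_label="p")
        for b, a in zip(before, model.backbone_params()):
            np.testing.assert_array_equal(b, a)

    def test_fine_tune_changes_backbone(self, rng):
        feats = _blob_features(rng)
        cfg = TrainConfig(backbone="tiny", strategy="fine_tune", fcl_neurons=32, epochs=3, seed=2)
        from fcdiff.tlnn import Classifier

        ref = Classifier(cfg, in_channels=2, rng=np.random.default_rng(cfg.seed))
        before = [p.copy() for p in ref.backbone_params()]
        model, _ = train_classifier(feats, cfg, positive_label="p")
        assert any(not np.array_equal(b, a) for b, a in zip(before, model.backbone_params()))

    def test_training_is_deterministic(self, rng):
        feats = _blob_features(rng, n_per_class=10)
        cfg = TrainConfig(backbone="tiny", fcl_neurons=16, epochs=5, seed=3)
        _, h1 = train_classifier(feats, cfg, positive_label="p")
        _, h2 = train_classifier(feats, cfg, positive_label="p")
        np.testing.assert_array_equal(h1.loss.to_numpy(), h2.loss.to_numpy())

    @pytest.mark.parametrize("backbone", ["vgg16", "resnet50"])
    def test_larger_backbones_run(self, rng, backbone):
        feats = _blob_features(rng, n_per_class=4, side=6)
        cfg = TrainConfig(backbone=backbone, fcl_neurons=0, epochs=1, batch_size=4, seed=0)
        model, hist = train_classifier(feats, cfg, positive_label="p")
        m = evaluate(model, feats)
        assert 0.0 <= m.auc <= 1.0

    def test_single_class_training_rejected(self, rng):
        feats = [
            DualChannelFeature(f"s{i}", rng.normal(size=(2, 2, 2)), "p") for i in range(4)
        ]
        with pytest.raises(ValueError):
            train_classifier(feats, TrainConfig(backbone="tiny", epochs=1, seed=0))


class TestEvaluate:
    def test_perfect_classifier_metrics(self, rng):
        feats = _blob_features(rng, sep=3.0)
        cfg = TrainConfig(backbone="tiny", fcl_neurons=32, epochs=30, seed=4)
        model, _ = train_classifier(feats, cfg, positive_label="p")
        m = evaluate(model, feats)
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (100.0, 100.0, 100.0, 1.0)

    def test_confusion_arithmetic_example(self):
        acc, sens, spec = metrics_from_confusion(tp=18, fp=7, tn=23, fn=2)
        assert sens == pytest.approx(90.0)
        assert spec == pytest.approx(76.66666666666667)
        assert acc == pytest.approx(82.0)

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_metric_formulas_match_definitions(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        acc, sens, spec = metrics_from_confusion(tp, fp, tn, fn)
        assert acc == pytest.approx(100 * (tp + tn) / (tp + fp + tn + fn))
        if tp + fn:
            assert sens == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert spec == pytest.approx(100 * tn / (tn + fp))

    def test_auc_equals_pairwise_concordance_oracle(self, rng):
        """Trapezoidal ROC AUC == Mann-Whitney concordance (ties 1/2), 500 cases."""
        from sklearn.metrics import roc_curve

        for _ in range(500):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            fpr, tpr, _ = roc_curve(y, scores)
            auc = np.trapezoid(tpr, fpr)
            pos, neg = scores[y == 1], scores[y == 0]
            gt = (pos[:, None] > neg[None, :]).sum()
            eq = (pos[:, None] == neg[None, :]).sum()
            concordance = (gt + 0.5 * eq) / (len(pos) * len(neg))
            assert auc == pytest.approx(concordance, abs=1e-10)

    def test_single_class_test_set_rejected(self, rng):
        feats = _blob_features(rng, n_per_class=5)
        cfg = TrainConfig(backbone="tiny", fcl_neurons=8, epochs=2, seed=5)
        model, _ = train_classifier(feats, cfg, positive_label="p")
        with pytest.raises(ValueError):
            evaluate(model, [f for f in feats if f.label == "p"])

    def test_roc_points_monotone(self, rng):
        feats = _blob_features(rng, n_per_class=15, sep=0.3)
        cfg = TrainConfig(backbone="tiny", fcl_neurons=8, epochs=3, seed=6)
        model, _ = train_classifier(feats, cfg, positive_label="p")
        m = evaluate(model, feats)
        pts = np.array(m.roc_points)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)


def test_stratified_split_preserves_classes(rng):
    labels = ["p"] * 30 + ["c"] * 20
    train, test = stratified_split(labels, test_size=10, seed=0)
    assert len(test) == 10 and len(train) == 40
    test_labels = [labels[i] for i in test]
    assert test_labels.count("p") == 6 and test_labels.count("c") == 4
    assert set(train) | set(test) == set(range(50))
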