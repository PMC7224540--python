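"""CNN branch: architecture contract, augmentation, training sanity,
decision semantics, determinism."""

import numpy as np
import pytest

from gonscreen import CnnClassifier, augment
from gonscreen.decision import ClassifierDecision
from gonscreen.nn import ConvNet


def test_all_conv_kernels_are_3x3():
    for backbone in ("small_default", "vgg_like"):
        net = ConvNet(backbone, seed=0)
        sizes = net.conv_kernel_sizes()
        assert len(sizes) >= 4
        assert all(k == (3, 3) for k in sizes)


def test_head_is_gap_plus_single_fc_and_softmax_sums_to_one():
    net = ConvNet("small_default", seed=0)
    assert net.has_gap_fc_head()
    x = np.random.default_rng(0).uniform(-0.5, 0.5, (1, 256, 256, 3)).astype(np.float32)
    p = net.predict_proba(x)
    assert p.shape == (1, 2)
    assert p.sum() == pytest.approx(1.0, abs=1e-5)


def test_unknown_backbone_rejected():
    with pytest.raises(ValueError):
        ConvNet("resnet", seed=0)


def test_augment_identity_and_seeded_repeatability():
    img = np.random.default_rng(1).integers(0, 255, (64, 64, 3)).astype(np.uint8)
    assert np.array_equal(augment(img, np.random.default_rng(0), (0, 0, 0, 0)), img)
    a = augment(img, np.random.default_rng(5))
    b = augment(img, np.random.default_rng(5))
    assert np.array_equal(a, b)


def test_augment_rotation_bounded():
    # landmark-registration oracle: a bar at known angle, shifted/zoomed off
    img = np.zeros((256, 256), dtype=np.uint8)
    img[126:130, 40:216] = 255  # horizontal bar through the center
    for trial in range(5):
        out = augment(img, np.random.default_rng(trial), (15.0, 0.0, 0.0, 0.0))
        ys, xs = np.where(out > 127)
        slope = np.polyfit(xs, ys, 1)[0]
        assert abs(np.degrees(np.arctan(slope))) <= 15.5


def test_training_reduces_loss_and_inference_is_deterministic(small_rois):
    specs, patches, _ = small_rois
    X = np.stack([p.pixels for p in patches])
    y = np.array([s.class_label for s in specs])
    clf = CnnClassifier(epochs=5, augmentation=None, seed=2).fit(X, y)
    assert clf.history_[-1]["loss"] < clf.history_[0]["loss"]
    p1, p2 = clf.predict_proba(X[:4]), clf.predict_proba(X[:4])
    assert np.array_equal(p1, p2)


def test_zero_epochs_keeps_init_and_empty_history(small_rois):
    specs, patches, _ = small_rois
    X = np.stack([p.pixels for p in patches[:6]])
    y = np.array([s.class_label for s in specs[:6]])
    clf = CnnClassifier(epochs=0, seed=3).fit(X, y)
    ref = ConvNet("small_default", seed=3, dropout_rate=0.5)
    assert clf.history_ == []
    assert np.array_equal(clf.model_.fc_layer.W, ref.fc_layer.W)


def test_single_class_manifest_rejected(small_rois):
    specs, patches, _ = small_rois
    X = np.stack([p.pixels for p in patches[:4]])
    with pytest.raises(ValueError):
        CnnClassifier(epochs=1).fit(X, np.array(["normal"] * 4))


@pytest.mark.parametrize(
    "p,label,conf",
    [(0.93, "glaucoma", 0.93), (0.40, "normal", 0.60), (0.50, "glaucoma", 0.50)],
)
def test_decision_semantics(p, label, conf):
    d = ClassifierDecision.from_p_glaucoma(p, source="cnn")
    assert d.label == label
    assert d.confidence == pytest.approx(conf)
    assert d.confidence >= 0.5


def test_decide_roundtrip_matches_predict(tiny_cnn, small_rois):
    specs, patches, _ = small_rois
    d = tiny_cnn.decide(patches[0].pixels)
    assert d.source == "cnn"
    assert d.label == tiny_cnn.predict(patches[0].pixels[None])[0]


def test_wrong_input_size_rejected(tiny_cnn):
    with pytest.raises(ValueError):
        tiny_cnn.predict_proba(np.zeros((1, 128, 128, 3), dtype=np.uint8))


def test_fine_tune_contracts(tiny_cnn, small_rois):
    specs, patches, _ = small_rois
    X = np.stack([p.pixels for p in patches[:8]])
    y = np.array([s.class_label for s in specs[:8]])
    with pytest.raises(ValueError):
        tiny_cnn.fine_tune(X[:0], y[:0])
    with pytest.raises(ValueError):
        tiny_cnn.fine_tune(X[:2], np.array(["cat", "dog"]))
    before = tiny_cnn.model_.fc_layer.W.copy()
    tuned = tiny_cnn.fine_tune(X, y, epochs=1)
    assert np.array_equal(tiny_cnn.model_.fc_layer.W, before)  # original untouched
    assert tuned is not tiny_cnn


def test_checkpoint_roundtrip(tmp_path, tiny_cnn, small_rois):
    specs, patches, _ = small_rois
    path = tmp_path / "model.npz"
    tiny_cnn.model_.save(path)
    net = ConvNet.load(path)
    X = np.stack([p.pixels for p in patches[:3]])
    a = tiny_cnn.model_.predict_proba(tiny_cnn._as_batch(X))
    b = net.predict_proba(tiny_cnn._as_batch(X))
    assert np.array_equal(a, b)
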