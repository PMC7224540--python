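"""Shared fixtures: small rendered ROI batches and a quickly-trained CNN.

Everything is generated programmatically from the synthetic module at fixed
seeds; no stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest

from gonscreen import (
    CnnClassifier,
    CdrSvmClassifier,
    generate_fundus,
    generate_specs,
)
from gonscreen.preprocess import FundusPreprocessor
from gonscreen.roi import RoiExtractor, extract_roi


def render_rois(n, seed, glaucoma_fraction=0.5, invalid_fraction=0.0, style=None):
    """Render n specs and push them through preprocessing + ROI extraction.

    Returns (specs, pre_patches, raw_patches); raw crops share the located
    center with the preprocessed patch.
    """
    specs = generate_specs(n, glaucoma_fraction, invalid_fraction, seed=seed,
                           style=style)
    pre = FundusPreprocessor()
    rx = RoiExtractor()
    pre_patches, raw_patches = [], []
    for spec in specs:
        img, _ = generate_fundus(spec)
        patch = rx.transform_one(pre.transform_one(img))
        pre_patches.append(patch)
        raw_patches.append(extract_roi(img, patch.center_in_source))
    return specs, pre_patches, raw_patches


@pytest.fixture(scope="session")
def small_rois():
    """30 valid captures (15 glaucoma / 15 normal) with their crops."""
    return render_rois(30, seed=314)


@pytest.fixture(scope="session")
def tiny_cnn(small_rois):
    """A small CNN trained briefly on the 30-ROI batch — enough structure for
    decision/CAM/pipeline tests, not meant to be accurate."""
    specs, patches, _ = small_rois
    X = np.stack([p.pixels for p in patches])
    y = np.array([s.class_label for s in specs])
    return CnnClassifier(epochs=4, augmentation=None, seed=11).fit(X, y)


def toy_feature_set(n_per_class=15, seed=5):
    """Cleanly separable (cdr, rdr_sup, rdr_inf) features: glaucoma cdr in
    [0.7, 0.9], normal in [0.3, 0.5], rims splitting the remainder."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for label, lo, hi in [("glaucoma", 0.7, 0.9), ("normal", 0.3, 0.5)]:
        for _ in range(n_per_class):
            cdr = rng.uniform(lo, hi)
            split = rng.uniform(0.4, 0.6)
            feats.append([cdr, split * (1 - cdr), (1 - split) * (1 - cdr)])
            labels.append(label)
    return np.array(feats), np.array(labels)


@pytest.fixture(scope="session")
def toy_svm():
    X, y = toy_feature_set()
    return CdrSvmClassifier(seed=5).fit(X, y)
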