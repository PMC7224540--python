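"""Metrics, splits, cross-validation structure, and AUC oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gonscreen import (
    ConfusionMatrix,
    compute_metrics,
    kfold_cv,
    roc_auc,
    stratified_split,
)
from gonscreen.synthetic import GLAUCOMA, NORMAL


def manifest(n_glaucoma, n_normal):
    return pd.DataFrame(
        {
            "path": [f"img{i}" for i in range(n_glaucoma + n_normal)],
            "label": [GLAUCOMA] * n_glaucoma + [NORMAL] * n_normal,
        }
    )


def test_metrics_hand_computed():
    acc, sens, spec = compute_metrics(ConfusionMatrix(tp=9, fn=1, tn=8, fp=2))
    assert acc == pytest.approx(0.85)
    assert sens == pytest.approx(0.90)
    assert spec == pytest.approx(0.80)


def test_metrics_all_correct_and_undefined_flags():
    acc, sens, spec = compute_metrics(ConfusionMatrix(tp=5, tn=5))
    assert (acc, sens, spec) == (1.0, 1.0, 1.0)
    _, sens, _ = compute_metrics(ConfusionMatrix(tn=5, fp=1))
    assert np.isnan(sens)
    with pytest.raises(ValueError):
        compute_metrics(ConfusionMatrix())


@given(
    tp=st.integers(0, 50), fp=st.integers(0, 50),
    tn=st.integers(0, 50), fn=st.integers(0, 50),
)
@settings(max_examples=60, deadline=None)
def test_metrics_match_definition_for_any_matrix(tp, fp, tn, fn):
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    if cm.total == 0:
        return
    acc, sens, spec = compute_metrics(cm)
    assert acc == (tp + tn) / (tp + tn + fp + fn)
    if tp + fn:
        assert sens == tp / (tp + fn)
    if tn + fp:
        assert spec == tn / (tn + fp)


def test_stratified_split_exact_allocation():
    train, test = stratified_split(manifest(60, 40), 0.8, seed=1)
    assert (train["label"] == GLAUCOMA).sum() == 48
    assert (train["label"] == NORMAL).sum() == 32
    assert len(test) == 20
    assert set(train.index).isdisjoint(test.index)


def test_split_shape_mirrors_large_cohort_partition():
    # 944 images at fraction 0.8085 -> 763 train / 181 test
    train, test = stratified_split(manifest(500, 444), 763 / 944, seed=2)
    assert len(train) == 763 and len(test) == 181


def test_split_deterministic_and_bounds_checked():
    m = manifest(10, 10)
    a = stratified_split(m, 0.8, seed=3)[0]
    b = stratified_split(m, 0.8, seed=3)[0]
    assert a.equals(b)
    with pytest.raises(ValueError):
        stratified_split(m, 1.2, seed=0)


class ParityDummy:
    """Deterministic rule for the CV oracle: glaucoma iff even row index."""

    def predict(self, rows):
        return np.where(rows.index % 2 == 0, GLAUCOMA, NORMAL)


def test_kfold_structure_and_dummy_oracle():
    m = manifest(50, 50)
    seen = []

    def train_fn(rows):
        return ParityDummy()

    def eval_fn(model, rows):
        seen.append(rows.index.to_numpy())
        acc = float((model.predict(rows) == rows["label"]).mean())
        return {"accuracy": acc}

    results, best = kfold_cv(m, 5, seed=4, train_fn=train_fn, eval_fn=eval_fn)
    # folds disjoint, cover exactly once, 80-20 split
    allv = np.concatenate(seen)
    assert len(allv) == 100 and len(np.unique(allv)) == 100
    assert all(len(v) == 20 for v in seen)
    for v, r in zip(seen, results):
        labels = m.loc[v, "label"]
        assert abs((labels == GLAUCOMA).sum() - 10) <= 1  # stratified
        # independent oracle for the parity rule
        expected = float(np.mean((v % 2 == 0) == (labels == GLAUCOMA)))
        assert r["accuracy"] == pytest.approx(expected)
    assert results[best]["accuracy"] == max(r["accuracy"] for r in results)


def test_kfold_rejects_bad_k():
    with pytest.raises(ValueError):
        kfold_cv(manifest(3, 3), 1, 0, None, None)
    with pytest.raises(ValueError):
        kfold_cv(manifest(3, 50), 5, 0, None, None)


def pair_counting_auc(scores, labels):
    """Mann-Whitney oracle: concordant pairs / (n_pos * n_neg), ties half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == GLAUCOMA]
    neg = scores[np.asarray(labels) == NORMAL]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_perfect_separation():
    scores = [0.9, 0.8, 0.85, 0.2, 0.1, 0.3]
    labels = [GLAUCOMA] * 3 + [NORMAL] * 3
    rep = roc_auc(scores, labels, n_boot=50, seed=0)
    assert rep.auc == 1.0
    assert rep.auc_ci_low <= rep.auc <= rep.auc_ci_high


def test_auc_equals_pair_counting_including_ties():
    scores = [0.9, 0.5, 0.5, 0.5, 0.3, 0.1]
    labels = [GLAUCOMA, GLAUCOMA, NORMAL, GLAUCOMA, NORMAL, NORMAL]
    rep = roc_auc(scores, labels, n_boot=10, seed=0)
    assert rep.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_auc_trapezoid_equals_pair_counting_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 15))
    scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
    labels = np.where(rng.uniform(size=n) < 0.5, GLAUCOMA, NORMAL)
    if len(set(labels)) < 2:
        return
    rep = roc_auc(scores, labels, n_boot=5, seed=0)
    assert rep.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)


def test_auc_near_half_for_random_scores():
    rng = np.random.default_rng(6)
    scores = rng.uniform(size=400)
    labels = np.where(rng.uniform(size=400) < 0.5, GLAUCOMA, NORMAL)
    rep = roc_auc(scores, labels, n_boot=300, seed=1)
    assert rep.auc_ci_low <= 0.5 <= rep.auc_ci_high


def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(7)
    scores = rng.uniform(size=50)
    labels = np.where(rng.uniform(size=50) < 0.4, GLAUCOMA, NORMAL)
    rep = roc_auc(scores, labels, n_boot=5, seed=0)
    pts = np.array(rep.roc_points)
    assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
    assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)


def test_one_class_labels_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [GLAUCOMA, GLAUCOMA], n_boot=5, seed=0)
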