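"""Confidence-gated routing and the threshold-selection sweep."""

import numpy as np
import pytest

from gonscreen import route, select_threshold, SWEEP_GRID
from gonscreen.decision import ClassifierDecision
from gonscreen.synthetic import GLAUCOMA, NORMAL

from conftest import toy_feature_set

GLAUCOMA_FEATURES = [0.85, 0.07, 0.08]
NORMAL_FEATURES = [0.35, 0.33, 0.32]


def cnn_dec(p):
    return ClassifierDecision.from_p_glaucoma(p, source="cnn")


def test_high_confidence_stays_with_cnn(toy_svm):
    d = route(cnn_dec(0.90), NORMAL_FEATURES, toy_svm, threshold=0.85)
    assert d.source == "cnn" and d.final_label == GLAUCOMA
    assert d.svm_decision is None


def test_low_confidence_routes_to_svm(toy_svm):
    d = route(cnn_dec(0.60), GLAUCOMA_FEATURES, toy_svm, threshold=0.85)
    assert d.source == "svm" and d.final_label == GLAUCOMA
    assert d.svm_decision is not None


def test_exact_threshold_is_not_lower(toy_svm):
    d = route(cnn_dec(0.85), GLAUCOMA_FEATURES, toy_svm, threshold=0.85)
    assert d.source == "cnn"


def test_missing_features_fall_back_to_cnn(toy_svm):
    for feats in (None, [np.nan, 0.3, 0.3]):
        d = route(cnn_dec(0.60), feats, toy_svm, threshold=0.85)
        assert d.source == "cnn" and d.fallback


def test_sweep_grid_has_eleven_points():
    assert len(SWEEP_GRID) == 11
    assert SWEEP_GRID[0] == 0.50 and SWEEP_GRID[-1] == 1.00


def test_all_confident_and_correct_returns_lowest_threshold(toy_svm):
    records = [(cnn_dec(1.0), GLAUCOMA_FEATURES, GLAUCOMA) for _ in range(5)]
    records += [(cnn_dec(0.0), NORMAL_FEATURES, NORMAL) for _ in range(5)]
    theta, table = select_threshold(records, toy_svm)
    assert theta == 0.50
    assert len(table) == 11


def test_empty_records_rejected(toy_svm):
    with pytest.raises(ValueError):
        select_threshold([], toy_svm)


def brute_force_best(records, svm, grid):
    """Independent sweep oracle: exhaustive loop, explicit counting."""
    best = None
    for theta in grid:
        tp = fn = tn = fp = 0
        for dec, feats, truth in records:
            if dec.confidence >= theta:
                label = dec.label
            else:
                label = svm.decide(feats).label
            if truth == GLAUCOMA:
                tp, fn = tp + (label == GLAUCOMA), fn + (label != GLAUCOMA)
            else:
                tn, fp = tn + (label != GLAUCOMA), fp + (label == GLAUCOMA)
        score = tp / (tp + fn) + tn / (tn + fp)
        if best is None or score > best[1] + 1e-12:
            best = (theta, score)
    return best[0]


def test_sweep_matches_brute_force_on_random_records(toy_svm):
    rng = np.random.default_rng(77)
    records = []
    for _ in range(40):
        truth = GLAUCOMA if rng.uniform() < 0.5 else NORMAL
        p = rng.uniform(0, 1)
        feats = GLAUCOMA_FEATURES if truth == GLAUCOMA else NORMAL_FEATURES
        records.append((cnn_dec(p), feats, truth))
    theta, _ = select_threshold(records, toy_svm)
    assert theta == brute_force_best(records, toy_svm, SWEEP_GRID)


def test_engineered_optimum_at_085(toy_svm):
    """CNN wrong exactly on its sub-0.85-confidence records; the SVM fixes
    them, so the sweep must land on 0.85."""
    records = []
    # confident and correct
    for p, truth in [(0.95, GLAUCOMA), (0.05, NORMAL)] * 4:
        feats = GLAUCOMA_FEATURES if truth == GLAUCOMA else NORMAL_FEATURES
        records.append((cnn_dec(p), feats, truth))
    # low-confidence and wrong; features carry the right answer
    for p, truth in [(0.20, GLAUCOMA), (0.80, NORMAL)] * 4:
        feats = GLAUCOMA_FEATURES if truth == GLAUCOMA else NORMAL_FEATURES
        records.append((cnn_dec(p), feats, truth))
    theta, _ = select_threshold(records, toy_svm)
    assert theta == 0.85


def test_degenerate_thresholds(toy_svm):
    rng = np.random.default_rng(13)
    records = []
    for _ in range(20):
        truth = GLAUCOMA if rng.uniform() < 0.5 else NORMAL
        feats = GLAUCOMA_FEATURES if truth == GLAUCOMA else NORMAL_FEATURES
        records.append((cnn_dec(rng.uniform(0, 0.999)), feats, truth))
    # theta = 0.5: binary confidence is always >= 0.5, ensemble == CNN
    for dec, feats, _ in records:
        assert route(dec, feats, toy_svm, 0.5).final_label == dec.label
    # theta = 1.0: any confidence < 1 goes to the SVM
    for dec, feats, _ in records:
        routed = route(dec, feats, toy_svm, 1.0)
        assert routed.source == "svm"
        assert routed.final_label == toy_svm.decide(feats).label


def test_gate_recovers_sensitivity_when_cnn_corrupted(toy_svm):
    """Advanced-disease safety: corrupt the CNN exactly on low-confidence
    glaucoma records; the gated ensemble's sensitivity must not fall below
    the corrupted CNN's."""
    records = []
    for p in [0.95, 0.9, 0.6, 0.55, 0.3, 0.2]:
        # true glaucoma with large cups; CNN below 0.85 votes normal
        dec = cnn_dec(p)
        records.append((dec, [0.8, 0.1, 0.1], GLAUCOMA))
    cnn_sens = np.mean([d.label == GLAUCOMA for d, _, _ in records])
    ens_sens = np.mean([
        route(d, f, toy_svm, 0.85).final_label == GLAUCOMA for d, f, _ in records
    ])
    assert ens_sens >= cnn_sens
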