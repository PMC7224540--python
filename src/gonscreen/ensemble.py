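"""Confidence-gated ensemble: the CNN decides unless its confidence falls
below a threshold, in which case the CDR-based SVM makes the final call.

The gate exists to avoid missing eyes with moderate-to-advanced disease: those
inevitably have an enlarged cup-to-disc ratio, so when the CNN is unsure the
decision is handed to the classifier built on exactly that sign.  "Below"
is read strictly: confidence >= threshold stays with the CNN.  The default
threshold 0.85 is the optimum of a sensitivity+specificity sweep over the grid
0.50, 0.55, ..., 1.00.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import ClassifierDecision
from .svm import CdrSvmClassifier
from .synthetic import GLAUCOMA

DEFAULT_THRESHOLD = 0.85
SWEEP_GRID = tuple(np.round(np.arange(0.50, 1.0001, 0.05), 2))  # 11 values


@dataclass
class EnsembleDecision:
    final_label: str
    source: str  # "cnn" | "svm"
    cnn_decision: ClassifierDecision
    svm_decision: ClassifierDecision | None
    threshold_used: float
    fallback: bool = False  # SVM wanted but features unavailable

    def __post_init__(self):
        assert (self.source == "svm") == (self.svm_decision is not None)


def route(
    cnn_decision: ClassifierDecision,
    features,
    svm: CdrSvmClassifier | None,
    threshold: float = DEFAULT_THRESHOLD,
) -> EnsembleDecision:
    """Apply the gate to one image.

    If CNN confidence >= threshold the CNN label is final and the SVM is never
    invoked.  Otherwise the SVM decides on the image's (cdr, rdr_sup, rdr_inf)
    features.  If those features are unavailable (segmentation failed,
    ``features`` is None or NaN), the CNN label is kept with ``fallback=True``
    so the pipeline stays total.
    """
    assert cnn_decision.source == "cnn"
    if cnn_decision.confidence >= threshold:
        return EnsembleDecision(cnn_decision.label, "cnn", cnn_decision, None,
                                threshold)
    feats_ok = features is not None and not np.isnan(
        np.asarray(features, dtype=float)
    ).any()
    if not feats_ok or svm is None:
        return EnsembleDecision(cnn_decision.label, "cnn", cnn_decision, None,
                                threshold, fallback=True)
    svm_decision = svm.decide(features)
    return EnsembleDecision(svm_decision.label, "svm", cnn_decision,
                            svm_decision, threshold)


def _sensitivity_specificity(records, svm, threshold):
    tp = fn = tn = fp = 0
    for cnn_dec, features, true_label in records:
        final = route(cnn_dec, features, svm, threshold).final_label
        if true_label == GLAUCOMA:
            tp += final == GLAUCOMA
            fn += final != GLAUCOMA
        else:
            tn += final != GLAUCOMA
            fp += final == GLAUCOMA
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens, spec


def select_threshold(
    validation_records,
    svm: CdrSvmClassifier,
    grid=SWEEP_GRID,
) -> tuple[float, list[dict]]:
    """Sweep the threshold grid and return the value maximizing
    sensitivity + specificity over the validation records, plus the full
    sweep table.

    ``validation_records`` is a list of (cnn_decision, features, true_label).
    Ties resolve to the lowest threshold (least SVM involvement).
    """
    if not validation_records:
        raise ValueError("empty validation records")
    table = []
    best_theta, best_score = None, -np.inf
    for theta in grid:
        sens, spec = _sensitivity_specificity(validation_records, svm, theta)
        table.append({"threshold": float(theta), "sensitivity": sens,
                      "specificity": spec, "youden_sum": sens + spec})
        if sens + spec > best_score + 1e-12:
            best_score, best_theta = sens + spec, float(theta)
    return best_theta, table


class ConfidenceGatedEnsemble:
    """Fitted-classifier composition applying the gate per image.

    Not an independent estimator to fit — it composes an already-fitted CNN
    and SVM; ``decide`` and ``decide_batch`` mirror route().
    """

    def __init__(self, cnn, svm, threshold: float = DEFAULT_THRESHOLD):
        self.cnn = cnn
        self.svm = svm
        self.threshold = threshold

    def decide(self, roi_pixels, features) -> EnsembleDecision:
        return route(self.cnn.decide(roi_pixels), features, self.svm,
                     self.threshold)

    def decide_batch(self, rois, features_matrix) -> list[EnsembleDecision]:
        return [self.decide(r, f) for r, f in zip(rois, features_matrix)]

    def predict(self, rois, features_matrix):
        return np.array(
            [d.final_label for d in self.decide_batch(rois, features_matrix)]
        )
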