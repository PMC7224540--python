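"""End-to-end orchestration: preprocess -> ROI -> CNN -> (low confidence?)
CDR features + SVM -> ensemble decision, plus the full synthetic experiment
(train, cross-validate, threshold sweep, evaluate) and the domain-shift /
fine-tuning experiment.

Every stochastic choice — dataset generation, splits, K-means, SGD init,
augmentation, bootstrap — derives from the run's single seed, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import synthetic
from .cnn import CnnClassifier
from .decision import ClassifierDecision
from .ensemble import (
    DEFAULT_THRESHOLD,
    ConfidenceGatedEnsemble,
    EnsembleDecision,
    route,
    select_threshold,
)
from .evaluation import evaluate_decisions, stratified_split
from .features import CdrFeatureExtractor
from .preprocess import FundusPreprocessor
from .roi import RoiExtractor
from .svm import CdrSvmClassifier
from .synthetic import GLAUCOMA, NORMAL


@dataclass
class PipelineConfig:
    """Resolved configuration of one experiment run (fully serializable)."""

    seed: int = 0
    n_images: int = 260
    glaucoma_fraction: float = 0.5
    invalid_fraction: float = 0.05
    train_fraction: float = 0.8
    validation_fraction: float = 0.25  # of the training set, for the sweep
    threshold: float = DEFAULT_THRESHOLD
    sweep_threshold: bool = True
    cnn_epochs: int = 18
    cnn_batch_size: int = 16
    cnn_learning_rate: float = 0.01
    # ablation switches mirroring the system's named recipes
    ablate_roi: bool = False            # "all except ROI selection"
    ablate_preprocessing: bool = False  # "all except preprocessing"
    ablate_augmentation: bool = False   # "all except augmentation"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class DetectionRecord:
    """One row per input image; ungradable images carry no label."""

    image_id: str
    roi_valid: bool
    rejection_reason: str
    cnn_decision: ClassifierDecision | None = None
    features: list | None = None
    ensemble_decision: EnsembleDecision | None = None

    @property
    def gradable(self) -> bool:
        return self.roi_valid


def run_detect(
    images,
    image_ids,
    cnn: CnnClassifier,
    svm: CdrSvmClassifier | None,
    threshold: float = DEFAULT_THRESHOLD,
    preprocessor: FundusPreprocessor | None = None,
    roi_extractor: RoiExtractor | None = None,
    feature_seed: int = 0,
    skip_roi_filter: bool = False,
) -> list[DetectionRecord]:
    """Detection over a batch of full-frame images.

    Rejected ROIs never reach a classifier: their records carry only the
    rejection reason.  Features are computed lazily — only when the CNN's
    confidence falls below the threshold.
    """
    preprocessor = preprocessor or FundusPreprocessor()
    roi_extractor = roi_extractor or RoiExtractor()
    fx = CdrFeatureExtractor(seed=feature_seed)
    records = []
    for img, image_id in zip(images, image_ids):
        pre = preprocessor.transform_one(img)
        patch = roi_extractor.transform_one(pre)
        if not patch.valid and not skip_roi_filter:
            records.append(
                DetectionRecord(image_id, False, patch.rejection_reason)
            )
            continue
        cnn_dec = cnn.decide(patch.pixels)
        features = None
        if cnn_dec.confidence < threshold and svm is not None:
            # channel segmentation runs on the raw-intensity crop at the same
            # center: it derives its own statistics and must keep cup contrast
            from .roi import extract_roi

            raw_patch = extract_roi(img, patch.center_in_source)
            features = fx.transform([raw_patch])[0]
        ens = route(cnn_dec, features, svm, threshold)
        records.append(
            DetectionRecord(
                image_id, True, "none", cnn_dec,
                None if features is None else list(np.asarray(features, float)),
                ens,
            )
        )
    return records


def _render_split(specs):
    images, truths = [], []
    for spec in specs:
        img, truth = synthetic.generate_fundus(spec)
        images.append(img)
        truths.append(truth)
    return images, truths


def _prepare_rois(images, config: PipelineConfig, roi_extractor=None):
    """Preprocessed ROI patches (validity + CNN input) paired with raw crops
    at the same centers (segmentation input)."""
    from .roi import extract_roi

    pre = FundusPreprocessor(normalize=not config.ablate_preprocessing,
                             amount=0.0 if config.ablate_preprocessing else 1.0)
    rx = roi_extractor or RoiExtractor()
    patches, raw_patches = [], []
    for img in images:
        patch = rx.transform_one(pre.transform_one(img))
        patches.append(patch)
        raw_patches.append(extract_roi(img, patch.center_in_source))
    return patches, raw_patches


def run_experiment(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """The full synthetic study: generate, filter, train both branches, sweep
    the gate threshold on validation data, evaluate CNN / SVM / ensemble on
    the held-out test set.

    Returns a dict of reports; writes JSON/CSV artifacts when ``out_dir`` is
    given.
    """
    rng = np.random.SeedSequence(config.seed)
    s_data, s_split, s_cnn, s_feat, s_svm, s_eval = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(6)
    ]

    specs = synthetic.generate_specs(
        config.n_images, config.glaucoma_fraction, config.invalid_fraction,
        seed=s_data,
    )
    images, truths = _render_split(specs)
    patches, raw_patches = _prepare_rois(images, config)

    # ROI validity accounting (the filter can be ablated)
    gradable_idx = [
        i for i, p in enumerate(patches)
        if p.valid or config.ablate_roi
    ]
    n_excluded = len(patches) - len(gradable_idx)
    manifest = pd.DataFrame(
        {
            "index": gradable_idx,
            "label": [specs[i].class_label for i in gradable_idx],
            "cdr_true": [specs[i].cdr_true for i in gradable_idx],
        }
    )

    train_m, test_m = stratified_split(manifest, config.train_fraction, seed=s_split)
    # carve the sweep-validation subset out of the training set
    if config.validation_fraction > 0:
        fit_m, val_m = stratified_split(
            train_m.reset_index(drop=True), 1 - config.validation_fraction,
            seed=s_split + 1,
        )
    else:
        fit_m, val_m = train_m.reset_index(drop=True), None

    def rois_of(m):
        return np.stack([patches[i].pixels for i in m["index"]])

    X_fit, y_fit = rois_of(fit_m), fit_m["label"].to_numpy()
    cnn = CnnClassifier(
        epochs=config.cnn_epochs, batch_size=config.cnn_batch_size,
        learning_rate=config.cnn_learning_rate,
        augmentation=None if config.ablate_augmentation else
        CnnClassifier().augmentation,
        seed=s_cnn,
    ).fit(X_fit, y_fit)

    fx = CdrFeatureExtractor(seed=s_feat)

    def feats_of(m):
        # segmentation consumes the raw-intensity crop at the located center;
        # invalid preprocessed patches never get here (gradable_idx filter)
        return fx.transform([raw_patches[i] for i in m["index"]])

    feats_fit = feats_of(fit_m)
    ok = ~np.isnan(feats_fit).any(axis=1)
    svm = CdrSvmClassifier(seed=s_svm).fit(feats_fit[ok], y_fit[ok])

    # threshold sweep on validation records
    sweep_table = None
    threshold = config.threshold
    if config.sweep_threshold and val_m is not None and len(val_m):
        val_rois = rois_of(val_m)
        val_feats = feats_of(val_m)
        records = [
            (cnn.decide(r), f, lab)
            for r, f, lab in zip(val_rois, val_feats, val_m["label"])
        ]
        threshold, sweep_table = select_threshold(records, svm)

    # held-out evaluation of all three classifiers
    X_test, y_test = rois_of(test_m), test_m["label"].to_numpy()
    test_feats = feats_of(test_m)
    p_cnn = cnn.p_glaucoma(X_test)
    cnn_pred = np.where(p_cnn >= 0.5, GLAUCOMA, NORMAL)

    ok_t = ~np.isnan(test_feats).any(axis=1)
    svm_pred = np.array([NORMAL] * len(y_test), dtype=object)
    p_svm = np.full(len(y_test), 0.5)
    if ok_t.any():
        svm_pred[ok_t] = svm.predict(test_feats[ok_t])
        p_svm[ok_t] = svm.p_glaucoma(test_feats[ok_t])
    svm_pred[~ok_t] = cnn_pred[~ok_t]

    ens = ConfidenceGatedEnsemble(cnn, svm, threshold)
    ens_decisions = ens.decide_batch(X_test, test_feats)
    ens_pred = np.array([d.final_label for d in ens_decisions])
    p_ens = np.array(
        [
            d.svm_decision.p_glaucoma if d.source == "svm" else d.cnn_decision.p_glaucoma
            for d in ens_decisions
        ]
    )

    results = {
        "config": asdict(config),
        "threshold_selected": threshold,
        "sweep_table": sweep_table,
        "n_images": config.n_images,
        "n_excluded_roi": n_excluded,
        "n_test": int(len(y_test)),
        "cnn": evaluate_decisions(y_test, cnn_pred, p_cnn,
                                  n_excluded_roi=n_excluded, seed=s_eval),
        "svm": evaluate_decisions(y_test, svm_pred, p_svm,
                                  n_excluded_roi=n_excluded, seed=s_eval),
        "ensemble": evaluate_decisions(y_test, ens_pred, p_ens,
                                       n_excluded_roi=n_excluded, seed=s_eval),
        "svm_features_failed": int((~ok_t).sum()),
        "cdr_mae_test": float(
            np.nanmean(np.abs(test_feats[:, 0] - test_m["cdr_true"].to_numpy()))
        ),
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            fh.write(config.to_json())
        serializable = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in results.items()
        }
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(serializable, fh, indent=2, default=float)
        if sweep_table:
            pd.DataFrame(sweep_table).to_csv(
                os.path.join(out_dir, "threshold_sweep.csv"), index=False
            )
    return results


# Style presets for the cross-camera generalizability experiment.  Style B
# emulates a second camera: dimmer exposure, softer optics, noisier sensor.
STYLE_A: dict = {}
STYLE_B: dict = {"brightness_gain": 0.55, "blur_sigma": 3.0, "noise_sd": 25.0}


def run_domain_shift_experiment(
    seed: int = 0,
    n_train_a: int = 120,
    n_test_a: int = 60,
    n_test_b: int = 60,
    n_finetune_b: int = 40,
    epochs: int = 25,
    finetune_epochs: int = 8,
) -> dict:
    """Cross-camera generalizability: train on style A, measure the accuracy
    drop on style B, then fine-tune with a small style-B set and measure the
    recovered fraction of the gap.

    ROIs are taken without brightness normalization so the style difference
    reaches the classifier (mirroring a deployment that meets a new camera).
    """
    ss = np.random.SeedSequence([seed, 7])
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)]

    def make_rois(n, style, s):
        specs = synthetic.generate_specs(n, 0.5, 0.0, seed=s, style=style or None)
        pre = FundusPreprocessor(normalize=False)
        rx = RoiExtractor()
        rois, labels = [], []
        for spec in specs:
            img, _ = synthetic.generate_fundus(spec)
            patch = rx.transform_one(pre.transform_one(img))
            if patch.valid:
                rois.append(patch.pixels)
                labels.append(spec.class_label)
        return np.stack(rois), np.array(labels)

    Xa, ya = make_rois(n_train_a, STYLE_A, seeds[0])
    Xa_test, ya_test = make_rois(n_test_a, STYLE_A, seeds[1])
    Xb_test, yb_test = make_rois(n_test_b, STYLE_B, seeds[2])
    Xb_ft, yb_ft = make_rois(n_finetune_b, STYLE_B, seeds[3])

    cnn = CnnClassifier(epochs=epochs, seed=seeds[4]).fit(Xa, ya)
    acc_a = float((cnn.predict(Xa_test) == ya_test).mean())
    acc_b = float((cnn.predict(Xb_test) == yb_test).mean())

    tuned = cnn.fine_tune(Xb_ft, yb_ft, epochs=finetune_epochs)
    acc_b_tuned = float((tuned.predict(Xb_test) == yb_test).mean())
    gap = acc_a - acc_b
    closed = (acc_b_tuned - acc_b) / gap if gap > 0 else float("nan")
    return {
        "acc_style_a": acc_a,
        "acc_style_b": acc_b,
        "acc_style_b_finetuned": acc_b_tuned,
        "gap": gap,
        "gap_closed_fraction": float(closed),
    }
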