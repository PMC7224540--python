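"""CNN branch: seeded augmentation and a scikit-learn-style classifier over
disc-centered ROIs.

The classifier wraps the in-package conv net (3x3 convolutions, GAP + single
FC head so class activation maps apply) and trains it with SGD + momentum on
cross-entropy, with dropout and geometric augmentation (rotation, shift,
shear, zoom) active during training only.  Inference is deterministic.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import AffineTransform, warp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .decision import ClassifierDecision
from .nn import ConvNet
from .synthetic import GLAUCOMA, NORMAL

# (rotation_deg, shift_frac, shear_deg, zoom_frac)
DEFAULT_AUGMENTATION = (10.0, 0.05, 4.0, 0.08)


def augment(image: np.ndarray, rng: np.random.Generator,
            bounds: tuple[float, float, float, float] = DEFAULT_AUGMENTATION
            ) -> np.ndarray:
    """One random geometric deformation: rotation, shift, shear, zoom, each
    drawn uniformly within its bound.  All-zero bounds return the input
    unchanged (exact identity); the label is never affected."""
    rot_deg, shift_frac, shear_deg, zoom_frac = bounds
    if rot_deg == 0 and shift_frac == 0 and shear_deg == 0 and zoom_frac == 0:
        return image
    h, w = image.shape[:2]
    angle = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    shear = np.deg2rad(rng.uniform(-shear_deg, shear_deg))
    zoom = 1.0 + rng.uniform(-zoom_frac, zoom_frac)
    tx = rng.uniform(-shift_frac, shift_frac) * w
    ty = rng.uniform(-shift_frac, shift_frac) * h
    center = np.array([w / 2.0, h / 2.0])
    t = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=angle, shear=shear, scale=(zoom, zoom))
        + AffineTransform(translation=center + [tx, ty])
    )
    out = warp(image.astype(np.float64), t.inverse, mode="edge", order=1,
               preserve_range=True)
    return out.astype(image.dtype)


class CnnClassifier(BaseEstimator, ClassifierMixin):
    """Conv-net glaucoma/normal classifier over 256x256x3 ROIs.

    Parameters
    ----------
    backbone : "small_default" (four 3x3-conv blocks, widths 16/32/64/64,
        trains in minutes on CPU) or "vgg_like" (deeper double-conv blocks).
    epochs, batch_size, learning_rate, momentum : SGD schedule.
    dropout_rate : dropout before the FC head, training only.
    augmentation : (rotation_deg, shift_frac, shear_deg, zoom_frac) bounds;
        None disables augmentation.
    validation_fraction : held-out share used for the per-epoch validation
        accuracy in ``history_`` and best-epoch checkpointing (0 disables).
    seed : drives weight init, shuffling, dropout and augmentation.

    Fitted attributes: ``model_`` (the conv net, best-validation checkpoint
    when validation is enabled), ``classes_``, ``history_`` (list of per-epoch
    dicts with loss / train_acc / val_acc).
    """

    def __init__(self, backbone="small_default", epochs=25, batch_size=16,
                 learning_rate=0.01, momentum=0.9, dropout_rate=0.5,
                 augmentation=DEFAULT_AUGMENTATION, validation_fraction=0.0,
                 seed=0):
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout_rate = dropout_rate
        self.augmentation = augmentation
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_batch(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1:] != (256, 256, 3):
            raise ValueError(f"expected (n, 256, 256, 3) ROIs, got {X.shape}")
        if X.dtype == np.uint8:
            X = X.astype(np.float32) / 255.0
        # center intensities: zero-mean inputs keep early SGD steps balanced
        return X.astype(np.float32) - np.float32(0.5)

    def _encode(self, y) -> np.ndarray:
        return np.array([np.searchsorted(self.classes_, v) for v in y])

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training manifest must contain both classes")
        self._X_train = np.asarray(X)  # kept for fine-tuning on the union
        self._y_train = y
        self.model_ = ConvNet(self.backbone, seed=self.seed,
                              dropout_rate=self.dropout_rate)
        self.history_ = []
        self._train(self.model_, self._X_train, y, self.epochs)
        return self

    def _train(self, net, X, y, epochs):
        Xf = self._as_batch(X)
        yi = self._encode(y)
        ss = np.random.SeedSequence([self.seed, 1])
        shuffle_rng, aug_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

        n = len(Xf)
        val_idx = np.array([], dtype=int)
        if self.validation_fraction > 0 and epochs > 0:
            order = shuffle_rng.permutation(n)
            n_val = max(1, int(round(n * self.validation_fraction)))
            val_idx, train_idx = order[:n_val], order[n_val:]
        else:
            train_idx = np.arange(n)
        Xtr, ytr = Xf[train_idx], yi[train_idx]
        best_val, best_state = -1.0, None

        for epoch in range(epochs):
            order = shuffle_rng.permutation(len(Xtr))
            losses = []
            for i in range(0, len(order), self.batch_size):
                idx = order[i : i + self.batch_size]
                xb = Xtr[idx]
                if self.augmentation is not None:
                    xb = np.stack(
                        [augment(im, aug_rng, self.augmentation) for im in xb]
                    )
                losses.append(
                    net.train_step(xb, ytr[idx], self.learning_rate, self.momentum)
                )
            rec = {"epoch": epoch, "loss": float(np.mean(losses))}
            rec["train_acc"] = float(
                (net.predict_proba(Xtr).argmax(1) == ytr).mean()
            )
            if len(val_idx):
                va = float(
                    (net.predict_proba(Xf[val_idx]).argmax(1) == yi[val_idx]).mean()
                )
                rec["val_acc"] = va
                if va > best_val:
                    best_val, best_state = va, net.copy()
            self.history_.append(rec)
        if best_state is not None:
            # keep the best-validation-accuracy checkpoint
            net.layers = best_state.layers
            net._velocity = best_state._velocity

    def fine_tune(self, X_extra, y_extra, epochs: int | None = None) -> "CnnClassifier":
        """Continue training on the union of the original and extra data.

        Returns a new fitted classifier; this one is untouched.  Extra data
        must share at least one class with the original training set.
        """
        check_is_fitted(self, "model_")
        y_extra = np.asarray(y_extra)
        if len(y_extra) == 0:
            raise ValueError("extra manifest is empty")
        if not set(y_extra) & set(self.classes_):
            raise ValueError("extra manifest shares no class with the original")
        new = CnnClassifier(**self.get_params())
        new.classes_ = self.classes_
        new._X_train = np.concatenate([self._X_train, np.asarray(X_extra)])
        new._y_train = np.concatenate([self._y_train, y_extra])
        new.model_ = self.model_.copy()
        new.history_ = list(self.history_)
        new._train(new.model_, new._X_train, new._y_train,
                   self.epochs if epochs is None else epochs)
        return new

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._as_batch(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def p_glaucoma(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        col = int(np.searchsorted(self.classes_, GLAUCOMA))
        return proba[:, col]

    def decide(self, roi_pixels: np.ndarray) -> ClassifierDecision:
        """Decision record for a single ROI (source tag ``cnn``)."""
        p = float(self.p_glaucoma(roi_pixels[None] if roi_pixels.ndim == 3
                                  else roi_pixels)[0])
        return ClassifierDecision.from_p_glaucoma(p, source="cnn")


# thin functional wrappers ------------------------------------------------

def train_cnn(X, y, **params) -> CnnClassifier:
    return CnnClassifier(**params).fit(X, y)


def predict_cnn(clf: CnnClassifier, roi_pixels: np.ndarray) -> ClassifierDecision:
    return clf.decide(roi_pixels)
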