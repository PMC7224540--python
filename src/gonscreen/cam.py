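"""Class activation maps for the GAP + single-FC conv net.

The map for a class is the FC layer's class weights projected back onto the
feature maps entering global average pooling:

    CAM(x, y) = sum_k  w_k[class] * f_k(x, y)

followed by ReLU (negative evidence dropped), per-image min-max normalization
to [0, 1] (an all-constant map normalizes to all zeros), and bilinear
upsampling to the 256x256 ROI frame.  High values mark regions that drove the
classification — over glaucomatous discs typically the cup, over healthy discs
the neuroretinal rim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .synthetic import GLAUCOMA


@dataclass
class CamHeatmap:
    values: np.ndarray  # feature-map resolution, normalized to [0, 1]
    upsampled: np.ndarray  # 256x256, normalized to [0, 1]
    target_class: str


def _normalize(cam: np.ndarray) -> np.ndarray:
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


def compute_cam(model, roi_pixels: np.ndarray, target_class: str = GLAUCOMA,
                out_size: int = 256) -> CamHeatmap:
    """CAM of ``target_class`` for one ROI.

    ``model`` may be a :class:`~gonscreen.cnn.CnnClassifier` or a raw
    :class:`~gonscreen.nn.ConvNet`; it must carry the GAP + single-FC head.
    """
    clf = None
    net = getattr(model, "model_", model)
    if hasattr(model, "classes_"):
        clf = model
    if not net.has_gap_fc_head():
        raise ValueError("CAM requires a GAP + single-FC head architecture")

    if clf is not None:
        class_idx = int(np.searchsorted(clf.classes_, target_class))
    else:
        class_idx = 0 if target_class == GLAUCOMA else 1

    x = roi_pixels[None] if roi_pixels.ndim == 3 else roi_pixels
    if x.dtype == np.uint8:
        # same intensity convention as CnnClassifier training input
        x = x.astype(np.float32) / 255.0 - 0.5
    fmaps = net.forward_features(x.astype(np.float32))[0]  # (h, w, c)
    weights = net.fc_layer.W[:, class_idx]  # (c,)
    cam = np.maximum(fmaps @ weights, 0.0)
    cam = _normalize(cam)
    up = resize(cam, (out_size, out_size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    return CamHeatmap(values=cam, upsampled=_normalize_if_needed(up),
                      target_class=target_class)


def _normalize_if_needed(up: np.ndarray) -> np.ndarray:
    # bilinear interpolation of a [0,1] grid stays in [0,1]; re-clip for safety
    return np.clip(up, 0.0, 1.0)


def overlay(heatmap: CamHeatmap, roi_pixels: np.ndarray,
            alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend the color-mapped heatmap over the ROI (uint8 RGB).

    Jet-style colormap: high activation renders red, low renders blue.
    ``alpha=0`` returns the ROI; ``alpha=1`` the pure colormapped heatmap.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    cmap = colormaps["jet"]
    colored = cmap(heatmap.upsampled)[..., :3] * 255.0
    base = roi_pixels.astype(np.float64)
    out = (1.0 - alpha) * base + alpha * colored
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
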