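"""Classical disc/cup segmentation and the three cup-to-disc-ratio features.

The glaucoma hallmarks measurable on a disc photograph are an enlarged
vertical cup-to-disc ratio (CDR) and thinning of the superior or inferior
neuroretinal rim.  This module recovers them from a disc-centered ROI by
channel separation:

1. vessels are suppressed by grayscale morphological closing,
2. the disc margin is segmented from the red channel (Otsu threshold, largest
   component, hole filling),
3. the cup is segmented from the green channel: subtract the scalar
   (mean + SD) of the ROI's green intensities, clip negatives, restrict to the
   disc interior, and split the remaining intensities with K-means (K=2) —
   the higher-mean cluster is the cup,
4. vertical diameters are read off along the vertical meridian through each
   component's centroid, giving CDR = cup length / disc diameter and the
   superior/inferior rim-to-disc ratios as the remaining shares.

The feature vector (cdr, rdr_sup, rdr_inf) always sums CDR and the two rim
ratios to exactly 1 (vertical-meridian decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, opening, disk
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .roi import RoiPatch

FEATURE_ORDER = ("cdr", "rdr_sup", "rdr_inf")

DEFAULT_CLOSING_RADIUS = 7  # larger than the max vessel width (5 px)
DEFAULT_OPENING_RADIUS = 3
DEFAULT_EROSION_RADIUS = 4  # strips the blurred disc-boundary ring before clustering
KMEANS_MIN_SEPARATION = 4.0  # intensity units; below this clustering is degenerate


class SegmentationFailure(RuntimeError):
    """Raised when a segmentation stage yields no usable mask."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"segmentation failed at stage={stage}: {message}")


@dataclass
class DiscCupGeometry:
    disc_diameter_v: float
    cup_length_v: float
    rim_sup: float
    rim_inf: float
    cdr: float
    rdr_sup: float
    rdr_inf: float
    disc_endpoints: tuple[tuple[int, int], tuple[int, int]]  # ((x,y) top, bottom)
    cup_endpoints: tuple[tuple[int, int], tuple[int, int]] | None
    flags: list[str] = field(default_factory=list)

    @property
    def feature_vector(self) -> np.ndarray:
        return np.array([self.cdr, self.rdr_sup, self.rdr_inf])


def remove_vessels(
    channel: np.ndarray,
    radius: int = DEFAULT_CLOSING_RADIUS,
    tophat_threshold: float = 20.0,
) -> np.ndarray:
    """Suppress dark thin structures (vessels) in a single channel.

    Vessel pixels are detected by the black top-hat of a grayscale closing
    with a disk element wider than any vessel (pixels the closing brightens
    by more than ``tophat_threshold``), then replaced by the value of the
    nearest unobstructed pixel.  Nearest-neighbor fill, unlike closing alone,
    reconstructs a small cup even when vessels cover most of it — the
    remaining cup pixels propagate inward instead of being overwritten by
    rim intensity.  A channel with no detected vessels is returned unchanged.
    """
    ch = channel.astype(np.float64)
    closed = closing(channel, disk(radius)).astype(np.float64)
    vessel = (closed - ch) > tophat_threshold
    if not vessel.any():
        return channel.copy()
    _, (iy, ix) = ndimage.distance_transform_edt(vessel, return_indices=True)
    return ch[iy, ix].astype(channel.dtype)


def _vertical_endpoints(mask: np.ndarray):
    """Topmost/bottommost mask pixels on the vertical line through the mask
    centroid; returns ((x, y_top), (x, y_bottom))."""
    ys, xs = np.nonzero(mask)
    ccol = int(round(xs.mean()))
    col_ys = np.nonzero(mask[:, ccol])[0]
    if col_ys.size == 0:  # centroid column can miss a concave mask
        ccol = int(np.bincount(xs).argmax())
        col_ys = np.nonzero(mask[:, ccol])[0]
    return (ccol, int(col_ys.min())), (ccol, int(col_ys.max()))


def segment_disc(red_channel: np.ndarray):
    """Disc margin from the (vessel-removed) red channel.

    Otsu threshold -> largest connected component -> fill holes.  Endpoints
    are the superior and inferior junctional points of the disc boundary along
    the vertical meridian.
    """
    if red_channel.max() - red_channel.min() < 1e-9:
        raise SegmentationFailure("disc", "uniform red channel")
    thresh = threshold_otsu(red_channel.astype(np.float64))
    binary = red_channel > thresh
    if not binary.any():
        raise SegmentationFailure("disc", "empty mask after thresholding")
    labels, n = ndimage.label(binary)
    largest = np.argmax(ndimage.sum_labels(binary, labels, range(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    h, w = mask.shape
    touches = (
        mask[0].any() and mask[-1].any() and mask[:, 0].any() and mask[:, -1].any()
    )
    if touches:
        raise SegmentationFailure("disc", "mask touches all four borders")
    return mask, _vertical_endpoints(mask)


def segment_cup(
    green_channel: np.ndarray,
    disc_mask: np.ndarray,
    seed: int = 0,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
    erosion_radius: int = DEFAULT_EROSION_RADIUS,
):
    """Cup area from the (vessel-removed) green channel via K-means (K=2).

    Redundant (below-typical) intensity is removed by subtracting the scalar
    mean + SD of the ROI's green channel and clipping negatives to zero.  The
    disc interior is then eroded by a few pixels — the blurred dark ring at
    the disc margin must not enter the clustering, or with a small cup the
    two clusters split boundary-vs-rim instead of rim-vs-cup — and the
    transformed intensities inside the eroded interior are split into two
    clusters; the higher-mean cluster is the cup (label-permutation safe).
    Degenerate clustering — cluster separation under a few intensity units,
    as for a uniform disc interior — yields an empty cup with a warning, not
    an error.

    Returns ``(cup_mask, cup_endpoints, degenerate_flag)``.
    """
    if not disc_mask.any():
        raise SegmentationFailure("cup", "empty disc mask")
    g = green_channel.astype(np.float64)
    shift = g.mean() + g.std()
    transformed = np.clip(g - shift, 0.0, None)

    interior = ndimage.binary_erosion(disc_mask, structure=disk(erosion_radius))
    if not interior.any():
        interior = disc_mask
    values = transformed[interior]
    empty = (np.zeros_like(disc_mask), None, True)
    if values.max() - values.min() < KMEANS_MIN_SEPARATION:
        warnings.warn("degenerate cup clustering: uniform disc interior")
        return empty
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    if abs(centers[0] - centers[1]) < KMEANS_MIN_SEPARATION:
        warnings.warn("degenerate cup clustering: cluster separation below epsilon")
        return empty
    cup_label = int(np.argmax(centers))  # cup is the brighter cluster

    cup_mask = np.zeros_like(disc_mask)
    cup_mask[interior] = labels == cup_label
    # close first: residual vessel shadows can cut a small cup into pieces
    # that opening alone would erase
    cup_mask = closing(cup_mask, disk(opening_radius + 2))
    cup_mask = opening(cup_mask, disk(opening_radius))
    if not cup_mask.any():
        warnings.warn("cup vanished under morphological opening")
        return empty
    lab, n = ndimage.label(cup_mask)
    largest = np.argmax(ndimage.sum_labels(cup_mask, lab, range(1, n + 1))) + 1
    cup_mask = (lab == largest) & disc_mask
    if not cup_mask.any():
        return empty
    return cup_mask, _vertical_endpoints(cup_mask), False


def compute_geometry(disc_mask, disc_endpoints, cup_mask, cup_endpoints) -> DiscCupGeometry:
    """Vertical diameters, rim widths, and the three ratios.

    Rim widths are the vertical distances from the disc endpoints to the cup
    endpoints; the three ratios are re-normalized to sum to exactly 1 because
    disc and cup use their own centroid meridians.  Cup endpoints outside the
    disc's vertical span are clipped and flagged.
    """
    (dx, dy_top), (_, dy_bot) = disc_endpoints
    disc_d = float(dy_bot - dy_top + 1)
    if disc_d <= 0:
        raise SegmentationFailure("geometry", "non-positive disc diameter")
    flags: list[str] = []
    if cup_endpoints is None or cup_mask is None or not np.any(cup_mask):
        cup_len = 0.0
        rim_sup = rim_inf = disc_d / 2.0
        flags.append("empty_cup")
        cup_eps = None
    else:
        (cx, cy_top), (_, cy_bot) = cup_endpoints
        if cy_top < dy_top or cy_bot > dy_bot:
            cy_top = max(cy_top, dy_top)
            cy_bot = min(cy_bot, dy_bot)
            flags.append("cup_clipped_to_disc_span")
        cup_len = float(cy_bot - cy_top + 1)
        rim_sup = float(cy_top - dy_top)
        rim_inf = float(dy_bot - cy_bot)
        cup_eps = ((cx, cy_top), (cx, cy_bot))

    total = cup_len + rim_sup + rim_inf
    cdr = cup_len / total
    rdr_sup = rim_sup / total
    rdr_inf = 1.0 - cdr - rdr_sup  # exact decomposition
    return DiscCupGeometry(
        disc_diameter_v=disc_d,
        cup_length_v=cup_len,
        rim_sup=rim_sup,
        rim_inf=rim_inf,
        cdr=cdr,
        rdr_sup=rdr_sup,
        rdr_inf=rdr_inf,
        disc_endpoints=disc_endpoints,
        cup_endpoints=cup_eps,
        flags=flags,
    )


def extract_geometry(roi: RoiPatch, seed: int = 0,
                     closing_radius: int = DEFAULT_CLOSING_RADIUS,
                     opening_radius: int = DEFAULT_OPENING_RADIUS) -> DiscCupGeometry:
    """Full classical pipeline on one valid ROI: vessel removal on both
    channels, disc then cup segmentation, geometry. Deterministic given seed."""
    if not roi.valid:
        raise ValueError("cannot extract features from an invalid ROI")
    red = remove_vessels(roi.pixels[..., 0], closing_radius)
    green = remove_vessels(roi.pixels[..., 1], closing_radius)
    disc_mask, disc_eps = segment_disc(red)
    cup_mask, cup_eps, degenerate = segment_cup(
        green, disc_mask, seed=seed, opening_radius=opening_radius
    )
    geom = compute_geometry(disc_mask, disc_eps, cup_mask, cup_eps)
    if degenerate:
        geom.flags.append("degenerate_clustering")
    return geom


def extract_features(roi: RoiPatch, seed: int = 0) -> np.ndarray:
    """Feature vector (cdr, rdr_sup, rdr_inf) for the SVM branch."""
    return extract_geometry(roi, seed=seed).feature_vector


class CdrFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of valid ROIs -> (n, 3) array of
    (cdr, rdr_sup, rdr_inf) features.

    ROIs whose segmentation fails produce a NaN row (callers decide the
    fallback; the ensemble falls back to the CNN label).
    """

    def __init__(self, seed=0, closing_radius=DEFAULT_CLOSING_RADIUS,
                 opening_radius=DEFAULT_OPENING_RADIUS):
        self.seed = seed
        self.closing_radius = closing_radius
        self.opening_radius = opening_radius

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        rows = []
        for roi in X:
            try:
                rows.append(
                    extract_geometry(
                        roi, self.seed, self.closing_radius, self.opening_radius
                    ).feature_vector
                )
            except (SegmentationFailure, ValueError):
                rows.append(np.full(3, np.nan))
        return np.asarray(rows)
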