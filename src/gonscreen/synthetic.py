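"""Synthetic fundus-image generator with analytically known disc/cup geometry.

Every downstream stage of the screening pipeline (ROI extraction, disc/cup
segmentation, CDR features, CNN, ensemble) is tested against images produced
here, because the true geometry — disc and cup masks, vertical cup-to-disc
ratio, superior/inferior rim widths — is known by construction.

The rendered scene is deliberately simple but exercises the pipeline's design:

* a dark reddish background,
* a bright elliptical optic disc whose **red** channel dominates everywhere
  inside the disc (so red-channel thresholding recovers the disc margin),
* a brighter inner cup whose **green** channel is elevated only inside the cup
  (so green-channel clustering recovers the cup),
* dark vessel polylines crossing the disc and cup (so vessel removal matters),
* global brightness gain, Gaussian blur and additive Gaussian noise.

Ground-truth masks are the pre-noise geometry.  Rendering is bit-deterministic
under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
import imageio.v3 as iio

NORMAL = "normal"
GLAUCOMA = "glaucoma"

# Pre-gain scene colors (R, G, B).  The disc saturates the red channel; the
# green channel separates cup (bright) from neuroretinal rim (moderate).
BACKGROUND_COLOR = (70.0, 28.0, 18.0)
DISC_COLOR = (250.0, 110.0, 40.0)
CUP_COLOR = (255.0, 235.0, 90.0)
VESSEL_COLOR = (60.0, 20.0, 15.0)

# Glaucomatous cups elongate vertically; the horizontal cup extent is kept a
# fixed fraction of the vertical one so the cup never dominates the disc area.
CUP_ASPECT = 0.85

DEFAULT_IMAGE_SIZE = 512
CDR_RANGE_GLAUCOMA = (0.65, 0.95)
CDR_RANGE_NORMAL = (0.25, 0.55)

MANIFEST_COLUMNS = ["path", "label", "split", "capture_valid", "cdr_true", "seed"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic fundus image.

    ``cdr_true`` is the vertical cup-to-disc ratio: cup vertical extent equals
    ``cdr_true * 2 * disc_radius_v``.  ``rim_split`` is the fraction of the
    non-cup vertical extent assigned to the superior rim, so
    superior rim + cup + inferior rim always equals the vertical disc diameter.
    """

    image_width: int = DEFAULT_IMAGE_SIZE
    image_height: int = DEFAULT_IMAGE_SIZE
    disc_center: tuple[float, float] = (256.0, 256.0)  # (x, y), 0-based
    disc_radius_v: float = 50.0
    disc_radius_h: float = 46.0
    cdr_true: float = 0.4
    rim_split: float = 0.5
    n_vessels: int = 5
    brightness_gain: float = 1.0
    blur_sigma: float = 0.8
    noise_sd: float = 8.0
    class_label: str = NORMAL
    capture_valid: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.cdr_true <= 1.0):
            raise ValueError(f"cdr_true must be in [0, 1], got {self.cdr_true}")
        if not (0.0 <= self.rim_split <= 1.0):
            raise ValueError(f"rim_split must be in [0, 1], got {self.rim_split}")
        if self.brightness_gain <= 0:
            raise ValueError("brightness_gain must be > 0")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if self.capture_valid and self.disc_center is not None:
            x, y = self.disc_center
            if (
                x - self.disc_radius_h < 0
                or x + self.disc_radius_h > self.image_width
                or y - self.disc_radius_v < 0
                or y + self.disc_radius_v > self.image_height
            ):
                raise ValueError(
                    "disc extends past image bounds but capture_valid is True"
                )


@dataclass
class GroundTruth:
    """Analytic truth for one rendered image (pre-noise geometry)."""

    disc_mask: np.ndarray
    cup_mask: np.ndarray
    cdr_true: float
    rdr_sup_true: float
    rdr_inf_true: float
    class_label: str
    capture_valid: bool

    def __post_init__(self):
        # vertical-meridian decomposition must hold exactly
        total = self.cdr_true + self.rdr_sup_true + self.rdr_inf_true
        if self.capture_valid and abs(total - 1.0) > 1e-9:
            raise ValueError(f"cdr + rdr_sup + rdr_inf = {total} != 1")


def _ellipse_mask(h, w, cx, cy, rx, ry):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _draw_vessels(img, spec, rng):
    """Dark polylines, 2-5 px wide, arcing vertically through the disc."""
    h, w = spec.image_height, spec.image_width
    cx, cy = spec.disc_center
    for _ in range(spec.n_vessels):
        x0 = cx + rng.uniform(-spec.disc_radius_h, spec.disc_radius_h)
        bow = rng.uniform(-0.25, 0.25)  # horizontal bowing of the arc
        width = rng.integers(2, 6)
        phase = rng.uniform(0, np.pi)
        ys = np.arange(0, h)
        xs = x0 + bow * (ys - cy) + 6.0 * np.sin(phase + ys / 40.0)
        mask = np.zeros((h, w), dtype=bool)
        for dy in range(-(width // 2), width - width // 2):
            xi = np.clip(np.round(xs) + dy, 0, w - 1).astype(int)
            mask[ys, xi] = True
        for c in range(3):
            img[..., c][mask] = VESSEL_COLOR[c]
    return img


def generate_fundus(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic fundus image and its analytic ground truth.

    Returns ``(image, truth)`` where ``image`` is an (H, W, 3) uint8 RGB array.
    Rendering order: background, disc, cup, vessels, then gain -> blur -> noise.
    Masks in ``truth`` are the pre-noise geometry.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width

    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        img[..., c] = BACKGROUND_COLOR[c]

    disc_mask = np.zeros((h, w), dtype=bool)
    cup_mask = np.zeros((h, w), dtype=bool)

    if spec.disc_center is not None:
        cx, cy = spec.disc_center
        rv, rh = spec.disc_radius_v, spec.disc_radius_h
        disc_mask = _ellipse_mask(h, w, cx, cy, rh, rv)
        for c in range(3):
            img[..., c][disc_mask] = DISC_COLOR[c]

        if spec.cdr_true > 0:
            # cup vertical semi-axis and center from cdr_true and rim_split:
            # sup_rim + cup + inf_rim = 2*rv with cup = cdr*2*rv
            cup_rv = spec.cdr_true * rv
            sup_rim = spec.rim_split * (1.0 - spec.cdr_true) * 2.0 * rv
            cup_cy = cy - rv + sup_rim + cup_rv
            cup_rh = max(spec.cdr_true * rh * CUP_ASPECT, 1.0)
            cup_mask = _ellipse_mask(h, w, cx, cup_cy, cup_rh, cup_rv) & disc_mask
            for c in range(3):
                img[..., c][cup_mask] = CUP_COLOR[c]

        img = _draw_vessels(img, spec, rng)

    img *= spec.brightness_gain
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    if spec.capture_valid:
        rdr_sup = spec.rim_split * (1.0 - spec.cdr_true)
        rdr_inf = (1.0 - spec.rim_split) * (1.0 - spec.cdr_true)
        # force exact decomposition against float rounding
        rdr_inf = 1.0 - spec.cdr_true - rdr_sup
        truth = GroundTruth(
            disc_mask, cup_mask, spec.cdr_true, rdr_sup, rdr_inf,
            spec.class_label, True,
        )
    else:
        truth = GroundTruth(
            disc_mask, cup_mask, spec.cdr_true, 0.0, 0.0, spec.class_label, False
        )
    return img, truth


def _random_spec(rng, label, capture_valid, image_size, cdr_range, seed):
    """Draw one SyntheticSpec from the study's image-population model."""
    half = image_size / 2.0
    rv = rng.uniform(42.0, 58.0)
    rh = rv * rng.uniform(0.85, 1.05)
    cdr = rng.uniform(*cdr_range)
    # normals keep near-symmetric rims; glaucomatous discs show focal
    # superior/inferior rim thinning (ISNT-rule violations)
    if label == GLAUCOMA:
        rim_split = rng.uniform(0.3, 0.7)
    else:
        rim_split = np.clip(rng.normal(0.5, 0.06), 0.35, 0.65)

    if capture_valid:
        cx = half + rng.uniform(-40, 40)
        cy = half + rng.uniform(-40, 40)
        center = (float(cx), float(cy))
    else:
        if rng.uniform() < 0.5:
            center = None  # disc absent from the field
        else:
            # disc hugging an image border: >= 25% of the width off-center,
            # so the clamped 256-crop cannot center it
            edge_off = rng.uniform(10.0, 60.0)
            side = rng.integers(0, 4)
            if side == 0:
                center = (edge_off, half + rng.uniform(-80, 80))
            elif side == 1:
                center = (image_size - edge_off, half + rng.uniform(-80, 80))
            elif side == 2:
                center = (half + rng.uniform(-80, 80), edge_off)
            else:
                center = (half + rng.uniform(-80, 80), image_size - edge_off)

    return SyntheticSpec(
        image_width=image_size,
        image_height=image_size,
        disc_center=center,
        disc_radius_v=float(rv),
        disc_radius_h=float(rh),
        cdr_true=float(cdr),
        rim_split=float(rim_split),
        n_vessels=int(rng.integers(4, 9)),
        brightness_gain=float(rng.uniform(0.85, 1.15)),
        blur_sigma=float(rng.uniform(0.5, 1.2)),
        noise_sd=float(rng.uniform(4.0, 10.0)),
        class_label=label,
        capture_valid=capture_valid,
        seed=seed,
    )


def generate_specs(
    n_images: int,
    glaucoma_fraction: float = 0.5,
    invalid_fraction: float = 0.0,
    seed: int = 0,
    image_size: int = DEFAULT_IMAGE_SIZE,
    cdr_range_glaucoma: tuple[float, float] = CDR_RANGE_GLAUCOMA,
    cdr_range_normal: tuple[float, float] = CDR_RANGE_NORMAL,
    style: dict | None = None,
) -> list[SyntheticSpec]:
    """Draw ``n_images`` specs with exact class/validity allocation.

    ``glaucoma_fraction`` and ``invalid_fraction`` are honoured exactly via
    rounding (``round(n * fraction)`` images get the minority flag).  ``style``
    optionally overrides capture-style fields (brightness_gain, blur_sigma,
    noise_sd) to emulate a different camera.
    """
    if not 0 <= glaucoma_fraction <= 1 or not 0 <= invalid_fraction <= 1:
        raise ValueError("fractions must be in [0, 1]")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    n_glaucoma = int(round(n_images * glaucoma_fraction))
    n_invalid = int(round(n_images * invalid_fraction))
    labels = [GLAUCOMA] * n_glaucoma + [NORMAL] * (n_images - n_glaucoma)
    validity = [False] * n_invalid + [True] * (n_images - n_invalid)
    rng.shuffle(labels)
    rng.shuffle(validity)

    specs = []
    for i, (label, valid) in enumerate(zip(labels, validity)):
        cdr_range = cdr_range_glaucoma if label == GLAUCOMA else cdr_range_normal
        img_seed = int(rng.integers(0, 2**31 - 1))
        spec = _random_spec(rng, label, valid, image_size, cdr_range, img_seed)
        if style:
            spec = SyntheticSpec(**{**asdict(spec), **style})
        specs.append(spec)
    return specs


def generate_dataset(
    out_dir: str,
    n_images: int,
    glaucoma_fraction: float = 0.5,
    invalid_fraction: float = 0.0,
    seed: int = 0,
    image_size: int = DEFAULT_IMAGE_SIZE,
    write_masks: bool = False,
    style: dict | None = None,
) -> pd.DataFrame:
    """Render a dataset to ``out_dir`` and return its manifest.

    Writes lossless PNGs plus ``manifest.csv`` with columns
    ``path,label,split,capture_valid,cdr_true,seed``.  Optionally writes the
    ground-truth disc/cup masks as 0/255 PNGs.
    """
    specs = generate_specs(
        n_images, glaucoma_fraction, invalid_fraction, seed, image_size, style=style
    )
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory not writable: {out_dir}")
    rows = []
    for i, spec in enumerate(specs):
        img, truth = generate_fundus(spec)
        name = f"img_{i:05d}.png"
        iio.imwrite(os.path.join(out_dir, name), img)
        if write_masks:
            iio.imwrite(
                os.path.join(out_dir, f"img_{i:05d}_disc.png"),
                truth.disc_mask.astype(np.uint8) * 255,
            )
            iio.imwrite(
                os.path.join(out_dir, f"img_{i:05d}_cup.png"),
                truth.cup_mask.astype(np.uint8) * 255,
            )
        rows.append(
            {
                "path": name,
                "label": spec.class_label,
                "split": "",
                "capture_valid": spec.capture_valid,
                "cdr_true": spec.cdr_true,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def measure_cdr_from_masks(disc_mask: np.ndarray, cup_mask: np.ndarray) -> float:
    """Brute-force vertical CDR from binary masks by pixel counting.

    Scans the vertical meridian through the disc centroid column for the
    topmost/bottommost on-pixels.  Serves as the independent oracle for both
    the generator and the segmentation stage.
    """
    if not disc_mask.any():
        raise ValueError("empty disc mask")
    cols = np.where(disc_mask.any(axis=0))[0]
    ccol = int(round(np.average(np.where(disc_mask)[1])))
    ccol = int(np.clip(ccol, cols.min(), cols.max()))
    disc_rows = np.where(disc_mask[:, ccol])[0]
    disc_len = disc_rows.max() - disc_rows.min() + 1
    if not cup_mask.any():
        return 0.0
    cup_ccol = int(round(np.average(np.where(cup_mask)[1])))
    cup_rows = np.where(cup_mask[:, cup_ccol])[0]
    cup_len = cup_rows.max() - cup_rows.min() + 1
    return float(cup_len) / float(disc_len)
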