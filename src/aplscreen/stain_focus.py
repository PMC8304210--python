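"""Leukocyte focusing on Romanowsky-stained blood-smear fields.

The focusing stage turns a raw RGB microscopy field into a list of
single-leukocyte crops ready for classification:

1. Reinhard-style color normalization against reference stain statistics,
   to suppress batch-to-batch staining variability.
2. Color deconvolution under the Beer-Lambert optical-density model into a
   methylene-blue (nucleus-avid) and an eosin (cytoplasm-avid) density map.
3. Binarization of the methylene-blue map (leukocyte nuclei are the only
   strongly basophilic objects in a peripheral smear), morphological
   clean-up, and connected-component bounding boxes.
4. Square, background-padded crops resized to the classifier input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.transform import resize

__all__ = [
    "SmearImage",
    "ColorStats",
    "StainMatrix",
    "StainMaps",
    "CellBox",
    "CellCrop",
    "DEFAULT_STAIN_MATRIX",
    "compute_color_stats",
    "normalize_color",
    "unmix_od",
    "deconvolve_stains",
    "binarize_leukocyte_map",
    "extract_cell_boxes",
    "crop_cells",
    "estimate_stain_vector",
    "focus_leukocytes",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SmearImage:
    """An RGB microscopy field, 8-bit, height x width x 3."""

    pixels: np.ndarray
    source_id: str = "field"
    pixel_space: str = "rgb"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"field too small: {px.shape[0]}x{px.shape[1]} (min 64x64)")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.pixel_space != "rgb":
            raise ValueError(f"unsupported pixel space {self.pixel_space!r}")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class ColorStats:
    """Per-channel mean/std of a field in ``space`` ('rgb' or 'lab')."""

    mean: np.ndarray
    std: np.ndarray
    space: str = "lab"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.std = np.asarray(self.std, dtype=float).reshape(3)
        if np.any(self.std < 0):
            raise ValueError("std components must be non-negative")
        if self.space not in ("rgb", "lab"):
            raise ValueError(f"unknown color space {self.space!r}")


@dataclass
class StainMatrix:
    """Two unit optical-density color vectors (rows: methylene blue, eosin)."""

    vectors: np.ndarray
    background_intensity: float = 255.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (2, 3):
            raise ValueError(f"stain matrix must be 2x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms <= 0):
            raise ValueError("stain vectors must be non-zero")
        v = v / norms[:, None]
        # reject (near-)parallel stain vectors: deconvolution would be singular
        cross = np.linalg.norm(np.cross(v[0], v[1]))
        if cross < 1e-6:
            raise ValueError("stain vectors are singular (parallel or nearly so)")
        if self.background_intensity <= 0:
            raise ValueError("background intensity must be positive")
        self.vectors = v

    @property
    def methylene_blue(self) -> np.ndarray:
        return self.vectors[0]

    @property
    def eosin(self) -> np.ndarray:
        return self.vectors[1]


@dataclass
class StainMaps:
    """Per-pixel stain densities recovered by color deconvolution."""

    methylene_blue: np.ndarray
    eosin: np.ndarray


@dataclass(frozen=True)
class CellBox:
    """0-based, half-open bounding box [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int
    area_px: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("box must have positive extent")
        if self.area_px > self.width * self.height:
            raise ValueError("component area cannot exceed box area")

    def iou(self, other: "CellBox") -> float:
        ix0 = max(self.x0, other.x0)
        iy0 = max(self.y0, other.y0)
        ix1 = min(self.x0 + self.width, other.x0 + other.width)
        iy1 = min(self.y0 + self.height, other.y0 + other.height)
        inter = max(0, ix1 - ix0) * max(0, iy1 - iy0)
        union = self.width * self.height + other.width * other.height - inter
        return inter / union if union else 0.0


@dataclass
class CellCrop:
    """A fixed-size RGB crop of a single cell."""

    pixels: np.ndarray
    origin_box: CellBox | None = None
    source_id: str = ""
    label: str | None = field(default=None)


# Default optical-density vectors for a Romanowsky-type stain pair.
# Methylene blue (basic, nucleus-avid) absorbs mostly red/green light; eosin
# (acidic, cytoplasm/erythrocyte-avid) absorbs mostly green. Rows are
# unit-normalized; override per batch when reference slides are available.
DEFAULT_STAIN_MATRIX = StainMatrix(
    vectors=np.array([[0.644, 0.717, 0.267], [0.093, 0.954, 0.283]]),
    background_intensity=255.0,
)

# offset inside the optical-density log; keeps OD finite on 8-bit zeros
OD_EPSILON = 1.0 / 255.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _to_space(pixels: np.ndarray, space: str) -> np.ndarray:
    if space == "rgb":
        return pixels.astype(np.float64)
    if space == "lab":
        return skcolor.rgb2lab(pixels.astype(np.float64) / 255.0)
    raise ValueError(f"unknown color space {space!r}")


def compute_color_stats(image: SmearImage, space: str = "lab") -> ColorStats:
    """Per-channel mean and standard deviation of a field in ``space``."""
    arr = _to_space(image.pixels, space)
    return ColorStats(mean=arr.mean(axis=(0, 1)), std=arr.std(axis=(0, 1)), space=space)


def normalize_color(image: SmearImage, reference: ColorStats) -> SmearImage:
    """Shift/scale each channel so its mean and std match ``reference``.

    Works in the reference's color space (Lab by default, the standard
    choice for stain-appearance transfer). A source channel with zero
    variance carries no transferable contrast and is set flat to the
    reference mean.
    """
    if not (np.all(np.isfinite(reference.mean)) and np.all(np.isfinite(reference.std))):
        raise ValueError("reference statistics must be finite")
    arr = _to_space(image.pixels, reference.space)
    mean = arr.mean(axis=(0, 1))
    std = arr.std(axis=(0, 1))
    out = np.empty_like(arr)
    for c in range(3):
        if std[c] == 0.0:
            out[..., c] = reference.mean[c]
        else:
            out[..., c] = (arr[..., c] - mean[c]) / std[c] * reference.std[c] + reference.mean[c]
    if reference.space == "lab":
        rgb = skcolor.lab2rgb(out) * 255.0
    else:
        rgb = out
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return SmearImage(pixels=rgb, source_id=image.source_id)


def optical_density(pixels: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Beer-Lambert optical density: OD = -log((I + eps) / I0) per channel."""
    i = np.asarray(pixels, dtype=np.float64)
    return -np.log((i + OD_EPSILON) / background_intensity)


def unmix_od(od: np.ndarray, stains: StainMatrix | None = None) -> np.ndarray:
    """Least-squares stain concentrations from optical densities.

    ``od`` is (..., 3); the result is (..., 2) with negative concentrations
    clipped to zero. This is the continuous-domain core of
    :func:`deconvolve_stains`.
    """
    stains = stains if stains is not None else DEFAULT_STAIN_MATRIX
    v = stains.vectors  # 2x3
    pinv = v.T @ np.linalg.inv(v @ v.T)  # right pseudo-inverse, 3x2
    conc = np.asarray(od, dtype=np.float64) @ pinv
    return np.clip(conc, 0.0, None)


def deconvolve_stains(image: SmearImage, stains: StainMatrix | None = None) -> StainMaps:
    """Unmix an RGB field into methylene-blue and eosin density maps.

    Per pixel the optical density is modeled as the linear combination
    OD = c_mb * v_mb + c_eo * v_eo; concentrations are recovered by
    least squares against the 2x3 stain matrix and clipped at zero.
    """
    stains = stains if stains is not None else DEFAULT_STAIN_MATRIX
    od = optical_density(image.pixels, stains.background_intensity)
    conc = unmix_od(od, stains)
    return StainMaps(methylene_blue=conc[..., 0], eosin=conc[..., 1])


def binarize_leukocyte_map(
    mb_map: np.ndarray,
    method: str = "multiotsu",
    min_area: int = 400,
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold the methylene-blue density map into a leukocyte mask.

    The mb histogram of a stained smear has three populations — unstained
    background (plus red cells, which take up almost no basic dye), the
    weakly basophilic leukocyte cytoplasm, and dense nuclear chromatin.
    ``method='multiotsu'`` (default) fits a 3-class Otsu split and keeps
    everything above the background class, so whole cells survive;
    ``'otsu'`` is the plain 2-class threshold (nuclei only, useful as an
    oracle on two-valued maps); ``'fixed'`` uses ``threshold``. A 3x3
    morphological opening removes speckle, holes are filled, and
    components smaller than ``min_area`` pixels are dropped. A constant
    (signal-free) map yields an empty mask rather than an error.
    """
    mb = np.asarray(mb_map, dtype=np.float64)
    if np.any(mb < 0):
        raise ValueError("density map must be non-negative")
    if method in ("otsu", "multiotsu"):
        if np.allclose(mb, mb.flat[0]):
            return np.zeros(mb.shape, dtype=bool)
        if method == "multiotsu":
            try:
                thr = threshold_multiotsu(mb, classes=3)[0]
            except ValueError:  # fewer than 3 populations: fall back
                thr = threshold_otsu(mb)
        else:
            thr = threshold_otsu(mb)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    mask = mb > thr
    mask = ndi.binary_opening(mask, structure=np.ones((3, 3), dtype=bool))
    mask = ndi.binary_fill_holes(mask)
    if min_area > 0:
        labeled = cc_label(mask, connectivity=2)
        counts = np.bincount(labeled.ravel())
        keep = counts >= min_area
        keep[0] = False
        mask = keep[labeled]
    return mask


def extract_cell_boxes(mask: np.ndarray, min_area: int = 400) -> list[CellBox]:
    """Bounding boxes of 8-connected mask components with area >= min_area.

    Boxes are 0-based half-open and sorted by (y0, x0).
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = cc_label(mask, connectivity=2)
    boxes = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        y0, x0, y1, x1 = region.bbox
        boxes.append(CellBox(x0=int(x0), y0=int(y0), width=int(x1 - x0),
                             height=int(y1 - y0), area_px=int(region.area)))
    boxes.sort(key=lambda b: (b.y0, b.x0))
    return boxes


def _modal_color(pixels: np.ndarray) -> np.ndarray:
    """Most frequent intensity per channel — a robust background estimate
    for smear fields, where background dominates the histogram."""
    return np.array([np.bincount(pixels[..., c].ravel(), minlength=256).argmax()
                     for c in range(3)], dtype=np.uint8)


def crop_cells(
    image: SmearImage,
    boxes: list[CellBox],
    pad_frac: float = 0.15,
    out_size: int = 224,
) -> list[CellCrop]:
    """Cut one square crop per box, background-padded, resized to out_size.

    Each box is expanded by ``pad_frac`` of its extent on every side and
    clamped to the image. The clamped crop is padded to square with the
    field's modal background color (no anisotropic stretch), then resized.
    """
    h, w = image.shape
    bg = _modal_color(image.pixels)
    crops: list[CellCrop] = []
    for box in boxes:
        if box.x0 < 0 or box.y0 < 0 or box.x0 + box.width > w or box.y0 + box.height > h:
            raise ValueError(f"box {box} lies outside the {h}x{w} image")
        px = int(round(box.width * pad_frac))
        py = int(round(box.height * pad_frac))
        x0, x1 = max(0, box.x0 - px), min(w, box.x0 + box.width + px)
        y0, y1 = max(0, box.y0 - py), min(h, box.y0 + box.height + py)
        patch = image.pixels[y0:y1, x0:x1]
        ph, pw = patch.shape[:2]
        side = max(ph, pw)
        square = np.empty((side, side, 3), dtype=np.uint8)
        square[:] = bg
        oy, ox = (side - ph) // 2, (side - pw) // 2
        square[oy:oy + ph, ox:ox + pw] = patch
        if side != out_size:
            resized = resize(square, (out_size, out_size, 3), order=1,
                             preserve_range=True, anti_aliasing=side > out_size)
            resized = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
        else:
            resized = square
        crops.append(CellCrop(pixels=resized, origin_box=box, source_id=image.source_id))
    return crops


def estimate_stain_vector(image: SmearImage, background_intensity: float = 255.0,
                          od_floor: float = 0.15) -> np.ndarray:
    """Estimate a unit OD color vector from a field stained with one pure dye.

    Averages the optical-density direction over pixels with meaningful
    absorbance (OD norm above ``od_floor``), which excludes background.
    """
    od = optical_density(image.pixels, background_intensity).reshape(-1, 3)
    norms = np.linalg.norm(od, axis=1)
    keep = od[norms > od_floor]
    if keep.size == 0:
        raise ValueError("no stained pixels above the OD floor")
    v = keep.mean(axis=0)
    return v / np.linalg.norm(v)


def focus_leukocytes(
    image: SmearImage,
    reference: ColorStats | None = None,
    stains: StainMatrix | None = None,
    min_area: int = 400,
    pad_frac: float = 0.15,
    out_size: int = 224,
) -> tuple[list[CellBox], list[CellCrop]]:
    """Full focusing stage: normalize, deconvolve, binarize, box, crop."""
    working = normalize_color(image, reference) if reference is not None else image
    maps = deconvolve_stains(working, stains)
    mask = binarize_leukocyte_map(maps.methylene_blue, min_area=min_area)
    boxes = extract_cell_boxes(mask, min_area=min_area)
    crops = crop_cells(working, boxes, pad_frac=pad_frac, out_size=out_size)
    return boxes, crops
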