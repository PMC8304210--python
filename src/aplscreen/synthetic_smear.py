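"""Synthetic Romanowsky-stained smear fields with known ground truth.

The generator renders blood-smear fields through the same Beer-Lambert
forward model the focusing stage inverts: each cell deposits methylene-blue
(nucleus/basophilic-granule) and eosin (cytoplasm/erythrocyte) density, the
two density maps are mixed through the stain matrix into optical density,
and transmitted RGB intensity is I = I0 * exp(-OD) plus Gaussian sensor
noise. Red cells are small, pale, eosin-dominant disks with central pallor;
leukocytes are larger cells whose nucleus morphology and granulation carry
the class signal:

* lymphocyte   — round, high nucleus:cell ratio, scant agranular cytoplasm
* neutrophil   — 3-5 connected nuclear lobes, fine faint granules
* monocyte     — large cell, kidney-shaped (indented) nucleus
* eosinophil   — bilobed nucleus, coarse bright eosin granules
* basophil     — dense coarse methylene-blue granules obscuring the nucleus
* promyelocyte — large cell, eccentric nucleus, heavy mixed granulation and
  a rod-shaped inclusion motif (the Auer-rod cue of abnormal promyelocytes)

Cells are placed without overlap by rejection sampling; every random draw
flows from one seed through ``numpy.random.SeedSequence`` spawning, so
fields, labels and crops are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stain_focus import (
    DEFAULT_STAIN_MATRIX,
    CellBox,
    SmearImage,
    StainMatrix,
)
from .compact_net.model import CLASS_NAMES

__all__ = ["SmearRecipe", "GroundTruth", "generate_smear", "generate_cell_dataset",
           "CLASS_NAMES"]


@dataclass(frozen=True)
class SmearRecipe:
    """Study conditions for one synthetic field."""

    image_size: tuple[int, int] = (384, 512)
    n_leukocytes: int = 10
    n_red_cells: int = 60
    class_mix: tuple[float, ...] = (1 / 6,) * 6
    stain_matrix: StainMatrix = field(default_factory=lambda: DEFAULT_STAIN_MATRIX)
    noise_sd: float = 2.0
    seed: int = 0
    leukocyte_radius: tuple[float, float] = (26.0, 34.0)
    red_cell_radius: tuple[float, float] = (10.0, 14.0)
    allow_overlap: bool = False

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class mix must sum to 1")
        if self.n_leukocytes < 0 or self.n_red_cells < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class GroundTruth:
    boxes: list[CellBox]
    labels: list[str]
    cell_params: list[dict]


# ---------------------------------------------------------------------------
# density painting helpers (all operate on float64 H x W maps)
# ---------------------------------------------------------------------------

def _disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    y, x = np.ogrid[:h, :w]
    d2 = (y - cy) ** 2 + (x - cx) ** 2
    # soft 1.5-px edge so quantized images do not alias
    return np.clip((r - np.sqrt(d2)) / 1.5 + 0.5, 0.0, 1.0)


def _paint_granules(mb: np.ndarray, eo: np.ndarray, rng: np.random.Generator,
                    cy: float, cx: float, r: float, n: int, dot_r: float,
                    mb_density: float, eo_density: float) -> None:
    h, w = mb.shape
    for _ in range(n):
        ang = rng.uniform(0, 2 * np.pi)
        rad = r * np.sqrt(rng.uniform(0, 1.0))
        gy, gx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        dot = _disk(h, w, gy, gx, dot_r * rng.uniform(0.7, 1.3))
        if mb_density:
            mb += mb_density * dot
        if eo_density:
            eo += eo_density * dot


def _paint_red_cell(mb: np.ndarray, eo: np.ndarray, rng: np.random.Generator,
                    cy: float, cx: float, r: float) -> None:
    body = _disk(*mb.shape, cy, cx, r)
    pallor = _disk(*mb.shape, cy, cx, r * 0.45)
    eo += 0.35 * body - 0.20 * pallor  # biconcave look: pale center


#: Maximum total stain density a pixel can accumulate (dye saturation).
DENSITY_CAP = 2.2

#: Relative cell size per class (monocytes/promyelocytes are the largest
#: peripheral leukocytes, lymphocytes the smallest).
CLASS_RADIUS_FACTOR = {
    "basophil": 0.85,
    "eosinophil": 0.95,
    "lymphocyte": 0.72,
    "monocyte": 1.12,
    "promyelocyte": 1.20,
    "neutrophil": 0.95,
}


def _paint_leukocyte(mb: np.ndarray, eo: np.ndarray, rng: np.random.Generator,
                     label: str, cy: float, cx: float, r: float) -> dict:
    h, w = mb.shape
    params: dict = {"label": label, "cy": cy, "cx": cx, "radius": r}
    cyto = _disk(h, w, cy, cx, r)
    if label == "lymphocyte":
        # thin rim of deep-blue cytoplasm around a round nucleus
        eo += 0.05 * cyto
        mb += 0.30 * cyto
        nr = 0.82 * r
        mb += 1.10 * _disk(h, w, cy, cx, nr)
        params["nucleus"] = {"shape": "round", "radius": nr}
    elif label == "neutrophil":
        eo += 0.24 * cyto  # pale pink cytoplasm
        mb += 0.26 * cyto
        n_lobes = int(rng.integers(3, 6))
        ang0 = rng.uniform(0, 2 * np.pi)
        lobe_r = 0.30 * r
        for i in range(n_lobes):
            ang = ang0 + 2 * np.pi * i / n_lobes
            ly = cy + 0.42 * r * np.sin(ang)
            lx = cx + 0.42 * r * np.cos(ang)
            mb += 1.0 * _disk(h, w, ly, lx, lobe_r)
        _paint_granules(mb, eo, rng, cy, cx, r * 0.9, 20, 1.0, 0.04, 0.05)
        params["nucleus"] = {"shape": "lobed", "n_lobes": n_lobes}
    elif label == "monocyte":
        eo += 0.04 * cyto
        mb += 0.42 * cyto  # abundant gray-blue cytoplasm
        nr = 0.60 * r
        body = _disk(h, w, cy - 0.05 * r, cx, nr)
        notch = _disk(h, w, cy - 0.05 * r + 0.45 * nr, cx + 0.55 * nr, 0.62 * nr)
        mb += 0.85 * np.clip(body - notch, 0.0, None)
        params["nucleus"] = {"shape": "kidney", "radius": nr}
    elif label == "eosinophil":
        eo += 0.30 * cyto
        mb += 0.26 * cyto
        for side in (-1, 1):
            mb += 0.95 * _disk(h, w, cy, cx + side * 0.38 * r, 0.33 * r)
        _paint_granules(mb, eo, rng, cy, cx, r * 0.9, 45, 1.8, 0.0, 0.70)
        params["nucleus"] = {"shape": "bilobed"}
    elif label == "basophil":
        eo += 0.04 * cyto
        mb += 0.45 * cyto
        mb += 0.50 * _disk(h, w, cy, cx, 0.55 * r)
        _paint_granules(mb, eo, rng, cy, cx, r * 0.85, 55, 1.9, 0.90, 0.0)
        params["nucleus"] = {"shape": "obscured"}
    elif label == "promyelocyte":
        eo += 0.18 * cyto
        mb += 0.28 * cyto
        nr = 0.58 * r
        ny, nx = cy - 0.18 * r, cx - 0.12 * r  # eccentric nucleus
        mb += 1.00 * _disk(h, w, ny, nx, nr)
        _paint_granules(mb, eo, rng, cy, cx, r * 0.9, 40, 1.5, 0.35, 0.35)
        # rod-shaped inclusion: dense line segment in the cytoplasm
        ang = rng.uniform(0, 2 * np.pi)
        length = 0.55 * r
        for t in np.linspace(-0.5, 0.5, max(int(length), 8)):
            ry = cy + 0.35 * r * np.sin(ang + np.pi / 2) + t * length * np.sin(ang)
            rx = cx + 0.35 * r * np.cos(ang + np.pi / 2) + t * length * np.cos(ang)
            mb += 0.5 * _disk(h, w, ry, rx, 1.3)
            eo += 0.3 * _disk(h, w, ry, rx, 1.3)
        params["nucleus"] = {"shape": "eccentric", "radius": nr, "rod_angle": float(ang)}
    else:
        raise ValueError(f"unknown leukocyte class {label!r}")
    return params


def _saturate(mb: np.ndarray, eo: np.ndarray) -> None:
    """Dye saturation: cap the total deposited density in place so the
    rendered 8-bit intensities stay clear of the quantization floor (total
    OD beyond ~2.2 is unresolvable at 255 gray levels anyway)."""
    total = mb + eo
    over = total > DENSITY_CAP
    if np.any(over):
        scale = DENSITY_CAP / total[over]
        mb[over] *= scale
        eo[over] *= scale


def _render(mb: np.ndarray, eo: np.ndarray, stains: StainMatrix,
            noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    conc = np.stack([mb, eo], axis=-1)
    od = conc @ stains.vectors  # H x W x 3 optical density
    img = stains.background_intensity * np.exp(-od)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _place_cells(rng: np.random.Generator, h: int, w: int, radii: list[float],
                 allow_overlap: bool, max_tries: int = 4000) -> list[tuple[float, float]]:
    centers: list[tuple[float, float, float]] = []
    placed: list[tuple[float, float]] = []
    for r in radii:
        for attempt in range(max_tries):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if allow_overlap or all((cy - oy) ** 2 + (cx - ox) ** 2 >= (r + orr) ** 2
                                    for oy, ox, orr in centers):
                centers.append((cy, cx, r))
                placed.append((cy, cx))
                break
        else:
            raise RuntimeError(
                "could not place all cells without overlap; reduce the cell "
                "counts or enlarge the field")
    return placed


def _compose(recipe: SmearRecipe) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Deposit the noise-free density maps and ground truth for a recipe."""
    h, w = recipe.image_size
    root = np.random.SeedSequence(recipe.seed)
    rng_place, rng_cells, _ = (np.random.default_rng(s) for s in root.spawn(3))
    mb = np.zeros((h, w))
    eo = np.zeros((h, w))

    labels = [CLASS_NAMES[i] for i in
              rng_cells.choice(6, size=recipe.n_leukocytes, p=recipe.class_mix)]
    leuk_radii = [CLASS_RADIUS_FACTOR[lab] * rng_cells.uniform(*recipe.leukocyte_radius)
                  for lab in labels]
    red_radii = [rng_cells.uniform(*recipe.red_cell_radius)
                 for _ in range(recipe.n_red_cells)]
    centers = _place_cells(rng_place, h, w, leuk_radii + red_radii,
                           recipe.allow_overlap)
    leuk_centers = centers[:recipe.n_leukocytes]
    red_centers = centers[recipe.n_leukocytes:]

    for (cy, cx), r in zip(red_centers, red_radii):
        _paint_red_cell(mb, eo, rng_cells, cy, cx, r)
    boxes, cell_params = [], []
    for label, (cy, cx), r in zip(labels, leuk_centers, leuk_radii):
        params = _paint_leukocyte(mb, eo, rng_cells, label, cy, cx, r)
        x0, y0 = max(0, int(np.floor(cx - r))), max(0, int(np.floor(cy - r)))
        x1, y1 = min(w, int(np.ceil(cx + r))), min(h, int(np.ceil(cy + r)))
        area = int(np.round(np.pi * r * r))
        boxes.append(CellBox(x0=x0, y0=y0, width=x1 - x0, height=y1 - y0,
                             area_px=min(area, (x1 - x0) * (y1 - y0))))
        cell_params.append(params)
    _saturate(mb, eo)
    return mb, eo, GroundTruth(boxes=boxes, labels=labels, cell_params=cell_params)


def generate_smear(recipe: SmearRecipe = SmearRecipe()) -> tuple[SmearImage, GroundTruth]:
    """Render one field plus ground-truth boxes/labels for its leukocytes."""
    mb, eo, truth = _compose(recipe)
    rng_noise = np.random.default_rng(np.random.SeedSequence(recipe.seed).spawn(3)[2])
    pixels = _render(mb, eo, recipe.stain_matrix, recipe.noise_sd, rng_noise)
    image = SmearImage(pixels=pixels, source_id=f"synthetic_{recipe.seed:06d}")
    return image, truth


def nominal_density_maps(recipe: SmearRecipe) -> tuple[np.ndarray, np.ndarray]:
    """The noise-free stain-density maps a recipe would deposit (for
    checking that deconvolution inverts the forward model)."""
    mb, eo, _ = _compose(recipe)
    return mb, eo


def generate_cell_dataset(
    n_per_class: int | None = 100,
    seed: int = 0,
    class_sizes: tuple[int, ...] | None = None,
    crop_size: int = 224,
    noise_sd: float = 2.0,
    stain_matrix: StainMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled single-cell crops (N x crop x crop x 3 uint8, N labels).

    ``class_sizes`` overrides ``n_per_class`` for imbalanced datasets (for
    example the clinical class proportions). Cells are centered with a
    small jitter; a few red cells share the frame as context.
    """
    if class_sizes is None:
        if n_per_class is None or n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        class_sizes = (n_per_class,) * 6
    if len(class_sizes) != 6:
        raise ValueError("class_sizes must have 6 entries")
    stains = stain_matrix if stain_matrix is not None else DEFAULT_STAIN_MATRIX
    total = int(sum(class_sizes))
    crops = np.empty((total, crop_size, crop_size, 3), dtype=np.uint8)
    labels = np.empty(total, dtype=np.int64)
    seeds = np.random.SeedSequence(seed).spawn(total)
    idx = 0
    for cls, size in enumerate(class_sizes):
        for _ in range(size):
            rng = np.random.default_rng(seeds[idx])
            mb = np.zeros((crop_size, crop_size))
            eo = np.zeros((crop_size, crop_size))
            scale = crop_size / 224.0
            r = CLASS_RADIUS_FACTOR[CLASS_NAMES[cls]] * rng.uniform(58.0, 70.0) * scale
            cy = crop_size / 2 + rng.uniform(-8, 8) * scale
            cx = crop_size / 2 + rng.uniform(-8, 8) * scale
            # a little red-cell context at the frame edge
            for _ in range(int(rng.integers(2, 5))):
                ang = rng.uniform(0, 2 * np.pi)
                rr = rng.uniform(24, 32) * scale
                dist = rng.uniform(0.85, 1.05) * (crop_size / 2)
                _paint_red_cell(mb, eo, rng, cy + dist * np.sin(ang),
                                cx + dist * np.cos(ang), rr)
            _paint_leukocyte(mb, eo, rng, CLASS_NAMES[cls], cy, cx, r)
            _saturate(mb, eo)
            crops[idx] = _render(mb, eo, stains, noise_sd, rng)
            labels[idx] = cls
            idx += 1
    return crops, labels
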