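"""Slide tiling and Macenko stain/brightness normalization.

A slide image is parcellated into a non-overlapping grid of square tiles;
tiles whose grayscale standard deviation is at or below a threshold carry no
tissue and are rejected, and a slide with fewer than ``min_tiles`` surviving
tiles is discarded entirely.

Stain normalization follows the Macenko procedure: pixels are mapped to
optical density (OD), background pixels below an OD floor are removed, the
two stain directions are taken as the angular extremes of the OD cloud
projected onto its top-2 principal plane, and concentrations are rescaled to a
reference image's robust maxima.  Brightness normalization maps each tile's
white point (its 99th-percentile luminance — in tissue tiles the white comes
from lumens and gaps) to the reference's before OD conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "TileSet",
    "StainNormalizer",
    "SlideRejected",
    "DegenerateStainError",
    "extract_tiles",
    "fit_normalizer",
    "normalize_tile",
    "read_slide_image",
    "write_tileset",
]

_GRAY = np.array([0.299, 0.587, 0.114])


class SlideRejected(Exception):
    """A slide failed tiling-level quality control; carries the reason."""

    def __init__(self, slide_id: str, reason: str):
        self.slide_id = slide_id
        self.reason = reason
        super().__init__(f"{slide_id}: {reason}")


class DegenerateStainError(ValueError):
    """The reference image has no usable two-stain structure."""


@dataclass
class TileSet:
    """Filtered tiles of one slide on a fixed grid (0-based row/col indices)."""

    slide_id: str
    patient_id: str
    tiles: list[tuple[int, int, np.ndarray]]
    tile_size: int
    mpp: float
    n_rejected: int

    def __len__(self) -> int:
        return len(self.tiles)

    def tile_array(self) -> np.ndarray:
        return np.stack([t for _, _, t in self.tiles])


@dataclass
class StainNormalizer:
    """Fitted Macenko reference: stain matrix, concentration scale, brightness."""

    stain_matrix: np.ndarray  # (3, 2), unit columns: (hematoxylin, eosin)
    max_concentrations: np.ndarray  # (2,), 99th percentile reference scale
    brightness_reference: float  # 99th-percentile (white-point) luminance of the reference
    od_floor: float = 0.15


def extract_tiles(
    image: np.ndarray,
    slide_id: str = "slide",
    patient_id: str = "patient",
    tile_size: int = 256,
    std_threshold: float = 5.0,
    min_tiles: int = 10,
    mpp: float | None = 0.5,
) -> TileSet:
    """Grid-tile a slide image and keep tiles with grayscale std > threshold.

    Partial tiles at the right/bottom edges are dropped.  Raises
    :class:`SlideRejected` when resolution metadata is missing or fewer than
    ``min_tiles`` tiles survive the filter.
    """
    if mpp is None:
        raise SlideRejected(slide_id, "missing MPP metadata")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise IOError(f"{slide_id}: expected an RGB image, got {image.shape}")
    h, w = image.shape[:2]
    n_rows, n_cols = h // tile_size, w // tile_size
    gray = image.astype(np.float64) @ _GRAY
    kept: list[tuple[int, int, np.ndarray]] = []
    n_rejected = 0
    for r in range(n_rows):
        for c in range(n_cols):
            sl = (slice(r * tile_size, (r + 1) * tile_size),
                  slice(c * tile_size, (c + 1) * tile_size))
            if gray[sl].std() > std_threshold:
                kept.append((r, c, np.ascontiguousarray(image[sl])))
            else:
                n_rejected += 1
    if len(kept) < min_tiles:
        raise SlideRejected(
            slide_id,
            f"only {len(kept)} tiles passed the std filter (< {min_tiles})",
        )
    return TileSet(slide_id, patient_id, kept, tile_size, float(mpp), n_rejected)


def _to_od(rgb: np.ndarray, white: float) -> np.ndarray:
    return -np.log(np.maximum(rgb.astype(np.float64), 1.0) / white)


def fit_normalizer(
    reference: np.ndarray,
    od_floor: float = 0.15,
    angle_percentile: float = 1.0,
    concentration_percentile: float = 99.0,
) -> StainNormalizer:
    """Fit Macenko stain vectors and concentration scale on a reference image.

    The hematoxylin column is the extreme with the larger red OD component
    (hematoxylin absorbs red more than eosin does).
    """
    ref = np.asarray(reference).reshape(-1, 3)
    luminance = ref.astype(np.float64) @ _GRAY
    white = float(np.percentile(luminance, 99))
    if white < 1:
        raise DegenerateStainError("reference image is black")
    od = _to_od(ref, white)
    fg = od[(od > od_floor).any(axis=1)]
    if len(fg) < 100:
        raise DegenerateStainError("too few stained pixels above the OD floor")

    # uncentered SVD: the top-2 right singular vectors span the stain plane
    _, svals, vt = np.linalg.svd(fg, full_matrices=False)
    if svals[1] < 1e-6 * max(svals[0], 1e-12):
        raise DegenerateStainError("OD cloud has fewer than two stain directions")
    plane = vt[:2].T  # (3, 2)
    # orient the plane so projections land in a half-plane
    for j in range(2):
        if plane[:, j].sum() < 0:
            plane[:, j] = -plane[:, j]
    proj = fg @ plane
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, angle_percentile)
    hi = np.percentile(angles, 100 - angle_percentile)
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    # stain vectors point into the positive octant
    v1 = np.abs(v1) / np.linalg.norm(v1)
    v2 = np.abs(v2) / np.linalg.norm(v2)
    if v1[0] < v2[0]:
        v1, v2 = v2, v1
    stain_matrix = np.column_stack([v1, v2])

    conc, *_ = np.linalg.lstsq(stain_matrix, fg.T, rcond=None)
    max_conc = np.percentile(np.maximum(conc, 0), concentration_percentile, axis=1)
    if (max_conc <= 0).any():
        raise DegenerateStainError("degenerate concentration scale")
    return StainNormalizer(stain_matrix, max_conc, white, od_floor)


def normalize_tile(
    tile: np.ndarray, normalizer: StainNormalizer
) -> tuple[np.ndarray, bool]:
    """Map one tile to the reference stain appearance.

    Returns ``(tile_out, ok)``; a degenerate tile (no stained pixels) is
    returned unchanged with ``ok=False`` and a warning.
    """
    tile = np.asarray(tile)
    shape = tile.shape
    flat = tile.reshape(-1, 3)
    luminance = flat.astype(np.float64) @ _GRAY
    white = float(np.percentile(luminance, 99))
    if white < 1:
        warnings.warn("degenerate (black) tile left unnormalized")
        return tile, False
    od = _to_od(flat, white)
    fg_mask = (od > normalizer.od_floor).any(axis=1)
    if fg_mask.sum() < 50:
        warnings.warn("tile has no stained pixels; left unnormalized")
        return tile, False

    conc, *_ = np.linalg.lstsq(normalizer.stain_matrix, od.T, rcond=None)
    conc = np.maximum(conc, 0)
    tile_max = np.percentile(conc[:, fg_mask], 99, axis=1)
    scale = np.where(tile_max > 1e-8, normalizer.max_concentrations / np.maximum(tile_max, 1e-8), 1.0)
    od_norm = (normalizer.stain_matrix @ (conc * scale[:, None])).T
    rgb = normalizer.brightness_reference * np.exp(-od_norm)
    out = np.clip(np.rint(rgb), 0, 255).astype(np.uint8).reshape(shape)
    return out, True


def read_slide_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF slide image into an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_tileset(tileset: TileSet, out_dir: str | Path) -> Path:
    """Write tile PNGs and a per-tile manifest TSV (slide_id, row, col, kept)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r, c, tile in tileset.tiles:
        path = out / f"{tileset.slide_id}_r{r:03d}_c{c:03d}.png"
        Image.fromarray(tile).save(path)
        rows.append((tileset.slide_id, r, c, True, float((tile.astype(np.float64) @ _GRAY).std())))
    manifest = out / f"{tileset.slide_id}_tiles.tsv"
    pd.DataFrame(
        rows, columns=["slide_id", "row", "col", "kept", "std"]
    ).to_csv(manifest, sep="\t", index=False)
    return manifest
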