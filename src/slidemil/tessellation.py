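"""Tissue masking and grid tessellation of slide images.

A slide is first downsampled (area averaging, default factor 32), the
thumbnail's HSV saturation channel is thresholded with Otsu's method
(background on H&E slides is near-white and saturation-poor, tissue is
colourful), and the full-resolution slide is then cut into a non-overlapping
grid of square tiles.  A tile is retained only if the mask cells covering it
are tissue at a fraction >= the configured threshold; the default threshold
of 1.0 keeps fully-tissue tiles only, so the classifier never sees
background.

Conventions: coordinates are 0-based with half-open tile extents; tiles are
indexed row-major over the full grid and listed in (y, x) order; partial edge
tiles are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.color import rgb2hsv

DEFAULT_DOWNSAMPLE = 32
DEFAULT_TISSUE_THRESHOLD = 1.0
_OTSU_BINS = 256


@dataclass
class TissueMask:
    """Binary tissue mask at thumbnail resolution.

    ``otsu_threshold`` is on the saturation scale [0, 1]; a pixel is tissue
    iff S >= otsu_threshold, so re-applying the stored threshold reproduces
    the mask.  ``degenerate`` flags a zero-variance saturation channel, for
    which the mask is all-background.
    """

    mask: np.ndarray
    downsample_factor: int
    otsu_threshold: float
    degenerate: bool = False


@dataclass
class TileRecord:
    """One retained grid tile: index n (row-major), full-resolution origin
    (x, y) with half-open ``tile_px`` extent, and its mask tissue fraction.
    ``label`` carries the annotated per-tile class when available."""

    slide_id: str
    n: int
    x: int
    y: int
    tile_px: int
    tissue_fraction: float
    label: Optional[int] = None


def build_thumbnail(slide_image: np.ndarray, factor: int) -> np.ndarray:
    """Area-averaged downsample by ``factor``; output dims = ceil(dims/factor).

    Partial edge blocks average over the pixels actually present.  factor=1
    returns the input values unchanged (as float64).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    img = np.asarray(slide_image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty slide image")
    if img.ndim == 2:
        img = img[:, :, None]
    h, w = img.shape[:2]
    row_starts = np.arange(0, h, factor)
    col_starts = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(img, row_starts, axis=0), col_starts, axis=1)
    row_counts = np.minimum(row_starts + factor, h) - row_starts
    col_counts = np.minimum(col_starts + factor, w) - col_starts
    counts = np.outer(row_counts, col_counts)[:, :, None]
    thumb = sums / counts
    return thumb[:, :, 0] if slide_image.ndim == 2 else thumb


def _saturation(thumbnail: np.ndarray) -> np.ndarray:
    thumb = np.asarray(thumbnail, dtype=np.float64)
    if thumb.ndim != 3 or thumb.shape[2] != 3:
        raise ValueError("expected an RGB thumbnail")
    return rgb2hsv(np.clip(thumb / 255.0, 0.0, 1.0))[:, :, 1]


def otsu_threshold_bin(counts: np.ndarray) -> int:
    """Otsu's threshold on a histogram: the bin index t* maximising the
    between-class variance of the split (bins <= t) vs (bins > t), ties
    broken toward the lower threshold."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    centers = np.arange(len(counts), dtype=np.float64)
    w0 = np.cumsum(counts)
    w1 = total - w0
    mu0 = np.cumsum(counts * centers)
    mu_t = mu0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu0 / w0
        m1 = (mu_t - mu0) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)
    return int(np.argmax(sigma_b))


def otsu_tissue_mask(thumbnail: np.ndarray) -> TissueMask:
    """Tissue mask via Otsu's thresholding on the HSV saturation channel.

    The saturation values are histogrammed into 256 bins over [0, 1];
    tissue = high saturation.  A zero-variance channel (e.g. an all-white
    thumbnail) yields an all-background mask with the degenerate flag set.
    """
    s = _saturation(thumbnail)
    q = np.minimum((s * _OTSU_BINS).astype(np.int64), _OTSU_BINS - 1)
    counts = np.bincount(q.ravel(), minlength=_OTSU_BINS)
    if np.count_nonzero(counts) <= 1:
        warnings.warn("degenerate Otsu input: zero-variance saturation channel")
        return TissueMask(
            mask=np.zeros(s.shape, dtype=bool),
            downsample_factor=1,
            otsu_threshold=1.0,
            degenerate=True,
        )
    t_star = otsu_threshold_bin(counts)
    threshold = (t_star + 1) / _OTSU_BINS
    return TissueMask(
        mask=s >= threshold, downsample_factor=1, otsu_threshold=float(threshold)
    )


def slide_tissue_mask(
    slide_image: np.ndarray, factor: int = DEFAULT_DOWNSAMPLE
) -> TissueMask:
    """Convenience: thumbnail at ``factor`` then Otsu mask, recording the factor."""
    mask = otsu_tissue_mask(build_thumbnail(slide_image, factor))
    mask.downsample_factor = factor
    return mask


def extract_tiles(
    slide_image: np.ndarray,
    mask: TissueMask,
    tile_px: int,
    tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD,
    slide_id: str = "",
) -> list[TileRecord]:
    """Non-overlapping grid tiles whose mask coverage is tissue at a fraction
    >= ``tissue_threshold``.

    The tissue fraction of a tile is the mean of the downsampled mask cells
    it covers, which is exact when ``tile_px`` is a multiple of the mask's
    downsample factor (enforced).  Tiles are returned ordered by (y, x);
    their index ``n`` is the row-major position in the full grid so it maps
    1:1 onto planted synthetic cell labels.
    """
    if not (0.0 < tissue_threshold <= 1.0):
        raise ValueError("tissue_threshold must be in (0, 1]")
    f = mask.downsample_factor
    if tile_px % f != 0:
        raise ValueError(f"tile_px={tile_px} must be a multiple of the mask factor {f}")
    h, w = slide_image.shape[:2]
    n_rows, n_cols = h // tile_px, w // tile_px
    if n_rows == 0 or n_cols == 0:
        warnings.warn("slide smaller than one tile; no tiles extracted")
        return []
    cells = tile_px // f
    m = mask.mask.astype(np.float64)
    records = []
    for r in range(n_rows):
        for c in range(n_cols):
            block = m[r * cells : (r + 1) * cells, c * cells : (c + 1) * cells]
            frac = float(block.mean())
            if frac >= tissue_threshold:
                records.append(
                    TileRecord(
                        slide_id=slide_id,
                        n=r * n_cols + c,
                        x=c * tile_px,
                        y=r * tile_px,
                        tile_px=tile_px,
                        tissue_fraction=frac,
                    )
                )
    return records


def tile_pixels(slide_image: np.ndarray, records: list[TileRecord]) -> np.ndarray:
    """Stack the pixel arrays of the given tiles: (n_tiles, tile_px, tile_px, 3)."""
    if not records:
        t = 0
        return np.empty((0, t, t, 3), dtype=slide_image.dtype)
    return np.stack(
        [slide_image[r.y : r.y + r.tile_px, r.x : r.x + r.tile_px] for r in records]
    )


def annotate_tiles(records: list[TileRecord], label_mask: np.ndarray) -> None:
    """Attach per-tile labels from a full-resolution label mask (0=background,
    1..3=class).  The tile label is the most severe class within its extent."""
    for r in records:
        block = label_mask[r.y : r.y + r.tile_px, r.x : r.x + r.tile_px]
        lab = int(block.max())
        r.label = lab if lab > 0 else None
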