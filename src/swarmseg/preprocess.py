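"""Shared preprocessing front-end for all six segmentation scenarios.

Medical images arrive with uneven illumination and low local contrast, so
every method in this package sees the same front-end: luminance grayscale
conversion, clip-limited adaptive histogram equalization (CLAHE), and — for
dermoscopic colour images — removal of occluding hair curves.

The grayscale conversion uses the 0.3/0.59/0.11 luminance weights,

    G = 0.3 R + 0.59 G + 0.11 B,

rounded half-up to 8-bit.  The enhancement step tiles the image into
regions, clips each region's histogram at ``clip_limit_multiplier`` times
the average bin occupancy (region pixel count / number of bins),
redistributes the clipped excess uniformly, equalizes through the clipped
CDF and blends neighbouring region mappings bilinearly — the classic CLAHE
construction, implemented here so the clip rule and the rounding convention
are exactly the documented ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import black_tophat, dilation, disk

__all__ = [
    "EnhanceParams",
    "FormatError",
    "to_grayscale",
    "average_pixels",
    "enhance",
    "remove_hair",
]

logger = logging.getLogger(__name__)

GRAY_WEIGHTS = (0.3, 0.59, 0.11)


class FormatError(ValueError):
    """Input image has an unsupported layout (e.g. channel count)."""


@dataclass(frozen=True)
class EnhanceParams:
    """CLAHE parameters.

    ``clip_limit_multiplier`` expresses the per-bin clip limit as a multiple
    of the region's average bin occupancy; values >= 1 keep the limit at or
    above the average (``np.inf`` disables clipping, recovering plain
    per-region histogram equalization).
    """

    clip_limit_multiplier: float = 4.0
    tile_rows: int = 8
    tile_cols: int = 8
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.clip_limit_multiplier < 1:
            raise ValueError(
                "clip_limit_multiplier must be >= 1, "
                f"got {self.clip_limit_multiplier}"
            )
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError(
                f"tile dims must be >= 1, got {self.tile_rows}x{self.tile_cols}"
            )
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(f"expected a grayscale (2-D) image, got shape {img.shape}")
    return img


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminance grayscale conversion; 1-channel input passes through."""
    img = np.asarray(img)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        gray = (
            GRAY_WEIGHTS[0] * img[..., 0].astype(float)
            + GRAY_WEIGHTS[1] * img[..., 1].astype(float)
            + GRAY_WEIGHTS[2] * img[..., 2].astype(float)
        )
        return _round_half_up(gray).astype(np.uint8)
    raise FormatError(
        f"channel count must be 1 or 3, got image of shape {img.shape}"
    )


def _tile_slices(n: int, tiles: int) -> list[slice]:
    edges = np.linspace(0, n, tiles + 1).round().astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(tiles)]


def average_pixels(img: np.ndarray, params: EnhanceParams) -> np.ndarray:
    """Average histogram bin occupancy per region: region pixels / n_bins.

    Returns a (tile_rows, tile_cols) array; this is the quantity the clip
    limit is expressed against.
    """
    img = _check_gray(img)
    rows = _tile_slices(img.shape[0], params.tile_rows)
    cols = _tile_slices(img.shape[1], params.tile_cols)
    out = np.empty((params.tile_rows, params.tile_cols), dtype=float)
    for i, rs in enumerate(rows):
        for j, cs in enumerate(cols):
            n_px = (rs.stop - rs.start) * (cs.stop - cs.start)
            if n_px == 0:
                raise ValueError(
                    f"region ({i},{j}) is empty: image {img.shape} cannot be "
                    f"tiled {params.tile_rows}x{params.tile_cols}"
                )
            out[i, j] = n_px / params.n_bins
    return out


def _tile_lut(tile: np.ndarray, params: EnhanceParams) -> np.ndarray:
    """Equalization lookup table for one region from its clipped histogram."""
    n_bins = params.n_bins
    bin_idx = (tile.astype(int) * n_bins) // 256
    hist = np.bincount(bin_idx.ravel(), minlength=n_bins).astype(float)
    total = hist.sum()

    # constant region: identity mapping by convention (redistributing a
    # single-spike histogram would shift the level for no reason)
    if np.count_nonzero(hist) <= 1:
        return np.linspace(0, 255, n_bins).round()

    if np.isfinite(params.clip_limit_multiplier):
        clip = params.clip_limit_multiplier * total / n_bins
        excess = np.maximum(hist - clip, 0.0).sum()
        hist = np.minimum(hist, clip) + excess / n_bins

    cdf = np.cumsum(hist)
    nonzero = cdf[cdf > 0]
    cdf_min = nonzero[0] if nonzero.size else 0.0
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # constant region: identity mapping
        return np.linspace(0, 255, n_bins).round()
    return _round_half_up(255.0 * (cdf - cdf_min) / denom)


def enhance(img: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Clip-limited adaptive histogram equalization.

    Per-region LUTs are blended bilinearly between neighbouring region
    centres, so the output is smooth across tile boundaries.  Output dtype,
    shape and [0, 255] range match the input contract.
    """
    params = params or EnhanceParams()
    img = _check_gray(img)
    h, w = img.shape
    tr, tc = params.tile_rows, params.tile_cols

    rows = _tile_slices(h, tr)
    cols = _tile_slices(w, tc)
    luts = np.empty((tr, tc, params.n_bins))
    centers_y = np.array([(s.start + s.stop - 1) / 2.0 for s in rows])
    centers_x = np.array([(s.start + s.stop - 1) / 2.0 for s in cols])
    for i, rs in enumerate(rows):
        for j, cs in enumerate(cols):
            luts[i, j] = _tile_lut(img[rs, cs], params)

    # fractional tile coordinates of every pixel, clamped at the border
    def _coords(n_pix: int, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = np.arange(n_pix, dtype=float)
        idx = np.clip(np.searchsorted(centers, pos) - 1, 0, len(centers) - 2)
        if len(centers) == 1:
            return np.zeros(n_pix, int), np.zeros(n_pix)
        span = centers[idx + 1] - centers[idx]
        frac = np.clip((pos - centers[idx]) / span, 0.0, 1.0)
        return idx, frac

    iy, fy = _coords(h, centers_y)
    ix, fx = _coords(w, centers_x)
    bins = (img.astype(int) * params.n_bins) // 256

    iy0 = iy[:, None]
    ix0 = ix[None, :]
    wy = fy[:, None]
    wx = fx[None, :]
    out = (
        (1 - wy) * (1 - wx) * luts[iy0, ix0, bins]
        + (1 - wy) * wx * luts[iy0, np.minimum(ix0 + 1, tc - 1), bins]
        + wy * (1 - wx) * luts[np.minimum(iy0 + 1, tr - 1), ix0, bins]
        + wy * wx * luts[np.minimum(iy0 + 1, tr - 1), np.minimum(ix0 + 1, tc - 1), bins]
    )
    return _round_half_up(np.clip(out, 0, 255)).astype(np.uint8)


def remove_hair(
    img: np.ndarray,
    footprint_radius: int = 5,
    min_hair_area: int = 30,
    min_response: float = 30.0,
) -> np.ndarray:
    """Detect and inpaint dark hair-like curves (dermoscopy artifact).

    Detection is a morphological black-tophat on the luminance channel,
    thresholded at the larger of Otsu's threshold and ``min_response``
    (the floor keeps unimodal noise responses from triggering), with
    speckles below ``min_hair_area`` pixels discarded; the surviving mask
    is dilated by one pixel.  Detected pixels are replaced by their nearest
    non-hair neighbour and smoothed inside the mask, which removes 1-3 px
    curves without touching the rest of the image.
    """
    img = np.asarray(img)
    color = img.ndim == 3
    gray = to_grayscale(img) if color else _check_gray(img)

    response = black_tophat(gray, disk(footprint_radius)).astype(float)
    if response.max() < min_response:
        return img.copy()

    hair = response > max(float(threshold_otsu(response)), min_response)
    comps = _cc_label(hair, connectivity=2)
    sizes = np.bincount(comps.ravel())
    hair = sizes[comps] >= min_hair_area
    hair &= comps > 0
    if not hair.any():
        return img.copy()
    hair = dilation(hair, disk(1))
    logger.info("remove_hair: inpainting %d pixels (%.2f%% of image)",
                hair.sum(), 100.0 * hair.mean())

    # nearest non-hair neighbour fill, then smooth only inside the mask
    _, (iy, ix) = ndimage.distance_transform_edt(hair, return_indices=True)

    def _fill(channel: np.ndarray) -> np.ndarray:
        filled = channel.astype(float)[iy, ix]
        smooth = ndimage.gaussian_filter(filled, sigma=2.0)
        out = channel.astype(float).copy()
        out[hair] = smooth[hair]
        return _round_half_up(np.clip(out, 0, 255)).astype(np.uint8)

    if color:
        return np.dstack([_fill(img[..., c]) for c in range(img.shape[2])])
    return _fill(img)


def prepare_image(
    img: np.ndarray,
    enhance_params: EnhanceParams | None = None,
    apply_enhance: bool = True,
    apply_hair_removal: bool = True,
) -> np.ndarray:
    """Full front-end used by every segmentation scenario.

    Colour inputs get hair removal then grayscale conversion; grayscale
    inputs skip hair removal.  Contrast enhancement is applied last.
    """
    img = np.asarray(img)
    if img.ndim == 3 and apply_hair_removal:
        img = remove_hair(img)
    gray = to_grayscale(img)
    if apply_enhance:
        gray = enhance(gray, enhance_params)
    return gray
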