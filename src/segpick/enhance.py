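"""Contrast enhancement and three-channel construction of micrographs.

Cryo-EM micrographs have very low contrast; before labeling or
segmentation they are enhanced and expanded into a three-channel image:

* channel 1 — global histogram equalization followed by an
  edge-preserving bilateral filter;
* channel 2 — a band-pass around the global median intensity ("median
  thresholding"), which boosts contrast in the median intensity range
  where particles live;
* channel 3 — a Gaussian adaptive threshold applied to channel 2.

The stacked channels are then CLAHE-equalized per channel.  All stages
operate on and return 8-bit images and are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, restoration

from .io_formats import Micrograph

__all__ = [
    "EnhanceParams",
    "ThreeChannelImage",
    "normalize_to_8bit",
    "clahe",
    "channel_hist_bilateral",
    "channel_median_threshold",
    "channel_adaptive_gaussian",
    "compose_three_channel",
]


@dataclass
class EnhanceParams:
    """Tunable parameters of the enhancement stages (8-bit intensity scale)."""

    gaussian_sigma: float = 1.0
    bilateral_diameter: int = 5
    bilateral_sigma_color: float = 25.0
    bilateral_sigma_space: float = 3.0
    clahe_clip_limit: float = 2.0
    clahe_tile: int = 8
    median_window: int = 40
    adaptive_block: int = 11
    adaptive_offset: float = 2.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.bilateral_diameter < 3 or self.bilateral_diameter % 2 == 0:
            raise ValueError("bilateral_diameter must be odd and >= 3")
        if self.bilateral_sigma_color <= 0 or self.bilateral_sigma_space <= 0:
            raise ValueError("bilateral sigmas must be > 0")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if self.clahe_tile < 1:
            raise ValueError("clahe_tile must be >= 1")
        if self.median_window < 0:
            raise ValueError("median_window must be >= 0")
        if self.adaptive_block < 3 or self.adaptive_block % 2 == 0:
            raise ValueError("adaptive_block must be odd and >= 3")


@dataclass
class ThreeChannelImage:
    """Three stacked 8-bit planes of identical height/width (H, W, 3)."""

    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3), got {self.channels.shape}")
        if self.channels.dtype != np.uint8:
            raise ValueError("channels must be uint8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]  # type: ignore[return-value]


def _as_u8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    return image


def normalize_to_8bit(micrograph: Micrograph | np.ndarray) -> np.ndarray:
    """Linearly rescale intensities to [0, 255] (uint8).

    min maps to 0 and max to 255; a constant image maps to all-128.
    Invariant to positive affine transforms of the input.
    """
    px = micrograph.pixels if isinstance(micrograph, Micrograph) else np.asarray(micrograph)
    px = px.astype(np.float64)
    if not np.all(np.isfinite(px)):
        raise ValueError("non-finite intensities")
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.full(px.shape, 128, dtype=np.uint8)
    scaled = (px - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def clahe(image: np.ndarray, clip_limit: float = 2.0, tile: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    The image is divided into ``tile`` x ``tile`` rectangles; each tile's
    256-bin histogram is clipped at ``clip_limit`` times the uniform bin
    height, the clipped excess is redistributed uniformly over all bins,
    and the resulting CDFs define per-tile intensity mappings that are
    bilinearly blended between neighbouring tile centres.
    """
    img = _as_u8(image)
    h, w = img.shape
    if tile < 1:
        raise ValueError("tile must be >= 1")
    if tile > h or tile > w:
        raise ValueError(f"tile grid {tile} larger than image {h}x{w}")
    ty = tx = tile
    # tile boundaries (tiles as equal as integer division allows)
    ys = np.linspace(0, h, ty + 1).astype(int)
    xs = np.linspace(0, w, tx + 1).astype(int)
    # per-tile lookup tables
    luts = np.zeros((ty, tx, 256), dtype=np.float64)
    for i in range(ty):
        for j in range(tx):
            block = img[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            n = block.size
            hist = np.bincount(block.ravel(), minlength=256).astype(np.float64)
            clip = max(clip_limit * n / 256.0, 1.0)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist)
            cdf_min = cdf[np.nonzero(hist)[0][0]] if hist.any() else 0.0
            denom = max(n - cdf_min, 1e-12)
            luts[i, j] = np.clip((cdf - cdf_min) * 255.0 / denom, 0.0, 255.0)
    # bilinear blend between the four neighbouring tile mappings
    cy = (ys[:-1] + ys[1:]) / 2.0  # tile centres
    cx = (xs[:-1] + xs[1:]) / 2.0
    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)
    iy = np.clip(np.searchsorted(cy, yy) - 1, 0, ty - 2) if ty > 1 else np.zeros(h, int)
    ix = np.clip(np.searchsorted(cx, xx) - 1, 0, tx - 2) if tx > 1 else np.zeros(w, int)
    if ty > 1:
        wy = np.clip((yy - cy[iy]) / (cy[iy + 1] - cy[iy]), 0.0, 1.0)
    else:
        wy = np.zeros(h)
    if tx > 1:
        wx = np.clip((xx - cx[ix]) / (cx[ix + 1] - cx[ix]), 0.0, 1.0)
    else:
        wx = np.zeros(w)
    iy2 = np.minimum(iy + 1, ty - 1)
    ix2 = np.minimum(ix + 1, tx - 1)
    IY = iy[:, None]
    IY2 = iy2[:, None]
    IX = ix[None, :]
    IX2 = ix2[None, :]
    WY = wy[:, None]
    WX = wx[None, :]
    v = img
    tl = luts[IY, IX, v]
    tr = luts[IY, IX2, v]
    bl = luts[IY2, IX, v]
    br = luts[IY2, IX2, v]
    out = (1 - WY) * ((1 - WX) * tl + WX * tr) + WY * ((1 - WX) * bl + WX * br)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def channel_hist_bilateral(image: np.ndarray, params: EnhanceParams) -> np.ndarray:
    """Global histogram equalization then edge-preserving bilateral filtering."""
    img = _as_u8(image)
    if img.min() == img.max():
        return img.copy()
    eq = np.clip(np.rint(exposure.equalize_hist(img) * 255.0), 0, 255).astype(np.uint8)
    filtered = restoration.denoise_bilateral(
        eq.astype(np.float64) / 255.0,
        win_size=params.bilateral_diameter,
        sigma_color=params.bilateral_sigma_color / 255.0,
        sigma_spatial=params.bilateral_sigma_space,
    )
    return np.clip(np.rint(filtered * 255.0), 0, 255).astype(np.uint8)


def channel_median_threshold(image: np.ndarray, median_window: int) -> np.ndarray:
    """Keep pixels within ``median_window`` of the global median; zero the rest."""
    if median_window < 0:
        raise ValueError("median_window must be >= 0")
    img = _as_u8(image)
    med = np.median(img)
    keep = np.abs(img.astype(np.int16) - med) <= median_window
    out = np.where(keep, img, 0).astype(np.uint8)
    return out


def channel_adaptive_gaussian(
    image: np.ndarray, adaptive_block: int, adaptive_offset: float
) -> np.ndarray:
    """Gaussian adaptive threshold: 255 where I exceeds the local mean by
    more than ``adaptive_offset``.

    The local mean is a Gaussian-weighted average over an
    ``adaptive_block`` x ``adaptive_block`` window (sigma tied to the
    block size the way standard CV libraries derive it).  A positive
    offset raises the bar, so flat regions map to 0 rather than firing
    on rounding noise.
    """
    if adaptive_block < 3 or adaptive_block % 2 == 0:
        raise ValueError("adaptive_block must be odd and >= 3")
    img = _as_u8(image).astype(np.float64)
    radius = (adaptive_block - 1) // 2
    sigma = 0.3 * ((adaptive_block - 1) * 0.5 - 1) + 0.8
    local_mean = ndimage.gaussian_filter(
        img, sigma=sigma, truncate=radius / sigma, mode="nearest"
    )
    return np.where(img > local_mean + adaptive_offset, 255, 0).astype(np.uint8)


def compose_three_channel(
    micrograph: Micrograph | np.ndarray, params: EnhanceParams | None = None
) -> ThreeChannelImage:
    """Build the three-channel network input from a raw micrograph.

    Channel 1 = equalize+bilateral; channel 2 = median band-pass;
    channel 3 = adaptive Gaussian threshold of channel 2.  Each channel
    is CLAHE-equalized at the end.
    """
    params = params or EnhanceParams()
    base = normalize_to_8bit(micrograph)
    c1 = channel_hist_bilateral(base, params)
    c2 = channel_median_threshold(base, params.median_window)
    c3 = channel_adaptive_gaussian(c2, params.adaptive_block, params.adaptive_offset)
    stack = [
        clahe(c, params.clahe_clip_limit, params.clahe_tile) for c in (c1, c2, c3)
    ]
    return ThreeChannelImage(channels=np.stack(stack, axis=2))
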