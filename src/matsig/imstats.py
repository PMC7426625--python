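"""Histogram-based image statistics of masked painting segments.

Four statistics per segment, computed over the segment mask only:

* Michelson contrast (P95 - P5) / (P95 + P5) of the luminance distribution
* skewness of the luminance distribution (population g1)
* colorfulness: fraction of occupied voxels when 8-bit RGB is binned into a
  16 x 16 x 16 colour cube
* mean luminance

Luminance defaults to Rec.709 luma of the linearly scaled 8-bit RGB values
(no gamma linearisation); the weights are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Rec.709 luma coefficients for (R, G, B).
REC709 = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class ImageStats:
    contrast: float          # Michelson, in [0, 1]
    skewness: float
    colorfulness: float      # occupied-voxel ratio, in (0, 1]
    mean_luminance: float    # in [0, 1]


def _masked_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    if not mask.any():
        raise ValueError("empty mask")
    return image[mask]


def luminance_map(image: np.ndarray, mask: np.ndarray,
                  weights: tuple[float, float, float] = REC709) -> np.ndarray:
    """Per-pixel luminance of the masked region, in [0, 1].

    8-bit RGB is scaled by 1/255 and combined with the given luma weights;
    grayscale input is scaled only.
    """
    px = _masked_pixels(image, mask).astype(np.float64)
    if px.ndim == 1:          # grayscale
        lum = px / 255.0
    else:
        w = np.asarray(weights, float)
        lum = (px[:, :3] / 255.0) @ w
    return lum


def michelson_contrast(luminances: np.ndarray) -> float:
    """(P95 - P5)/(P95 + P5) with linear-interpolation percentiles.

    Undefined (raises) when P95 + P5 == 0, i.e. effectively all-black input.
    """
    lum = np.asarray(luminances, float)
    if lum.size < 2:
        raise ValueError("need at least 2 luminance values")
    p5, p95 = np.percentile(lum, [5.0, 95.0])
    denom = p95 + p5
    if denom == 0:
        raise ValueError("contrast undefined: 5th and 95th percentiles are both zero")
    return float((p95 - p5) / denom)


def luminance_skewness(luminances: np.ndarray) -> float:
    """Third standardized moment (population estimator g1)."""
    lum = np.asarray(luminances, float)
    if lum.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(lum) == 0:
        raise ValueError("skewness undefined for zero-variance input")
    return float(sps.skew(lum, bias=True))


def colorfulness(image: np.ndarray, mask: np.ndarray, bins_per_channel: int = 16) -> float:
    """Occupied-voxel ratio in a binned RGB cube.

    Each 8-bit channel is rescaled to ``bins_per_channel`` levels (default 16,
    i.e. floor(v / 16)); the statistic is the number of distinct occupied
    (R, G, B) voxels divided by bins_per_channel**3.
    """
    px = _masked_pixels(image, mask)
    if px.ndim == 1:
        px = np.stack([px] * 3, axis=-1)
    binned = (px[:, :3].astype(np.uint16) * bins_per_channel // 256).astype(np.uint16)
    codes = (binned[:, 0] * bins_per_channel + binned[:, 1]) * bins_per_channel + binned[:, 2]
    return float(len(np.unique(codes)) / bins_per_channel**3)


def mean_luminance(luminances: np.ndarray) -> float:
    lum = np.asarray(luminances, float)
    if lum.size == 0:
        raise ValueError("empty input")
    return float(lum.mean())


def segment_stats(image: np.ndarray, mask: np.ndarray,
                  weights: tuple[float, float, float] = REC709) -> ImageStats:
    """All four statistics for one masked segment."""
    lum = luminance_map(image, mask, weights)
    return ImageStats(
        contrast=michelson_contrast(lum),
        skewness=luminance_skewness(lum),
        colorfulness=colorfulness(image, mask),
        mean_luminance=mean_luminance(lum),
    )
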