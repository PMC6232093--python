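"""Global tissue detection: find the complete tissue section on the slide.

Tissue is whatever is both bright enough on the chosen channel (after mild
Gaussian smoothing to suppress shot noise) and locally homogeneous enough
to be stained tissue rather than speckle, with sub-minimal fragments
(< 10 µm² by default) removed by a minimal-size rule.

"Homogeneity" here is the local coefficient of variation of the channel in
a sliding window, rescaled to a bounded range so thresholds are scale-free:
h = S · cv / (1 + cv) with S = 5 (or 255 for configurations written against
an 8-bit preview).  h = 0 is perfectly flat signal; h → S is pure speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu

from .slide_model import LabelMask, Slide, area_um2

__all__ = ["TissueParams", "detect_tissue", "suggest_brightness_min"]

TISSUE_LABEL = 1


@dataclass
class TissueParams:
    """Thresholds for global tissue detection.

    channel          channel used for detection (nuclear counterstain by default)
    brightness_min   minimum smoothed intensity, grey-value levels
    homogeneity_max  maximum local heterogeneity, in [0, homogeneity_scale]
    min_area_um2     connected components smaller than this are dropped (µm²)
    smooth_sigma     Gaussian σ (px) applied before the brightness test
    window           side (px) of the sliding window for the heterogeneity map
    homogeneity_scale  5.0 (default) or 255.0 for 8-bit-style configs
    """

    channel: str = "DAPI"
    brightness_min: float = 500.0
    homogeneity_max: float = 5.0
    min_area_um2: float = 10.0
    smooth_sigma: float = 2.0
    window: int = 15
    homogeneity_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.homogeneity_scale not in (5.0, 255.0):
            raise ValueError("homogeneity_scale must be 5 or 255")
        if not 0 <= self.homogeneity_max <= self.homogeneity_scale:
            raise ValueError("homogeneity_max outside its scale")


def _local_cv(img: np.ndarray, window: int) -> np.ndarray:
    """Local coefficient of variation in a window×window neighbourhood."""
    mean = ndi.uniform_filter(img, size=window)
    sq = ndi.uniform_filter(img * img, size=window)
    var = np.maximum(sq - mean * mean, 0.0)
    return np.sqrt(var) / np.maximum(mean, 1e-9)


def heterogeneity_map(
    slide: Slide, channel: str = "DAPI", window: int = 15, scale: float = 5.0
) -> np.ndarray:
    """Bounded local-heterogeneity statistic, in [0, scale)."""
    cv = _local_cv(slide.channel(channel).astype(np.float64), window)
    return scale * cv / (1.0 + cv)


def detect_tissue(slide: Slide, params: TissueParams | None = None) -> LabelMask:
    """Binary tissue mask for a slide.

    A pixel is tissue iff its Gaussian-smoothed brightness on
    ``params.channel`` is ≥ ``brightness_min`` and its local heterogeneity
    is ≤ ``homogeneity_max``; connected components with an area below
    ``min_area_um2`` are then removed.
    """
    params = params or TissueParams()
    img = slide.channel(params.channel).astype(np.float64)
    limit = 2**slide.bit_depth
    if not 0 <= params.brightness_min < limit:
        raise ValueError(
            f"brightness_min {params.brightness_min} outside the {slide.bit_depth}-bit range"
        )
    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    mask = smoothed >= params.brightness_min
    if params.homogeneity_max < params.homogeneity_scale:
        het = heterogeneity_map(
            slide, params.channel, params.window, params.homogeneity_scale
        )
        mask &= het <= params.homogeneity_max
    # minimal-size rule: drop fragments below min_area_um2
    min_px = int(np.ceil(params.min_area_um2 / slide.pixel_size**2))
    if min_px > 1 and mask.any():
        comp, ncomp = ndi.label(mask)
        sizes = np.bincount(comp.ravel(), minlength=ncomp + 1)
        keep = sizes >= min_px
        keep[0] = False
        mask = keep[comp]
    labels = mask.astype(np.int64) * TISSUE_LABEL
    legend = {TISSUE_LABEL: "tissue"} if mask.any() else {}
    return LabelMask(labels, legend)


def suggest_brightness_min(slide: Slide, params: TissueParams | None = None) -> float:
    """Otsu-based starting point for ``brightness_min``.

    A convenience for the iterative, visually confirmed tuning such
    thresholds normally get; the stored configuration stays authoritative
    and this value is never applied implicitly.
    """
    params = params or TissueParams()
    smoothed = gaussian(
        slide.channel(params.channel).astype(np.float64),
        sigma=params.smooth_sigma,
        preserve_range=True,
    )
    return float(threshold_otsu(smoothed))


def mask_area_um2(mask: LabelMask, pixel_size: float) -> float:
    return area_um2(int(np.count_nonzero(mask.labels)), pixel_size)
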