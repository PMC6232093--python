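"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from ifquant import pipeline, synthgen
from ifquant.slide_model import Slide


def disk_mask(shape: tuple[int, int], center: tuple[int, int], radius_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def disks_slide(
    centers: list[tuple[int, int]],
    radius_px: float,
    shape: tuple[int, int] = (512, 512),
    level: int = 20000,
    pixel_size: float = 0.5,
    channel: str = "DAPI",
) -> Slide:
    """Flat-intensity disks on a dark background (plateau test case)."""
    img = np.zeros(shape, dtype=np.uint16)
    for c in centers:
        img[disk_mask(shape, c, radius_px)] = level
    return Slide({channel: img, "FITC": np.zeros(shape, np.uint16)}, pixel_size)


@pytest.fixture(scope="session")
def small_synth():
    """768² synthetic slide + ground truth for engine-level tests (~180 cells)."""
    cfg = synthgen.SynthConfig(shape=(768, 768), seed=11)
    slide, gt = synthgen.generate_slide(cfg)
    return cfg, slide, gt


@pytest.fixture(scope="session")
def small_result(small_synth):
    """Full pipeline result on the 768² fixture."""
    _, slide, gt = small_synth
    return pipeline.analyze_slide(
        slide, None, exemplar_mask=gt.roi_mask, slide_id="small"
    )


@pytest.fixture(scope="session")
def big_synth():
    """2048² default-condition fixture (generated once per session)."""
    cfg = synthgen.SynthConfig(shape=(2048, 2048), seed=23)
    slide, gt = synthgen.generate_slide(cfg)
    return cfg, slide, gt
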