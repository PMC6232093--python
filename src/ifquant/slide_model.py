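"""Data model and I/O for calibrated multichannel slides and label masks.

A :class:`Slide` is the in-memory form of a multichannel fluorescence field
or whole-slide image: named 2-D integer intensity grids (grey-value levels)
sharing one pixel calibration in µm/pixel.  A :class:`LabelMask` carries any
integer labelling of the same grid (tissue mask, region classes, cell ids)
together with a legend mapping labels to class names.

Interchange formats are open ones: multi-page TIFF/OME-style TIFF for
images (one page per channel, calibration and channel names stored in the
image description), single-page integer TIFF for masks, CSV for tables.
Pixel coordinates are 0-based (row, col) with the origin at the top-left.
Areas are µm² internally; reports additionally carry mm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import DensityReport

__all__ = [
    "Slide",
    "LabelMask",
    "ChannelRole",
    "load_slide",
    "save_slide",
    "load_mask",
    "save_mask",
    "area_um2",
    "write_report",
    "read_report",
]

#: µm/pixel of the scanner setup the default parameters were tuned for.
DEFAULT_PIXEL_SIZE_UM = 0.161028

#: key under which slide metadata is stored in the TIFF image description
_META_KEY = "ifquant"


class SlideFormatError(ValueError):
    """Raised when a file does not match the declared slide layout."""


@dataclass
class ChannelRole:
    """Role of one fluorescence channel in an analysis.

    Exactly one channel per analysis is ``nuclear`` (the DAPI counterstain
    used for cell identification); any number may be ``membrane``.
    """

    role: str
    name: str

    def __post_init__(self) -> None:
        if self.role not in ("nuclear", "membrane"):
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class Slide:
    """Calibrated multichannel intensity image.

    Parameters
    ----------
    channels
        Mapping channel name → 2-D integer intensity array. All channels
        must share the same shape and fit the declared bit depth.
    pixel_size
        Edge length of one pixel in µm (> 0).
    bit_depth
        Intensity bit depth; 16 gives grey values in [0, 65536).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("slide needs at least one channel")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        limit = 2**self.bit_depth
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if arr.size and (arr.min() < 0 or arr.max() >= limit):
                raise ValueError(
                    f"channel {name!r} intensities exceed {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; slide has {self.channel_names}"
            ) from None

    def restricted_to(self, mask: np.ndarray) -> "Slide":
        """Copy of the slide with intensities outside ``mask`` zeroed."""
        out = {n: np.where(mask, a, 0).astype(a.dtype) for n, a in self.channels.items()}
        return Slide(out, self.pixel_size, self.bit_depth)


@dataclass
class LabelMask:
    """Integer labelling of a slide grid; 0 means unassigned.

    ``legend`` maps every nonzero label that occurs to a class name.
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_mask(self, class_name: str) -> np.ndarray:
        """Boolean mask of all pixels whose label maps to ``class_name``."""
        wanted = [k for k, v in self.legend.items() if v == class_name]
        return np.isin(self.labels, wanted)

    def binary(self) -> np.ndarray:
        return self.labels != 0


# ---------------------------------------------------------------------------
# geometry helpers


def area_um2(pixel_count: int, pixel_size: float) -> float:
    """Convert a pixel count into µm² for a given calibration.

    area = pixel_count × pixel_size², e.g. 386 px at 0.161028 µm/px
    ≈ 10.01 µm² — the footprint of the minimal-fragment rule.
    """
    if pixel_count < 0:
        raise ValueError("pixel_count must be >= 0")
    return float(pixel_count) * float(pixel_size) ** 2


# ---------------------------------------------------------------------------
# slide I/O


def save_slide(slide: Slide, path: str | Path) -> None:
    """Write a slide as a multi-page TIFF (one page per channel).

    Channel names, pixel size and bit depth go into the image description
    so that :func:`load_slide` round-trips without sidecar files.
    """
    meta = {
        _META_KEY: {
            "channels": slide.channel_names,
            "pixel_size_um": slide.pixel_size,
            "bit_depth": slide.bit_depth,
        }
    }
    dtype = np.uint16 if slide.bit_depth <= 16 else np.uint32
    stack = np.stack([slide.channels[n].astype(dtype) for n in slide.channel_names])
    tifffile.imwrite(str(path), stack, description=json.dumps(meta))


def _read_description(tif: tifffile.TiffFile) -> dict:
    try:
        desc = tif.pages[0].description
        meta = json.loads(desc) if desc else {}
    except (json.JSONDecodeError, AttributeError):
        meta = {}
    return meta.get(_META_KEY, {})


def load_slide(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    pixel_size: float | None = None,
    bit_depth: int | None = None,
) -> Slide:
    """Load a multi-page TIFF as a :class:`Slide`.

    Metadata written by :func:`save_slide` supplies channel names, pixel
    size and bit depth; arguments override it.  A file with neither stored
    nor supplied pixel size is rejected rather than silently assumed to be
    1 µm/px.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        meta = _read_description(tif)
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise SlideFormatError(f"expected 2-D pages, got array of shape {data.shape}")

    names = list(channel_names) if channel_names is not None else meta.get("channels")
    if names is None:
        names = [f"C{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise SlideFormatError(
            f"channel-count mismatch: file has {data.shape[0]} pages, "
            f"{len(names)} names supplied"
        )
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if px is None:
        raise SlideFormatError(
            f"{path} carries no pixel size; pass pixel_size= explicitly"
        )
    depth = bit_depth if bit_depth is not None else meta.get("bit_depth", 16)
    channels = {n: data[i] for i, n in enumerate(names)}
    return Slide(channels, float(px), int(depth))


def save_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as int32 TIFF, legend in the image description."""
    meta = {_META_KEY: {"legend": {str(k): v for k, v in mask.legend.items()}}}
    tifffile.imwrite(str(path), mask.labels.astype(np.int32), description=json.dumps(meta))


def load_mask(path: str | Path, legend: Mapping[int, str] | None = None) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        meta = _read_description(tif)
        labels = tif.asarray()
    if legend is None:
        legend = {int(k): v for k, v in meta.get("legend", {}).items()}
    return LabelMask(labels.astype(np.int64), dict(legend))


# ---------------------------------------------------------------------------
# report I/O (columns documented in quantify.DensityReport)


def write_report(report: "DensityReport", path: str | Path) -> None:
    """Write a density report as CSV, one row per (slide, region class)."""
    report.to_frame().to_csv(path, index=False)


def read_report(path: str | Path):
    """Read back a CSV written by :func:`write_report`."""
    from .quantify import DensityReport

    return DensityReport.from_frame(_read_csv(path))


def _read_csv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)
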