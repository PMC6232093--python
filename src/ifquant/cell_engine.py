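"""Cellular analysis: nuclei, simulated cell bodies, phenotypes, artifacts.

Detection runs per region of interest.  Nuclei come from the nuclear
counterstain (DAPI) with a mean-nuclear-area prior (35 µm² by default)
driving the separation of touching nuclei; cell bodies are then simulated
around each nucleus either by competitive growth into supra-threshold
membrane staining ("inside cytoplasmic stain", the default) or by isotropic
dilation to the mean cell area ("growth from nuclei", the fallback for weak
or blotchy membrane signal).  Phenotypes require nuclear and membrane
co-staining — a membrane-positive detection without a nucleus is never a
cell — which is what makes the classification robust to fluorochrome
aggregates.

Grey values on the nuclear channel are also expressed in arbitrary units
(a.u.): a.u. = g.v.l / 32768, so the full 16-bit range maps onto [0, 2].
All intensity thresholds compare with inclusive ≥.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .roi_engine import BIS_SUFFIX, ROILabeling
from .slide_model import Slide

__all__ = [
    "NucleusParams",
    "CellParams",
    "ClassificationThresholds",
    "PhenotypeScheme",
    "CellRecord",
    "CellPopulation",
    "Nuclei",
    "detect_nuclei",
    "simulate_cells",
    "calibrate_thresholds",
    "classify_cells",
    "exclude_artifacts",
    "AU_DIVISOR",
]

#: grey-value levels per arbitrary unit (65,536 g.v.l ↔ 2.0 a.u.)
AU_DIVISOR = 32768.0


@dataclass
class NucleusParams:
    """Nucleus-detection settings.

    intensity_range_au   accepted nuclear intensity window, arbitrary units
    mean_nuclear_area_um2  the area prior (µm²) that sets the separation
                           footprint for touching nuclei
    area_gate_um2        hard per-nucleus area gates (µm²)
    detection_threshold_au  explicit foreground threshold; None → Otsu on
                            the smoothed channel within the analysed region
    """

    intensity_range_au: tuple[float, float] = (0.0, 2.0)
    mean_nuclear_area_um2: float = 35.0
    area_tolerance_um2: float = 5.0
    area_gate_um2: tuple[float, float] = (10.0, 150.0)
    smooth_sigma: float = 1.5
    detection_threshold_au: float | None = None
    peak_separation_factor: float = 0.45
    au_divisor: float = AU_DIVISOR

    def __post_init__(self) -> None:
        lo, hi = self.intensity_range_au
        if lo > hi:
            raise ValueError("intensity range min > max")
        if not self.mean_nuclear_area_um2 > 0:
            raise ValueError("mean_nuclear_area_um2 must be > 0")

    @property
    def expected_diameter_um(self) -> float:
        return 2.0 * float(np.sqrt(self.mean_nuclear_area_um2 / np.pi))


@dataclass
class CellParams:
    """Cell-simulation settings.

    The delimitation threshold is distinct from the classification
    threshold for the same channel: delimitation decides which pixels a
    cell may grow into (CD45 default 1,600 g.v.l; Cy3 default 48,356, the
    lower bound of its delimitation range), classification decides the
    phenotype from mean intensities (:class:`ClassificationThresholds`).
    """

    membrane_channel: str = "FITC"
    membrane_threshold: float = 1600.0
    mean_cell_area_um2: float = 38.0
    area_tolerance_um2: float = 5.0
    mode: str = "inside_cytoplasmic_stain"

    def __post_init__(self) -> None:
        if self.mode not in ("inside_cytoplasmic_stain", "growth_from_nuclei"):
            raise ValueError(f"unknown cell-simulation mode {self.mode!r}")


@dataclass
class ClassificationThresholds:
    """Mean-intensity thresholds (g.v.l) for phenotype calls."""

    nuclear_min: float = 1000.0
    marker_min: dict[str, float] = field(default_factory=lambda: {"FITC": 1300.0})
    intensity_max: float = 65536.0

    @classmethod
    def single_cd45(cls) -> "ClassificationThresholds":
        """Single-staining defaults: DAPI 1,000 / FITC 1,300 g.v.l."""
        return cls(nuclear_min=1000.0, marker_min={"FITC": 1300.0})

    @classmethod
    def double_cd3_cd4(cls) -> "ClassificationThresholds":
        """Double-staining defaults: DAPI 500 / Cy3 2,500 / FITC 1,500."""
        return cls(nuclear_min=500.0, marker_min={"CY3": 2500.0, "FITC": 1500.0})


@dataclass
class PhenotypeScheme:
    """Marker scheme mapping channels to phenotype classes.

    single_CD45: one membrane marker → {positive, negative}.
    double_CD3_CD4: CD3 (Cy3) and CD4 (FITC) → the four CD3±CD4± classes.
    """

    name: str
    nuclear_channel: str = "DAPI"
    marker_channels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def single_cd45(cls, membrane_channel: str = "FITC") -> "PhenotypeScheme":
        return cls("single_CD45", marker_channels={"CD45": membrane_channel})

    @classmethod
    def double_cd3_cd4(
        cls, cd3_channel: str = "CY3", cd4_channel: str = "FITC"
    ) -> "PhenotypeScheme":
        return cls(
            "double_CD3_CD4",
            marker_channels={"CD3": cd3_channel, "CD4": cd4_channel},
        )

    @property
    def classes(self) -> list[str]:
        if self.name == "single_CD45":
            return ["positive", "negative"]
        return ["CD3+CD4+", "CD3+CD4-", "CD3-CD4+", "CD3-CD4-"]

    @property
    def positive_classes(self) -> list[str]:
        """Classes counted as marker-positive (CD3+ for double staining)."""
        if self.name == "single_CD45":
            return ["positive"]
        return ["CD3+CD4+", "CD3+CD4-"]

    def __post_init__(self) -> None:
        if self.name not in ("single_CD45", "double_CD3_CD4"):
            raise ValueError(f"unknown scheme {self.name!r}")


@dataclass
class CellRecord:
    """One detected cell with footprints summarised as areas and means."""

    id: int
    roi_object_id: int
    roi_class: str
    centroid: tuple[float, float]
    nucleus_area_um2: float
    cell_area_um2: float
    nucleus_mean: dict[str, float]
    cell_mean: dict[str, float]
    phenotype: str | None = None
    excluded_reason: str | None = None


@dataclass
class Nuclei:
    """Detected nucleus footprints as a label image plus summaries."""

    label_image: np.ndarray
    ids: np.ndarray
    centroids: np.ndarray  # (n, 2) row/col
    areas_um2: np.ndarray
    pixel_size: float

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class CellPopulation:
    """All cells of one slide plus the underlying label images."""

    cells: list[CellRecord]
    cell_label_image: np.ndarray
    nucleus_label_image: np.ndarray

    def __len__(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# nucleus detection


def detect_nuclei(
    slide: Slide,
    labeling: ROILabeling | None,
    iroi_classes: list[str] | tuple[str, ...] | None = None,
    params: NucleusParams | None = None,
    nuclear_channel: str = "DAPI",
) -> Nuclei:
    """Detect nuclei inside the listed region classes.

    Foreground on the smoothed nuclear channel (within the configured
    arbitrary-unit window) is split into individual nuclei by a
    distance-transform watershed whose marker spacing comes from the mean
    nuclear-area prior; nuclei outside the hard area gates are dropped.
    ``labeling=None`` analyses the whole frame (used for threshold
    calibration on single fields).
    """
    params = params or NucleusParams()
    img = slide.channel(nuclear_channel).astype(np.float64)
    au = img / params.au_divisor

    if labeling is None:
        region = np.ones(slide.shape, dtype=bool)
    else:
        if iroi_classes is None:
            raise ValueError("iroi_classes required when a labeling is given")
        unknown = set(iroi_classes) - labeling.classes_present
        if unknown:
            raise ValueError(f"classes not in labeling: {sorted(unknown)}")
        region = np.zeros(slide.shape, dtype=bool)
        for cls in iroi_classes:
            region |= labeling.class_mask(cls)

    smoothed = gaussian(au, sigma=params.smooth_sigma, preserve_range=True)
    lo, hi = params.intensity_range_au
    in_range = (smoothed >= lo) & (smoothed <= hi) & region
    if params.detection_threshold_au is not None:
        thr = params.detection_threshold_au
    else:
        vals = smoothed[region]
        if vals.size == 0 or vals.max() <= 0:
            return _empty_nuclei(slide)
        thr = float(threshold_otsu(vals))
    fg = in_range & (smoothed >= max(thr, lo))
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return _empty_nuclei(slide)

    # split touching nuclei: watershed on a relief combining intensity
    # (nuclei peak at their centres) and the distance transform (which
    # alone separates non-dense clumps and breaks flat plateaus), with
    # peaks at least peak_separation_factor × expected diameter apart
    dist = ndi.distance_transform_edt(fg)
    relief = smoothed / max(float(smoothed[fg].max()), 1e-9)
    relief = np.where(fg, relief, 0.0) + 0.10 * dist / max(float(dist.max()), 1e-9)
    min_dist = max(
        1, int(round(params.peak_separation_factor * params.expected_diameter_um / slide.pixel_size))
    )
    # disk footprint: suppression radius is Euclidean, not the square
    # window min_distance implies (which would over-suppress diagonals)
    from skimage.morphology import disk as _disk

    peaks = peak_local_max(
        relief, footprint=_disk(min_dist), labels=fg, exclude_border=False
    )
    if len(peaks) == 0:
        return _empty_nuclei(slide)
    markers = np.zeros(slide.shape, dtype=np.int64)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    nuc = watershed(-relief, markers=markers, mask=fg)
    nuc = _split_oversized(nuc, relief, params, slide.pixel_size)

    # area gates
    px2 = slide.pixel_size**2
    ids = np.arange(1, int(nuc.max()) + 1)
    areas = np.bincount(nuc.ravel(), minlength=len(ids) + 1)[1:] * px2
    lo_a, hi_a = params.area_gate_um2
    keep = (areas >= lo_a) & (areas <= hi_a)
    lut = np.zeros(len(ids) + 1, dtype=np.int64)
    lut[ids[keep]] = np.arange(1, keep.sum() + 1)
    nuc = lut[nuc]
    n = int(keep.sum())
    if n == 0:
        return _empty_nuclei(slide)
    new_ids = np.arange(1, n + 1)
    coms = np.asarray(ndi.center_of_mass(np.ones_like(nuc), nuc, new_ids))
    areas = np.bincount(nuc.ravel(), minlength=n + 1)[1:] * px2
    return Nuclei(nuc, new_ids, coms, areas, slide.pixel_size)


def _split_oversized(
    nuc: np.ndarray, relief: np.ndarray, params: NucleusParams, pixel_size: float
) -> np.ndarray:
    """Area-prior-driven declumping of merged detections.

    In densely packed regions (the blurry, high-cellular-density follicle
    case) some nuclei present no intensity maximum that survives the
    global peak suppression, so the first watershed pass merges them into
    a neighbour's region.  The mean-area prior flags any region larger
    than 1.5× the prior as a clump; inside such regions only, peaks are
    re-detected with a halved suppression radius and the clump is
    re-flooded from them.
    """
    from skimage.morphology import disk as _disk

    px2 = pixel_size**2
    prior = params.mean_nuclear_area_um2
    n_max = int(nuc.max())
    if n_max == 0:
        return nuc
    areas = np.bincount(nuc.ravel(), minlength=n_max + 1)[1:] * px2
    # self-calibrated single-nucleus area: singles dominate the region
    # population, and foreground thresholding shrinks them below the
    # prior by a slide-dependent factor the median captures
    plausible = areas[(areas >= 0.4 * prior) & (areas <= 2.0 * prior)]
    a_hat = float(np.median(plausible)) if plausible.size else prior
    a_hat = float(np.clip(a_hat, 0.6 * prior, 1.2 * prior))
    clumps = np.nonzero(areas > 1.30 * a_hat)[0] + 1
    if clumps.size == 0:
        return nuc
    inner_rad = max(
        2,
        int(round(0.5 * params.peak_separation_factor
                  * params.expected_diameter_um / pixel_size)),
    )
    footprint = _disk(inner_rad)
    # area of a clump of k overlapping nuclei grows ≈ affinely in k:
    # a ≈ 0.125·a_hat + 0.875·a_hat·k (overlap eats part of each addition)
    increment = 0.875 * a_hat
    min_part_px = int(round(0.3 * a_hat / px2))
    next_id = n_max + 1
    out = nuc
    slices = ndi.find_objects(out)
    for rid in clumps:
        sl = slices[rid - 1]
        sel = out[sl] == rid
        k_target = int(round((areas[rid - 1] - 0.125 * a_hat) / increment))
        sub_relief = np.where(sel, relief[sl], -np.inf)
        peaks = peak_local_max(
            sub_relief, footprint=footprint, labels=sel, exclude_border=False
        )
        if len(peaks) >= max(2, k_target):
            markers = np.zeros(sel.shape, dtype=np.int64)
            markers[tuple(peaks.T)] = np.arange(len(peaks)) + 1
            parts = watershed(-sub_relief, markers=markers, mask=sel)
        elif k_target >= 2:
            parts = _lloyd_partition(sel, sub_relief, k_target)
        else:
            continue
        parts = _absorb_small_parts(parts, min_part_px)
        n_new = int(parts.max())
        if n_new < 2:
            continue
        region = out[sl]
        grow = sel & (parts > 1)
        region[grow] = next_id + parts[grow] - 2
        next_id += n_new - 1
    return out


def _absorb_small_parts(parts: np.ndarray, min_px: int) -> np.ndarray:
    """Merge declump parts below min_px into their largest touching part,
    then relabel parts consecutively from 1."""
    n = int(parts.max())
    if n >= 2 and min_px > 0:
        sizes = np.bincount(parts.ravel(), minlength=n + 1)
        small = [i for i in range(1, n + 1) if 0 < sizes[i] < min_px]
        for sid in small:
            if np.count_nonzero(parts > 0) == sizes[sid]:
                break  # nothing left to merge into
            grown = ndi.binary_dilation(parts == sid)
            neighbours = np.unique(parts[grown & (parts != sid) & (parts > 0)])
            if neighbours.size:
                tgt = int(neighbours[np.argmax(sizes[neighbours])])
                parts[parts == sid] = tgt
                sizes[tgt] += sizes[sid]
                sizes[sid] = 0
    # consecutive relabel keeping part 1 first if present
    labs = np.unique(parts)
    labs = labs[labs > 0]
    lut = np.zeros(int(parts.max()) + 1, dtype=np.int64)
    lut[labs] = np.arange(1, labs.size + 1)
    return lut[parts]


def _lloyd_partition(sel: np.ndarray, relief: np.ndarray, k: int) -> np.ndarray:
    """Deterministic k-way split of a pixel region: farthest-point seeds
    starting at the relief maximum, then Lloyd iterations on coordinates."""
    coords = np.argwhere(sel).astype(np.float64)
    vals = relief[sel]
    centers = [coords[int(np.argmax(vals))]]
    d2 = np.sum((coords - centers[0]) ** 2, axis=1)
    for _ in range(k - 1):
        centers.append(coords[int(np.argmax(d2))])
        d2 = np.minimum(d2, np.sum((coords - centers[-1]) ** 2, axis=1))
    centers = np.asarray(centers)
    assign = np.zeros(len(coords), dtype=np.int64)
    for _ in range(12):
        dd = np.sum((coords[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(dd, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            m = assign == j
            if m.any():
                centers[j] = coords[m].mean(axis=0)
    parts = np.zeros(sel.shape, dtype=np.int64)
    parts[sel] = assign + 1
    return parts


def _empty_nuclei(slide: Slide) -> Nuclei:
    return Nuclei(
        np.zeros(slide.shape, dtype=np.int64),
        np.zeros(0, dtype=np.int64),
        np.zeros((0, 2)),
        np.zeros(0),
        slide.pixel_size,
    )


# ---------------------------------------------------------------------------
# cell simulation


def simulate_cells(
    nuclei: Nuclei,
    slide: Slide,
    labeling: ROILabeling | None,
    params: CellParams | None = None,
) -> CellPopulation:
    """Simulate one cell body per nucleus; bodies never overlap.

    inside_cytoplasmic_stain: each cell grows from its nucleus into
    contiguous supra-threshold membrane pixels, competing with neighbours
    (simultaneous growth ordered by distance to the nearest nucleus) and
    capped at mean_cell_area + tolerance.  A nucleus with no qualifying
    adjacent membrane keeps its nucleus footprint as the cell footprint.

    growth_from_nuclei: isotropic dilation to mean_cell_area ignoring the
    membrane signal (within tissue).

    Cells never cross ROI-object borders; a border-straddling footprint is
    clipped to its nucleus's ROI object (majority of nucleus pixels, ties
    to the nucleus centroid's object).
    """
    params = params or CellParams()
    shape = slide.shape
    if len(nuclei) == 0:
        return CellPopulation([], np.zeros(shape, np.int64), nuclei.label_image)

    nuc_lab = nuclei.label_image
    dist_to_nuc = ndi.distance_transform_edt(nuc_lab == 0)

    if params.mode == "inside_cytoplasmic_stain":
        membrane = slide.channel(params.membrane_channel).astype(np.float64)
        qualify = membrane >= params.membrane_threshold
        grow_mask = qualify | (nuc_lab > 0)
        cap_um2 = params.mean_cell_area_um2 + params.area_tolerance_um2
    else:
        grow_mask = (
            labeling.layer.tissue_mask if labeling is not None else np.ones(shape, bool)
        )
        grow_mask = grow_mask | (nuc_lab > 0)
        cap_um2 = params.mean_cell_area_um2

    cells_lab = watershed(dist_to_nuc, markers=nuc_lab, mask=grow_mask)

    px2 = slide.pixel_size**2
    cap_px = max(1, int(round(cap_um2 / px2)))

    roi_img = labeling.roi_label_image() if labeling is not None else None
    roi_class_of = (
        {r.id: r.class_name for r in labeling.roi_objects} if labeling is not None else {}
    )

    out_lab = np.zeros(shape, dtype=np.int64)
    records: list[CellRecord] = []
    slices = ndi.find_objects(cells_lab)
    structure = ndi.generate_binary_structure(2, 1)
    for k, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = cells_lab[sl] == k
        nuc_sub = nuc_lab[sl] == k
        # ROI constraint: clip to the nucleus's ROI object
        roi_id = 0
        if roi_img is not None:
            roi_sub = roi_img[sl]
            vals = roi_sub[nuc_sub]
            if vals.size:
                nz = vals[vals > 0]
                roi_id = int(np.bincount(nz).argmax()) if nz.size else 0
            if roi_id:
                sub = sub & ((roi_sub == roi_id) | nuc_sub)
        # cap at the mean-cell-area budget, nearest-to-nucleus pixels first
        n_px = int(sub.sum())
        if n_px > cap_px:
            d = np.where(sub, dist_to_nuc[sl], np.inf)
            order = np.argsort(d, axis=None, kind="stable")[:cap_px]
            keep = np.zeros(sub.size, dtype=bool)
            keep[order] = True
            sub = keep.reshape(sub.shape) | nuc_sub
        # keep the component containing the nucleus
        comp, nc = ndi.label(sub, structure=structure)
        if nc > 1:
            ids_on_nuc = np.unique(comp[nuc_sub])
            ids_on_nuc = ids_on_nuc[ids_on_nuc > 0]
            sub = np.isin(comp, ids_on_nuc) if ids_on_nuc.size else nuc_sub
        out_sub = out_lab[sl]
        out_sub[sub] = k
        records.append(
            CellRecord(
                id=k,
                roi_object_id=roi_id,
                roi_class=roi_class_of.get(roi_id, ""),
                centroid=tuple(nuclei.centroids[k - 1]),
                nucleus_area_um2=float(nuclei.areas_um2[k - 1]),
                cell_area_um2=float(sub.sum()) * px2,
                nucleus_mean={},
                cell_mean={},
            )
        )

    ids = np.array([r.id for r in records], dtype=np.int64)
    for name, arr in slide.channels.items():
        arr = arr.astype(np.float64)
        nuc_means = ndi.mean(arr, labels=nuc_lab, index=ids)
        cell_means = ndi.mean(arr, labels=out_lab, index=ids)
        for r, nm, cm in zip(records, nuc_means, cell_means):
            r.nucleus_mean[name] = float(nm)
            r.cell_mean[name] = float(cm)
    return CellPopulation(records, out_lab, nuc_lab)


# ---------------------------------------------------------------------------
# threshold calibration


def calibrate_thresholds(
    positive_fields: list[Slide],
    control_fields: list[Slide],
    nuclear_channel: str = "DAPI",
    marker_channel: str = "FITC",
    params: NucleusParams | None = None,
    nuclear_percentile: float = 5.0,
    marker_percentile: float = 99.5,
) -> ClassificationThresholds:
    """Suggest preliminary classification thresholds from calibration fields.

    nuclear_min = minimum over positive fields of the per-field robust
    nuclear statistic (5th percentile of per-nucleus mean DAPI);
    marker_min = maximum over antibody-free control fields of the per-field
    robust marker statistic (99.5th percentile of marker pixels).  These
    are starting points — the stored configuration remains authoritative.
    """
    if not positive_fields or not control_fields:
        raise ValueError("need at least one positive and one control field")
    params = params or NucleusParams()
    nuclear_stats = []
    for fld in positive_fields:
        nuc = detect_nuclei(fld, None, None, params, nuclear_channel)
        if len(nuc) == 0:
            nuclear_stats.append(0.0)
            continue
        means = ndi.mean(
            fld.channel(nuclear_channel).astype(np.float64),
            labels=nuc.label_image,
            index=nuc.ids,
        )
        nuclear_stats.append(float(np.percentile(means, nuclear_percentile)))
    marker_stats = [
        float(np.percentile(fld.channel(marker_channel), marker_percentile))
        for fld in control_fields
    ]
    return ClassificationThresholds(
        nuclear_min=min(nuclear_stats),
        marker_min={marker_channel: max(marker_stats)},
    )


# ---------------------------------------------------------------------------
# phenotype classification


def classify_cells(
    cells: list[CellRecord] | CellPopulation,
    thresholds: ClassificationThresholds,
    scheme: PhenotypeScheme,
) -> list[CellRecord]:
    """Assign every cell exactly one phenotype.

    The nuclear gate uses the mean nuclear-channel intensity over the
    nucleus footprint; marker calls use mean marker intensity over the
    whole cell footprint.  All comparisons are inclusive (≥).
    """
    records = cells.cells if isinstance(cells, CellPopulation) else cells
    for marker, channel in scheme.marker_channels.items():
        if channel not in thresholds.marker_min:
            raise ValueError(f"no marker_min threshold for channel {channel!r} ({marker})")
    for r in records:
        for channel in scheme.marker_channels.values():
            if channel not in r.cell_mean:
                raise ValueError(f"cell {r.id} has no intensity for channel {channel!r}")
        nuclear_ok = r.nucleus_mean.get(scheme.nuclear_channel, 0.0) >= thresholds.nuclear_min
        if scheme.name == "single_CD45":
            channel = scheme.marker_channels["CD45"]
            marker_ok = r.cell_mean[channel] >= thresholds.marker_min[channel]
            r.phenotype = "positive" if (nuclear_ok and marker_ok) else "negative"
        else:
            cd3_ch = scheme.marker_channels["CD3"]
            cd4_ch = scheme.marker_channels["CD4"]
            cd3 = nuclear_ok and r.cell_mean[cd3_ch] >= thresholds.marker_min[cd3_ch]
            cd4 = nuclear_ok and r.cell_mean[cd4_ch] >= thresholds.marker_min[cd4_ch]
            r.phenotype = f"CD3{'+' if cd3 else '-'}CD4{'+' if cd4 else '-'}"
    return records


# ---------------------------------------------------------------------------
# artifact exclusion


def exclude_artifacts(
    cells: list[CellRecord] | CellPopulation,
    labeling: ROILabeling | None = None,
    min_cell_area_um2: float = 10.0,
) -> tuple[list[CellRecord], list[tuple[int, str]]]:
    """Drop artifact detections; every exclusion is logged with a reason.

    Membrane blobs without nuclei never become cells (the co-staining gate
    upstream), so the remaining filters are: cells whose nucleus centroid
    falls in an edge-exclusion ``*_bis`` region (their counts are dropped
    but the bis area stays in density denominators, see
    :mod:`ifquant.quantify`), and cells below the minimum cell area.
    """
    records = cells.cells if isinstance(cells, CellPopulation) else cells
    kept: list[CellRecord] = []
    excluded: list[tuple[int, str]] = []
    for r in records:
        if r.roi_class.endswith(BIS_SUFFIX):
            r.excluded_reason = "edge_exclusion"
            excluded.append((r.id, "edge_exclusion"))
        elif r.cell_area_um2 < min_cell_area_um2:
            r.excluded_reason = "below_min_cell_area"
            excluded.append((r.id, "below_min_cell_area"))
        else:
            kept.append(r)
    return kept, excluded
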