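"""Synthetic multichannel colon-like slides with exact ground truth.

The generator emulates the imagery the pipeline is built for: a tissue
section on a dark background containing a textured mucosa band, dense
round lymphoid-follicle nuclear clusters, irregular tumor blobs and an
other-tissue remainder; a DAPI nuclear channel rendering ~35 µm² nuclei;
one or two membrane channels with ring-like staining around
phenotype-positive cells; background noise; fluorochrome-aggregate
artifacts and, optionally, tissue-edge autofluorescence with matching
``mucosa_bis`` edge-exclusion ground truth.

Default per-region marker-positive densities are the colon study
conditions: lymphoid follicle 2.10×10⁴, mucosa 2.97×10³ and tumor
3.22×10³ cells/mm².  Cell placement is a hard-core point process (dart
throwing with a minimum separation expressed as a fraction of the nucleus
diameter); requested densities that cannot be packed raise an explicit
overcrowding error rather than silently thinning.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.morphology import disk

from .cell_engine import CellRecord
from .slide_model import DEFAULT_PIXEL_SIZE_UM, LabelMask, Slide

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_slide",
    "generate_negative_control",
    "OvercrowdingError",
    "match_to_ground_truth",
]

REGIONS = ("mucosa", "lymphoid_follicle", "tumor", "other_tissue", "background")

#: region-class codes used in ground-truth masks
GT_CODES = {
    "mucosa": 1,
    "lymphoid_follicle": 2,
    "tumor": 3,
    "other_tissue": 4,
    "background": 5,
    "mucosa_bis": 6,
    "tumor_bis": 7,
}


class OvercrowdingError(RuntimeError):
    """A region cannot fit its requested cell density."""


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the study conditions.

    Densities are marker-positive cells/mm² per region (the published
    per-region values); ``negative_density`` adds marker-negative cells on
    top.  ``separation_factor`` scales the hard-core minimum separation in
    units of the mean nucleus diameter; the follicle value is below 1
    because follicles are the densely packed compartment whose requested
    density exceeds what full-diameter separation can geometrically hold —
    the resulting nucleus overlap is also what exercises prior-driven
    nucleus splitting there.
    """

    shape: tuple[int, int] = (2048, 2048)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = 16
    scheme: str = "single"  # "single" (CD45/FITC) or "double" (CD3/Cy3 + CD4/FITC)
    seed: int = 0

    # geometry (fractions of the tissue bounding box / short side)
    tissue_frac: float = 0.90
    mucosa_band_frac: float = 0.25
    n_follicles: int = 2
    n_tumors: int = 2
    follicle_radius_frac: float = 0.27
    tumor_radius_frac: float = 0.30

    # cells: marker-positive density (cells/mm²) and additional negatives
    positive_density: dict[str, float] = field(
        default_factory=lambda: {
            "mucosa": 2.97e3,
            "lymphoid_follicle": 2.10e4,
            "tumor": 3.22e3,
            "other_tissue": 0.0,
        }
    )
    negative_density: dict[str, float] = field(
        default_factory=lambda: {
            "mucosa": 2.97e3,
            "lymphoid_follicle": 1.1e3,
            "tumor": 3.22e3,
            "other_tissue": 1.5e3,
        }
    )
    #: for the double scheme: fraction of CD3+ cells that are also CD4+
    cd4_fraction: float = 0.6

    mean_nucleus_area_um2: float = 35.0
    nucleus_area_sd_um2: float = 4.0
    mean_cell_area_um2: float = 38.0
    separation_factor: dict[str, float] = field(
        default_factory=lambda: {
            "mucosa": 1.0,
            "lymphoid_follicle": 0.85,
            "tumor": 1.0,
            "other_tissue": 1.0,
        }
    )
    #: "dart" = hard-core dart throwing (sparse compartments);
    #: "hex_packed" = jittered hexagonal close packing for compartments
    #: whose requested density exceeds what random sequential placement
    #: can reach (lymphocytes in follicles sit jammed against each other)
    placement_mode: dict[str, str] = field(
        default_factory=lambda: {"lymphoid_follicle": "hex_packed"}
    )

    # rendering levels (g.v.l)
    dapi_nucleus_level: float = 22000.0
    dapi_nucleus_sd: float = 3000.0
    dapi_base: dict[str, float] = field(
        default_factory=lambda: {
            "background": 150.0,
            "other_tissue": 1500.0,
            "mucosa": 4000.0,
            "lymphoid_follicle": 6000.0,
            "tumor": 8000.0,
        }
    )
    noise_sd: float = 80.0
    membrane_ring_level: float = 8000.0
    membrane_ring_sd: float = 800.0
    cy3_ring_level: float = 52000.0
    cy3_ring_sd: float = 1500.0
    membrane_background: float = 200.0
    follicle_blur_sigma_px: float = 2.0

    # artifacts
    n_aggregates: int = 4
    aggregate_level: float = 20000.0
    edge_autofluorescence: bool = False
    edge_band_um: float = 8.0
    edge_level: float = 5000.0

    def __post_init__(self) -> None:
        if self.scheme not in ("single", "double"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for d in (self.positive_density, self.negative_density):
            if any(v < 0 for v in d.values()):
                raise ValueError("densities must be >= 0")
        if not 0 <= self.cd4_fraction <= 1:
            raise ValueError("cd4_fraction must be in [0, 1]")

    @property
    def channel_names(self) -> list[str]:
        return ["DAPI", "FITC"] if self.scheme == "single" else ["DAPI", "CY3", "FITC"]


@dataclass
class GroundTruth:
    """Everything the generator knows: the test oracle.

    cells columns: cell_id, row, col, region, phenotype, nucleus_area_um2;
    artifacts columns: row, col, kind.
    """

    roi_mask: LabelMask
    cells: pd.DataFrame
    artifacts: pd.DataFrame
    pixel_size: float

    def region_area_um2(self, region: str) -> float:
        return float(np.count_nonzero(self.roi_mask.class_mask(region))) * self.pixel_size**2

    def positive_count(self, region: str, positive_phenotypes=("positive",)) -> int:
        sel = (self.cells["region"] == region) & self.cells["phenotype"].isin(
            positive_phenotypes
        )
        return int(sel.sum())

    def positive_density(self, region: str, positive_phenotypes=("positive",)) -> float:
        area = self.region_area_um2(region) + self.region_area_um2(region + "_bis")
        n = self.positive_count(region, positive_phenotypes)
        return n * 1e6 / area if area else 0.0


# ---------------------------------------------------------------------------
# geometry


def _region_map(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer region map using GT_CODES over the full frame."""
    h, w = config.shape
    rows, cols = np.mgrid[0:h, 0:w]
    m = np.full(config.shape, GT_CODES["background"], dtype=np.int64)

    th = int(h * config.tissue_frac)
    tw = int(w * config.tissue_frac)
    r0, c0 = (h - th) // 2, (w - tw) // 2
    tissue = (rows >= r0) & (rows < r0 + th) & (cols >= c0) & (cols < c0 + tw)
    # soften the corners so the section has a rounded outline
    rad = int(0.08 * min(th, tw))
    for cr, cc in ((r0, c0), (r0, c0 + tw - 1), (r0 + th - 1, c0), (r0 + th - 1, c0 + tw - 1)):
        corner_r = r0 + rad if cr == r0 else r0 + th - 1 - rad
        corner_c = c0 + rad if cc == c0 else c0 + tw - 1 - rad
        # pixels in the square corner but outside the quarter-circle
        in_sq = (np.abs(rows - cr) <= rad) & (np.abs(cols - cc) <= rad)
        out_circ = (rows - corner_r) ** 2 + (cols - corner_c) ** 2 > rad**2
        tissue &= ~(in_sq & out_circ)
    m[tissue] = GT_CODES["other_tissue"]

    band_w = int(tw * config.mucosa_band_frac)
    mucosa = tissue & (cols < c0 + band_w)
    m[mucosa] = GT_CODES["mucosa"]

    short = min(th, tw)
    f_rad = config.follicle_radius_frac * short / 2.0
    t_rad = config.tumor_radius_frac * short / 2.0

    # follicles: disks in the mid column of the non-mucosa part
    f_col = c0 + band_w + int(0.35 * (tw - band_w))
    for i in range(config.n_follicles):
        fr = r0 + int(th * (0.25 + 0.5 * (i / max(1, config.n_follicles - 1))))
        d2 = (rows - fr) ** 2 + (cols - f_col) ** 2
        m[(d2 <= f_rad**2) & tissue] = GT_CODES["lymphoid_follicle"]

    # tumors: irregular blobs toward the right edge
    t_col = c0 + band_w + int(0.78 * (tw - band_w))
    for i in range(config.n_tumors):
        tr = r0 + int(th * (0.25 + 0.5 * (i / max(1, config.n_tumors - 1))))
        phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
        dy = rows - tr
        dx = cols - t_col
        ang = np.arctan2(dy, dx)
        r_mod = t_rad * (1.0 + 0.22 * np.sin(3 * ang + phi1) + 0.12 * np.sin(5 * ang + phi2))
        sel = (dy**2 + dx**2 <= r_mod**2) & tissue
        m[sel & (m != GT_CODES["lymphoid_follicle"])] = GT_CODES["tumor"]

    if config.edge_autofluorescence:
        band_px = max(1, int(round(config.edge_band_um / config.pixel_size)))
        interior = ndi.binary_erosion(tissue, structure=disk(band_px))
        edge = tissue & ~interior
        m[edge & (m == GT_CODES["mucosa"])] = GT_CODES["mucosa_bis"]
        m[edge & (m == GT_CODES["tumor"])] = GT_CODES["tumor_bis"]
    return m


# ---------------------------------------------------------------------------
# hard-core cell placement


def _place_cells(
    region_mask: np.ndarray,
    n_target: int,
    min_sep_px: float,
    rng: np.random.Generator,
    occupied: dict[tuple[int, int], list[tuple[float, float]]],
    grid_cell: float,
) -> list[tuple[int, int]]:
    """Dart-throwing with a global spatial hash; raises on overcrowding."""
    if n_target == 0:
        return []
    cand = np.flatnonzero(region_mask.ravel())
    if cand.size == 0:
        raise OvercrowdingError("region has no placeable pixels")
    w = region_mask.shape[1]
    placed: list[tuple[int, int]] = []
    attempts_left = 2000 * n_target
    sep2 = min_sep_px * min_sep_px
    while len(placed) < n_target:
        if attempts_left <= 0:
            raise OvercrowdingError(
                f"placed {len(placed)}/{n_target} cells before exhausting attempts; "
                "requested density exceeds what the region can pack"
            )
        attempts_left -= 1
        idx = int(cand[rng.integers(cand.size)])
        r, c = divmod(idx, w)
        gr, gc = int(r // grid_cell), int(c // grid_cell)
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for (pr, pc) in occupied.get((gr + dr, gc + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed.append((r, c))
            occupied.setdefault((gr, gc), []).append((float(r), float(c)))
    return placed


def _place_cells_hex(
    region_mask: np.ndarray,
    n_target: int,
    spacing_px: float,
    rng: np.random.Generator,
    occupied: dict[tuple[int, int], list[tuple[float, float]]],
    grid_cell: float,
    jitter_frac: float = 0.12,
) -> list[tuple[int, int]]:
    """Jittered hexagonal close packing; raises on overcrowding.

    A hexagonal lattice at ``spacing_px`` is laid over the region, each
    site jittered by up to ``jitter_frac``·spacing, and ``n_target`` sites
    are drawn at random.  This reaches the near-touching densities of
    jammed cell packings that random sequential (dart) placement cannot.
    """
    if n_target == 0:
        return []
    h, w = region_mask.shape
    dy = spacing_px * np.sqrt(3) / 2.0
    sites = []
    jit = jitter_frac * spacing_px
    row_vals = np.arange(dy / 2.0, h, dy)
    for i, rv in enumerate(row_vals):
        offset = spacing_px / 2.0 if i % 2 else 0.0
        for cv in np.arange(offset + spacing_px / 2.0, w, spacing_px):
            r = int(round(rv + rng.uniform(-jit, jit)))
            c = int(round(cv + rng.uniform(-jit, jit)))
            if 0 <= r < h and 0 <= c < w and region_mask[r, c]:
                sites.append((r, c))
    if n_target > len(sites):
        raise OvercrowdingError(
            f"hex-packed region holds {len(sites)} sites, {n_target} cells requested"
        )
    chosen = rng.choice(len(sites), size=n_target, replace=False)
    placed = [sites[i] for i in sorted(chosen.tolist())]
    for r, c in placed:
        gr, gc = int(r // grid_cell), int(c // grid_cell)
        occupied.setdefault((gr, gc), []).append((float(r), float(c)))
    return placed


# ---------------------------------------------------------------------------
# rendering


def _draw_disk(img: np.ndarray, r: int, c: int, radius_px: float, value: float) -> None:
    rad = int(np.ceil(radius_px))
    h, w = img.shape
    r0, r1 = max(0, r - rad), min(h, r + rad + 1)
    c0, c1 = max(0, c - rad), min(w, c + rad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    sel = (yy - r) ** 2 + (xx - c) ** 2 <= radius_px**2
    img[r0:r1, c0:c1][sel] = value


def _draw_nucleus(img: np.ndarray, r: int, c: int, radius_px: float, value: float) -> None:
    """Nucleus with a radial falloff (bright centre, 70% at the rim), as
    widefield DAPI renders chromatin; overlaps keep the brighter value so
    touching nuclei still show per-nucleus intensity maxima."""
    rad = int(np.ceil(radius_px))
    h, w = img.shape
    r0, r1 = max(0, r - rad), min(h, r + rad + 1)
    c0, c1 = max(0, c - rad), min(w, c + rad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = ((yy - r) ** 2 + (xx - c) ** 2) / radius_px**2
    profile = np.where(d2 <= 1.0, value * (1.0 - 0.3 * d2), 0.0)
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, profile, out=patch)


def _draw_ring(
    img: np.ndarray, r: int, c: int, r_inner_px: float, r_outer_px: float, value: float
) -> None:
    rad = int(np.ceil(r_outer_px))
    h, w = img.shape
    r0, r1 = max(0, r - rad), min(h, r + rad + 1)
    c0, c1 = max(0, c - rad), min(w, c + rad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - r) ** 2 + (xx - c) ** 2
    sel = (d2 <= r_outer_px**2) & (d2 >= r_inner_px**2)
    img[r0:r1, c0:c1][sel] = value


def _generate(config: SynthConfig, omit: frozenset[str]) -> tuple[Slide, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size
    px2 = px * px
    region_map = _region_map(config, rng)

    mean_rad_px = float(np.sqrt(config.mean_nucleus_area_um2 / np.pi)) / px
    grid_cell = max(2.0, mean_rad_px * 2.0)
    occupied: dict[tuple[int, int], list[tuple[float, float]]] = {}

    # placement regions: erode by half a nucleus radius — centres stay
    # clearly inside their region (a little rim spill is realistic) while
    # keeping the effective packing density close to the nominal one
    erode = disk(max(1, int(round(mean_rad_px / 2))))
    records = []
    cid = 0
    for region in ("mucosa", "lymphoid_follicle", "tumor", "other_tissue"):
        codes = [GT_CODES[region]]
        bis = region + "_bis"
        if config.edge_autofluorescence and bis in GT_CODES:
            codes.append(GT_CODES[bis])
        rmask = np.isin(region_map, codes)
        area_mm2 = rmask.sum() * px2 / 1e6
        place_mask = ndi.binary_erosion(rmask, structure=erode)
        n_pos = int(rng.poisson(config.positive_density.get(region, 0.0) * area_mm2))
        n_neg = int(rng.poisson(config.negative_density.get(region, 0.0) * area_mm2))
        sep_px = (
            config.separation_factor.get(region, 1.0) * 2.0 * mean_rad_px
        )
        if config.placement_mode.get(region, "dart") == "hex_packed":
            # lattice capacity is the packing bound here, so only a thin
            # rim is eroded; jammed nuclei do brush their compartment edge
            hex_mask = ndi.binary_erosion(rmask, structure=disk(2))
            pts = _place_cells_hex(
                hex_mask, n_pos + n_neg, sep_px, rng, occupied, grid_cell
            )
        else:
            pts = _place_cells(place_mask, n_pos + n_neg, sep_px, rng, occupied, grid_cell)
        flags = np.array([True] * n_pos + [False] * n_neg)
        rng.shuffle(flags)
        for (r, c), is_pos in zip(pts, flags):
            cid += 1
            area = float(
                np.clip(
                    rng.normal(config.mean_nucleus_area_um2, config.nucleus_area_sd_um2),
                    20.0,
                    60.0,
                )
            )
            cell_region = region
            if config.edge_autofluorescence and bis in GT_CODES:
                if region_map[r, c] == GT_CODES[bis]:
                    cell_region = bis
            if config.scheme == "single":
                pheno = "positive" if is_pos else "negative"
                cd3 = cd4 = is_pos  # unused for single
            else:
                cd3 = bool(is_pos)
                cd4 = bool(is_pos and rng.random() < config.cd4_fraction)
                pheno = f"CD3{'+' if cd3 else '-'}CD4{'+' if cd4 else '-'}"
            records.append(
                {
                    "cell_id": cid,
                    "row": r,
                    "col": c,
                    "region": cell_region,
                    "phenotype": pheno,
                    "nucleus_area_um2": area,
                    "_cd3": cd3,
                    "_cd4": cd4,
                }
            )
    cells = pd.DataFrame(
        records,
        columns=[
            "cell_id", "row", "col", "region", "phenotype",
            "nucleus_area_um2", "_cd3", "_cd4",
        ],
    )

    # ---------------- channels ----------------
    h, w = config.shape
    base_lut = np.zeros(max(GT_CODES.values()) + 1)
    for name, lvl in config.dapi_base.items():
        base_lut[GT_CODES[name]] = lvl
    base_lut[GT_CODES["mucosa_bis"]] = config.dapi_base["mucosa"]
    base_lut[GT_CODES["tumor_bis"]] = config.dapi_base["tumor"]
    dapi = base_lut[region_map].astype(np.float64)
    # mucosa crypt-like texture: periodic modulation along rows
    mucosa_sel = np.isin(region_map, [GT_CODES["mucosa"], GT_CODES["mucosa_bis"]])
    if mucosa_sel.any():
        rows = np.arange(h)[:, None]
        texture = 1200.0 * np.sin(2 * np.pi * rows * px / 25.0)
        dapi += np.where(mucosa_sel, np.broadcast_to(texture, (h, w)), 0.0)

    for rec in records:
        rad_px = float(np.sqrt(rec["nucleus_area_um2"] / np.pi)) / px
        level = float(
            np.clip(rng.normal(config.dapi_nucleus_level, config.dapi_nucleus_sd), 8000, 60000)
        )
        _draw_nucleus(dapi, rec["row"], rec["col"], rad_px, level)

    # follicles: blur to emulate the dense, smeared nuclear signal
    if config.follicle_blur_sigma_px > 0:
        fol = np.isin(region_map, [GT_CODES["lymphoid_follicle"]])
        if fol.any():
            blurred = gaussian(dapi, sigma=config.follicle_blur_sigma_px, preserve_range=True)
            dapi = np.where(fol, blurred, dapi)

    dapi += rng.normal(0.0, config.noise_sd, size=config.shape)

    cell_rad_px = float(np.sqrt(config.mean_cell_area_um2 / np.pi)) / px

    def _membrane_channel(level: float, sd: float, marker: str) -> np.ndarray:
        # rng draws happen for every stained cell regardless of omission so
        # that a negative control shares the stained slide's cell layout
        ch = np.full(config.shape, config.membrane_background, dtype=np.float64)
        for rec in records:
            if config.scheme == "single":
                stain = rec["phenotype"] == "positive"
            else:
                stain = rec["_cd3"] if marker == "CD3" else rec["_cd4"]
            if not stain:
                continue
            ring_level = float(np.clip(rng.normal(level, sd), 0, 65535))
            if marker in omit:
                continue
            nuc_rad = float(np.sqrt(rec["nucleus_area_um2"] / np.pi)) / px
            _draw_ring(
                ch, rec["row"], rec["col"], 0.6 * nuc_rad, max(cell_rad_px, nuc_rad + 1), ring_level
            )
        ch += rng.normal(0.0, config.noise_sd, size=config.shape)
        return ch

    channels: dict[str, np.ndarray] = {}
    if config.scheme == "single":
        fitc = _membrane_channel(config.membrane_ring_level, config.membrane_ring_sd, "CD45")
    else:
        cy3 = _membrane_channel(config.cy3_ring_level, config.cy3_ring_sd, "CD3")
        fitc = _membrane_channel(config.membrane_ring_level, config.membrane_ring_sd, "CD4")

    # artifacts: fluorochrome aggregates — extracellular deposits of the
    # detection fluorochrome (bright membrane signal, no nucleus), so they
    # are placed clear of cells and vanish when that marker is omitted
    tissue_sel = region_map != GT_CODES["background"]
    art_rows = []
    fitc_marker = "CD45" if config.scheme == "single" else "CD4"
    cand = np.flatnonzero(tissue_sel.ravel())
    agg_sep_px = 4.0 * mean_rad_px
    placed_aggs = 0
    attempts = 200 * max(1, config.n_aggregates)
    while placed_aggs < config.n_aggregates and attempts > 0:
        attempts -= 1
        idx = int(cand[rng.integers(cand.size)])
        r, c = divmod(idx, w)
        gr, gc = int(r // grid_cell), int(c // grid_cell)
        reach = int(np.ceil(agg_sep_px / grid_cell))
        clear = True
        for dr in range(-reach, reach + 1):
            for dc in range(-reach, reach + 1):
                for (pr, pc) in occupied.get((gr + dr, gc + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < agg_sep_px**2:
                        clear = False
                        break
                if not clear:
                    break
            if not clear:
                break
        if not clear:
            continue
        if fitc_marker not in omit:
            _draw_disk(fitc, r, c, 1.5 / px, config.aggregate_level)
        art_rows.append({"row": r, "col": c, "kind": "aggregate"})
        placed_aggs += 1
    if config.edge_autofluorescence:
        band_px = max(1, int(round(config.edge_band_um / config.pixel_size)))
        interior = ndi.binary_erosion(tissue_sel, structure=disk(band_px))
        edge = tissue_sel & ~interior
        fitc = np.where(edge, np.maximum(fitc, config.edge_level), fitc)
        if config.scheme == "double":
            cy3 = np.where(edge, np.maximum(cy3, 49000.0), cy3)
        art_rows.append({"row": -1, "col": -1, "kind": "edge_autofluorescence"})
    artifacts = pd.DataFrame(art_rows, columns=["row", "col", "kind"])

    channels["DAPI"] = np.clip(dapi, 0, 65535).astype(np.uint16)
    if config.scheme == "double":
        channels["CY3"] = np.clip(cy3, 0, 65535).astype(np.uint16)
    channels["FITC"] = np.clip(fitc, 0, 65535).astype(np.uint16)

    # ground truth with omitted markers forced negative
    if omit:
        if config.scheme == "single":
            cells["phenotype"] = "negative"
        else:
            cd3 = cells["_cd3"] & ("CD3" not in omit)
            cd4 = cells["_cd4"] & ("CD4" not in omit)
            cells["phenotype"] = [
                f"CD3{'+' if a else '-'}CD4{'+' if b else '-'}" for a, b in zip(cd3, cd4)
            ]
    gt_cells = cells.drop(columns=["_cd3", "_cd4"])
    legend = {v: k for k, v in GT_CODES.items() if v in np.unique(region_map)}
    gt = GroundTruth(
        LabelMask(region_map, legend), gt_cells, artifacts, config.pixel_size
    )
    slide = Slide(channels, config.pixel_size, config.bit_depth)
    return slide, gt


def generate_slide(config: SynthConfig) -> tuple[Slide, GroundTruth]:
    """Generate a stained synthetic slide and its ground truth."""
    return _generate(config, frozenset())


def generate_negative_control(
    config: SynthConfig, omit: str | None = None
) -> tuple[Slide, GroundTruth]:
    """No-primary-antibody control: identical layout and cells, but the
    omitted marker's channel carries only sub-threshold background and the
    ground truth marks every cell negative for that marker.

    ``omit`` is ignored for the single scheme (the one membrane marker is
    omitted); for the double scheme it must be "CD3" or "CD4".
    """
    if config.scheme == "single":
        markers = frozenset({"CD45"})
    else:
        if omit not in ("CD3", "CD4"):
            raise ValueError("double-staining control must omit 'CD3' or 'CD4'")
        markers = frozenset({omit})
    return _generate(config, markers)


# ---------------------------------------------------------------------------
# ground-truth matching (test / validation oracle)


def match_to_ground_truth(
    cells: list[CellRecord],
    gt: GroundTruth,
    region: str,
    positive_phenotypes: tuple[str, ...] = ("positive",),
    max_dist_um: float = 6.0,
) -> dict[str, float]:
    """Greedy nearest-neighbour matching of detected positive cells to
    ground-truth positive cells of one region; returns precision, recall,
    F1 and the counts."""
    det = np.array(
        [c.centroid for c in cells if c.roi_class == region and c.phenotype in positive_phenotypes]
    ).reshape(-1, 2)
    truth = gt.cells[
        (gt.cells["region"] == region) & gt.cells["phenotype"].isin(positive_phenotypes)
    ]
    tpts = truth[["row", "col"]].to_numpy(float)
    max_px = max_dist_um / gt.pixel_size
    n_det, n_true = len(det), len(tpts)
    if n_det == 0 or n_true == 0:
        tp = 0
    else:
        d = np.linalg.norm(det[:, None, :] - tpts[None, :, :], axis=2)
        tp = 0
        used_d = np.zeros(n_det, bool)
        used_t = np.zeros(n_true, bool)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if d[i, j] > max_px:
                break
            if used_d[i] or used_t[j]:
                continue
            used_d[i] = used_t[j] = True
            tp += 1
    precision = tp / n_det if n_det else (1.0 if n_true == 0 else 0.0)
    recall = tp / n_true if n_true else 1.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return {
        "tp": tp,
        "n_detected": n_det,
        "n_true": n_true,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
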