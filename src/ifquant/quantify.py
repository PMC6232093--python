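"""Per-region areas, cell densities and validation statistics.

The headline quantity is the marker-positive cell density of a region
class, in cells/mm²:

    density = positive cells × 10⁶ / (region area [µm²] + bis area [µm²])

The bis term carries the edge-exclusion convention: cells detected in a
``*_bis`` region are never counted in the numerator, but the bis area
still belongs to the parent region's denominator, so edge trimming cannot
inflate densities.

Validation statistics are the ones used for such pipelines: Pearson
correlation between reported densities and an expert 0–5 manual score
(t-transform p with n−2 degrees of freedom), and a one-way ANOVA comparing
densities across region classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cell_engine import CellRecord, PhenotypeScheme
from .roi_engine import BIS_SUFFIX, IROI_CLASSES, ROILabeling

__all__ = [
    "DensityReport",
    "ManualScoreTable",
    "density",
    "summarize",
    "correlate_manual",
    "compare_rois",
]

UM2_PER_MM2 = 1e6


def density(count: int, area_um2: float, bis_area_um2: float = 0.0) -> float:
    """Cell density in cells/mm² from a count and µm² areas.

    density = count × 10⁶ / (area + bis area).  Zero area with zero count
    is 0 by convention; a positive count on zero area is an error.
    """
    total_area = float(area_um2) + float(bis_area_um2)
    if count < 0:
        raise ValueError("count must be >= 0")
    if total_area < 0:
        raise ValueError("areas must be >= 0")
    if total_area == 0:
        if count == 0:
            return 0.0
        raise ValueError("positive count over zero area")
    return count * UM2_PER_MM2 / total_area


@dataclass
class DensityReport:
    """Per-(slide, region class) areas, counts and densities.

    One row per slide and region class with columns:

    slide_id, roi_class, area_um2, area_mm2, bis_area_um2, total_cells,
    count_<phenotype>... and density_<phenotype>... (cells/mm², computed
    with the bis area folded into the denominator).
    """

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DensityReport":
        return cls(frame.reset_index(drop=True))

    @classmethod
    def concat(cls, reports: list["DensityReport"]) -> "DensityReport":
        frames = [r.rows for r in reports if len(r.rows)]
        if not frames:
            return cls()
        return cls(pd.concat(frames, ignore_index=True))

    def row(self, slide_id: str, roi_class: str) -> pd.Series:
        sel = (self.rows["slide_id"] == slide_id) & (self.rows["roi_class"] == roi_class)
        match = self.rows[sel]
        if len(match) != 1:
            raise KeyError(f"{slide_id}/{roi_class}: {len(match)} rows")
        return match.iloc[0]

    def densities(self, roi_class: str, phenotype: str) -> np.ndarray:
        sel = self.rows["roi_class"] == roi_class
        return self.rows.loc[sel, f"density_{phenotype}"].to_numpy(float)


def summarize(
    labeling: ROILabeling,
    cells: list[CellRecord],
    scheme: PhenotypeScheme,
    slide_id: str = "slide",
    roi_classes: tuple[str, ...] = IROI_CLASSES,
) -> DensityReport:
    """Aggregate a slide's labeling and cells into a density report.

    One row per requested region class; ``*_bis`` areas are folded into
    the parent class's denominator only.  Cells must reference ROI classes
    the labeling knows.
    """
    known = labeling.classes_present
    for c in cells:
        if c.roi_class and c.roi_class not in known:
            raise ValueError(f"cell {c.id} references unknown ROI class {c.roi_class!r}")
    phenos = scheme.classes
    recs = []
    for cls in roi_classes:
        area = labeling.class_area_um2(cls)
        bis_area = labeling.class_area_um2(cls + BIS_SUFFIX)
        mine = [c for c in cells if c.roi_class == cls]
        counts = {p: sum(1 for c in mine if c.phenotype == p) for p in phenos}
        rec = {
            "slide_id": slide_id,
            "roi_class": cls,
            "area_um2": area,
            "area_mm2": area / UM2_PER_MM2,
            "bis_area_um2": bis_area,
            "total_cells": len(mine),
        }
        for p in phenos:
            rec[f"count_{p}"] = counts[p]
            rec[f"density_{p}"] = density(counts[p], area, bis_area)
        recs.append(rec)
    return DensityReport(pd.DataFrame(recs))


@dataclass
class ManualScoreTable:
    """Expert density grades: rows of (slide_id, roi_class, score in [0, 5])."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"slide_id", "roi_class", "score"}
        missing = needed - set(self.rows.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        s = self.rows["score"]
        if ((s < 0) | (s > 5)).any():
            raise ValueError("scores must lie in [0, 5]")

    @classmethod
    def from_csv(cls, path) -> "ManualScoreTable":
        return cls(pd.read_csv(path))


class ZeroVarianceError(ValueError):
    """Correlation is undefined when either variable is constant."""


def correlate_manual(
    report: DensityReport,
    scores: ManualScoreTable,
    roi_class: str,
    phenotype: str = "positive",
) -> tuple[float, float]:
    """Pearson correlation between reported densities and manual scores.

    Pairs are matched by slide_id for one region class; the p-value is the
    two-sided t-transform with n−2 degrees of freedom.  Fewer than three
    pairs, or zero variance in either variable, is an explicit error.
    """
    rep = report.rows[report.rows["roi_class"] == roi_class]
    sc = scores.rows[scores.rows["roi_class"] == roi_class]
    merged = rep.merge(sc, on="slide_id", suffixes=("", "_score"))
    x = merged[f"density_{phenotype}"].to_numpy(float)
    y = merged["score"].to_numpy(float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired observations, have {len(x)}")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ZeroVarianceError("constant densities or scores")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_rois(
    report: DensityReport,
    phenotype: str = "positive",
    roi_classes: tuple[str, ...] = IROI_CLASSES,
) -> tuple[float, float]:
    """One-way ANOVA of densities across region classes.

    Groups are the per-slide densities of each region class; the classical
    F statistic from between/within sums of squares and its p-value from
    the F distribution are returned.
    """
    groups = [report.densities(cls, phenotype) for cls in roi_classes]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for cls, g in zip(roi_classes, groups):
        if len(g) < 2:
            raise ValueError(f"group {cls!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
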