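"""End-to-end orchestration: one configuration, whole slides, batches.

Stage order is fixed: tissue detection → segmentation → ROI classification
→ rule-based reclassification → (optional) manual corrections → cellular
analysis → export.  One configuration serves a whole batch of slides so
that every section of a study is analysed with the same settings; each run
writes a manifest recording the fully resolved parameters and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cell_engine, quantify, roi_engine, segmentation, tissue_detection
from .cell_engine import (
    CellParams,
    CellPopulation,
    ClassificationThresholds,
    NucleusParams,
    PhenotypeScheme,
)
from .roi_engine import (
    BIS_SUFFIX,
    DEFAULT_CLASSES,
    IROI_CLASSES,
    ReclassRule,
    ROIClassSet,
    ROILabeling,
    TrainingExemplar,
)
from .slide_model import LabelMask, Slide, load_mask, load_slide, save_mask, write_report
from .tissue_detection import TissueParams

__all__ = ["AnalysisSettings", "PipelineConfig", "PipelineResult", "analyze_slide", "run_pipeline", "run_batch"]

log = logging.getLogger(__name__)

PIPELINE_VERSION = "0.1.0"


@dataclass
class AnalysisSettings:
    """Everything the analysis itself needs, independent of file paths."""

    tissue: TissueParams = field(default_factory=TissueParams)
    scale: float = 4.0
    base_area_um2: float = segmentation.DEFAULT_BASE_AREA_UM2
    class_set: ROIClassSet = field(default_factory=ROIClassSet)
    rules: list[ReclassRule] = field(default_factory=roi_engine.default_ruleset)
    manual_edits: list[tuple[int, str]] = field(default_factory=list)
    nucleus: NucleusParams = field(default_factory=NucleusParams)
    cell: CellParams = field(default_factory=CellParams)
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds.single_cd45
    )
    scheme: PhenotypeScheme = field(default_factory=PhenotypeScheme.single_cd45)
    iroi_classes: tuple[str, ...] = IROI_CLASSES
    min_cell_area_um2: float = 10.0
    seed: int = 17

    @classmethod
    def double_cd3_cd4(cls, **kw) -> "AnalysisSettings":
        """Defaults for the CD3(Cy3)/CD4(FITC) double-staining scheme."""
        return cls(
            cell=CellParams(
                membrane_channel="CY3",
                membrane_threshold=48356.0,
                mean_cell_area_um2=36.0,
            ),
            thresholds=ClassificationThresholds.double_cd3_cd4(),
            scheme=PhenotypeScheme.double_cd3_cd4(),
            **kw,
        )


@dataclass
class PipelineResult:
    """Report plus every intermediate artifact of one slide run."""

    slide_id: str
    report: quantify.DensityReport
    tissue_mask: LabelMask
    layer: segmentation.ObjectLayer
    labeling_raw: ROILabeling
    labeling: ROILabeling
    cells: CellPopulation
    kept_cells: list
    exclusions: list[tuple[int, str]]
    manifest: dict


def _check_scheme_channels(slide: Slide, settings: AnalysisSettings) -> None:
    needed = {settings.tissue.channel, settings.cell.membrane_channel}
    needed |= set(settings.scheme.marker_channels.values())
    needed.add(settings.scheme.nuclear_channel)
    missing = needed - set(slide.channel_names)
    if missing:
        raise ValueError(
            f"slide lacks channels {sorted(missing)}; has {slide.channel_names}"
        )


def analyze_slide(
    slide: Slide,
    exemplars: list[TrainingExemplar] | None,
    settings: AnalysisSettings | None = None,
    exemplar_mask: LabelMask | None = None,
    slide_id: str = "slide",
) -> PipelineResult:
    """Run the full analysis on one in-memory slide.

    Exemplars may be given directly or derived from a labelled exemplar
    mask by majority overlap.  All validation happens before any heavy
    computation; any stage error aborts with the stage name.
    """
    settings = settings or AnalysisSettings()
    _check_scheme_channels(slide, settings)
    t0 = time.time()
    manifest: dict = {
        "slide_id": slide_id,
        "version": PIPELINE_VERSION,
        "seed": settings.seed,
        "pixel_size_um": slide.pixel_size,
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                out = fn()
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                manifest["stages"][name] = {"status": "failed", "error": str(e)}
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"status": "ok", "t": round(time.time() - t0, 2)}
            return out

        return wrap

    tissue_mask = _stage("tissue_detection")(
        lambda: tissue_detection.detect_tissue(slide, settings.tissue)
    )
    layer = _stage("segmentation")(
        lambda: segmentation.compute_features(
            segmentation.segment_primitives(
                slide, tissue_mask, settings.scale, settings.base_area_um2
            ),
            slide,
            nuclear_channel=settings.scheme.nuclear_channel,
        )
    )
    manifest["stages"]["segmentation"]["n_objects"] = len(layer)

    if exemplars is None and exemplar_mask is None:
        raise ValueError("provide exemplars or an exemplar mask")

    def _train():
        ex = exemplars
        if ex is None:
            ex = roi_engine.exemplars_from_mask(layer, exemplar_mask)
        # the tissue mask already excludes background, so classes of the
        # configured set that yield no exemplar (typically background) are
        # dropped from training rather than treated as an error
        present_classes = {e.class_name for e in ex}
        trainable = tuple(c for c in settings.class_set.classes if c in present_classes)
        trainable += tuple(sorted(present_classes - set(trainable)))
        class_set = ROIClassSet(trainable)
        return roi_engine.train_classifier(layer, ex, class_set, seed=settings.seed)

    clf = _stage("roi_training")(_train)
    labeling_raw = _stage("roi_classification")(
        lambda: roi_engine.classify_objects(clf, layer)
    )
    labeling = _stage("roi_rules")(
        lambda: roi_engine.apply_rules(labeling_raw, settings.rules)
    )
    if settings.manual_edits:
        labeling = _stage("roi_manual_correction")(
            lambda: roi_engine.manual_correct(labeling, settings.manual_edits)
        )

    present = labeling.classes_present
    analysis_classes = [c for c in settings.iroi_classes if c in present]
    analysis_classes += [
        c + BIS_SUFFIX for c in settings.iroi_classes if c + BIS_SUFFIX in present
    ]
    nuclei = _stage("nucleus_detection")(
        lambda: cell_engine.detect_nuclei(
            slide,
            labeling,
            analysis_classes,
            settings.nucleus,
            nuclear_channel=settings.scheme.nuclear_channel,
        )
    )
    manifest["stages"]["nucleus_detection"]["n_nuclei"] = len(nuclei)
    cells = _stage("cell_simulation")(
        lambda: cell_engine.simulate_cells(nuclei, slide, labeling, settings.cell)
    )
    _stage("cell_classification")(
        lambda: cell_engine.classify_cells(cells, settings.thresholds, settings.scheme)
    )
    kept, exclusions = _stage("artifact_exclusion")(
        lambda: cell_engine.exclude_artifacts(
            cells, labeling, settings.min_cell_area_um2
        )
    )
    manifest["stages"]["artifact_exclusion"]["n_excluded"] = len(exclusions)
    report = _stage("export")(
        lambda: quantify.summarize(
            labeling, kept, settings.scheme, slide_id=slide_id,
            roi_classes=tuple(c for c in settings.iroi_classes if c in present),
        )
    )
    manifest["n_cells"] = len(cells)
    manifest["runtime_s"] = round(time.time() - t0, 2)
    log.info("slide %s: %d objects, %d cells, %.1fs", slide_id, len(layer), len(cells), manifest["runtime_s"])
    return PipelineResult(
        slide_id, report, tissue_mask, layer, labeling_raw, labeling, cells,
        kept, exclusions, manifest,
    )


# ---------------------------------------------------------------------------
# file-based runs


@dataclass
class PipelineConfig:
    """File-level run configuration (one YAML file is the source of truth)."""

    slide_path: str
    exemplar_mask_path: str
    out_dir: str
    channel_names: list[str] | None = None
    pixel_size: float | None = None
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        s = raw.get("settings", {})
        settings = AnalysisSettings(
            tissue=TissueParams(**s.get("tissue", {})),
            scale=s.get("scale", 4.0),
            base_area_um2=s.get("base_area_um2", segmentation.DEFAULT_BASE_AREA_UM2),
            class_set=ROIClassSet(tuple(s.get("classes", DEFAULT_CLASSES))),
            rules=[ReclassRule(**r) for r in s.get("rules", [])]
            if "rules" in s
            else roi_engine.default_ruleset(),
            nucleus=NucleusParams(**s.get("nucleus", {})),
            cell=CellParams(**s.get("cell", {})),
            thresholds=ClassificationThresholds(**s["thresholds"])
            if "thresholds" in s
            else ClassificationThresholds.single_cd45(),
            scheme=PhenotypeScheme.double_cd3_cd4()
            if s.get("scheme") == "double_CD3_CD4"
            else PhenotypeScheme.single_cd45(),
            min_cell_area_um2=s.get("min_cell_area_um2", 10.0),
            seed=s.get("seed", 17),
        )
        return cls(
            slide_path=raw["slide_path"],
            exemplar_mask_path=raw["exemplar_mask_path"],
            out_dir=raw.get("out_dir", "ifquant_out"),
            channel_names=raw.get("channel_names"),
            pixel_size=raw.get("pixel_size"),
            settings=settings,
        )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    return str(o)


def run_pipeline(config: PipelineConfig) -> quantify.DensityReport:
    """File-based run: load, analyse, write every artifact plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slide_path = Path(config.slide_path)
    slide = load_slide(slide_path, config.channel_names, config.pixel_size)
    mask = load_mask(config.exemplar_mask_path)
    result = analyze_slide(
        slide, None, config.settings, exemplar_mask=mask, slide_id=slide_path.stem
    )
    stem = slide_path.stem
    save_mask(result.tissue_mask, out / f"{stem}_tissue.tiff")
    save_mask(result.labeling.to_mask(), out / f"{stem}_roi.tiff")
    _write_cell_table(result, out / f"{stem}_cells.csv")
    write_report(result.report, out / f"{stem}_report.csv")
    resolved = {
        "config": {
            "slide_path": str(config.slide_path),
            "exemplar_mask_path": str(config.exemplar_mask_path),
            "settings": asdict(config.settings),
        },
        "manifest": result.manifest,
    }
    (out / f"{stem}_manifest.json").write_text(
        json.dumps(resolved, indent=2, default=_json_default)
    )
    return result.report


def _write_cell_table(result: PipelineResult, path: Path) -> None:
    import pandas as pd

    rows = []
    for c in result.cells.cells:
        rows.append(
            {
                "cell_id": c.id,
                "row": c.centroid[0],
                "col": c.centroid[1],
                "roi_class": c.roi_class,
                "nucleus_area_um2": c.nucleus_area_um2,
                "cell_area_um2": c.cell_area_um2,
                "phenotype": c.phenotype,
                "excluded_reason": c.excluded_reason or "",
                **{f"nucleus_mean_{k}": v for k, v in c.nucleus_mean.items()},
                **{f"cell_mean_{k}": v for k, v in c.cell_mean.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def run_batch(
    slides: list[tuple[str, Slide, LabelMask]],
    settings: AnalysisSettings | None = None,
) -> quantify.DensityReport:
    """Apply one settings object to many slides (one config, many slides)
    and concatenate the per-slide reports."""
    settings = settings or AnalysisSettings()
    reports = []
    for slide_id, slide, exemplar_mask in slides:
        res = analyze_slide(
            slide, None, settings, exemplar_mask=exemplar_mask, slide_id=slide_id
        )
        reports.append(res.report)
    return quantify.DensityReport.concat(reports)
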