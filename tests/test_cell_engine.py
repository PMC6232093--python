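"""Cellular analysis: nucleus detection, cell simulation, thresholds,
phenotyping and artifact exclusion."""

import numpy as np
import pytest
from conftest import disk_mask, disks_slide

from ifquant.cell_engine import (
    CellParams,
    ClassificationThresholds,
    NucleusParams,
    PhenotypeScheme,
    CellRecord,
    calibrate_thresholds,
    classify_cells,
    detect_nuclei,
    exclude_artifacts,
    simulate_cells,
)
from ifquant.slide_model import Slide

PX = 0.5  # µm/px used by the geometric fixtures
R35 = float(np.sqrt(35.0 / np.pi) / PX)  # radius in px of a 35 µm² nucleus


def grid_centers(n, shape=(512, 512), step=48, start=30):
    pts = []
    r = start
    while len(pts) < n:
        c = start
        while c < shape[1] - start and len(pts) < n:
            pts.append((r, c))
            c += step
        r += step
        assert r < shape[0] - start or len(pts) >= n
    return pts


class TestNucleusDetection:
    def test_zero_signal_gives_no_nuclei(self):
        s = disks_slide([], R35)
        nuc = detect_nuclei(s, None, None, NucleusParams())
        assert len(nuc) == 0

    def test_fifty_disks_counted_exactly_with_tight_centroids(self):
        centers = grid_centers(50)
        s = disks_slide(centers, R35, pixel_size=PX)
        nuc = detect_nuclei(s, None, None, NucleusParams())
        assert len(nuc) == 50
        got = {tuple(np.round(c).astype(int)) for c in nuc.centroids}
        for ctr in centers:
            best = min(np.hypot(g[0] - ctr[0], g[1] - ctr[1]) for g in got)
            assert best <= 1.0

    def test_fused_pair_split_by_area_prior(self):
        # two 35 µm² disks whose rims are bridged by a 2 px neck
        c1, c2 = (100, 100), (100, int(100 + 2 * R35 + 2))
        img = np.zeros((200, 220), np.uint16)
        img[disk_mask(img.shape, c1, R35)] = 20000
        img[disk_mask(img.shape, c2, R35)] = 20000
        img[99:101, c1[1] : c2[1]] = 20000  # the neck
        s = Slide({"DAPI": img, "FITC": np.zeros_like(img)}, PX)
        nuc = detect_nuclei(s, None, None, NucleusParams())
        assert len(nuc) == 2

    def test_area_gates_drop_debris_and_sheets(self):
        img = np.zeros((256, 256), np.uint16)
        img[disk_mask(img.shape, (40, 40), 2.0)] = 20000  # ~3 µm² speck
        img[120:220, 40:220] = 20000  # huge sheet, far above the upper gate
        s = Slide({"DAPI": img, "FITC": np.zeros_like(img)}, PX)
        nuc = detect_nuclei(
            s, None, None, NucleusParams(peak_separation_factor=2.0)
        )
        areas = nuc.areas_um2
        assert ((areas >= 10.0) & (areas <= 150.0)).all()

    def test_detection_restricted_to_requested_regions(self, small_synth, small_result):
        _, slide, gt = small_synth
        labeling = small_result.labeling
        nuc = detect_nuclei(slide, labeling, ["lymphoid_follicle"], NucleusParams())
        follicle = labeling.class_mask("lymphoid_follicle")
        assert (nuc.label_image[~follicle] == 0).all()

    def test_unknown_region_rejected(self, small_result):
        s = disks_slide([(50, 50)], R35)
        with pytest.raises(ValueError, match="not in labeling"):
            detect_nuclei(s, small_result.labeling, ["no_such_region"], NucleusParams())


class TestCellSimulation:
    def _one_cell(self, ring: bool, mode="inside_cytoplasmic_stain"):
        ctr = (100, 100)
        dapi = np.zeros((200, 200), np.uint16)
        dapi[disk_mask(dapi.shape, ctr, R35)] = 20000
        fitc = np.full((200, 200), 200, np.uint16)
        if ring:
            r_cell = float(np.sqrt(38.0 / np.pi) / PX)
            d2 = (np.mgrid[0:200, 0:200][0] - ctr[0]) ** 2 + (
                np.mgrid[0:200, 0:200][1] - ctr[1]
            ) ** 2
            fitc[(d2 <= (r_cell + 1) ** 2) & (d2 >= (0.5 * R35) ** 2)] = 8000
        s = Slide({"DAPI": dapi, "FITC": fitc}, PX)
        nuc = detect_nuclei(s, None, None, NucleusParams())
        assert len(nuc) == 1
        pop = simulate_cells(nuc, s, None, CellParams(mode=mode))
        return pop

    def test_no_membrane_signal_cell_equals_nucleus(self):
        pop = self._one_cell(ring=False)
        cell = pop.cells[0]
        np.testing.assert_array_equal(
            pop.cell_label_image > 0, pop.nucleus_label_image > 0
        )
        assert cell.cell_area_um2 == pytest.approx(cell.nucleus_area_um2)

    def test_ringed_nucleus_reaches_mean_cell_area(self):
        pop = self._one_cell(ring=True)
        assert pop.cells[0].cell_area_um2 == pytest.approx(38.0, abs=5.0)

    def test_growth_from_nuclei_ignores_membrane(self):
        pop = self._one_cell(ring=False, mode="growth_from_nuclei")
        assert pop.cells[0].cell_area_um2 == pytest.approx(38.0, abs=5.0)

    def test_adjacent_nuclei_partition_shared_blob_disjointly(self):
        c1, c2 = (100, 80), (100, 80 + int(2.4 * R35))
        dapi = np.zeros((200, 200), np.uint16)
        dapi[disk_mask(dapi.shape, c1, R35)] = 20000
        dapi[disk_mask(dapi.shape, c2, R35)] = 20000
        fitc = np.full((200, 200), 200, np.uint16)
        fitc[80:120, 50:150] = 8000  # one blob over both cells
        s = Slide({"DAPI": dapi, "FITC": fitc}, PX)
        nuc = detect_nuclei(s, None, None, NucleusParams())
        assert len(nuc) == 2
        pop = simulate_cells(nuc, s, None, CellParams())
        lab = pop.cell_label_image
        assert set(np.unique(lab)) == {0, 1, 2}
        # no pixel claimed twice is structural (one label per pixel); both
        # cells hit their area cap without overlapping
        for c in pop.cells:
            assert c.cell_area_um2 <= 38.0 + 5.0 + 1e-6

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            CellParams(mode="telepathic")


class TestCalibration:
    def test_zero_controls_give_zero_marker_threshold(self):
        zero = Slide(
            {"DAPI": np.zeros((64, 64), np.uint16), "FITC": np.zeros((64, 64), np.uint16)},
            PX,
        )
        pos = disks_slide([(30, 30)], R35, shape=(64, 64), pixel_size=PX)
        thr = calibrate_thresholds([pos], [zero])
        assert thr.marker_min["FITC"] == 0.0

    def test_control_percentile_matches_numpy_oracle(self):
        rng = np.random.default_rng(12)
        noise = rng.integers(0, 1251, (128, 128)).astype(np.uint16)
        ctrl = Slide({"DAPI": np.zeros_like(noise), "FITC": noise}, PX)
        pos = disks_slide([(60, 60)], R35, shape=(128, 128), pixel_size=PX)
        thr = calibrate_thresholds([pos], [ctrl])
        assert thr.marker_min["FITC"] == pytest.approx(
            float(np.percentile(noise, 99.5))
        )
        assert thr.marker_min["FITC"] <= 1300.0  # consistent with the adopted default

    def test_single_positive_field_statistic(self):
        pos = disks_slide([(60, 60), (60, 120)], R35, shape=(200, 200), level=21000, pixel_size=PX)
        thr = calibrate_thresholds([pos], [pos])
        nuc = detect_nuclei(pos, None, None, NucleusParams())
        from scipy import ndimage as ndi

        means = ndi.mean(
            pos.channel("DAPI").astype(float), nuc.label_image, nuc.ids
        )
        assert thr.nuclear_min == pytest.approx(float(np.percentile(means, 5.0)))

    def test_empty_field_lists_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([], [])


def make_cell(nuc_dapi, cell_fitc, cell_cy3=None, roi_class="mucosa") -> CellRecord:
    cm = {"FITC": cell_fitc, "DAPI": nuc_dapi}
    if cell_cy3 is not None:
        cm["CY3"] = cell_cy3
    return CellRecord(
        id=1, roi_object_id=1, roi_class=roi_class, centroid=(0, 0),
        nucleus_area_um2=35.0, cell_area_um2=38.0,
        nucleus_mean={"DAPI": nuc_dapi}, cell_mean=cm,
    )


class TestClassification:
    def test_single_scheme_with_study_thresholds(self):
        thr = ClassificationThresholds.single_cd45()
        scheme = PhenotypeScheme.single_cd45()
        assert classify_cells([make_cell(1200, 1500)], thr, scheme)[0].phenotype == "positive"
        # inclusive boundary: 1299 fails a 1300 threshold, 1300 passes
        assert classify_cells([make_cell(1200, 1299)], thr, scheme)[0].phenotype == "negative"
        assert classify_cells([make_cell(1200, 1300)], thr, scheme)[0].phenotype == "positive"
        assert classify_cells([make_cell(999, 99999)], thr, scheme)[0].phenotype == "negative"

    def test_double_scheme_co_staining(self):
        thr = ClassificationThresholds.double_cd3_cd4()
        scheme = PhenotypeScheme.double_cd3_cd4()
        assert (
            classify_cells([make_cell(600, 1000, cell_cy3=3000)], thr, scheme)[0].phenotype
            == "CD3+CD4-"
        )
        assert (
            classify_cells([make_cell(600, 2000, cell_cy3=3000)], thr, scheme)[0].phenotype
            == "CD3+CD4+"
        )
        assert (
            classify_cells([make_cell(400, 2000, cell_cy3=3000)], thr, scheme)[0].phenotype
            == "CD3-CD4-"
        )

    def test_missing_scheme_channel_rejected(self):
        thr = ClassificationThresholds.single_cd45()
        with pytest.raises(ValueError, match="threshold"):
            classify_cells([make_cell(1, 1)], ClassificationThresholds(marker_min={}), PhenotypeScheme.single_cd45())
        cell = make_cell(1200, 1500)
        del cell.cell_mean["FITC"]
        with pytest.raises(ValueError, match="no intensity"):
            classify_cells([cell], thr, PhenotypeScheme.single_cd45())

    def test_threshold_monotonicity_sweep(self, small_synth, small_result):
        cells = small_result.kept_cells
        scheme = PhenotypeScheme.single_cd45()
        prev = None
        for m in np.linspace(200, 12000, 10):
            thr = ClassificationThresholds(nuclear_min=1000, marker_min={"FITC": m})
            n_pos = sum(
                1 for c in classify_cells(list(cells), thr, scheme) if c.phenotype == "positive"
            )
            if prev is not None:
                assert n_pos <= prev
            prev = n_pos
        prev = None
        for nm in np.linspace(200, 30000, 10):
            thr = ClassificationThresholds(nuclear_min=nm, marker_min={"FITC": 1300})
            n_pos = sum(
                1 for c in classify_cells(list(cells), thr, scheme) if c.phenotype == "positive"
            )
            if prev is not None:
                assert n_pos <= prev
            prev = n_pos

    def test_every_cell_gets_exactly_one_phenotype(self, small_result):
        phenos = [c.phenotype for c in small_result.cells.cells]
        assert all(p in ("positive", "negative") for p in phenos)


class TestArtifactExclusion:
    def test_membrane_blob_without_nucleus_never_a_cell(self):
        img = np.zeros((128, 128), np.uint16)
        fitc = np.full((128, 128), 200, np.uint16)
        fitc[disk_mask((128, 128), (64, 64), 10)] = 30000
        s = Slide({"DAPI": img, "FITC": fitc}, PX)
        nuc = detect_nuclei(s, None, None, NucleusParams())
        pop = simulate_cells(nuc, s, None, CellParams())
        assert len(pop) == 0

    def test_bis_cells_excluded_and_logged(self):
        cells = [
            make_cell(2000, 2000, roi_class="mucosa"),
            make_cell(2000, 2000, roi_class="mucosa_bis"),
        ]
        cells[1].id = 2
        kept, log = exclude_artifacts(cells)
        assert [c.roi_class for c in kept] == ["mucosa"]
        assert log == [(2, "edge_exclusion")]

    def test_sub_minimal_cells_dropped_with_reason(self):
        small = make_cell(2000, 2000)
        small.cell_area_um2 = 4.0
        kept, log = exclude_artifacts([small], min_cell_area_um2=10.0)
        assert kept == []
        assert log == [(1, "below_min_cell_area")]

    def test_generator_aggregates_yield_no_false_positives(self, small_synth, small_result):
        _, _, gt = small_synth
        aggs = gt.artifacts[gt.artifacts.kind == "aggregate"]
        assert len(aggs) > 0
        pos = np.array(
            [c.centroid for c in small_result.kept_cells if c.phenotype == "positive"]
        ).reshape(-1, 2)
        for _, a in aggs.iterrows():
            if len(pos):
                d = np.hypot(pos[:, 0] - a.row, pos[:, 1] - a.col).min()
                assert d > 3.0 / 0.161028  # no positive call sits on an aggregate


class TestDisjointness:
    def test_no_pixel_in_two_cells_and_nucleus_inside_cell(self, small_result):
        pop = small_result.cells
        lab = pop.cell_label_image
        nuc = pop.nucleus_label_image
        # one label per pixel is structural; additionally every nucleus
        # pixel must carry its own cell's label
        sel = nuc > 0
        assert (lab[sel] == nuc[sel]).all()
        # cells stay inside tissue, so total cell cover is bounded by it
        tissue = small_result.tissue_mask.binary()
        assert (lab[~tissue] == 0).all()
        assert np.count_nonzero(lab) <= np.count_nonzero(tissue)
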