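"""ROI engine: training, classification, merging, rules, manual edits."""

import numpy as np
import pytest

from ifquant.roi_engine import (
    ReclassRule,
    ROIClassSet,
    ROILabeling,
    TrainingExemplar,
    apply_rules,
    classify_objects,
    default_ruleset,
    exemplars_from_mask,
    manual_correct,
    pixel_agreement,
    rule_matches,
    train_classifier,
)
from ifquant.segmentation import ObjectLayer, PrimitiveObject, compute_features
from ifquant.slide_model import LabelMask, Slide


def block_layer(nrows=4, ncols=4, block=20, levels=None, pixel_size=1.0):
    """Grid-of-blocks layer over a constructed slide; area per block =
    block² µm² at 1 µm/px, so rule thresholds are exact."""
    shape = (nrows * block, ncols * block)
    lab = np.zeros(shape, np.int64)
    img = np.zeros(shape, np.float64)
    oid = 0
    for i in range(nrows):
        for j in range(ncols):
            oid += 1
            sl = np.s_[block * i : block * (i + 1), block * j : block * (j + 1)]
            lab[sl] = oid
            img[sl] = levels[oid] if levels and oid in levels else 1000.0 * oid
    slide = Slide({"DAPI": img.astype(np.uint16), "FITC": np.zeros(shape, np.uint16)}, pixel_size)
    layer = ObjectLayer(lab, [PrimitiveObject(id=i) for i in range(1, oid + 1)], 1.0, pixel_size)
    compute_features(layer, slide)
    return layer, slide


class TestClassSet:
    def test_bounds(self):
        with pytest.raises(ValueError):
            ROIClassSet(("only_one",))
        with pytest.raises(ValueError):
            ROIClassSet(tuple(f"c{i}" for i in range(9)))
        assert len(ROIClassSet(tuple(f"c{i}" for i in range(8))).classes) == 8

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ROIClassSet(("a", "a", "b"))


class TestTraining:
    def test_separable_classes_classified_perfectly(self):
        # blocks 1-8 dim, 9-16 bright; train on half of each, predict all
        levels = {i: (2000 if i <= 8 else 30000) for i in range(1, 17)}
        layer, _ = block_layer(levels=levels)
        cs = ROIClassSet(("dim", "bright"))
        exemplars = [TrainingExemplar(i, "dim") for i in (1, 2, 3, 4)] + [
            TrainingExemplar(i, "bright") for i in (9, 10, 11, 12)
        ]
        clf = train_classifier(layer, exemplars, cs, seed=5)
        labeling = classify_objects(clf, layer)
        for i in range(1, 17):
            assert labeling.class_of[i] == ("dim" if i <= 8 else "bright")

    def test_five_standard_classes_accepted(self):
        levels = {i: 3000 * ((i - 1) % 5 + 1) for i in range(1, 17)}
        layer, _ = block_layer(levels=levels)
        cs = ROIClassSet()
        exemplars = [
            TrainingExemplar(i, cs.classes[(i - 1) % 5]) for i in range(1, 16)
        ]
        clf = train_classifier(layer, exemplars, cs, seed=1)
        assert set(clf.class_set.classes) == set(cs.classes)

    def test_empty_class_rejected(self):
        layer, _ = block_layer()
        with pytest.raises(ValueError, match="without exemplars"):
            train_classifier(
                layer, [TrainingExemplar(1, "a")], ROIClassSet(("a", "b")), seed=0
            )

    def test_conflicting_duplicate_labels_rejected(self):
        layer, _ = block_layer()
        with pytest.raises(ValueError, match="labelled both"):
            train_classifier(
                layer,
                [TrainingExemplar(1, "a"), TrainingExemplar(1, "b"), TrainingExemplar(2, "b")],
                ROIClassSet(("a", "b")),
                seed=0,
            )

    def test_reproducible_under_fixed_seed(self):
        levels = {i: 1500 * i for i in range(1, 17)}
        layer, _ = block_layer(levels=levels)
        cs = ROIClassSet(("lo", "hi"))
        ex = [TrainingExemplar(i, "lo") for i in (1, 2, 3)] + [
            TrainingExemplar(i, "hi") for i in (14, 15, 16)
        ]
        a = classify_objects(train_classifier(layer, ex, cs, seed=9), layer)
        b = classify_objects(train_classifier(layer, ex, cs, seed=9), layer)
        assert a.class_of == b.class_of

    def test_feature_schema_mismatch_rejected(self):
        layer, _ = block_layer()
        cs = ROIClassSet(("a", "b"))
        ex = [TrainingExemplar(1, "a"), TrainingExemplar(2, "b")]
        clf = train_classifier(layer, ex, cs, seed=0)
        clf.feature_names = clf.feature_names[:-1]
        with pytest.raises(ValueError, match="schema"):
            classify_objects(clf, layer)

    def test_empty_layer_gives_empty_labeling(self):
        layer, _ = block_layer()
        cs = ROIClassSet(("a", "b"))
        clf = train_classifier(
            layer, [TrainingExemplar(1, "a"), TrainingExemplar(2, "b")], cs, seed=0
        )
        empty = ObjectLayer(np.zeros((8, 8), np.int64), [], 1.0, 1.0)
        assert classify_objects(clf, empty).roi_objects == []


class TestMergingAndLabeling:
    def test_touching_same_class_primitives_merge(self):
        layer, _ = block_layer(nrows=2, ncols=2)
        lab = ROILabeling.from_classes(layer, {1: "a", 2: "a", 3: "b", 4: "b"})
        assert len(lab.roi_objects) == 2
        assert {tuple(r.primitive_ids) for r in lab.roi_objects} == {(1, 2), (3, 4)}

    def test_partition_preserved_total_area(self):
        layer, _ = block_layer()
        lab = ROILabeling.from_classes(layer, {i: "a" if i % 3 else "b" for i in layer.ids})
        assert sum(r.area_um2 for r in lab.roi_objects) == pytest.approx(
            sum(o.area_um2 for o in layer.objects)
        )

    def test_exemplars_from_mask_majority_overlap(self):
        layer, _ = block_layer(nrows=2, ncols=2)
        truth = np.zeros((40, 40), np.int64)
        truth[:, :25] = 1  # covers block 1 fully, 60% of block 2's columns
        truth[:, 25:] = 2
        mask = LabelMask(truth, {1: "left", 2: "right"})
        ex = {e.object_id: e.class_name for e in exemplars_from_mask(layer, mask)}
        assert ex[1] == "left" and ex[3] == "left"
        # blocks 2/4 are 75% right-labelled → majority right at 0.5 overlap
        assert ex[2] == "right" and ex[4] == "right"
        # at a stricter overlap requirement the mixed blocks drop out
        strict = {e.object_id for e in exemplars_from_mask(layer, mask, min_overlap=0.8)}
        assert strict == {1, 3}


class TestRules:
    def _toy(self):
        # 4×4 blocks of 400 µm²: follicle-labelled 2×2 patch (area 1600),
        # a mucosa island inside tumor, the rest tumor/other
        layer, _ = block_layer()
        classes = {i: "other_tissue" for i in layer.ids}
        for i in (6, 7, 10, 11):
            classes[i] = "tumor"
        classes[6] = "mucosa"  # island: neighbours 2,5,7,10 → ¾ tumor… see below
        return layer, classes

    def test_size_rule_relabels_only_matching_objects(self):
        layer, _ = block_layer()
        classes = {i: "other_tissue" for i in layer.ids}
        for i in (1, 2, 5, 6):
            classes[i] = "lymphoid_follicle"  # merged area 1600 µm²
        classes[16] = "lymphoid_follicle"  # isolated 400 µm²
        lab = ROILabeling.from_classes(layer, classes)
        rule = ReclassRule("lymphoid_follicle", "tumor", "area_um2", ">=", 1000.0)
        # brute-force oracle: predicate per ROI object
        expected = {
            r.id: (r.class_name == "lymphoid_follicle" and r.area_um2 >= 1000.0)
            for r in lab.roi_objects
        }
        for r in lab.roi_objects:
            assert rule_matches(lab, r, rule) == (
                expected[r.id] if r.class_name == "lymphoid_follicle" else rule_matches(lab, r, rule)
            )
        out = apply_rules(lab, [rule])
        assert all(out.class_of[i] == "tumor" for i in (1, 2, 5, 6))
        assert out.class_of[16] == "lymphoid_follicle"
        assert all(
            out.class_of[i] == classes[i] for i in layer.ids if i not in (1, 2, 5, 6)
        )

    def test_border_rule_threshold_boundary(self):
        # centre block 6 surrounded by 2,5,7,10; make 3 of 4 tumor → 75%
        layer, _ = block_layer()
        classes = {i: "other_tissue" for i in layer.ids}
        classes[6] = "mucosa"
        for i in (2, 5, 7):
            classes[i] = "tumor"
        lab = ROILabeling.from_classes(layer, classes)
        roi6 = next(r for r in lab.roi_objects if r.primitive_ids == [6])
        rb = lab.roi_relative_border(roi6)
        assert rb["tumor"] == pytest.approx(0.75)
        hit = ReclassRule("mucosa", "tumor", "relative_border", ">=", 0.7, ref_class="tumor")
        miss = ReclassRule("mucosa", "tumor", "relative_border", ">=", 0.8, ref_class="tumor")
        assert apply_rules(lab, [hit]).class_of[6] == "tumor"
        assert apply_rules(lab, [miss]).class_of[6] == "mucosa"

    def test_distance_rule(self):
        layer, _ = block_layer()
        classes = {i: "other_tissue" for i in layer.ids}
        classes[1] = "mucosa"   # adjacent to tumor block 2 → distance 0
        classes[2] = "tumor"
        classes[16] = "mucosa"  # far corner
        lab = ROILabeling.from_classes(layer, classes)
        rule = ReclassRule("mucosa", "tumor", "distance_to_um", "<=", 5.0, ref_class="tumor")
        out = apply_rules(lab, [rule])
        assert out.class_of[1] == "tumor"
        assert out.class_of[16] == "mucosa"

    def test_empty_rule_list_is_identity(self):
        layer, _ = block_layer()
        lab = ROILabeling.from_classes(layer, {i: "a" for i in layer.ids})
        assert apply_rules(lab, []).class_of == lab.class_of

    def test_unknown_class_rejected_before_mutation(self):
        layer, _ = block_layer()
        lab = ROILabeling.from_classes(layer, {i: "a" for i in layer.ids})
        rules = [
            ReclassRule("a", "b", "area_um2", ">=", 0.0),
            ReclassRule("ghost", "a", "relative_border", ">=", 0.5, ref_class="missing"),
        ]
        with pytest.raises(ValueError, match="unknown class"):
            apply_rules(lab, rules)
        assert lab.class_of[1] == "a"  # untouched

    def test_rules_apply_in_order_seeing_refreshed_labels(self):
        # rule 1 converts block 6 to tumor; rule 2 then sees 6 as tumor
        layer, _ = block_layer()
        classes = {i: "other_tissue" for i in layer.ids}
        classes[6] = "mucosa"
        classes[7] = "mucosa"
        for i in (2, 5, 10):
            classes[i] = "tumor"
        lab = ROILabeling.from_classes(layer, classes)
        r1 = ReclassRule("mucosa", "tumor", "area_um2", ">=", 500.0)  # hits merged {6,7}
        r2 = ReclassRule(
            "other_tissue", "tumor", "relative_border", ">=", 0.74, ref_class="tumor"
        )
        out = apply_rules(lab, [r1, r2])
        assert out.class_of[6] == out.class_of[7] == "tumor"
        # reversed order: rule 2 first sees less tumor border, fires nowhere
        out_rev = apply_rules(lab, [r2, r1])
        fired = sum(
            1 for i in layer.ids
            if out.class_of[i] == "tumor" and classes[i] == "other_tissue"
        )
        fired_rev = sum(
            1 for i in layer.ids
            if out_rev.class_of[i] == "tumor" and classes[i] == "other_tissue"
        )
        assert fired >= fired_rev

    def test_rule_never_creates_or_destroys_tissue(self):
        layer, _ = block_layer()
        classes = {i: "mucosa" if i % 2 else "tumor" for i in layer.ids}
        lab = ROILabeling.from_classes(layer, classes)
        out = apply_rules(lab, default_ruleset())
        assert set(out.class_of) == set(lab.class_of)
        assert sum(r.area_um2 for r in out.roi_objects) == pytest.approx(
            sum(r.area_um2 for r in lab.roi_objects)
        )

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ReclassRule("a", "a", "area_um2", ">=", 1.0)
        with pytest.raises(ValueError):
            ReclassRule("a", "b", "area_um2", "!=", 1.0)
        with pytest.raises(ValueError):
            ReclassRule("a", "b", "relative_border", ">=", 0.5)  # no ref_class
        with pytest.raises(ValueError):
            ReclassRule("a", "b", "area_um2", ">=", float("nan"))


class TestManualCorrection:
    def test_empty_edits_identity(self):
        layer, _ = block_layer()
        lab = ROILabeling.from_classes(layer, {i: "a" for i in layer.ids})
        assert manual_correct(lab, []) is lab

    def test_single_edit_changes_only_target(self):
        layer, _ = block_layer(nrows=2, ncols=2)
        lab = ROILabeling.from_classes(layer, {1: "a", 2: "b", 3: "b", 4: "a"})
        target = next(r for r in lab.roi_objects if r.primitive_ids == [1])
        out = manual_correct(lab, [(target.id, "other_tissue")])
        assert out.class_of[1] == "other_tissue"
        assert all(out.class_of[i] == lab.class_of[i] for i in (2, 3, 4))
        edited = next(r for r in out.roi_objects if 1 in r.primitive_ids)
        assert edited.provenance == "manual"

    def test_disjoint_edits_commute(self):
        layer, _ = block_layer()
        lab = ROILabeling.from_classes(layer, {i: f"c{i % 4}" for i in layer.ids})
        ids = [r.id for r in lab.roi_objects]
        e1, e2 = (ids[0], "c1"), (ids[-1], "c2")
        a = manual_correct(manual_correct(lab, [e1]), [(e2[0], e2[1])])
        # ids can shift after re-merge; apply both orders from scratch instead
        b = manual_correct(lab, [e1, e2])
        assert a.class_of == b.class_of

    def test_unknown_id_rejected(self):
        layer, _ = block_layer()
        lab = ROILabeling.from_classes(layer, {i: "a" for i in layer.ids})
        with pytest.raises(KeyError):
            manual_correct(lab, [(9999, "a")])


class TestOnSyntheticSlide:
    def test_classification_accuracy_and_rule_improvement(self, small_synth, small_result):
        _, slide, gt = small_synth
        res = small_result
        raw = pixel_agreement(res.labeling_raw, gt.roi_mask)
        ruled = pixel_agreement(res.labeling, gt.roi_mask)
        assert raw >= 0.95
        assert ruled >= raw - 1e-9  # default rules never hurt agreement
        # regression: the documented error mode (a false-mucosa island in a
        # follicle) is repaired by the shipped ruleset
        follicle_prims = [
            i for i, c in res.labeling.class_of.items() if c == "lymphoid_follicle"
        ]
        assert follicle_prims, "fixture lost its follicles"
        # pick an interior follicle primitive (all neighbours follicle)
        inner = next(
            i for i in follicle_prims
            if all(
                res.labeling.class_of.get(n) == "lymphoid_follicle"
                for n in res.layer.object(i).neighbor_ids
            )
        )
        corrupted_classes = dict(res.labeling.class_of)
        corrupted_classes[inner] = "mucosa"
        corrupted = ROILabeling.from_classes(res.layer, corrupted_classes)
        repaired = apply_rules(corrupted, default_ruleset())
        assert repaired.class_of[inner] == "lymphoid_follicle"
        assert pixel_agreement(repaired, gt.roi_mask) > pixel_agreement(
            corrupted, gt.roi_mask
        )

    def test_every_primitive_has_exactly_one_class_at_all_stages(self, small_result):
        for labeling in (small_result.labeling_raw, small_result.labeling):
            assert set(labeling.class_of) == set(small_result.layer.ids)
            covered = sorted(p for r in labeling.roi_objects for p in r.primitive_ids)
            assert covered == sorted(small_result.layer.ids)
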