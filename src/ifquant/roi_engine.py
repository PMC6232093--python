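"""Region-of-interest classification of primitive objects.

The workflow mirrors supervised object-based tissue analysis: a handful of
exemplar primitive objects per region class train a classifier over the
object feature vector; every primitive is then classified and touching
same-class primitives are merged into ROI objects; an ordered list of
conditional reclassification rules repairs systematic errors (e.g. a
follicle-labelled object far too large to be a follicle is really tumor);
finally programmatic manual corrections replace the interactive check a
human operator would do at a workstation.

Class sets hold up to eight region classes.  The three immune regions of
interest (iROIs) of the colon workflow are mucosa, lymphoid_follicle and
tumor; *_bis variants are edge-exclusion classes whose area still counts
toward density denominators (see :mod:`ifquant.quantify`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .segmentation import ObjectLayer
from .slide_model import LabelMask

__all__ = [
    "ROIClassSet",
    "TrainingExemplar",
    "ReclassRule",
    "ROIObject",
    "ROILabeling",
    "ROIClassifier",
    "train_classifier",
    "classify_objects",
    "apply_rules",
    "manual_correct",
    "exemplars_from_mask",
    "default_ruleset",
    "load_rules",
    "IROI_CLASSES",
    "DEFAULT_CLASSES",
]

log = logging.getLogger(__name__)

MAX_CLASSES = 8

IROI_CLASSES = ("mucosa", "lymphoid_follicle", "tumor")
DEFAULT_CLASSES = (
    "mucosa",
    "lymphoid_follicle",
    "tumor",
    "other_tissue",
    "background",
)
BIS_SUFFIX = "_bis"


def parent_class(name: str) -> str:
    """mucosa_bis → mucosa; non-bis names map to themselves."""
    return name[: -len(BIS_SUFFIX)] if name.endswith(BIS_SUFFIX) else name


@dataclass
class ROIClassSet:
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        if not 2 <= len(self.classes) <= MAX_CLASSES:
            raise ValueError(
                f"need between 2 and {MAX_CLASSES} region classes, got {len(self.classes)}"
            )
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class names must be unique")

    def __contains__(self, name: str) -> bool:
        return name in self.classes


@dataclass(frozen=True)
class TrainingExemplar:
    object_id: int
    class_name: str


_RULE_FEATURES = (
    "area_um2",
    "relative_border",
    "distance_to_um",
    "heterogeneity",
    "local_density",
)
_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">=": np.greater_equal,
    ">": np.greater,
}


@dataclass(frozen=True)
class ReclassRule:
    """One conditional reclassification: relabel every ROI object of
    ``source`` whose feature satisfies ``op threshold`` as ``target``.

    ``relative_border`` and ``distance_to_um`` require ``ref_class``: the
    neighbour/target class the border fraction or distance is measured
    against.  Distances are in µm, areas in µm².
    """

    source: str
    target: str
    feature: str
    op: str
    threshold: float
    ref_class: str | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("rule source and target must differ")
        if self.feature not in _RULE_FEATURES:
            raise ValueError(f"unknown rule feature {self.feature!r}")
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("rule threshold must be finite")
        if self.feature in ("relative_border", "distance_to_um") and not self.ref_class:
            raise ValueError(f"{self.feature} rules need ref_class")


@dataclass
class ROIObject:
    """A merged, connected, same-class group of primitive objects."""

    id: int
    class_name: str
    primitive_ids: list[int]
    area_um2: float
    provenance: str = "trained"


@dataclass
class ROILabeling:
    """Assignment of every tissue primitive to exactly one ROI object."""

    layer: ObjectLayer
    class_of: dict[int, str]
    roi_objects: list[ROIObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._roi_by_id = {r.id: r for r in self.roi_objects}

    # -- construction -------------------------------------------------

    @classmethod
    def from_classes(
        cls,
        layer: ObjectLayer,
        class_of: dict[int, str],
        provenance_of: dict[int, str] | None = None,
    ) -> "ROILabeling":
        """Build a labeling by merging touching same-class primitives."""
        missing = set(layer.ids) - set(class_of)
        if missing:
            raise ValueError(f"{len(missing)} primitives without a class")
        provenance_of = provenance_of or {}
        # union-find over same-class adjacency
        parent = {i: i for i in layer.ids}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in layer.adjacency.edges:
            if class_of[a] == class_of[b]:
                parent[find(a)] = find(b)
        groups: dict[int, list[int]] = {}
        for i in layer.ids:
            groups.setdefault(find(i), []).append(i)
        rois = []
        for rid, members in enumerate(
            sorted(groups.values(), key=lambda m: min(m)), start=1
        ):
            provs = {provenance_of.get(m, "trained") for m in members}
            prov = provs.pop() if len(provs) == 1 else "mixed"
            rois.append(
                ROIObject(
                    id=rid,
                    class_name=class_of[members[0]],
                    primitive_ids=sorted(members),
                    area_um2=sum(layer.object(m).area_um2 for m in members),
                    provenance=prov,
                )
            )
        return cls(layer, dict(class_of), rois)

    # -- queries -------------------------------------------------------

    def roi_object(self, rid: int) -> ROIObject:
        return self._roi_by_id[rid]

    @property
    def classes_present(self) -> set[str]:
        return set(self.class_of.values())

    def roi_of_primitive(self) -> dict[int, int]:
        out = {}
        for r in self.roi_objects:
            for p in r.primitive_ids:
                out[p] = r.id
        return out

    def roi_label_image(self) -> np.ndarray:
        """Pixel map of ROI-object ids (0 outside tissue)."""
        lut = np.zeros(int(self.layer.label_image.max()) + 1, dtype=np.int64)
        for r in self.roi_objects:
            lut[r.primitive_ids] = r.id
        return lut[self.layer.label_image]

    def to_mask(self) -> LabelMask:
        """Class map as a LabelMask (labels follow sorted class names)."""
        names = sorted(self.classes_present)
        code = {n: i + 1 for i, n in enumerate(names)}
        lut = np.zeros(int(self.layer.label_image.max()) + 1, dtype=np.int64)
        for pid, cls in self.class_of.items():
            lut[pid] = code[cls]
        return LabelMask(lut[self.layer.label_image], {v: k for k, v in code.items()})

    def class_mask(self, class_name: str) -> np.ndarray:
        lut = np.zeros(int(self.layer.label_image.max()) + 1, dtype=bool)
        for pid, cls in self.class_of.items():
            if cls == class_name:
                lut[pid] = True
        return lut[self.layer.label_image]

    def class_area_um2(self, class_name: str) -> float:
        return sum(
            r.area_um2 for r in self.roi_objects if r.class_name == class_name
        )

    # -- ROI-object-level features for rules ---------------------------

    def roi_relative_border(self, roi: ROIObject) -> dict[str, float]:
        """Border fractions of a merged ROI object against neighbour
        classes (contacts internal to the ROI object are excluded; the
        remainder to 1 is mask border)."""
        members = set(roi.primitive_ids)
        per_class: dict[str, float] = {}
        total = 0
        for pid in roi.primitive_ids:
            obj = self.layer.object(pid)
            total += obj.mask_border_count
            for nid, cnt in obj.border_counts.items():
                if nid in members:
                    continue
                total += cnt
                cls = self.class_of[nid]
                per_class[cls] = per_class.get(cls, 0.0) + cnt
        if total == 0:
            return {}
        return {c: v / total for c, v in per_class.items()}

    def roi_heterogeneity(self, roi: ROIObject, nuclear_channel: str = "DAPI") -> float:
        """Pooled coefficient of variation of the nuclear channel."""
        n_tot = 0
        s1 = 0.0
        s2 = 0.0
        for pid in roi.primitive_ids:
            o = self.layer.object(pid)
            mu = o.channel_mean.get(nuclear_channel, 0.0)
            sd = o.channel_std.get(nuclear_channel, 0.0)
            n_tot += o.n_pixels
            s1 += o.n_pixels * mu
            s2 += o.n_pixels * (sd * sd + mu * mu)
        if n_tot == 0 or s1 <= 0:
            return 0.0
        mean = s1 / n_tot
        var = max(s2 / n_tot - mean * mean, 0.0)
        return float(np.sqrt(var) / mean)

    def roi_local_density(self, roi: ROIObject) -> float:
        n = sum(self.layer.object(p).n_pixels for p in roi.primitive_ids)
        s = sum(
            self.layer.object(p).n_pixels * self.layer.object(p).local_density
            for p in roi.primitive_ids
        )
        return s / n if n else 0.0


# ---------------------------------------------------------------------------
# classifier


@dataclass
class ROIClassifier:
    """Deterministic multi-class learner over the object feature vector.

    The default family is a seeded random forest on standardised features;
    ``family="nearest_centroid"`` gives the simpler fallback.  The feature
    schema is recorded so a layer with different features is rejected.
    """

    model: Pipeline
    class_set: ROIClassSet
    feature_names: list[str]
    family: str = "random_forest"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def train_classifier(
    layer: ObjectLayer,
    exemplars: list[TrainingExemplar],
    class_set: ROIClassSet,
    seed: int = 0,
    family: str = "random_forest",
) -> ROIClassifier:
    """Train a region classifier from exemplar primitive objects.

    Every class in ``class_set`` needs at least one exemplar; conflicting
    duplicate labels are rejected.  Training-set accuracy is logged.
    """
    seen: dict[int, str] = {}
    for ex in exemplars:
        if ex.class_name not in class_set:
            raise ValueError(f"exemplar class {ex.class_name!r} not in class set")
        if ex.object_id in seen and seen[ex.object_id] != ex.class_name:
            raise ValueError(
                f"object {ex.object_id} labelled both {seen[ex.object_id]!r} "
                f"and {ex.class_name!r}"
            )
        seen[ex.object_id] = ex.class_name
    counts = {c: 0 for c in class_set.classes}
    for cls in seen.values():
        counts[cls] += 1
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"classes without exemplars: {empty}")

    X_all = layer.feature_matrix()
    idx = {oid: k for k, oid in enumerate(layer.ids)}
    rows = [idx[o] for o in seen]
    X = X_all[rows]
    y = np.array([seen[o] for o in seen])

    if family == "random_forest":
        est = RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1, min_samples_leaf=1
        )
    elif family == "nearest_centroid":
        from sklearn.neighbors import NearestCentroid

        est = NearestCentroid()
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    model = Pipeline([("scale", StandardScaler()), ("clf", est)])
    model.fit(X, y)
    acc = float(np.mean(model.predict(X) == y))
    log.info("trained %s on %d exemplars, training accuracy %.3f", family, len(y), acc)
    return ROIClassifier(model, class_set, layer.feature_names(), family)


def classify_objects(classifier: ROIClassifier, layer: ObjectLayer) -> ROILabeling:
    """Classify every primitive and merge touching same-class primitives."""
    if not layer.objects:
        return ROILabeling(layer, {}, [])
    if layer.feature_names() != classifier.feature_names:
        raise ValueError(
            "feature-schema mismatch between classifier and layer: "
            f"{classifier.feature_names} vs {layer.feature_names()}"
        )
    pred = classifier.predict(layer.feature_matrix())
    class_of = {oid: str(c) for oid, c in zip(layer.ids, pred)}
    return ROILabeling.from_classes(layer, class_of)


def exemplars_from_mask(
    layer: ObjectLayer, mask: LabelMask, min_overlap: float = 0.5
) -> list[TrainingExemplar]:
    """Derive exemplars from a labelled mask by majority overlap.

    A primitive becomes an exemplar of class X when ≥ ``min_overlap`` of
    its pixels carry a mask label whose legend entry is X.
    """
    lab = layer.label_image
    sel = lab > 0
    pairs = np.stack([lab[sel], mask.labels[sel]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    per_obj: dict[int, dict[int, int]] = {}
    for (oid, ml), n in zip(uniq.tolist(), counts.tolist()):
        per_obj.setdefault(oid, {})[ml] = n
    out = []
    for oid, cc in per_obj.items():
        total = sum(cc.values())
        ml, n = max(cc.items(), key=lambda kv: kv[1])
        if ml == 0 or n / total < min_overlap:
            continue
        out.append(TrainingExemplar(oid, mask.legend[ml]))
    return out


# ---------------------------------------------------------------------------
# rule engine


def _rule_feature_value(
    labeling: ROILabeling,
    roi: ROIObject,
    rule: ReclassRule,
    dist_cache: dict[str, np.ndarray],
) -> float:
    if rule.feature == "area_um2":
        return roi.area_um2
    if rule.feature == "relative_border":
        return labeling.roi_relative_border(roi).get(rule.ref_class, 0.0)
    if rule.feature == "heterogeneity":
        return labeling.roi_heterogeneity(roi)
    if rule.feature == "local_density":
        return labeling.roi_local_density(roi)
    if rule.feature == "distance_to_um":
        if rule.ref_class not in dist_cache:
            ref_mask = labeling.class_mask(rule.ref_class)
            if ref_mask.any():
                d = ndi.distance_transform_edt(~ref_mask) * labeling.layer.pixel_size
            else:
                d = np.full(ref_mask.shape, np.inf)
            dist_cache[rule.ref_class] = d
        rmask = np.isin(
            labeling.layer.label_image, np.asarray(roi.primitive_ids, dtype=np.int64)
        )
        return float(dist_cache[rule.ref_class][rmask].min())
    raise AssertionError(rule.feature)


def rule_matches(labeling: ROILabeling, roi: ROIObject, rule: ReclassRule) -> bool:
    """Evaluate one rule's predicate on one ROI object."""
    val = _rule_feature_value(labeling, roi, rule, {})
    return bool(_OPS[rule.op](val, rule.threshold))


def apply_rules(labeling: ROILabeling, rules: list[ReclassRule]) -> ROILabeling:
    """Apply reclassification rules strictly in list order.

    Each rule relabels every current ROI object of its source class whose
    predicate holds; merging and feature refresh happen after each rule so
    later rules see the updated labelling.  All rules are validated before
    any mutation.
    """
    known = labeling.classes_present | {r.target for r in rules} | {
        r.source for r in rules
    }
    for rule in rules:
        for cls in (rule.source, rule.target, rule.ref_class):
            if cls is not None and cls not in known:
                raise ValueError(f"rule references unknown class {cls!r}")

    current = labeling
    provenance = {
        p: r.provenance for r in labeling.roi_objects for p in r.primitive_ids
    }
    for k, rule in enumerate(rules, start=1):
        dist_cache: dict[str, np.ndarray] = {}
        class_of = dict(current.class_of)
        changed = False
        for roi in current.roi_objects:
            if roi.class_name != rule.source:
                continue
            val = _rule_feature_value(current, roi, rule, dist_cache)
            if _OPS[rule.op](val, rule.threshold):
                for pid in roi.primitive_ids:
                    class_of[pid] = rule.target
                    provenance[pid] = f"reclassified_by_rule_{k}"
                changed = True
        if changed:
            current = ROILabeling.from_classes(current.layer, class_of, provenance)
    return current


def manual_correct(
    labeling: ROILabeling, edits: list[tuple[int, str]]
) -> ROILabeling:
    """Programmatic replacement for the interactive visual-check step.

    Each edit (roi_object_id, new_class) relabels exactly that ROI
    object's primitives; merging is re-run afterwards and the affected
    primitives carry ``manual`` provenance.  Disjoint edits commute.
    """
    known = labeling.classes_present | {c for _, c in edits}
    for rid, cls in edits:
        if rid not in labeling._roi_by_id:
            raise KeyError(f"unknown ROI object id {rid}")
        if cls not in known:
            raise ValueError(f"unknown class {cls!r}")
    if not edits:
        return labeling
    class_of = dict(labeling.class_of)
    provenance = {
        p: r.provenance for r in labeling.roi_objects for p in r.primitive_ids
    }
    for rid, cls in edits:
        for pid in labeling.roi_object(rid).primitive_ids:
            class_of[pid] = cls
            provenance[pid] = "manual"
    return ROILabeling.from_classes(labeling.layer, class_of, provenance)


# ---------------------------------------------------------------------------
# default ruleset and YAML I/O


def default_ruleset(
    follicle_max_area_um2: float = 5.0e4,
    border_fraction: float = 0.7,
) -> list[ReclassRule]:
    """The shipped four-composer ruleset.

    1. follicle-labelled objects too large to be follicles are tumor
       (size-based: a "false lymphoid follicle" detected inside a dense
       tumor);
    2. mucosa-labelled objects mostly bordered by tumor are tumor ("false
       mucosa" islands inside tumors, by relationship to the neighbour
       object);
    3–4. mucosa- or tumor-labelled objects mostly bordered by lymphoid
       follicle are follicle (rim fragments of the densely packed
       follicle that fall between class signatures).

    Thresholds are configuration, not measurements: follicles in this
    workflow are ≲ 10⁴ µm² structures, so 5×10⁴ µm² (0.05 mm²) cleanly
    separates "follicle-sized" from "tumor-sized".
    """
    return [
        ReclassRule("lymphoid_follicle", "tumor", "area_um2", ">=", follicle_max_area_um2),
        ReclassRule(
            "mucosa", "tumor", "relative_border", ">=", border_fraction, ref_class="tumor"
        ),
        ReclassRule(
            "mucosa", "lymphoid_follicle", "relative_border", ">=",
            border_fraction, ref_class="lymphoid_follicle",
        ),
        ReclassRule(
            "tumor", "lymphoid_follicle", "relative_border", ">=",
            border_fraction, ref_class="lymphoid_follicle",
        ),
    ]


def load_rules(path) -> list[ReclassRule]:
    """Read rules from a YAML list of {source, target, feature, op,
    threshold[, ref_class]} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [
        ReclassRule(
            source=r["source"],
            target=r["target"],
            feature=r["feature"],
            op=str(r["op"]),
            threshold=float(r["threshold"]),
            ref_class=r.get("ref_class"),
        )
        for r in raw
    ]


def pixel_agreement(labeling: ROILabeling, truth: LabelMask) -> float:
    """Fraction of tissue pixels whose class matches a ground-truth mask."""
    pred = labeling.to_mask()
    sel = labeling.layer.tissue_mask & (truth.labels > 0)
    if not sel.any():
        return 0.0
    # compare class names, not label codes, through both legends
    pred_codes = {k: v for k, v in pred.legend.items()}
    truth_codes = {k: v for k, v in truth.legend.items()}
    pl = pred.labels[sel]
    tl = truth.labels[sel]
    # vectorised name comparison through LUTs
    max_p = max(pred_codes) if pred_codes else 0
    max_t = max(truth_codes) if truth_codes else 0
    names = sorted(set(pred_codes.values()) | set(truth_codes.values()))
    name_id = {n: i + 1 for i, n in enumerate(names)}
    lut_p = np.zeros(max_p + 1, dtype=np.int64)
    for k, v in pred_codes.items():
        lut_p[k] = name_id[v]
    lut_t = np.zeros(max_t + 1, dtype=np.int64)
    for k, v in truth_codes.items():
        lut_t[k] = name_id[v]
    return float(np.mean(lut_p[pl] == lut_t[tl]))
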