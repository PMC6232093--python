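# Methods

This note documents the models and procedures implemented in `ifquant`,
the parameters that matter, the synthetic data the test suite runs on,
and the numerical choices made where the design was genuinely open.

## Pipeline overview

Stages run in a fixed order on a calibrated multichannel slide
(default calibration 0.161028 µm/pixel, 16-bit grey values):

1. **Tissue detection** — a pixel is tissue iff its Gaussian-smoothed
   (σ = 2 px) brightness on the detection channel (DAPI by default) is
   ≥ `brightness_min` and its local heterogeneity is ≤ `homogeneity_max`;
   connected fragments under `min_area_um2` (default 10 µm²) are removed.
   Heterogeneity is the sliding-window (15×15 px) coefficient of
   variation cv mapped to a bounded scale, h = S·cv/(1+cv) with S = 5
   (S = 255 supported for configurations written against an 8-bit
   preview). Both forms are monotone in cv, so thresholds on either
   behave identically up to rescaling. An Otsu-based helper suggests a
   starting `brightness_min`; it is never applied implicitly.

2. **Primitive-object segmentation** — seeds on a hexagonal lattice whose
   spacing targets a mean object area of `base_area_um2 / scale²`
   (defaults 1024 µm² and scale 4 → ≈ 64 µm² objects), grown by watershed
   on the pooled per-channel Sobel gradient within the tissue mask, then
   split into connected components so each object is connected. The
   scale→area law is this package's convention: only the ordinal
   behaviour of "scale" (higher scale → smaller objects, easing cell
   individualisation but blurring region context) is inherent to the
   method. Per object we compute area, perimeter, compactness
   4π·A/P² (clipped to 1 against rasterisation), per-channel mean/σ,
   nuclear coefficient of variation ("heterogeneity"), a local nuclear
   density (below), the neighbour graph and boundary-contact counts from
   which relative borders per neighbour class are derived.

   *Local nuclear density* is estimated from coverage: the fraction of
   nuclear-foreground pixels (Otsu on the smoothed channel) in a ~50 µm
   window divided by the mean single-nucleus area, giving nuclei/mm².
   A blob-count estimator collapses where touching nuclei fuse into one
   component — precisely the dense follicles the feature must flag — so
   coverage is used instead; it stays monotone in true packing density.

3. **ROI classification** — a seeded random forest (200 trees,
   standardised features; nearest-centroid available as a fallback
   family) trained on exemplar primitive objects, given directly or
   derived from a labelled mask by ≥ 50 % majority overlap. Class sets
   hold 2–8 region classes. After prediction, touching same-class
   primitives merge into ROI objects (transitive closure of same-class
   adjacency). Because the tissue mask already excludes background,
   configured classes with no exemplar (typically `background`) are
   dropped from training rather than treated as an error.

4. **Rule-based reclassification** — ordered conditional rules, each
   `source → target if feature op threshold`, with the feature vocabulary
   {area, relative border to a class, distance to a class, heterogeneity,
   local density}. Rules apply strictly in order; merging and feature
   refresh happen after each rule so later rules see updated labels; all
   rules are validated before any mutation. The shipped four-rule set:
   over-large "follicles" become tumor (0.05 mm² threshold — an order of
   magnitude above plausible follicle size and below tumor size);
   mucosa mostly bordered by tumor becomes tumor; mucosa or tumor
   fragments mostly bordered by follicle become follicle (the
   characteristic error at the rim of the densely packed follicle, where
   mixed-content objects fall between class signatures). A raw
   distance-to-tumor predicate was considered for rule 2 and rejected as
   the default because it also relabels genuine mucosa touching a tumor;
   the predicate remains available in the vocabulary. All thresholds are
   configuration, not measurements.

5. **Manual correction** — a programmatic edit API (`roi_object_id →
   new_class`) standing in for the interactive visual check; edits on
   disjoint objects commute, provenance is recorded.

6. **Cellular analysis** — per selected region classes (the three iROIs
   plus any `*_bis` present):

   *Nuclei.* Foreground = smoothed DAPI (σ = 1.5 px) within the
   configured intensity window (0–2 a.u.; a.u. = g.v.l/32,768 so 16-bit
   spans [0, 2]), thresholded by Otsu within the analysed region unless
   an explicit threshold is set. Splitting is a watershed on a relief
   combining normalised intensity with a 0.10-weighted distance
   transform; markers are relief maxima with a Euclidean suppression
   radius of 0.45 × the expected diameter from the 35 µm² mean-area
   prior. A declumping pass then re-splits any region larger than 1.3×
   a self-calibrated single-nucleus area (the median region area, which
   absorbs the slide-dependent shrinkage of thresholding): within such a
   clump, peaks are re-detected at half the suppression radius, or — when
   intensity shows no per-nucleus maxima at all, as in blurred
   high-density packs — the clump is divided into
   round((A − 0.125·â)/0.875·â) parts by deterministic farthest-point
   seeded Lloyd iterations (the 0.875 increment reflects the area a
   packed nucleus adds to a clump's union). Sub-gate fragments are
   absorbed into their largest neighbour; hard per-nucleus gates
   [10, 150] µm² apply last.

   *Cells.* "Inside cytoplasmic stain": each cell grows from its nucleus
   into contiguous membrane pixels ≥ the delimitation threshold (CD45
   1,600 g.v.l; Cy3 48,356, the lower bound of its delimitation range —
   delimitation and classification thresholds are deliberately separate
   knobs), competing with neighbours by distance-to-nearest-nucleus and
   capped at mean cell area + tolerance (38 ± 5 µm² single, 36 µm²
   double). A nucleus with no qualifying adjacent membrane keeps its
   nucleus footprint. "Growth from nuclei" dilates isotropically to the
   mean cell area ignoring membrane signal. Cells never overlap and
   never cross ROI-object borders (border-straddlers are clipped to the
   ROI object holding the majority of their nucleus).

   *Phenotypes.* Nuclear gate on the mean DAPI over the nucleus
   footprint; marker calls on mean marker intensity over the whole cell
   footprint; all comparisons inclusive ≥. Single scheme:
   positive/negative. Double scheme: CD3± by Cy3 and CD4± by FITC after
   the nuclear gate, four exhaustive mutually exclusive classes. The
   nuclear-and-membrane co-staining requirement is what makes
   fluorochrome aggregates (bright membrane, no nucleus) invisible to
   the counter.

   *Calibration helper.* Preliminary thresholds from calibration fields:
   nuclear_min = min over positive fields of the 5th percentile of
   per-nucleus DAPI means; marker_min = max over antibody-free control
   fields of the 99.5th percentile of marker pixels. The percentile
   choice is this package's reading of "minimal"/"maximal" field
   statistics robust to single hot pixels; the values are suggestions
   and the stored configuration remains authoritative.

   *Artifact exclusion.* Cells whose nucleus sits in a `*_bis`
   edge-exclusion region are dropped from counts (logged
   `edge_exclusion`); cells under 10 µm² are dropped
   (`below_min_cell_area`); every exclusion carries a reason code.

7. **Quantification** — density = count × 10⁶ / (area + bis area), areas
   in µm², density in cells/mm². The canonical reading of the density
   formula places the 10⁶ as the µm²→mm² conversion; the alternative
   literal reading (dividing by area × 10⁶) would yield densities six
   orders of magnitude below the reported ~10³–10⁴ cells/mm² range and
   is therefore rejected. `bis` areas enter denominators only; `bis`
   cells never enter numerators. Pearson r uses the two-sided t-transform
   with n−2 degrees of freedom and raises explicitly on zero variance;
   the across-region comparison is a classical one-way ANOVA. Both are
   cross-checked in the test suite against hand-written sums-of-squares
   oracles. No multiple-testing correction is applied.

## Synthetic slides and what they do (not) show

The generator lays out a rounded tissue section on a dark background:
a textured mucosa band (sinusoidal crypt-like DAPI modulation), round
lymphoid-follicle disks, irregular tumor blobs (sinusoidally modulated
radii), an other-tissue remainder and background. Per region it draws a
Poisson number of cells from the configured marker-positive densities —
defaults are the study conditions: follicle 2.10×10⁴, mucosa 2.97×10³,
tumor 3.22×10³ cells/mm² — plus configurable negatives, renders ~35 µm²
nuclei (truncated normal, σ = 4 µm²) with a radial intensity falloff and
a region-specific blur over follicles (the "blurry DAPI from high
cellular density" case the splitting contract exists for), ring-like
membrane staining (annulus from 0.6 nucleus-radius to the cell radius)
around positive cells, background noise, fluorochrome aggregates placed
clear of cells, and optionally a bright tissue-edge autofluorescence rim
with matching `mucosa_bis`/`tumor_bis` ground truth. Negative controls
re-use the identical cell layout with the omitted marker's channel
reduced to background and ground-truth phenotypes forced negative.

**Cell placement.** Sparse compartments use hard-core dart throwing with
minimum separation = one nucleus diameter; infeasible densities raise an
explicit overcrowding error. The follicle is different: its published
density exceeds the jamming coverage of random sequential placement
(≈ 0.547 for hard disks, i.e. ≈ 1.56×10⁴/mm² for 35 µm² nuclei), while
real lymphocytes reach it by packing like a jammed granular medium —
near-touching, slightly deformed. Follicles therefore use a jittered
hexagonal close packing (spacing 0.85 × nucleus diameter, 12 % jitter,
sites drawn at random to the Poisson count), which reproduces that
regime; the lattice capacity is the packing bound and overcrowding still
fails loudly.

**What passing tests show — and don't.** The synthetic slides give exact
ground truth and strongly distinct region signatures; they exercise the
contracts (separability, splitting under dense packing, co-staining
robustness to aggregates, bis-area bookkeeping) but are far easier than
real tissue: no autofocus failures, no uneven illumination, no
red-blood-cell autofluorescence spectra, no genuinely ambiguous region
boundaries, and region texture differences are cleaner than histology.
Accuracy numbers on them are upper bounds, not field performance.

## Problem sizes

Desk-scale fields are the target (≤ 4096²; no pyramid streaming). The
shipped verification uses 2048² px fields (330 µm side, ~500 cells) for
the control and count-recovery runs, 18 sections at 1024² for the
density ordering/ANOVA, and 256–768² fields in unit tests. On these
sizes the full pipeline runs in seconds to tens of seconds per field.
The 18-section loop skips a section whose Poisson draw exceeds the
follicle packing capacity and draws the next seed — the per-section
failure probability is small but not zero, and silent thinning would
bias densities downward.

## Numerical choices and edge cases

- All thresholds compare with inclusive ≥ (boundary behaviour tested).
- Watershed ties break by pixel order; every stage is deterministic for
  a fixed seed, and the classifier seed is the single source of
  randomness in the analysis path.
- Empty inputs degrade explicitly: empty tissue mask → empty layer (not
  an error); empty rule list → identity; zero-area region with zero
  cells → density 0; positive count over zero area → error; constant
  score vectors → explicit zero-variance error rather than silent NaN.
- Compactness is clipped to 1 for tiny rasterised objects; perimeter is
  floored at one pixel.
- A slide file without stored pixel size is rejected unless a pixel size
  is passed explicitly — 1 µm/px is never assumed.
- ROI assignment of border-straddling cells: majority of nucleus pixels,
  ties resolved toward the nucleus centroid's object.
- Downsampled analysis for the region stages (the coarse-resolution
  shortcut some workflows use) is not implemented; all stages run at
  full resolution, which desk-scale fields permit.

## Known limitations

- The region classifier sees only first-order object features; subtle
  texture classes (e.g. two background sub-tones) are modelled as one
  class.
- Polynuclear/aberrant structures have no dedicated detector; the
  documented mitigation is membrane-only detection at reduced
  resolution via the `growth_from_nuclei` mode and configuration.
- The declumping count model (affine area growth per packed nucleus) is
  calibrated for near-circular nuclei around the 35 µm² prior; strongly
  elongated nuclei would need a different prior.
- Manual scores are consumed, never simulated; correlation validation
  therefore requires an external score table.
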