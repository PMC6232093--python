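# ifquant

Object-based quantification of immune cells on whole-slide
immunofluorescence images of intestinal tissue.

Slide-wide scoring of immune infiltration — how many CD45⁺ leukocytes or
CD3⁺/CD4⁺ T cells sit in the mucosa, in lymphoid follicles, in tumors —
is usually done by eye on a few random fields. `ifquant` implements the
automated alternative: a hierarchical object-based image analysis that
detects the whole tissue section, partitions it into small "primitive
objects", classifies those objects into region classes from a handful of
training exemplars, repairs systematic errors with ordered conditional
rules, detects nuclei and simulates cell bodies per region, calls
phenotypes from co-staining thresholds, and reports per-region
immune-cell densities with validation statistics. A synthetic-slide
generator with exact ground truth makes every stage testable end to end
without any microscope.

It is aimed at image-analysis and computational-pathology researchers who
want an open, scriptable version of this workflow class (the commercial
original runs inside a proprietary GUI), and at method developers who
need a ground-truthed benchmark for region classification and in-tissue
cell counting.

## The quantity at the core

For each immune region of interest (iROI) *x* — mucosa, lymphoid
follicle, tumor — the pipeline reports the marker-positive cell density

```
density_x [cells/mm²] = N⁺_x × 10⁶ / (Area_x [µm²] + Area_x,bis [µm²])
```

where `N⁺_x` counts cells passing the nuclear *and* membrane-marker
thresholds inside region *x* and the optional `bis` term is the
edge-exclusion area: cells in a `*_bis` rim (tissue-edge
autofluorescence) are never counted, but their area stays in the
denominator so edge trimming cannot inflate densities. A cell is a
nucleus (DAPI foreground split under a 35 µm² mean-nuclear-area prior)
plus a simulated body grown competitively into supra-threshold membrane
staining ("inside cytoplasmic stain") or dilated isotropically ("growth
from nuclei"). Phenotypes compare mean intensities with inclusive ≥
against per-channel thresholds (defaults: DAPI 1,000 / FITC 1,300 g.v.l
for single CD45 staining; DAPI 500 / Cy3 2,500 / FITC 1,500 for
CD3/CD4 double staining at 16-bit depth).

Validation statistics: Pearson correlation of densities against an
expert 0–5 manual score, and one-way ANOVA of densities across regions.

## Worked example

```python
from ifquant import synthgen, pipeline

cfg = synthgen.SynthConfig(shape=(1024, 1024), seed=7)   # 165 µm × 165 µm field
slide, gt = synthgen.generate_slide(cfg)                 # + exact ground truth
result = pipeline.analyze_slide(slide, None, exemplar_mask=gt.roi_mask,
                                slide_id="demo")
cols = ["roi_class", "area_mm2", "total_cells", "count_positive", "density_positive"]
print(result.report.to_frame()[cols].round(4).to_string(index=False))
```

prints

```
        roi_class  area_mm2  total_cells  count_positive  density_positive
           mucosa    0.0055           33              13         2358.9475
lymphoid_follicle    0.0025           56              56        22409.6130
            tumor    0.0032           23              11         3410.0640
```

Read: on this simulated field the lymphoid follicles carry ≈ 2.2×10⁴
CD45⁺ cells/mm², roughly seven times the mucosa (≈ 2.4×10³) and tumor
(≈ 3.4×10³) densities — the ordering expected of gut-associated lymphoid
tissue, and within Poisson scatter of the generator's configured
region densities (2.10×10⁴ / 2.97×10³ / 3.22×10³ cells/mm²). The slide
summary for the same run: 348 primitive objects, 112 cells, 0 excluded.

There is also a CLI (`ifquant synthesize`, `ifquant detect-tissue`,
`ifquant segment`, `ifquant classify-roi`, `ifquant run`, `ifquant
batch`, `ifquant quantify`) that maps one YAML configuration over single
slides or whole batches; every run writes its intermediate masks, the
cell table, the density report and a manifest with the fully resolved
parameters and seed.

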