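# bodymetry

Contactless body girth estimation from multi-angle 2D silhouettes.

Given a set of images (or binary silhouette masks) of an upright subject
taken at uniform angular increments over 0–180° (default 30°, i.e. seven
views) plus the subject's true stature in cm, the pipeline:

1. segments each view into a clean silhouette (Otsu threshold, largest
   4-connected component, hole fill; a Canny edge map is exposed for
   inspection),
2. extracts per-row pixel widths and scales them to cm via the stature
   anchor (`cm = stature_cm * px / silhouette_height_px`),
3. aligns all views onto a common grid of normalized heights, treating
   each view's half-width as the radial extent at that angle,
4. estimates every row's circumference two ways — a law-of-cosines
   inscribed polygon over the angle fan (a dodecagon at 30° steps) and the
   classic two-view ellipse approximation `2π√((a²+b²)/2)` — and
5. locates the waist (band minimum) and hip (band maximum) landmarks and
   reports their circumferences, with error statistics and old-vs-new
   change reports for longitudinal monitoring.

Because no public dataset of calibrated body photographs exists, the
`phantom` module generates synthetic ground truth: superellipse-stacked
body phantoms with analytic cross-section girths and support widths, a
deterministic silhouette renderer (orthographic or pinhole), and fixture
sets (masks + manifest + truth CSV) that feed the measurement pipeline.

## CLI

```sh
# render a 7-view phantom fixture set with oracle truth
bodymetry simulate --preset hourglass --step 30 --px-per-cm 20 --seed 0 --out fixtures/hg

# measure it (stature comes from the manifest, or pass --height-cm)
bodymetry measure --views fixtures/hg --out results/hg

# error statistics from (label, actual, measured) pairs
bodymetry evaluate --pairs pairs.csv --out results

# cosine-vs-ellipse comparison against known truth
bodymetry evaluate --truth truth.json --measured results/hg/measurements.json --out results
```

Presets: `cylinder`, `elliptic`, `hourglass`, and a matched
`thin`/`overweight` pair differing only by a torso scale factor. Custom
phantoms load from YAML/JSON (see `PhantomSpec`).

## Library entry points

```python
import bodymetry as bm

fan = bm.RadialFan.from_radii([0.75, 0.71, 0.62, 0.56, 0.62, 0.71, 0.75])
bm.cosine_perimeter(fan).value        # inscribed-polygon circumference
bm.ellipse_perimeter(0.75, 0.56).value

from bodymetry import phantom, measure
spec = phantom.preset("hourglass")
views = {a: phantom.render_view(spec, a, 20.0) for a in range(0, 181, 30)}
result = measure.measure_subject(views, spec.stature_cm)
result.waist_cm, result.hip_cm, result.waist_row_frac
```

Notes on conventions: radii are half-widths (projected support widths
divided by two), the full perimeter is twice the 0–180° half-perimeter
(front/back symmetry is assumed), the angular step must divide 180
exactly, and reported values are rounded to 2 decimals while internal
computation stays at full precision.
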