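# Methods

This note documents the models, estimators, conventions and defaults used
by `cytomorph`, and what the synthetic-scene validation does and does not
establish.

## Synthetic scene model

A scene is a field of non-overlapping cells of two phenotypes:

* **mesenchymal** — a rasterized ellipse (optionally perturbed by a seeded
  low-frequency radial ripple, ≤ 10% of the local radius), axes drawn
  uniformly from configured ranges;
* **polarized** — an elliptical body fused with a single straight
  protrusion emanating from one pole along the body orientation, tapering
  linearly from its neck width to 2 px at the tip. The tip-to-far-pole
  extent is exactly `body_major + protrusion_length`, which gives every
  length measurement an analytic oracle. Protrusions are straight by
  design; curvature would break the oracle and the source morphology is a
  single long, essentially straight process.

Nuclei are smaller co-oriented ellipses, displaced along the orientation
axis toward the protrusion neck by `nucleus_offset_frac` of the body
semi-major axis (polarized cells; centred otherwise), mirroring the
reported nuclear displacement into the cell-body enlargement.

Intensity model, per channel: `(Σ level·mask + background) × shading`,
then optional Poisson noise and additive Gaussian noise, clipped to 16-bit
unsigned. The shading field is a Gaussian bump normalized to mean 1
(default amplitude 0.3, σ = 0.4 × the smaller frame dimension). The σ was
chosen as realistic vignetting that varies appreciably within the frame; a
much broader bump degenerates toward a global gain, which no within-frame
estimator can meaningfully separate from signal. Cell placement is
rejection sampling with a bounded retry count (default 100 per cell) and a
separation margin (default 5 px) so thresholding cannot merge neighbours;
failure raises an explicit error naming the constraint.

Defaults in `SceneConfig` describe a 1388×1040 px field at 0.32 µm/px
(20× objective) with ~12 cells per field and protrusion lengths spanning
the reported 41–116 µm range; bit depth, pixel size and field size are not
fixed by the source protocol, so all are exposed as configuration. Tests
and examples use smaller frames (512–640 px at 1 µm/px) with
proportionally scaled cells to keep suites fast; these sizes are package
choices, stated here once.

**What the generator does not emulate:** optical blur (no PSF), uneven
marker distribution inside a cell (levels are per-cell constants), touching
or overlapping cells, debris, and segmentation ambiguity. Passing the
recovery tests therefore shows the *measurement* chain is unbiased given
reasonable segmentation; it does not certify segmentation performance on
real, cluttered micrographs.

## Morphometry conventions

* **Perimeter** — length of the marching-squares (0.5-level) contour after
  a circular moving-average smoothing over 5 vertices. Raw crack-length
  counting overestimates curved boundaries by up to ~8%, which biases the
  shape index low and breaks the circle → CSI = 1 identity; the smoothed
  contour restores rasterized circles to within ~1% while leaving squares
  within 2% of their true perimeter.
* **CSI / NSI** — `4πA/P²` with A the pixel count. The shape index is read
  as standard circularity; the formula is configuration in the sense that
  any `RegionProps`-based definition can be substituted.
* **Feret diameter/angle** — rotating calipers over the convex hull of the
  boundary pixels' half-integer corners. Using pixel corners (not centres)
  makes the caliper length of an axis-aligned n-px rectangle exactly n.
  Exact ties (e.g. the two diagonals of a rectangle) break toward the
  smaller angle in [0, 180). The caliper equals the brute-force maximum
  pairwise corner distance exactly — asserted, not approximated.
* **AR** — moment-equivalent ellipse axes ratio, from central second
  moments.
* **CL** — the maximum Feret diameter in µm, not the moment major axis: for
  a polarized cell the moment axis underestimates tip-to-tip length. The
  moment axis is recorded alongside as a secondary column.
* **NP** — maximum Feret diameter divided by the maximum Euclidean distance
  from the nucleus centroid to the boundary corners. With the centroid
  inside the mask this is provably in [1, 2] (the diameter of a point set
  bounds the distance from any interior point to its farthest vertex, and
  is at most twice it). A geodesic variant (distances measured inside the
  mask) is available behind a flag; Euclidean is the default because it
  admits exact toy oracles.
* **Protrusion length** — the mask is skeletonized; the body centre is the
  skeleton pixel of maximal inscribed width (2 × distance transform); the
  neck is the first point, walking toward a skeleton endpoint, where local
  width falls below 50% of the body's maximum width; the branch length is
  the smoothed-polyline length of the skeleton path from neck to endpoint
  (the smoothing removes the ~8% raster inflation of 8-connected chains).
  Branches shorter than half the body width are pole artifacts of
  ellipse skeletons and are discarded — this is what makes a plain ellipse
  report "no protrusion" rather than a spurious few-pixel branch. The neck
  convention sits slightly inside the body pole, giving a small (~3–4%)
  systematic overestimate of the generator's protrusion length; this is the
  price of a definition that needs no access to ground truth.
* **Phenotype call** — elongated/polarized iff AR ≥ 3 and exactly one
  protrusion longer than one body minor-axis length. The source reports
  phenotype fractions without stating its criterion; these thresholds are
  configuration, calibrated on the generator where they separate the two
  phenotypes with ≥ 95% agreement.

## Fluorescence quantification

Pipeline per image: flat-field correction → opening background subtraction
→ per-cell integration → background-ROI estimation → CTCF.

* **Flat-field correction** — the illumination estimate is a large-scale
  Gaussian smoothing (default σ = 100 px) of the image with foreground
  masked out: when an Otsu split finds a foreground ≥ 1.5× brighter than
  the background, those pixels are excluded via normalized convolution,
  because bright cells otherwise inflate the local estimate. The
  divide-by-estimate step is iterated (default 6×) since a single pass
  attenuates the very bump it measures; the global mean is preserved
  (within 0.1%). The smoothing runs on a grid downsampled to ~σ/20 — the
  estimate carries no structure below σ, so this is exact up to bilinear
  interpolation and keeps the cost trivial. On generator scenes the
  correction removes ≥ 90% of the injected shading amplitude and leaves
  per-cell integrated intensities within ~1% of their unshaded reference.
  All-zero images are returned unchanged with a warning: empty fields must
  not crash a batch run.
* **Opening background** — grayscale opening with a rasterized disk;
  "disk of d pixels" is read as diameter d (radius d//2). The operation
  default follows the source (d = 20), but a disk only estimates the
  background if it is wider than the widest bright object — otherwise the
  opening reproduces the cells and subtraction cancels their signal. The
  quantification configs used on synthetic scenes therefore size the disk
  above the largest cell minor axis (e.g. 45 px for ≤ 38 px cells). Border
  handling for all morphology and convolution is replicate padding, which
  avoids dark rims that would bias background estimates.
* **CTCF** — default `cFID − Ac·MFB`, with MFB the mean of five seeded,
  disjoint, cell-free square ROIs (default 30×30 px; automated rather than
  hand-drawn so runs are reproducible). The printed form of the formula in
  the source multiplies in the mean ROI area as well (`cFID − Ac·MAb·MFB`);
  taken literally it is dimensionally inconsistent, so it is provided as
  `mode="literal"` for fidelity and the standard form is the default. The
  mode is recorded in every output row.

Measured invariances (asserted by the suite): CTCF is exactly invariant to
a constant intensity offset (the opening shifts with the image and MFB
absorbs the rest), linear in marker level (R² ≥ 0.99 noise-free), within
±5% under 30% shading once flat-fielding is on, and visibly biased with it
off.

## Statistics

One-way fixed-effects ANOVA (explicit sum-of-squares decomposition; the
p-value is checked against scipy and against permutation nulls). Dunn's
test ranks all observations jointly with mid-ranks,
`z = ΔR̄ / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ))`, two-sided
normal p-values, Bonferroni adjustment by default (the source names the
test but not the adjustment; Holm is available). Pearson correlation uses
the t transform. Boxplots use linear-interpolation quartiles with 1.5×IQR
Tukey fences; outliers are listed explicitly. Star annotations follow the
figure-legend convention (* p<0.05, ** p<0.01, *** p<0.005,
**** p<0.0001). Simulated calibration: on 2000 null datasets
(3 groups × 30), both the ANOVA rejection rate and the Dunn family-wise
rejection rate stay within 3 standard errors of α = 0.05 (Bonferroni makes
Dunn conservative).

Mean ± SD and median/range summaries are both computed and written to the
stats output, since group displays legitimately use either.

## Pipeline and reproducibility

A run is a `RunConfig` (YAML-serializable). The global seed fans out as
`SeedSequence([seed, stage_index, field_index])`, so stages are
independently reproducible and identical configs give byte-identical CSVs
(asserted). `run_config.json` is written before any computation; the final
manifest records per-stage counts, warnings and SHA-256 checksums of every
output. Whether illumination correction is applied before segmentation, or
only to intensity quantification, is a config switch
(`SegmentationConfig.flatfield_first`), since the source protocol does not
pin the ordering.

## Known limitations

* Segmentation is threshold-based (Otsu) and assumes separable cells; the
  generator guarantees separation, real micrographs may not.
* The protrusion measure assumes a single dominant branch; heavily
  branched cells would need the branch-count output interpreted with care.
* Feret angle uses the maximum-caliper direction; a minimum-Feret variant
  is not implemented.
* The reported study-scale percent changes (CSI reductions, AR/CL
  increases, phenotype fractions) depend on that study's own micrographs
  and culture conditions; this package validates the measurement chain on
  synthetic ground truth, not those biological effect sizes.
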