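# cytomorph

Quantitative cyto-morphometry and fluorescence quantification for cell
micrographs, built for studies that read a cell's state from its shape —
for example stem cells acquiring a neuronal-like, elongated/polarized
morphology on a biomaterial surface, versus retaining a spread,
fibroblast-like one.

The package is aimed at cell-biology and biomaterials groups who need the
standard per-cell readouts from fluorescence images (phalloidin/DAPI plus
marker channels), with every step reproducible and testable:

* **Morphometric descriptors** per cell and nucleus:
  - cell shape index `CSI = 4πA / P²` (1 for a circle, → 0 when elongated)
    and its nuclear counterpart NSI;
  - aspect ratio `AR` of the moment-equivalent ellipse (major/minor axis);
  - cell length `CL` — the maximum Feret (caliper) diameter in calibrated
    µm — and the Feret angle (orientation randomness);
  - nuclear positioning `NP = CL / max distance from the nucleus centroid
    to the cell boundary` (2 = centred nucleus, → 1 = nucleus at a pole);
  - protrusion length, measured geodesically along the mask skeleton from
    the body/protrusion neck to the tip;
  - an elongated/polarized vs mesenchymal phenotype call
    (AR ≥ 3, exactly one protrusion longer than the cell body width).
* **Corrected total cell fluorescence**:
  `CTCF = cFID − Ac · MFB`, where cFID is the integrated density under the
  cell mask, Ac the masked area and MFB the mean background fluorescence of
  five automatically placed, cell-free ROIs — after flat-field illumination
  correction and background subtraction by grayscale morphological opening
  (disk structuring element).
* **Group statistics**: percent change versus control, one-way ANOVA,
  Dunn's rank-based multiple comparison test (Bonferroni/Holm), Pearson
  correlation, and boxplot summaries with Tukey outlier flagging.
* **A synthetic scene generator** that renders both phenotypes with nuclei,
  per-channel marker levels, multiplicative shading, background and noise —
  with complete ground truth, so the whole pipeline can be validated
  end-to-end against known geometry and intensities.

## Worked example

`examples/02_morphometry.py` renders a mixed scene (8 cells, half polarized
with 80–150 px protrusions, at 1 µm/px), segments it and measures every
cell:

```
 cell_id           phenotype   csi   nsi     ar   cl_um  np_ratio  protrusion_um
       1 elongated_polarized 0.122 0.825 12.494 196.148     1.212        151.647
       2 elongated_polarized 0.207 0.981  5.135 128.845     1.275         93.635
       ...
       7         mesenchymal 0.945 0.951  1.456  65.513     1.997          0.000
       8         mesenchymal 0.988 0.994  1.163  61.465     1.998          0.000
```

Polarized cells read low CSI (elongated outline), high AR, long CL, a
protrusion comparable to their length, and a nucleus displaced toward the
body (NP ≈ 1.2); spread cells sit near CSI ≈ 1, AR ≈ 1.2, NP ≈ 2 with no
protrusion. `examples/05_simulated_experiment.py` then runs a two-condition
study whose only difference is the protrusion-length range (80–110 px vs
160–200 px) and recovers it from the pixels:

```
Dunn CTR vs PBCE: z = -7.30, adjusted p = 2.92e-13 ****
```

The other examples cover scene generation with ground truth (`01`), CTCF
quantification under shading and noise (`03`, errors within a few percent
of the true `area × level` signal), and the statistics layer (`04`).

A thin CLI mirrors the library for batch use:

```
cytomorph generate --config scene.yaml --outdir out/
cytomorph run-all --config run.yaml --seed 1
cytomorph simulate-experiment --config design.yaml --outdir study/
```

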