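"""End-to-end simulated study with an injected protrusion-length effect.

Two conditions share every generator parameter except the protrusion-length
range; the full pipeline (render -> segment -> measure -> rank statistics)
must recover the difference. This is the package's main self-validation
loop: the generator defines truth, the statistics must find exactly it.
"""

from cytomorph import Condition, ExperimentDesign, SceneConfig, simulate_experiment
from cytomorph.pipeline import SegmentationConfig, compare_conditions
from cytomorph.group_stats import significance_stars

base = SceneConfig(
    width_px=640,
    height_px=640,
    n_cells=6,
    polarized_fraction=1.0,
    scale_um_per_px=1.0,
    polarized_major_px=(36, 50),
    polarized_minor_px=(20, 30),
    protrusion_length_px=(80, 110),
    protrusion_width_px=(6, 10),
)

design = ExperimentDesign(
    base_scene=base,
    conditions=[
        Condition("CTR", n_fields=6),
        Condition("PBCE", overrides={"protrusion_length_px": (160, 200)}, n_fields=6),
    ],
    segmentation=SegmentationConfig(min_cell_area_px=150, min_nucleus_area_px=20),
    seed=1,
)

table, truth = simulate_experiment(design)
print(table.groupby("substrate")["protrusion_um"].describe().round(1))

res = compare_conditions(table, "protrusion_um")
row = res.pairs.iloc[0]
print(f"\nDunn {row.group_i} vs {row.group_j}: z = {row.z:+.2f}, "
      f"adjusted p = {row.p_adj:.3g} {significance_stars(row.p_adj)}")
print(f"(injected truth: CTR protrusions 80-110 px, PBCE 160-200 px)")
# The adjusted p-value far below 0.05 shows the pipeline recovers the
# injected morphological effect from pixels alone.
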