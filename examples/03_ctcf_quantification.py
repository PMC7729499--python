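"""Corrected total cell fluorescence (CTCF) for a marker channel.

Renders a scene whose marker level is known exactly, runs the quantification
pipeline (flat-field correction, opening-background subtraction, masked
integration, five seeded background ROIs) and compares each cell's CTCF to
the ground-truth `area x level` product.
"""

from cytomorph import QuantConfig, SceneConfig, quantify_marker, render_scene

LEVEL = 120.0  # true marker intensity (a.u.) above background

config = SceneConfig(
    width_px=512,
    height_px=512,
    n_cells=6,
    polarized_fraction=0.0,
    seed=11,
    scale_um_per_px=1.0,
    mesenchymal_major_px=(44, 54),
    mesenchymal_minor_px=(30, 38),
    channel_levels={"marker": (LEVEL, LEVEL)},
    shading_amplitude=0.3,
    noise_gaussian_sd=3.0,
)

channels, truth = render_scene(config)

# the opening disk must be wider than the widest cell (38 px here), or the
# "background" image would contain the cells themselves
quant = QuantConfig(flatfield=True, background_disk_px=45, roi_size_px=20, seed=0)
table, meta = quantify_marker(
    channels["marker"].astype(float), truth.label_image, quant
)

print(table[["cell_id", "cfid", "ac", "mfb", "ctcf"]].round(1).to_string(index=False))
print(f"\nbackground ROIs used: {meta['background_rois']}")
for _, row in table.iterrows():
    expected = row["ac"] * LEVEL
    err = (row["ctcf"] - expected) / expected * 100
    print(f"cell {int(row.cell_id)}: CTCF {row.ctcf:9.0f}  expected {expected:9.0f}"
          f"  error {err:+.2f}%")
# Despite 30% illumination shading and added noise, CTCF recovers each
# cell's true integrated signal to within a few percent.
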