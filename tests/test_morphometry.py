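"""Shape descriptors against analytic and brute-force oracles, plus
parameter-recovery properties on generator ground truth."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from cytomorph import (
    Calibration,
    CellParams,
    PhenotypeThresholds,
    aspect_ratio,
    cell_length,
    classify_phenotype,
    csi,
    feret_diameter,
    nsi,
    nuclear_positioning,
    protrusion_length,
    region_properties,
)
from cytomorph.morphometry import boundary_corners
from cytomorph.scenegen import make_mesenchymal_mask, make_polarized_mask, render_scene

from conftest import small_scene

CAL = Calibration(1.0)


def circle_mask(radius: int) -> np.ndarray:
    size = 2 * radius + 21
    img = np.zeros((size, size), bool)
    rr, cc = draw_disk((size // 2, size // 2), radius)
    img[rr, cc] = True
    return img


def ellipse_mask(a: float, b: float) -> np.ndarray:
    h, w = int(2 * b + 20), int(2 * a + 20)
    img = np.zeros((h, w), bool)
    rr, cc = draw_ellipse(h // 2, w // 2, b, a)
    img[rr, cc] = True
    return img


def ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


class TestRegionProperties:
    def test_circle_area_and_aspect(self):
        props = region_properties(circle_mask(50).astype(int), 1)
        assert props.area_px2 == pytest.approx(math.pi * 50**2, rel=0.02)
        assert aspect_ratio(props) == pytest.approx(1.0, rel=0.03)

    def test_rectangle_feret_diagonal(self):
        mask = np.zeros((60, 140), bool)
        mask[20:40, 20:120] = True  # 100 x 20 px
        props = region_properties(mask.astype(int), 1)
        assert props.feret_max_px == pytest.approx(math.hypot(100, 20), rel=0.02)
        assert props.feret_angle_deg == pytest.approx(
            math.degrees(math.atan2(20, 100)), abs=3.0
        )

    def test_missing_label(self):
        with pytest.raises(ValueError, match="label"):
            region_properties(np.ones((5, 5), int), 7)

    @pytest.mark.parametrize("seed", range(8))
    def test_feret_equals_brute_force_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        from scipy import ndimage as ndi

        img = rng.random((30, 30)) > 0.55
        lab, n = ndi.label(img)
        if n == 0:
            pytest.skip("empty sample")
        sizes = ndi.sum(img, lab, range(1, n + 1))
        mask = lab == 1 + int(np.argmax(sizes))
        pts = boundary_corners(mask)
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        assert feret_diameter(mask)[0] == float(np.sqrt(d2.max()))


class TestShapeIndices:
    def test_circle_csi_is_one(self):
        for r in (30, 50):
            props = region_properties(circle_mask(r).astype(int), 1)
            assert csi(props) == pytest.approx(1.0, abs=0.05)

    def test_square_csi_is_pi_over_four(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        props = region_properties(mask.astype(int), 1)
        assert csi(props) == pytest.approx(math.pi / 4, abs=0.05)

    def test_ellipse_csi_matches_ramanujan_oracle(self):
        a, b = 60, 15  # 120 x 30 px ellipse
        props = region_properties(ellipse_mask(a, b).astype(int), 1)
        expected = 4 * math.pi * (math.pi * a * b) / ramanujan_perimeter(a, b) ** 2
        assert csi(props) == pytest.approx(expected, rel=0.05)

    def test_nsi_is_csi_on_the_same_region(self):
        props = region_properties(ellipse_mask(30, 12).astype(int), 1)
        assert nsi(props) == csi(props)

    def test_nsi_monotone_with_elongation(self):
        slim = region_properties(ellipse_mask(20, 5).astype(int), 1)
        round_ = region_properties(ellipse_mask(20, 15).astype(int), 1)
        assert nsi(slim) < nsi(round_)

    def test_csi_invariant_under_rotation_and_translation(self):
        mask = ellipse_mask(40, 14)
        base = csi(region_properties(mask.astype(int), 1))
        for k in (1, 2, 3):
            rotated = np.rot90(mask, k)
            assert csi(region_properties(rotated.astype(int), 1)) == pytest.approx(
                base, rel=0.02
            )
        shifted = np.roll(mask, (3, 5), axis=(0, 1))
        assert csi(region_properties(shifted.astype(int), 1)) == pytest.approx(
            base, rel=1e-9
        )

    def test_degenerate_perimeter_rejected(self):
        from cytomorph.morphometry import RegionProps

        bad = RegionProps(1, 0, (0, 0), 1, 1, 1, 0, (0, 0, 1, 1))
        with pytest.raises(ValueError):
            csi(bad)


class TestAxisDescriptors:
    def test_ellipse_aspect_ratio(self):
        props = region_properties(ellipse_mask(40, 10).astype(int), 1)
        assert aspect_ratio(props) == pytest.approx(4.0, rel=0.03)

    def test_cell_length_is_calibrated_feret(self):
        from cytomorph.morphometry import RegionProps

        props = RegionProps(1, 1, (0, 0), 1, 1, 500.0, 0, (0, 0, 1, 1))
        assert cell_length(props, Calibration(0.32)) == pytest.approx(160.0)

    def test_zero_scale_is_a_calibration_error(self):
        with pytest.raises(ValueError):
            Calibration(0.0)

    def test_polarized_cell_ar_exceeds_body_only(self):
        body = CellParams("mesenchymal", 50, 30, 10.0, 20, 12)
        full = CellParams("polarized", 50, 30, 10.0, 20, 12, 120, 8, 0.4)
        m_body = make_mesenchymal_mask(body, (400, 400), (200, 200))
        m_full = make_polarized_mask(full, (400, 400), (200, 200))
        ar_body = aspect_ratio(region_properties(m_body.astype(int), 1))
        ar_full = aspect_ratio(region_properties(m_full.astype(int), 1))
        assert ar_full > ar_body


class TestNuclearPositioning:
    def rod(self):
        mask = np.zeros((15, 111), bool)
        mask[5:10, 5:106] = True
        return mask

    def test_centered_nucleus_gives_two(self):
        assert nuclear_positioning(self.rod(), (55.0, 7.0)) == pytest.approx(
            2.0, abs=0.02
        )

    def test_nucleus_at_tip_gives_one(self):
        assert nuclear_positioning(self.rod(), (5.0, 7.0)) == pytest.approx(
            1.0, abs=0.02
        )

    def test_nucleus_at_quarter_gives_four_thirds(self):
        assert nuclear_positioning(self.rod(), (30.0, 7.0)) == pytest.approx(
            4.0 / 3.0, abs=0.02
        )

    def test_centroid_outside_mask_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            nuclear_positioning(self.rod(), (2.0, 2.0))

    def test_np_bounded_on_random_cells(self, recovery_noise_free):
        vals = recovery_noise_free["np_ratio"].dropna()
        assert len(vals) > 100
        assert ((vals >= 1.0) & (vals <= 2.0)).all()


class TestProtrusion:
    def test_straight_protrusion_length_recovered(self):
        p = CellParams("polarized", 50, 30, 0.0, 20, 12, 150, 8, 0.4)
        mask = make_polarized_mask(p, (120, 280), (60, 60))
        res = protrusion_length(mask, CAL)
        assert res.detected and res.n_protrusions == 1
        assert res.length_um == pytest.approx(150.0, abs=8.0)

    def test_mesenchymal_ellipse_has_no_protrusion(self):
        p = CellParams("mesenchymal", 80, 40, 0.0, 30, 16)
        res = protrusion_length(make_mesenchymal_mask(p, (120, 120)), CAL)
        assert res.length_um == 0.0 and not res.detected

    def test_rotation_by_90_degrees_preserves_length(self):
        p = CellParams("polarized", 50, 30, 20.0, 20, 12, 130, 8, 0.4)
        mask = make_polarized_mask(p, (340, 340), (170, 170))
        a = protrusion_length(mask, CAL).length_um
        b = protrusion_length(np.rot90(mask), CAL).length_um
        assert b == pytest.approx(a, rel=0.02)


class TestClassification:
    def test_round_cell_is_mesenchymal(self):
        assert (
            classify_phenotype(ar=1.1, protrusion_um=0.0, n_protrusions=0,
                               minor_axis_um=40.0)
            == "mesenchymal"
        )

    def test_polarized_cell_with_defaults(self):
        assert (
            classify_phenotype(ar=5.0, protrusion_um=120.0, n_protrusions=1,
                               minor_axis_um=30.0)
            == "elongated_polarized"
        )

    def test_multiple_protrusions_excluded_when_required(self):
        kwargs = dict(ar=5.0, protrusion_um=120.0, n_protrusions=2,
                      minor_axis_um=30.0)
        assert classify_phenotype(**kwargs) == "mesenchymal"
        loose = PhenotypeThresholds(require_single_protrusion=False)
        assert classify_phenotype(**kwargs, thresholds=loose) == "elongated_polarized"

    def test_ground_truth_phenotypes_recovered(self, recovery_noise_free):
        tab = recovery_noise_free
        agree = (tab["phenotype"] == "elongated_polarized") == (
            tab["true_phenotype"] == "polarized"
        )
        assert agree.mean() >= 0.95


class TestParameterRecovery:
    def test_noise_free_recovery_within_5pct(self, recovery_noise_free):
        tab = recovery_noise_free
        ar_err = (tab["ar"] - tab["true_ar"]).abs() / tab["true_ar"]
        cl_err = (tab["cl_um"] - tab["true_extent_px"]).abs() / tab["true_extent_px"]
        pol = tab[tab["true_phenotype"] == "polarized"]
        pr_err = (pol["protrusion_um"] - pol["true_protrusion_px"]).abs() / pol[
            "true_protrusion_px"
        ]
        assert ar_err.mean() <= 0.05
        assert cl_err.mean() <= 0.05
        assert pr_err.mean() <= 0.05

    def test_default_noise_recovery_within_10pct(self, recovery_default_noise):
        tab = recovery_default_noise
        cl_err = (tab["cl_um"] - tab["true_extent_px"]).abs() / tab["true_extent_px"]
        pol = tab[tab["true_phenotype"] == "polarized"]
        pr_err = (pol["protrusion_um"] - pol["true_protrusion_px"]).abs() / pol[
            "true_protrusion_px"
        ]
        assert cl_err.mean() <= 0.10
        assert pr_err.mean() <= 0.10


def test_feret_angles_of_isotropic_population_are_uniform():
    """Randomly oriented cells must show no preferred Feret angle."""
    angles = []
    seed = 300
    while len(angles) < 200:
        cfg = small_scene(seed=seed, polarized_fraction=1.0, noise_gaussian_sd=0.0)
        _, truth = render_scene(cfg)
        lab = truth.label_image
        for cell in truth.cells:
            angles.append(feret_diameter(lab == cell.index + 1)[1])
        seed += 1
    counts, _ = np.histogram(angles, bins=6, range=(0, 180))
    p = sps.chisquare(counts).pvalue
    assert p > 0.01  # goodness of fit to uniform not rejected
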