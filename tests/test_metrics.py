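import numpy as np
import pytest

from macmind import (
    DisplacementField,
    LandmarkSet,
    Volume,
    dsc,
    evaluate_panel,
    hd95,
    mutual_information,
    rvd_abs,
    ssim,
    tre,
    voe,
)
from macmind.metrics import entropy


class TestMutualInformation:
    def test_self_mi_equals_entropy(self, rng):
        v = Volume(rng.random((16, 16, 16)))
        mi = mutual_information(v, v, bins=32)
        h = entropy(v, bins=32)
        assert mi == pytest.approx(h, rel=1e-10)

    def test_independent_noise_near_zero(self):
        """Independent uniform volumes share almost no information; the
        finite-sample bias at 32 bins on 32^3 voxels stays under 0.05 nats."""
        for seed in range(1, 21):
            a = Volume(np.random.default_rng(seed).random((32, 32, 32)))
            b = Volume(np.random.default_rng(1000 + seed).random((32, 32, 32)))
            assert mutual_information(a, b, bins=32) < 0.05

    def test_invariant_under_affine_rescaling(self, rng):
        v = Volume(rng.random((12, 12, 12)))
        assert mutual_information(v, Volume(4.0 * v.data + 2.0)) == pytest.approx(
            mutual_information(v, v), rel=1e-10
        )

    def test_constant_image_returns_zero(self):
        v = Volume(np.ones((8, 8, 8)))
        assert mutual_information(v, v) == 0.0


class TestSSIM:
    def test_identity_is_one(self, rng):
        v = Volume(rng.random((10, 10, 10)))
        assert ssim(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_image_scores_lower(self):
        data = np.zeros((8, 8, 8))
        data[:4] = 1.0
        v = Volume(data)
        inv = Volume(1.0 - data)
        assert ssim(v, inv) < ssim(v, v)

    def test_matches_direct_product_formula(self, rng):
        a = rng.random((16, 16, 16))
        b = rng.random((16, 16, 16))
        c1, c2 = 0.01 ** 2, 0.03 ** 2
        x = (a - a.min()) / (a.max() - a.min())
        y = (b - b.min()) / (b.max() - b.min())
        expected = ((2 * x.mean() * y.mean() + c1) * (2 * np.mean((x - x.mean()) * (y - y.mean())) + c2)) / (
            (x.mean() ** 2 + y.mean() ** 2 + c1) * (x.var() + y.var() + c2)
        )
        assert ssim(Volume(a), Volume(b)) == pytest.approx(expected, abs=1e-12)

    def test_literal_variant_differs(self, rng):
        v = Volume(rng.random((8, 8, 8)))
        assert ssim(v, v, literal_form=True) != pytest.approx(1.0, abs=1e-3)


class TestMaskOverlap:
    def _boxes(self):
        a = np.zeros((8, 4, 1), dtype=int)
        b = np.zeros((8, 4, 1), dtype=int)
        a[0:2] = 1
        b[1:3] = 1
        return a, b

    def test_dsc_identity_and_disjoint(self):
        a, b = self._boxes()
        assert dsc(a, a.copy()) == 100.0
        disjoint = np.zeros_like(a)
        disjoint[6:8] = 1
        assert dsc(a, disjoint) == 0.0

    def test_dsc_half_overlap(self):
        a, b = self._boxes()
        assert dsc(a, b) == pytest.approx(50.0)

    def test_dsc_both_empty_warns_100(self):
        z = np.zeros((4, 4, 4), dtype=int)
        assert dsc(z, z) == 100.0
        with pytest.raises(ValueError):
            dsc(z, z, strict=True)

    def test_rvd_abs_values(self):
        base = np.zeros((6, 6, 6), dtype=int)
        gt = base.copy(); gt[:2, :5, :1] = 1          # 10 voxels
        seg = base.copy(); seg[:3, :4, :1] = 1        # 12 voxels
        assert rvd_abs(seg, gt) == pytest.approx(20.0)
        assert rvd_abs(gt, gt) == 0.0
        double = base.copy(); double[:4, :5, :1] = 1  # 20 voxels
        assert rvd_abs(double, gt) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            rvd_abs(seg, base)

    def test_voe_identity_and_disjoint(self):
        a, _ = self._boxes()
        assert voe(a, a.copy()) == 0.0
        disjoint = np.zeros_like(a)
        disjoint[6:8] = 1
        assert voe(a, disjoint) == 100.0

    def test_jaccard_dice_identity_random_masks(self):
        """DSC = 2(100 - VOE) / (200 - VOE) on arbitrary mask pairs."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.random((6, 6, 6)) > 0.6
            b = rng.random((6, 6, 6)) > 0.6
            if not (a.any() or b.any()):
                continue
            v = voe(a, b)
            d = dsc(a, b)
            assert d == pytest.approx(200 * (100 - v) / (200 - v), abs=1e-10)


class TestHd95:
    def test_identical_masks_zero(self):
        m = np.zeros((10, 10, 10), dtype=int)
        m[2:6, 2:6, 2:6] = 1
        assert hd95(m, m.copy()) == 0.0

    def test_shifted_cube_three_mm(self):
        a = np.zeros((12, 8, 8), dtype=int)
        b = np.zeros((12, 8, 8), dtype=int)
        a[0:4, 2:6, 2:6] = 1
        b[3:7, 2:6, 2:6] = 1
        assert hd95(a, b, spacing=(1, 1, 1)) == pytest.approx(3.0)

    def test_symmetric(self):
        rng = np.random.default_rng(8)
        a = np.zeros((10, 10, 10), dtype=int)
        b = np.zeros((10, 10, 10), dtype=int)
        a[2:7, 2:6, 3:7] = 1
        b[4:9, 3:8, 2:6] = 1
        assert hd95(a, b) == pytest.approx(hd95(b, a), rel=1e-12)

    def test_spacing_scales_distances(self):
        a = np.zeros((12, 8, 8), dtype=int)
        b = np.zeros((12, 8, 8), dtype=int)
        a[0:4, 2:6, 2:6] = 1
        b[3:7, 2:6, 2:6] = 1
        assert hd95(a, b, spacing=(2, 1, 1)) == pytest.approx(6.0)

    def test_empty_mask_rejected(self):
        m = np.zeros((6, 6, 6), dtype=int)
        full = m.copy(); full[2:4, 2:4, 2:4] = 1
        with pytest.raises(ValueError, match="non-empty"):
            hd95(m, full)


class TestTRE:
    def test_zero_field_coincident_landmarks(self):
        lms = LandmarkSet(ids=["a", "b"], points=[[3, 4, 5], [10, 10, 10]])
        errs = tre(lms, LandmarkSet(ids=["a", "b"], points=[[3, 4, 5], [10, 10, 10]]))
        np.testing.assert_allclose(errs, 0.0)

    def test_345_offset_gives_five_mm(self):
        f = LandmarkSet(ids=["p"], points=[[5.0, 5.0, 5.0]])
        m = LandmarkSet(ids=["p"], points=[[8.0, 9.0, 5.0]])
        phi = DisplacementField(np.zeros((16, 16, 16, 3)))
        assert tre(f, m, phi)[0] == pytest.approx(5.0)

    def test_matches_by_id_not_order(self):
        f = LandmarkSet(ids=["a", "b"], points=[[0, 0, 0], [5, 0, 0]])
        m = LandmarkSet(ids=["b", "a"], points=[[5, 0, 0], [0, 0, 3]])
        errs = tre(f, m)
        np.testing.assert_allclose(errs, [3.0, 0.0])

    def test_phantom_true_field_maps_landmarks(self, small_phantom):
        case = small_phantom
        errs = tre(
            case.landmarks_b, case.landmarks_a, case.phi_true, case.config.spacing
        )
        assert errs.max() < 0.5 * max(case.config.spacing)

    def test_landmark_outside_domain_rejected(self):
        f = LandmarkSet(ids=["p"], points=[[50.0, 0.0, 0.0]])
        m = LandmarkSet(ids=["p"], points=[[0.0, 0.0, 0.0]])
        phi = DisplacementField(np.zeros((8, 8, 8, 3)))
        with pytest.raises(ValueError, match="outside"):
            tre(f, m, phi)


def test_evaluate_panel_all_fields_present(small_phantom):
    case = small_phantom
    panel = evaluate_panel(
        case.vol_b,
        case.vol_a,
        fixed_label=case.label_organ_b,
        warped_label=case.label_organ_a,
        fixed_lms=case.landmarks_b,
        moving_lms=case.landmarks_a,
        phi=case.phi_true,
    )
    d = panel.to_dict()
    assert all(d[k] is not None for k in d)
    assert 0 <= d["dsc_percent"] <= 100
    assert d["tre_mean_mm"] < 0.5
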