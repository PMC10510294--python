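import numpy as np
import pytest

from macmind import (
    DescriptorConfig,
    Volume,
    aggregate_macmind,
    build_bin_assignment,
    build_connection_layout,
    macmind,
    mind_descriptor,
    msssc,
    patch_ssd_map,
    ssc_feature_map,
)
from macmind.descriptors import FeatureMap, mind_sublayout
from macmind.reference import (
    naive_aggregate,
    naive_macmind,
    naive_mind,
    naive_msssc,
    naive_patch_ssd_map,
    naive_ssc,
)


class TestConnectionLayout:
    def test_ssc_layout_counts(self):
        lay = build_connection_layout(1, 2)
        assert lay.e_p == 18
        assert lay.n_orientations == 9

    def test_mind_sublayout_counts(self):
        sub = mind_sublayout(build_connection_layout(1, 2))
        assert sub.e_p == 6
        assert sub.n_orientations == 3

    def test_scale_two_is_scale_one_doubled(self):
        """Brute-force check: the scale-2 pair geometry is the scale-1 layout
        with every offset doubled."""
        lay1 = build_connection_layout(1, 2)
        lay2 = build_connection_layout(2, 2)
        assert lay2.distance == 4
        assert lay2.pairs == lay1.pairs
        np.testing.assert_array_equal(lay2.offsets, 2 * lay1.offsets)
        assert lay2.orientation_class == lay1.orientation_class

    def test_pairs_exclude_collinear_opposites(self):
        lay = build_connection_layout(1, 1)
        for i, j in lay.pairs:
            assert not np.array_equal(lay.offsets[i], -lay.offsets[j]) or i == 0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            build_connection_layout(0, 2)


class TestPatchSSD:
    def test_constant_image_gives_zero(self):
        v = Volume(np.full((8, 8, 8), 3.7))
        out = patch_ssd_map(v, ((0, 0, 0), (2, 0, 0)), 3)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_bruteforce_everywhere(self):
        rng = np.random.default_rng(5)
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0  # single bright voxel
        v = Volume(data)
        fast = patch_ssd_map(v, ((0, 0, 0), (2, 0, 0)), 3)
        naive = naive_patch_ssd_map(v, ((0, 0, 0), (2, 0, 0)), 3)
        np.testing.assert_allclose(fast, naive, atol=1e-12)
        v2 = Volume(rng.random((9, 9, 9)))
        fast2 = patch_ssd_map(v2, ((1, -1, 0), (0, 0, 2)), 3)
        naive2 = naive_patch_ssd_map(v2, ((1, -1, 0), (0, 0, 2)), 3)
        np.testing.assert_allclose(fast2, naive2, atol=1e-12)

    def test_quadratic_intensity_homogeneity(self, random_volume):
        a = 2.5
        base = patch_ssd_map(random_volume, ((0, 0, 0), (0, 2, 0)), 3)
        scaled = patch_ssd_map(
            Volume(a * random_volume.data), ((0, 0, 0), (0, 2, 0)), 3
        )
        np.testing.assert_allclose(scaled, a ** 2 * base, rtol=1e-10)

    def test_even_patch_size_rejected(self, random_volume):
        with pytest.raises(ValueError, match="odd"):
            patch_ssd_map(random_volume, ((0, 0, 0), (1, 0, 0)), 4)


class TestMind:
    def test_constant_image_all_ones(self):
        v = Volume(np.full((8, 8, 8), 5.0))
        f = mind_descriptor(v, L=1, R1=3)
        assert f.n_channels == 6
        np.testing.assert_allclose(f.data, 1.0, atol=1e-6)

    def test_affine_intensity_invariance(self, random_volume):
        base = mind_descriptor(random_volume, L=1, R1=3)
        mapped = mind_descriptor(Volume(3.0 * random_volume.data + 7.0), L=1, R1=3)
        np.testing.assert_allclose(mapped.data, base.data, atol=1e-6)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        v = Volume(rng.random((7, 7, 7)))
        fast = mind_descriptor(v, L=1, R1=3)
        naive = naive_mind(v, L=1, R1=3)
        np.testing.assert_allclose(fast.data, naive, atol=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            mind_descriptor(Volume(np.zeros((3, 3, 3))), L=2, R1=5)


class TestSSC:
    def test_constant_image_all_ones(self):
        lay = build_connection_layout(1, 1)
        f = ssc_feature_map(Volume(np.full((7, 7, 7), 2.0)), lay, 3)
        assert f.n_channels == 18
        np.testing.assert_allclose(f.data, 1.0, atol=1e-6)

    def test_neglog_channels_sum_to_pair_count(self, random_volume):
        lay = build_connection_layout(1, 1)
        f = ssc_feature_map(random_volume, lay, 3)
        s = -np.log(f.data.astype(np.float64)).sum(axis=-1)
        np.testing.assert_allclose(s, 18.0, atol=1e-4)

    def test_matches_naive_oracle(self, random_volume):
        lay = build_connection_layout(1, 1)
        fast = ssc_feature_map(random_volume, lay, 3)
        naive = naive_ssc(random_volume, lay, 3)
        np.testing.assert_allclose(fast.data, naive, atol=1e-6)

    def test_channel_range(self, random_volume):
        lay = build_connection_layout(1, 2)
        f = ssc_feature_map(random_volume, lay, 3)
        assert (f.data > 0).all() and (f.data <= 1.0 + 1e-7).all()


class TestMsSSC:
    def test_single_scale_reduces_to_ssc(self, random_volume):
        cfg = DescriptorConfig(L=1, R1=3, K=1, alphas=(1.0,))
        lay = build_connection_layout(1, 1)
        np.testing.assert_allclose(
            msssc(random_volume, cfg).data,
            ssc_feature_map(random_volume, lay, 3).data,
            atol=1e-7,
        )

    def test_two_scale_weighted_sum(self, random_volume):
        cfg = DescriptorConfig(L=1, R1=3, K=2, alphas=(0.7, 0.3))
        combined = msssc(random_volume, cfg).data.astype(np.float64)
        s1 = ssc_feature_map(random_volume, build_connection_layout(1, 1), 3).data
        s2 = ssc_feature_map(random_volume, build_connection_layout(2, 1), 3).data
        np.testing.assert_allclose(
            combined, 0.7 * s1.astype(np.float64) + 0.3 * s2.astype(np.float64),
            atol=1e-6,
        )

    def test_matches_naive_oracle(self, random_volume):
        cfg = DescriptorConfig(L=1, R1=3, K=2, alphas=(0.7, 0.3))
        np.testing.assert_allclose(
            msssc(random_volume, cfg).data, naive_msssc(random_volume, cfg), atol=1e-6
        )

    def test_alphas_normalized(self):
        cfg = DescriptorConfig(K=2, alphas=(7, 3))
        assert cfg.alphas == (0.7, 0.3)


class TestBinAssignment:
    def test_2d_mode_sixteen_bins(self):
        ba = build_bin_assignment(5, Na=8, Nr=2, Nh=1, two_d=True)
        assert ba.n_bins == 16
        assert not ba.empty_bins

    def test_default_3d_partition(self):
        ba = build_bin_assignment(5, Na=8, Nr=2, Nh=2)
        assert ba.n_bins == 32
        assert ba.counts.sum() == ba.n_assigned
        # partition: every assigned offset in exactly one bin (exhaustive)
        seen = {}
        for n, offs in enumerate(ba.offsets_by_bin):
            for o in offs:
                assert o not in seen
                seen[o] = n
        assert seen == ba.bin_of_offset

    def test_kernels_average_to_one(self):
        ba = build_bin_assignment(5)
        k = ba.kernels()
        sums = k.reshape(ba.n_bins, -1).sum(axis=1)
        counts = ba.counts
        np.testing.assert_allclose(sums[counts > 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(sums[counts == 0], 0.0)

    def test_corners_outside_cylinder_unassigned(self):
        ba = build_bin_assignment(5)
        assert (2, 2, 0) not in ba.bin_of_offset  # xy radius 2.83 > 2.5
        assert (2, 0, 2) in ba.bin_of_offset

    def test_small_window_reports_empty_bins(self):
        ba = build_bin_assignment(3, Na=8, Nr=2, Nh=2)
        assert ba.empty_bins  # R2=3 cannot populate 32 bins


class TestAggregation:
    def test_uniform_map_is_fixed_point(self):
        vals = np.arange(1.0, 5.0)
        data = np.broadcast_to(vals, (7, 7, 7, 4)).copy()
        fm = FeatureMap(data=data)
        ba = build_bin_assignment(3, Na=4, Nr=1, Nh=1)
        out = aggregate_macmind(fm, ba)
        for n in range(ba.n_bins):
            if n in ba.empty_bins:
                continue
            np.testing.assert_allclose(
                out.data[..., n * 4 : (n + 1) * 4], data, atol=1e-6
            )

    def test_empty_bins_zero_filled(self):
        fm = FeatureMap(data=np.ones((7, 7, 7, 2)))
        ba = build_bin_assignment(3, Na=8, Nr=2, Nh=2)
        out = aggregate_macmind(fm, ba)
        for n in ba.empty_bins:
            np.testing.assert_array_equal(out.data[..., n * 2 : (n + 1) * 2], 0.0)

    def test_matches_naive_oracle(self, rng):
        mss = FeatureMap(data=rng.random((11, 11, 11, 3)).astype(np.float32))
        ba = build_bin_assignment(5)
        fast = aggregate_macmind(mss, ba)
        naive = naive_aggregate(mss.data, ba)
        np.testing.assert_allclose(fast.data, naive, atol=1e-6)


class TestMacmind:
    def test_channel_count_is_m_times_n(self, rng):
        v = Volume(rng.random((12, 12, 12)))
        cfg = DescriptorConfig(L=1, R1=3, R2=3, K=1, alphas=(1.0,), Na=4, Nr=1, Nh=2)
        out = macmind(v, cfg)
        assert out.n_channels == 18 * cfg.n_bins

    def test_default_config_gives_576_channels(self, rng):
        v = Volume(rng.random((16, 16, 16)))
        out = macmind(v)
        assert out.n_channels == 576

    def test_affine_intensity_invariance(self, rng):
        v = Volume(rng.random((12, 12, 12)))
        cfg = DescriptorConfig(L=1, R1=3, R2=3, K=2, alphas=(0.7, 0.3), Na=4, Nr=1, Nh=2)
        base = macmind(v, cfg)
        mapped = macmind(Volume(2.0 * v.data + 5.0), cfg)
        np.testing.assert_allclose(mapped.data, base.data, atol=1e-5)

    def test_integer_translation_equivariance(self, rng):
        """Shifting the image by an integer vector shifts the feature map on
        the interior (away from boundary padding effects)."""
        data = rng.random((14, 14, 14))
        shifted = np.roll(data, shift=(2, 0, 0), axis=(0, 1, 2))
        cfg = DescriptorConfig(L=1, R1=3, R2=3, K=1, alphas=(1.0,), Na=4, Nr=1, Nh=2)
        fa = macmind(Volume(data), cfg).data
        fb = macmind(Volume(shifted), cfg).data
        margin = 5
        np.testing.assert_allclose(
            fb[2 + margin : 14 - margin, margin:-margin, margin:-margin],
            fa[margin : 12 - margin, margin:-margin, margin:-margin],
            atol=1e-5,
        )

    def test_matches_end_to_end_naive_oracle(self, rng):
        v = Volume(rng.random((12, 12, 12)))
        cfg = DescriptorConfig(L=1, R1=3, R2=3, K=2, alphas=(0.7, 0.3), Na=4, Nr=1, Nh=2)
        np.testing.assert_allclose(
            macmind(v, cfg).data.astype(np.float64), naive_macmind(v, cfg), atol=1e-5
        )

    def test_determinism(self, rng):
        v = Volume(rng.random((12, 12, 12)))
        cfg = DescriptorConfig(L=1, R1=3, R2=3, K=1, alphas=(1.0,), Na=4, Nr=1, Nh=1)
        a = macmind(v, cfg)
        b = macmind(Volume(v.data.copy()), cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_footprint_error_names_minimum_size(self):
        with pytest.raises(ValueError, match="must be >= 9"):
            macmind(Volume(np.zeros((8, 8, 8))))

    def test_save_writes_nifti_and_sidecar(self, rng, tmp_path):
        v = Volume(rng.random((10, 10, 10)))
        cfg = DescriptorConfig(L=1, R1=3, R2=3, K=1, alphas=(1.0,), Na=4, Nr=1, Nh=1)
        fm = macmind(v, cfg)
        out = tmp_path / "feat.nii.gz"
        fm.save(out)
        assert out.exists()
        assert (tmp_path / "feat.channels.json").exists()


def test_config_yaml_round_trip(tmp_path):
    import yaml

    cfg = DescriptorConfig()
    p = tmp_path / "cfg.yaml"
    p.write_text(yaml.safe_dump({"descriptor": cfg.to_dict()}))
    assert DescriptorConfig.from_yaml(p) == cfg
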