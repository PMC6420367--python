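"""Voxel-level quantification: PVC, normalization, extraction, t-maps,
cluster thresholding."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tauroc as tr
from tauroc.volumes import VolumeGrid

from conftest import flood_fill_components


def _vol(arr, kind="activity"):
    return VolumeGrid(np.asarray(arr, dtype=float), kind=kind)


def _phantom_atlas(spec):
    ref = tuple(lab for lab, name in spec.label_map.items()
                if name in spec.reference_regions)
    meta = tuple(lab for lab in spec.label_map if lab not in ref)
    return tr.AtlasDefinition(spec.label_map, (), ref, meta)


class TestPVC:
    def test_exact_division_and_identity(self):
        pet = _vol(np.full((2, 2, 2), 0.5))
        half = _vol(np.full((2, 2, 2), 0.25), "fraction")
        out = tr.pvc_two_compartment(pet, half, half)
        assert np.allclose(out.values, 1.0)
        full = _vol(np.full((2, 2, 2), 1.0), "fraction")
        zero = _vol(np.zeros((2, 2, 2)), "fraction")
        ident = tr.pvc_two_compartment(pet, full, zero)
        assert np.array_equal(ident.values, pet.values)

    def test_low_tissue_voxels_invalidated_not_clamped(self):
        pet = _vol(np.ones((1, 1, 3)))
        gm = _vol(np.array([[[0.05, 0.2, 0.9]]]), "fraction")
        wm = _vol(np.zeros((1, 1, 3)), "fraction")
        out = tr.pvc_two_compartment(pet, gm, wm, min_tissue=0.2)
        assert np.isnan(out.values[0, 0, 0])
        assert np.allclose(out.values[0, 0, 1:], [5.0, 1 / 0.9])

    def test_error_conditions(self):
        pet = _vol(np.ones((1, 1, 2)))
        neg = VolumeGrid(np.full((1, 1, 2), 0.5), kind="activity")
        neg.values[0, 0, 0] = -0.1
        zero = _vol(np.zeros((1, 1, 2)), "fraction")
        with pytest.raises(ValueError, match="negative"):
            tr.pvc_two_compartment(pet, neg, zero)
        with pytest.raises(ValueError, match="every voxel"):
            tr.pvc_two_compartment(pet, zero, zero, min_tissue=0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.2, 1.0), st.floats(0.01, 5.0))
    def test_correction_never_decreases_signal(self, tissue, uptake):
        # dividing by a fraction <= 1 can only inflate the voxel value
        pet = _vol(np.full((1, 1, 1), uptake * tissue))
        gm = _vol(np.full((1, 1, 1), tissue), "fraction")
        wm = _vol(np.zeros((1, 1, 1)), "fraction")
        out = tr.pvc_two_compartment(pet, gm, wm)
        assert out.values[0, 0, 0] >= pet.values[0, 0, 0] - 1e-12

    def test_phantom_csf_correction_recovers_truth(self):
        # region with 40% CSF: corrected mean = truth, uncorrected = 0.6*truth
        spec = tr.PhantomSpec(
            grid_shape=(8, 8, 8),
            region_layout={"a": ((0, 4), (0, 8), (0, 8)),
                           "ref": ((4, 8), (0, 8), (0, 8))},
            true_uptake={"a": 2.0, "ref": 1.0},
            tissue_fractions={"a": (0.4, 0.2, 0.4), "ref": (1.0, 0.0, 0.0)},
            reference_regions=("ref",))
        pet, gm, wm, _csf, labels = tr.generate_phantom(spec)
        corrected = tr.pvc_two_compartment(pet, gm, wm)
        a = labels.values == [k for k, v in spec.label_map.items() if v == "a"][0]
        assert np.allclose(corrected.values[a], 2.0)
        assert np.allclose(pet.values[a], 0.6 * 2.0)


class TestNormalize:
    def test_scale_invariance_and_reference_median(self, noise_free_phantom):
        spec, (pet, gm, wm, _csf, labels) = noise_free_phantom
        atlas = _phantom_atlas(spec)
        suvr1 = tr.normalize_suvr(pet, labels, atlas)
        scaled = pet.with_values(pet.values * 7.3)
        suvr2 = tr.normalize_suvr(scaled, labels, atlas)
        assert np.allclose(suvr1.values, suvr2.values, equal_nan=True)
        ref_mask = np.isin(labels.values, atlas.reference_labels)
        assert np.isclose(np.median(suvr1.values[ref_mask]), 1.0)

    def test_median_arithmetic(self):
        pet = _vol(np.array([[[1.0, 2.0, 4.0, 4.0]]]))
        labels = VolumeGrid(np.array([[[1, 1, 1, 2]]]), kind="label")
        atlas = tr.AtlasDefinition({1: "ref", 2: "target"}, (), (1,))
        out = tr.normalize_suvr(pet, labels, atlas)
        assert np.isclose(out.values[0, 0, 3], 2.0)  # 4.0 / median{1,2,4}

    def test_empty_reference_fails(self):
        pet = _vol(np.ones((1, 1, 2)))
        labels = VolumeGrid(np.zeros((1, 1, 2), dtype=int), kind="label")
        atlas = tr.AtlasDefinition({1: "ref"}, (), (1,))
        with pytest.raises(ValueError, match="reference"):
            tr.normalize_suvr(pet, labels, atlas)


class TestExtractRegional:
    def test_median_and_missing_contract(self):
        pet = _vol(np.array([[[1.0, 1.1, 1.2, np.nan, np.nan, 2.0]]]), "suvr")
        labels = VolumeGrid(np.array([[[1, 1, 1, 2, 2, 3]]]), kind="label")
        atlas = tr.AtlasDefinition({1: "a", 2: "b", 3: "ref", 4: "ghost"}, (), (3,))
        with pytest.warns(UserWarning, match="ghost"):
            row = tr.extract_regional(pet, labels, atlas)
        assert row["a"] == pytest.approx(1.1)
        assert np.isnan(row["b"])      # all voxels invalid -> missing, not 0
        assert np.isnan(row["ghost"])  # label absent from volume -> missing

    def test_phantom_end_to_end_exact(self, noise_free_phantom):
        # zero noise: recovered SUVR equals true uptake ratio, exactly
        spec, (pet, gm, wm, _csf, labels) = noise_free_phantom
        atlas = _phantom_atlas(spec)
        row = tr.quantify_volume(pet, gm, wm, labels, atlas)
        for name, uptake in spec.true_uptake.items():
            truth = uptake / spec.true_uptake["reference"]
            assert row[name] == pytest.approx(truth, rel=1e-12)

    def test_no_pvc_equals_pvc_at_full_tissue(self):
        spec = tr.PhantomSpec(
            grid_shape=(6, 6, 6),
            region_layout={"a": ((0, 3), (0, 6), (0, 6)),
                           "ref": ((3, 6), (0, 6), (0, 6))},
            true_uptake={"a": 1.8, "ref": 1.0},
            tissue_fractions={"a": (0.7, 0.3, 0.0), "ref": (0.6, 0.4, 0.0)},
            reference_regions=("ref",))
        pet, gm, wm, _csf, labels = tr.generate_phantom(spec)
        atlas = _phantom_atlas(spec)
        with_pvc = tr.quantify_volume(pet, gm, wm, labels, atlas, pvc=True)
        without = tr.quantify_volume(pet, None, None, labels, atlas, pvc=False)
        pd.testing.assert_series_equal(with_pvc, without)


class TestMetaRoi:
    def test_constant_volume_and_single_region_consistency(self):
        pet = _vol(np.full((2, 2, 2), 1.36), "suvr")
        labels = VolumeGrid(np.array([[[1, 1], [2, 2]], [[2, 2], [3, 3]]]),
                            kind="label")
        atlas = tr.AtlasDefinition({1: "a", 2: "b", 3: "ref"}, (), (3,), (1, 2))
        assert tr.global_meta_roi_suvr(pet, labels, atlas) == pytest.approx(1.36)
        one = tr.AtlasDefinition({1: "a", 2: "b", 3: "ref"}, (), (3,), (1,))
        row = tr.extract_regional(pet, labels, one)
        assert tr.global_meta_roi_suvr(pet, labels, one) == row["a"]

    def test_pooled_median_not_mean_of_regions(self):
        # two equal-size constant regions a=1, b=3 plus one extra b voxel:
        # pooled median is 3, whereas a mean of regional medians would be 2
        vals = np.array([[[1.0, 1.0, 3.0, 3.0, 3.0]]])
        pet = _vol(vals, "suvr")
        labels = VolumeGrid(np.array([[[1, 1, 2, 2, 2]]]), kind="label")
        atlas = tr.AtlasDefinition({1: "a", 2: "b"}, (), (1,), (1, 2))
        assert tr.global_meta_roi_suvr(pet, labels, atlas) == pytest.approx(3.0)


class TestVoxelwiseTTest:
    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        a = [_vol(rng.normal(size=(3, 3, 3))) for _ in range(4)]
        b = [_vol(rng.normal(0.5, size=(3, 3, 3))) for _ in range(5)]
        t_map, p_map = tr.voxelwise_ttest(a, b)
        ref = stats.ttest_ind(np.stack([v.values for v in a]),
                              np.stack([v.values for v in b]), axis=0,
                              equal_var=True)
        assert np.allclose(t_map.values, ref.statistic)
        assert np.allclose(p_map.values, ref.pvalue)

    def test_hand_computed_3v3(self):
        # pooled t for {1,2,3} vs {2,4,6}: t = -2 / sqrt(2.5 * 2/3)
        a = [_vol(np.full((1, 1, 1), v)) for v in (1.0, 2.0, 3.0)]
        b = [_vol(np.full((1, 1, 1), v)) for v in (2.0, 4.0, 6.0)]
        t_map, p_map = tr.voxelwise_ttest(a, b)
        assert t_map.values[0, 0, 0] == pytest.approx(-2 / np.sqrt(2.5 * 2 / 3))
        assert 0 < p_map.values[0, 0, 0] < 1

    def test_identical_means_and_zero_variance(self):
        a = [_vol(np.ones((2, 2, 2))), _vol(np.ones((2, 2, 2)))]
        t_map, p_map = tr.voxelwise_ttest(a, [v.with_values(v.values.copy()) for v in a])
        assert np.allclose(t_map.values, 0.0)
        assert np.allclose(p_map.values, 1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = [_vol(rng.normal(size=(4, 4, 4))) for _ in range(3)]
        b = [_vol(rng.normal(size=(4, 4, 4))) for _ in range(3)]
        t_ab, p_ab = tr.voxelwise_ttest(a, b)
        t_ba, p_ba = tr.voxelwise_ttest(b, a)
        assert np.allclose(t_ab.values, -t_ba.values)
        assert np.allclose(p_ab.values, p_ba.values)

    def test_invalid_voxels_propagate(self):
        a = [_vol(np.ones((1, 1, 2))) for _ in range(2)]
        a[0].values[0, 0, 0] = np.nan
        b = [_vol(np.full((1, 1, 2), 2.0)) for _ in range(2)]
        t_map, p_map = tr.voxelwise_ttest(a, b)
        assert np.isnan(t_map.values[0, 0, 0]) and np.isnan(p_map.values[0, 0, 0])
        assert np.isfinite(t_map.values[0, 0, 1])


class TestClusterThreshold:
    def _planted(self, sizes, shape=(16, 16, 16)):
        p = np.ones(shape)
        x = 0
        for s in sizes:  # disjoint straight rods, clearly separated
            p[x, 0, :s] = 1e-6
            x += 2
        return _vol(p, "stat"), _vol(np.where(p < 0.5, 5.0, 0.0), "stat")

    def test_strict_extent_boundary(self):
        p25, t25 = self._planted([25], shape=(16, 16, 26))
        assert len(tr.cluster_threshold(p25, t25, extent=25).clusters) == 0
        p26, t26 = self._planted([26], shape=(16, 16, 27))
        res = tr.cluster_threshold(p26, t26, extent=25)
        assert list(res.clusters["n_voxels"]) == [26]

    def test_planted_components_against_flood_fill(self):
        p, t = self._planted([10, 26, 40], shape=(16, 16, 41))
        res = tr.cluster_threshold(p, t, extent=25)
        assert list(res.clusters["n_voxels"]) == [40, 26]
        oracle = flood_fill_components(p.values < 0.001)
        assert oracle == [40, 26, 10]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_fixture_matches_flood_fill(self, connectivity):
        rng = np.random.default_rng(12)
        mask = rng.random((12, 12, 12)) < 0.25
        p = _vol(np.where(mask, 1e-5, 0.9), "stat")
        t = _vol(np.where(mask, 4.0, 0.0), "stat")
        res = tr.cluster_threshold(p, t, extent=0, connectivity=connectivity)
        sizes = sorted(res.clusters["n_voxels"], reverse=True)
        assert sizes == flood_fill_components(mask, connectivity)

    def test_diagonal_neighbors_by_connectivity(self):
        # edge-diagonal joins under 18 but not 6; corner joins only under 26
        p = np.ones((3, 3, 3))
        p[0, 0, 0] = p[0, 1, 1] = 1e-6  # edge diagonal
        vol = _vol(p, "stat")
        t = _vol(np.zeros((3, 3, 3)), "stat")
        assert len(tr.cluster_threshold(vol, t, extent=0, connectivity=6).clusters) == 2
        assert len(tr.cluster_threshold(vol, t, extent=0, connectivity=18).clusters) == 1

    def test_phantom_signal_confined_to_target(self):
        # two phantom groups differing only in one region
        from dataclasses import replace
        spec = tr.default_phantom_spec(noise_sd=0.02)
        boosted = dict(spec.true_uptake)
        boosted["target_3"] += 0.5
        spec_b = replace(spec, true_uptake=boosted)
        a = [tr.generate_phantom(spec, seed=i)[0] for i in range(4)]
        b = [tr.generate_phantom(spec_b, seed=100 + i)[0] for i in range(4)]
        t_map, p_map = tr.voxelwise_ttest(b, a)
        res = tr.cluster_threshold(p_map, t_map, p_thresh=0.001, extent=25)
        assert len(res.clusters) >= 1
        lab = tr.generate_phantom(spec, seed=0)[4]
        target = [k for k, v in spec.label_map.items() if v == "target_3"][0]
        in_cluster = res.cluster_mask.values > 0
        assert (lab.values[in_cluster] == target).mean() > 0.95
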