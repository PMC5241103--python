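import numpy as np
import pytest

from smrirt import (Mask, ScalarMap, VolumeGrid, fold_cho_naa, normalize_fold,
                    ratio_map, resample_trilinear, segment_nawm,
                    threshold_segmentation)


def _const(grid, value, valid=None):
    return ScalarMap(grid, np.full(grid.shape, float(value)), valid=valid)


class TestRatioMap:
    def test_elementwise_quotient(self, unit_grid):
        rng = np.random.default_rng(0)
        cho = ScalarMap(unit_grid, rng.uniform(0.5, 3.0, unit_grid.shape))
        naa = ScalarMap(unit_grid, rng.uniform(0.5, 3.0, unit_grid.shape))
        r = ratio_map(cho, naa)
        assert np.abs(r.values - cho.values / naa.values).max() < 1e-12

    def test_zero_naa_voxel_flagged_invalid(self, unit_grid):
        cho = _const(unit_grid, 2.0)
        naa_vals = np.ones(unit_grid.shape)
        naa_vals[3, 3, 3] = 0.0
        r = ratio_map(cho, ScalarMap(unit_grid, naa_vals))
        assert not r.valid[3, 3, 3]
        assert r.values[0, 0, 0] == 2.0

    def test_grid_mismatch_rejected(self, unit_grid, smri_grid):
        with pytest.raises(ValueError, match="same grid"):
            ratio_map(_const(unit_grid, 1.0), _const(smri_grid, 1.0))


def _hemis(grid, split=5):
    h = np.zeros(grid.shape, dtype=np.int8)
    h[:split] = 1
    h[split:] = 2
    return h


class TestSegmentNawm:
    def test_pure_contralateral_wm(self, unit_grid):
        wm_vals = np.zeros(unit_grid.shape)
        wm_vals[:5] = 1.0  # left hemisphere all WM
        wm = ScalarMap(unit_grid, wm_vals)
        nawm = segment_nawm(wm, _hemis(unit_grid), tumor_side=2,
                            min_volume_cm3=0.1)
        assert np.array_equal(nawm.data, _hemis(unit_grid) == 1)

    def test_exclusion_covering_contralateral_side_errors(self, unit_grid):
        wm = _const(unit_grid, 1.0)
        ex = Mask(unit_grid, np.ones(unit_grid.shape, bool), "GTV1")
        with pytest.raises(ValueError, match="refusing to normalize"):
            segment_nawm(wm, _hemis(unit_grid), 2, [ex], min_volume_cm3=0.1)

    def test_exclusion_dilated_by_safety_margin(self):
        g = VolumeGrid((40, 20, 20), (1.0, 1.0, 1.0))
        wm = _const(g, 1.0)
        ex_arr = np.zeros(g.shape, bool)
        ex_arr[10, 10, 10] = True
        nawm = segment_nawm(wm, _hemis(g, 20), tumor_side=2,
                            exclusions=[Mask(g, ex_arr, "gtv")],
                            exclusion_margin_mm=5.0, min_volume_cm3=0.1)
        assert not nawm.data[10, 10, 10]
        assert not nawm.data[14, 10, 10]  # 4 mm away, inside the 5 mm margin
        assert nawm.data[16, 10, 10]      # 6 mm away, outside it

    def test_phantom_nawm_mean_recovers_baseline(self, noiseless_truth):
        t = noiseless_truth
        nawm = segment_nawm(t.wm_prob, t.hemispheres, t.tumor_side, [t.gtv1])
        ratio = resample_trilinear(ratio_map(t.cho, t.naa), t.brain.grid)
        ok = nawm.data & ratio.valid
        mean = ratio.values[ok].mean()
        assert mean == pytest.approx(t.params.baseline, rel=0.01)


class TestNormalizeFold:
    def test_constant_map_becomes_unity(self, unit_grid):
        nawm = Mask(unit_grid, np.ones(unit_grid.shape, bool), "NAWM")
        fold = normalize_fold(_const(unit_grid, 2.0), nawm)
        assert np.allclose(fold.values, 1.0)
        assert fold.reference_mean == pytest.approx(2.0)

    def test_two_level_map(self, unit_grid):
        vals = np.ones(unit_grid.shape)
        vals[:5] = 3.0  # half of NAWM at 3x, half at 1x -> mean 2
        nawm = Mask(unit_grid, np.ones(unit_grid.shape, bool), "NAWM")
        fold = normalize_fold(ScalarMap(unit_grid, vals), nawm)
        assert np.allclose(fold.values[:5], 1.5)
        assert np.allclose(fold.values[5:], 0.5)

    def test_nawm_mean_is_unity_by_construction(self, unit_grid):
        rng = np.random.default_rng(4)
        nawm = Mask(unit_grid, rng.random(unit_grid.shape) < 0.5, "NAWM")
        m = ScalarMap(unit_grid, rng.uniform(0.2, 4.0, unit_grid.shape))
        fold = normalize_fold(m, nawm)
        assert fold.values[nawm.data].mean() == pytest.approx(1.0, abs=1e-6)

    def test_idempotence(self, unit_grid):
        rng = np.random.default_rng(5)
        nawm = Mask(unit_grid, rng.random(unit_grid.shape) < 0.5, "NAWM")
        m = ScalarMap(unit_grid, rng.uniform(0.2, 4.0, unit_grid.shape))
        once = normalize_fold(m, nawm)
        twice = normalize_fold(once, nawm)
        assert np.abs(twice.values - once.values).max() < 1e-12

    @pytest.mark.parametrize("c", [0.1, 1.0, 10.0])
    def test_scale_invariance(self, unit_grid, c):
        rng = np.random.default_rng(6)
        nawm = Mask(unit_grid, rng.random(unit_grid.shape) < 0.5, "NAWM")
        vals = rng.uniform(0.2, 4.0, unit_grid.shape)
        f1 = normalize_fold(ScalarMap(unit_grid, vals), nawm)
        f2 = normalize_fold(ScalarMap(unit_grid, c * vals), nawm)
        assert np.abs(f1.values - f2.values).max() < 1e-12

    def test_guards(self, unit_grid):
        nawm = Mask(unit_grid, np.ones(unit_grid.shape, bool), "NAWM")
        with pytest.raises(ValueError, match="non-positive"):
            normalize_fold(_const(unit_grid, -1.0), nawm)
        mostly_invalid = _const(unit_grid, 1.0,
                                valid=np.zeros(unit_grid.shape, bool))
        with pytest.raises(ValueError, match="valid on only"):
            normalize_fold(mostly_invalid, nawm)

    def test_separate_vs_ratio_first_modes_differ(self, unit_grid):
        rng = np.random.default_rng(7)
        cho = ScalarMap(unit_grid, rng.uniform(0.5, 2.0, unit_grid.shape))
        naa = ScalarMap(unit_grid, rng.uniform(0.5, 2.0, unit_grid.shape))
        nawm = Mask(unit_grid, np.ones(unit_grid.shape, bool), "NAWM")
        a = fold_cho_naa(cho, naa, nawm, mode="ratio-first")
        b = fold_cho_naa(cho, naa, nawm, mode="separate")
        # mean-of-quotient != quotient-of-means on random data
        assert not np.allclose(a.values, b.values)
        assert a.values[nawm.data].mean() == pytest.approx(1.0, abs=1e-6)


class TestThresholdSegmentation:
    def test_closed_boundary_rule(self):
        g = VolumeGrid((3, 1, 1), (1.0, 1.0, 1.0))
        vals = np.array([1.4, 1.5, 1.6]).reshape(3, 1, 1)
        from smrirt.metabolite import FoldMap
        fold = FoldMap(ScalarMap(g, vals, "fold-normal"), 1.0)
        brain = Mask(g, np.ones(g.shape, bool), "brain")
        seg = threshold_segmentation(fold, 1.5, brain)
        assert seg.data.ravel().tolist() == [False, True, True]

    def test_level_below_min_gives_brain_and_valid(self, unit_grid):
        from smrirt.metabolite import FoldMap
        rng = np.random.default_rng(8)
        valid = rng.random(unit_grid.shape) < 0.9
        fold = FoldMap(ScalarMap(unit_grid, np.full(unit_grid.shape, 2.0),
                                 "fold-normal", valid), 1.0)
        brain = Mask(unit_grid, rng.random(unit_grid.shape) < 0.8, "brain")
        seg = threshold_segmentation(fold, 0.01, brain)
        assert np.array_equal(seg.data, brain.data & valid)

    def test_monotone_nesting(self, noiseless_truth):
        t = noiseless_truth
        nawm = segment_nawm(t.wm_prob, t.hemispheres, t.tumor_side, [t.gtv1])
        fold = normalize_fold(resample_trilinear(ratio_map(t.cho, t.naa),
                                                 t.brain.grid), nawm)
        segs = [threshold_segmentation(fold, L, t.brain) for L in (1.5, 1.75, 2.0)]
        assert segs[2].issubset(segs[1])
        assert segs[1].issubset(segs[0])

    def test_component_filter_keeps_only_touching(self):
        g = VolumeGrid((20, 5, 5), (1.0, 1.0, 1.0))
        from smrirt.metabolite import FoldMap
        vals = np.zeros(g.shape)
        vals[2:5] = 2.0    # blob touching the anchor
        vals[12:15] = 2.0  # disjoint blob
        fold = FoldMap(ScalarMap(g, vals, "fold-normal"), 1.0)
        brain = Mask(g, np.ones(g.shape, bool), "brain")
        anchor = Mask(g, np.zeros(g.shape, bool), "GTV2")
        anchor.data[3] = True
        seg = threshold_segmentation(fold, 1.5, brain, keep_touching=anchor)
        assert seg.data[2:5].all()
        assert not seg.data[12:15].any()
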