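import numpy as np
import pytest

from smrirt import (Mask, PlanConfig, ScalarMap, VolumeGrid, build_conventional,
                    build_smri, coverage_percent, dice, evaluate_plan,
                    generate_dose, isodose_mask, max_dose_in, percent_increase,
                    recurrence_coverage, volume_cm3, volume_outside)

from conftest import random_grid, random_mask


# independent set-of-voxel-index oracles
def _vox(m):
    return {tuple(ijk) for ijk in np.argwhere(m.data)}


class TestDice:
    def test_identity_disjoint_and_half(self, unit_grid):
        a = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        a.data[0, 0, 0] = a.data[0, 0, 1] = True
        b = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        b.data[0, 0, 1] = b.data[0, 0, 2] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == pytest.approx(0.5)  # |a|=|b|=2, overlap 1
        c = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        c.data[5, 5, 5] = True
        assert dice(a, c) == 0.0

    def test_both_empty_convention(self, unit_grid):
        e = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        assert dice(e, e) == 1.0

    def test_symmetry_random(self, unit_grid):
        rng = np.random.default_rng(0)
        a, b = random_mask(unit_grid, rng), random_mask(unit_grid, rng)
        assert dice(a, b) == dice(b, a)


class TestVolumes:
    def test_volume_examples(self, unit_grid, smri_grid):
        m = Mask(unit_grid, np.ones(unit_grid.shape, bool))
        assert volume_cm3(m) == pytest.approx(1.0)
        e = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        assert volume_cm3(e) == 0.0
        seven = Mask(smri_grid, np.zeros(smri_grid.shape, bool))
        seven.data.ravel()[:7] = True
        assert volume_cm3(seven) == pytest.approx(7 * 0.108416, rel=1e-9)

    def test_percent_increase(self, unit_grid):
        base = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        base.data[:5] = True
        assert percent_increase(base, base) == 0.0
        double = Mask(unit_grid, np.ones(unit_grid.shape, bool))
        assert percent_increase(base, double) == pytest.approx(100.0)
        with pytest.raises(ValueError, match="empty base"):
            percent_increase(Mask(unit_grid, np.zeros(unit_grid.shape, bool)), base)

    def test_percent_increase_formula(self, unit_grid):
        # 40 cm3 -> 69.64 cm3 is a 74.1% increase
        assert 100 * (69.64 - 40.0) / 40.0 == pytest.approx(74.1)


class TestIsodoseAndCoverage:
    def test_isodose_boundary_closed(self, unit_grid):
        d = ScalarMap(unit_grid, np.full(unit_grid.shape, 60.0), "Gy")
        assert isodose_mask(d, 60.0).count == 1000
        assert isodose_mask(d, 60.001).count == 0

    def test_coverage_examples(self, unit_grid):
        rng = np.random.default_rng(1)
        vals = np.zeros(unit_grid.shape)
        target = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        target.data.ravel()[:100] = True
        vals.ravel()[:82] = 60.0  # exactly 82 of 100 target voxels at level
        dose = ScalarMap(unit_grid, vals, "Gy")
        assert coverage_percent(target, dose, 60.0) == pytest.approx(82.0)
        assert coverage_percent(target, dose, 0.0) == 100.0
        with pytest.raises(ValueError, match="empty target"):
            coverage_percent(Mask(unit_grid, np.zeros(unit_grid.shape, bool)),
                             dose, 60.0)

    def test_coverage_monotone_in_level(self, unit_grid):
        rng = np.random.default_rng(2)
        dose = ScalarMap(unit_grid, rng.uniform(0, 70, unit_grid.shape), "Gy")
        target = random_mask(unit_grid, rng, p=0.5)
        covs = [coverage_percent(target, dose, lv) for lv in (10, 30, 50, 60)]
        assert covs == sorted(covs, reverse=True)


class TestVolumeOutside:
    def test_examples(self, unit_grid):
        seg = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        seg.data.ravel()[:100] = True
        inside = Mask(unit_grid, np.ones(unit_grid.shape, bool))
        assert volume_outside(seg, inside) == (0.0, 0.0)
        none = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        cm3, pct = volume_outside(seg, none)
        assert cm3 == pytest.approx(volume_cm3(seg))
        assert pct == 100.0
        region = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        region.data.ravel()[:60] = True  # 40 of 100 seg voxels escape
        cm3, pct = volume_outside(seg, region)
        assert pct == pytest.approx(40.0)
        assert cm3 == pytest.approx(0.04)

    def test_empty_seg_warns(self, unit_grid):
        e = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        with pytest.warns(UserWarning):
            assert volume_outside(e, e) == (0.0, 0.0)

    def test_additivity_exact(self, unit_grid):
        rng = np.random.default_rng(3)
        seg = random_mask(unit_grid, rng)
        region = random_mask(unit_grid, rng)
        cm3, _ = volume_outside(seg, region)
        inter = seg.intersection(region)
        assert cm3 + inter.volume_cm3 == pytest.approx(seg.volume_cm3, abs=1e-12)


class TestMaxDose:
    def test_examples(self, unit_grid):
        organ = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        organ.data[:2] = True
        vals = np.full(unit_grid.shape, 53.9)
        assert max_dose_in(organ, ScalarMap(unit_grid, vals, "Gy")) == 53.9
        vals[1, 1, 1] = 59.9
        assert max_dose_in(organ, ScalarMap(unit_grid, vals, "Gy")) == 59.9
        with pytest.raises(ValueError, match="empty organ"):
            max_dose_in(Mask(unit_grid, np.zeros(unit_grid.shape, bool)),
                        ScalarMap(unit_grid, vals, "Gy"))

    def test_organ_outside_penumbra_nearly_unirradiated(self):
        g = VolumeGrid((60, 20, 20), (1.0, 1.0, 1.0))
        target = Mask(g, np.zeros(g.shape, bool))
        target.data[:6] = True
        dose = generate_dose([(target, 60.0)], g, penumbra_mm=5.0)
        organ = Mask(g, np.zeros(g.shape, bool))
        organ.data[50:] = True  # >= 44 mm from the target
        assert max_dose_in(organ, dose) < 0.01 * 60.0


class TestRecurrenceCoverage:
    def test_examples(self, unit_grid):
        rec = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        rec.data.ravel()[:10] = True
        everything = Mask(unit_grid, np.ones(unit_grid.shape, bool))
        assert recurrence_coverage(rec, everything) == 100.0
        half = Mask(unit_grid, np.zeros(unit_grid.shape, bool))
        half.data.ravel()[:5] = True
        assert recurrence_coverage(rec, half) == pytest.approx(50.0)

    def test_monotone_under_union(self, unit_grid):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rec = random_mask(unit_grid, rng, p=0.2)
            if rec.is_empty:
                continue
            ctv = random_mask(unit_grid, rng, p=0.3)
            bigger = ctv.union(random_mask(unit_grid, rng, p=0.3))
            assert recurrence_coverage(rec, bigger) >= recurrence_coverage(rec, ctv)


class TestEvaluatePlan:
    def _setup(self):
        g = VolumeGrid((48, 48, 48), (1.5, 1.5, 1.5))
        brain = Mask(g, np.ones(g.shape, bool), "brain")
        gtv = Mask(g, np.zeros(g.shape, bool), "GTV")
        gtv.data[20:28, 20:28, 20:28] = True
        cfg = PlanConfig()
        pv = build_conventional(gtv, gtv, brain, cfg)
        dose = generate_dose([(pv["PTV1"], cfg.rx_ptv1_gy),
                              (pv["PTV2"], cfg.rx_ptv2_gy)], g)
        return g, pv, dose, cfg

    def test_conformal_plan_meets_goals(self):
        g, pv, dose, cfg = self._setup()
        rec = evaluate_plan(pv, dose, cfg=cfg)
        assert rec.coverage_ptv1_pct >= 95.0
        assert rec.coverage_ptv2_pct >= 95.0
        assert rec.violations == []

    def test_halved_dose_flags_violation(self):
        g, pv, dose, cfg = self._setup()
        weak = ScalarMap(g, 0.5 * dose.values, "Gy")
        rec = evaluate_plan(pv, weak, cfg=cfg)
        assert rec.coverage_ptv2_pct == 0.0
        assert any("coverage" in v for v in rec.violations)

    def test_organ_overlapping_boost_hits_hard_limit_boundary(self):
        g, pv, dose, cfg = self._setup()
        organ = Mask(g, pv["PTV2"].data.copy(), "brainstem")
        rec = evaluate_plan(pv, dose, organs={"brainstem": organ}, cfg=cfg)
        assert rec.brainstem_max_gy == pytest.approx(60.0)
        # at exactly 60 Gy the hard limit is not exceeded, but the soft
        # 54 Gy budget is blown
        assert any("54" in v for v in rec.violations)

    def test_smri_record_fields_populated(self):
        g, pv, dose, cfg = self._setup()
        seg = Mask(g, np.zeros(g.shape, bool), "seg")
        seg.data[5:15, 5:15, 5:15] = True
        out = build_smri(pv, seg, cfg)
        rec_mask = Mask(g, np.zeros(g.shape, bool), "rec")
        rec_mask.data[22:26, 22:26, 22:26] = True
        row = evaluate_plan(out, dose, rec=rec_mask, cfg=cfg, threshold=1.5)
        assert row.vol_smri_ctv2_cm3 > row.vol_ctv2_cm3
        assert 0.0 <= row.dice_ctv2 <= 1.0
        assert row.seg_outside_idl2_pct > 0
        assert row.recurrence_cov_ctv_pct == 100.0


class TestOracleEquivalence:
    """Spot equivalence with voxel-set enumeration oracles (the full
    1000-trial sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(10))
    def test_set_metrics_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = random_grid(rng)
        a, b = random_mask(g, rng), random_mask(g, rng)
        va, vb = _vox(a), _vox(b)
        if va or vb:
            assert dice(a, b) == pytest.approx(
                2 * len(va & vb) / (len(va) + len(vb)), abs=1e-12)
        if va:
            cm3, pct = volume_outside(a, b)
            assert pct == pytest.approx(100 * len(va - vb) / len(va), abs=1e-12)
            assert cm3 == pytest.approx(len(va - vb) * g.voxel_volume_cm3, abs=1e-12)
        dose = ScalarMap(g, rng.uniform(0, 70, g.shape), "Gy")
        if va:
            level = float(rng.uniform(0, 70))
            covered = sum(1 for v in va if dose.values[v] >= level)
            assert coverage_percent(a, dose, level) == pytest.approx(
                100 * covered / len(va), abs=1e-12)
            assert max_dose_in(a, dose) == max(dose.values[v] for v in va)
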