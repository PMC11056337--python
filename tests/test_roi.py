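"""roi module: regional statistics, bilateral averaging, rates, aggregation."""

import numpy as np
import pandas as pd
import pytest

import zsmap as z
from zsmap.roi import (AtrophyCorrectionRecord, MissingRegionWarning, ROIAtlas,
                       RegionStats, aggregate_dementia_regions, atrophy_correction_rate,
                       bilateral_average, regional_stats, select_pathological)
from zsmap.volume import ImageVolume
from zsmap.zscore import ZScoreMap

from conftest import make_grid


def _two_region_atlas(grid):
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[:3] = 1   # left block
    labels[5:] = 2   # right block
    regions = pd.DataFrame([
        {"label": 1, "name": "block", "hemisphere": "L", "partner_label": 2,
         "dementia_related": False},
        {"label": 2, "name": "block", "hemisphere": "R", "partner_label": 1,
         "dementia_related": False},
    ])
    return ROIAtlas(labels=ImageVolume(grid, labels, "label"), regions=regions)


def _zmap_from(grid, zvals, domain=None):
    if domain is None:
        domain = np.ones(grid.shape, dtype=bool)
    return ZScoreMap(z=ImageVolume(grid, np.where(domain, zvals, np.nan), "zmap"),
                     analysis_mask=ImageVolume(grid, domain.astype(float), "probability"),
                     masked_variant=False, db_n=5)


class TestRegionalStats:
    def test_constant_region(self):
        grid = make_grid((8, 2, 2))
        zmap = _zmap_from(grid, np.full(grid.shape, 1.5))
        stats = regional_stats(zmap, _two_region_atlas(grid), z_extent=2.0)
        assert all(s.mean_z == pytest.approx(1.5) for s in stats)
        assert all(s.extent_pct == 0.0 for s in stats)

    def test_half_high_half_zero(self):
        grid = make_grid((8, 2, 2))
        zvals = np.zeros(grid.shape)
        # label-1 block has 3*2*2 = 12 voxels; put exactly 6 of them at 3.0
        zvals[0, :, :] = 3.0
        zvals[1, 0, :] = 3.0
        zmap = _zmap_from(grid, zvals)
        stats = regional_stats(zmap, _two_region_atlas(grid), z_extent=2.0)
        left = next(s for s in stats if s.side == "L")
        assert left.mean_z == pytest.approx(1.5)
        assert left.extent_pct == pytest.approx(50.0)

    def test_brute_force_recount(self):
        rng = np.random.default_rng(19)
        grid = make_grid((8, 2, 2))
        zvals = rng.normal(size=grid.shape)
        atlas = _two_region_atlas(grid)
        zmap = _zmap_from(grid, zvals)
        stats = {s.side: s for s in regional_stats(zmap, atlas, z_extent=1.0)}
        labels = np.asarray(atlas.labels.values)
        for side, label in (("L", 1), ("R", 2)):
            voxels = zvals[labels == label]
            assert stats[side].mean_z == pytest.approx(voxels.mean())
            assert stats[side].extent_pct == pytest.approx(
                100.0 * (voxels >= 1.0).sum() / voxels.size)
            assert stats[side].n_voxels == voxels.size

    def test_empty_region_omitted_with_warning(self):
        grid = make_grid((8, 2, 2))
        domain = np.zeros(grid.shape, dtype=bool)
        domain[:3] = True  # only label 1 intersects
        zmap = _zmap_from(grid, np.zeros(grid.shape), domain)
        with pytest.warns(MissingRegionWarning):
            stats = regional_stats(zmap, _two_region_atlas(grid))
        assert [s.side for s in stats] == ["L"]


class TestBilateralAverage:
    def _stat(self, region, side, mean_z, extent=0.0):
        return RegionStats(region=region, side=side, mean_z=mean_z,
                           extent_pct=extent, n_voxels=10)

    def test_pair_collapses_to_mean(self):
        out = bilateral_average([self._stat("a", "L", 1.0, 20.0),
                                 self._stat("a", "R", 2.0, 40.0)])
        assert len(out) == 1
        assert out[0].side == "bilateral"
        assert out[0].mean_z == pytest.approx(1.5)
        assert out[0].extent_pct == pytest.approx(30.0)
        assert out[0].n_voxels == 20

    def test_midline_passthrough(self):
        out = bilateral_average([self._stat("mid", "midline", 0.7)])
        assert out[0].side == "midline" and out[0].mean_z == 0.7

    def test_single_side_warns(self):
        with pytest.warns(MissingRegionWarning):
            out = bilateral_average([self._stat("a", "L", 1.0)])
        assert out[0].side == "L"

    def test_symmetric_phantom_sides_agree(self, clean_cohort_study):
        cohort = clean_cohort_study["cohort"]
        atlas = cohort.atlas
        labels = np.asarray(atlas.labels.values)
        for name in ("precuneus", "angular"):
            left, right = atlas.labels_for_name(name)
            assert abs((labels == left).sum() - (labels == right).sum()) <= \
                0.02 * (labels == left).sum()


class TestSelectPathological:
    def _sides(self, left, right):
        return [RegionStats("r", "L", left, 0.0, 5),
                RegionStats("r", "R", right, 0.0, 5)]

    def test_either_side_rule(self):
        assert len(select_pathological(self._sides(0.4, 0.6))) == 2

    def test_strict_inequality(self):
        assert select_pathological(self._sides(0.5, 0.5)) == []

    def test_all_zero_empty(self):
        assert select_pathological(self._sides(0.0, 0.0)) == []


class TestRate:
    def test_scale_invariance(self):
        base = atrophy_correction_rate(1.2, 0.8)
        for k in (0.5, 2.0, 7.3):
            assert atrophy_correction_rate(1.2 * k, 0.8 * k) == pytest.approx(base)

    def test_record_sign_semantics(self):
        over = AtrophyCorrectionRecord.from_pair("r", 1.0, 0.8)
        assert over.overestimated and over.rate_pct == pytest.approx(20.0)
        under = AtrophyCorrectionRecord.from_pair("r", 1.0, 1.2)
        assert under.underestimated and under.rate_pct == pytest.approx(-20.0)


class TestAggregation:
    def test_ad_unmasked_average(self):
        means = (1.73, 1.98, 1.57, 1.56, 1.59)
        df = pd.DataFrame([
            {"region": r, "group": "ad", "z_unmasked": m, "z_masked": 1.0,
             "rate_pct": 10.0}
            for r, m in zip(z.DEMENTIA_REGIONS, means)
        ])
        summary = aggregate_dementia_regions(df)
        assert summary.average_of_5.loc["ad", "z_unmasked"] == pytest.approx(1.69, abs=0.005)

    def test_superior_parietal_rate_summary(self):
        rows = []
        rates = {"normal": 12.6, "mci": 12.5, "ad": 14.6}
        for r in z.DEMENTIA_REGIONS:
            for g, rate in rates.items():
                rows.append({"region": r, "group": g, "z_unmasked": 1.0,
                             "z_masked": 0.9, "rate_pct": rate})
        summary = aggregate_dementia_regions(pd.DataFrame(rows))
        sp = summary.region_rates.loc["superior_parietal"]
        assert sp["rate_mean"] == pytest.approx(13.2, abs=0.05)
        assert sp["rate_sd"] == pytest.approx(1.2, abs=0.05)

    def test_equal_inputs_zero_sd(self):
        rows = [{"region": r, "group": g, "z_unmasked": 1.3, "z_masked": 1.1,
                 "rate_pct": 8.0}
                for r in z.DEMENTIA_REGIONS for g in ("a", "b", "c")]
        summary = aggregate_dementia_regions(pd.DataFrame(rows))
        assert np.allclose(summary.region_rates["rate_sd"], 0.0)
        assert summary.overall_rate_mean == pytest.approx(8.0)

    def test_missing_cell_rejected(self):
        rows = [{"region": "precuneus", "group": "ad", "z_unmasked": 1.0,
                 "z_masked": 0.9, "rate_pct": 10.0},
                {"region": "angular", "group": "mci", "z_unmasked": 1.0,
                 "z_masked": 0.9, "rate_pct": 10.0}]
        with pytest.raises(ValueError):
            aggregate_dementia_regions(pd.DataFrame(rows))


class TestAtlasValidation:
    def test_unknown_label_rejected(self):
        grid = make_grid((4, 4, 4))
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[0] = 9
        regions = pd.DataFrame([{"label": 1, "name": "a", "hemisphere": "midline",
                                 "partner_label": pd.NA, "dementia_related": False}])
        with pytest.raises(ValueError):
            ROIAtlas(labels=ImageVolume(grid, labels, "label"), regions=regions)

    def test_asymmetric_pairing_rejected(self):
        grid = make_grid((4, 4, 4))
        labels = np.zeros(grid.shape, dtype=np.int32)
        regions = pd.DataFrame([
            {"label": 1, "name": "a", "hemisphere": "L", "partner_label": 2,
             "dementia_related": False},
            {"label": 2, "name": "a", "hemisphere": "R", "partner_label": 3,
             "dementia_related": False},
            {"label": 3, "name": "b", "hemisphere": "midline", "partner_label": pd.NA,
             "dementia_related": False},
        ])
        with pytest.raises(ValueError):
            ROIAtlas(labels=ImageVolume(grid, labels, "label"), regions=regions)

    def test_save_load_roundtrip(self, tmp_path):
        grid = make_grid((8, 2, 2))
        atlas = _two_region_atlas(grid)
        atlas.save(tmp_path / "atlas")
        back = ROIAtlas.load(tmp_path / "atlas")
        assert np.array_equal(back.labels.values, atlas.labels.values)
        assert back.labels_for_name("block") == [1, 2]


class TestExtentMonotonicity:
    def test_extent_non_increasing_in_threshold(self):
        rng = np.random.default_rng(20)
        grid = make_grid((8, 2, 2))
        zmap = _zmap_from(grid, rng.normal(size=grid.shape) * 2)
        atlas = _two_region_atlas(grid)
        extents = []
        for cut in (0.0, 0.5, 1.0, 2.0, 3.0):
            stats = regional_stats(zmap, atlas, z_extent=cut)
            extents.append(sum(s.extent_pct for s in stats))
        assert all(a >= b for a, b in zip(extents, extents[1:]))
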