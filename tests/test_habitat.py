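"""Wash-in map, bounded sphere, upper-quartile habitat, Dice."""

import numpy as np
import pytest

from dcehabitat.habitat import (
    WashInMap,
    compute_habitat,
    dice,
    representative_curve,
    search_sphere,
    washin_map,
)
from dcehabitat.preprocess import DCESeries, dce_normalize


def brute_force_upper_quartile(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Sort-based oracle: linear-interpolation Q3 and a >=-threshold mask."""
    s = np.sort(values)
    h = 0.75 * (s.size - 1)
    lo = int(np.floor(h))
    thr = s[lo] if lo + 1 >= s.size else s[lo] + (h - lo) * (s[lo + 1] - s[lo])
    return thr, values >= thr


def _full_masks(shape):
    prostate = np.ones(shape, dtype=bool)
    tz = np.zeros(shape, dtype=bool)
    return {"prostate": prostate, "pz": prostate & ~tz, "tz": tz}


class TestWashinMap:
    def test_zero_noise_map_matches_truth(self, noiseless_patient):
        p = noiseless_patient
        series = dce_normalize(p.dce, p.masks["artery"])
        truth = p.truth[0]
        lesion = p.masks["lesion_0"]
        wmap = washin_map(series, lesion)
        # normalization divides all intensities by the arterial peak, so wi
        # scales by the same factor
        artery = p.dce.intensities[p.masks["artery"]].mean(axis=0)
        scale = artery.max() - artery[:p.dce.pre_contrast_frames].mean()
        from dcehabitat.model import extract_features
        wi_truth = extract_features(truth.params).wi / scale
        vals = wmap.values[lesion]
        assert np.all(np.abs(vals - wi_truth) / wi_truth < 1e-3)

    def test_constant_voxels_flagged_zero(self):
        data = np.full((3, 3, 2, 10), 5.0)
        s = DCESeries(intensities=data, times=np.arange(10) * 7.0,
                      voxel_spacing=(1, 1, 1), temporal_resolution=7.0)
        wmap = washin_map(s, np.ones((3, 3, 2), dtype=bool))
        assert np.all(wmap.values[wmap.defined] == 0.0)
        assert wmap.fit_flags[wmap.defined].all()

    def test_undefined_outside_mask(self, noiseless_patient):
        p = noiseless_patient
        lesion = p.masks["lesion_0"]
        wmap = washin_map(p.dce, lesion)
        assert np.isnan(wmap.values[~lesion]).all()


class TestSearchSphere:
    def test_sphere_volume_matches_analytic(self):
        shape, spacing = (40, 40, 40), (1.0, 1.0, 1.0)
        masks = _full_masks(shape)
        center = (19.5, 19.5, 19.5)
        region, zone = search_sphere(center, masks, spacing, radius_mm=15.0)
        vol = region.sum() * 1.0
        assert abs(vol - 14137.17) / 14137.17 < 0.02
        assert zone == "PZ"

    def test_zone_majority_rule(self):
        shape, spacing = (20, 20, 10), (1.0, 1.0, 1.0)
        prostate = np.ones(shape, dtype=bool)
        tz = np.zeros(shape, dtype=bool)
        tz[:12] = True  # x < 12 is TZ
        masks = {"prostate": prostate, "tz": tz, "pz": prostate & ~tz}
        lesion = np.zeros(shape, dtype=bool)
        lesion[6:16, 5, 5] = True  # 6 voxels in TZ, 4 in PZ
        _, zone = search_sphere((10.0, 5.0, 5.0), masks, spacing,
                                radius_mm=5.0, lesion_mask=lesion)
        assert zone == "TZ"
        lesion2 = np.zeros(shape, dtype=bool)
        lesion2[8:18, 5, 5] = True  # 4 in TZ, 6 in PZ
        _, zone2 = search_sphere((13.0, 5.0, 5.0), masks, spacing,
                                 radius_mm=5.0, lesion_mask=lesion2)
        assert zone2 == "PZ"

    def test_zero_radius_single_voxel(self):
        masks = _full_masks((10, 10, 10))
        region, _ = search_sphere((4.0, 4.0, 4.0), masks, (1.0, 1.0, 1.0),
                                  radius_mm=0.0)
        assert region.sum() == 1 and region[4, 4, 4]

    def test_empty_intersection_raises(self):
        shape = (10, 10, 10)
        masks = _full_masks(shape)
        masks["prostate"] = np.zeros(shape, dtype=bool)
        masks["pz"] = np.zeros(shape, dtype=bool)
        with pytest.raises(ValueError, match="empty search region"):
            search_sphere((5.0, 5.0, 5.0), masks, (1.0, 1.0, 1.0), 3.0)


class TestComputeHabitat:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sorted_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (8, 8, 4)
        values = rng.normal(size=shape)
        search = rng.random(shape) < 0.6
        wmap = WashInMap(values=np.where(search, values, np.nan),
                         defined=search, fit_flags=np.zeros(shape, bool))
        hab = compute_habitat(wmap, search)
        thr, oracle_sel = brute_force_upper_quartile(values[search])
        assert hab.threshold == pytest.approx(thr)
        assert np.array_equal(hab.voxels[search], oracle_sel)
        assert not hab.voxels[~search].any()

    def test_uniform_map_returns_whole_region_flagged(self):
        shape = (5, 5, 2)
        search = np.ones(shape, dtype=bool)
        wmap = WashInMap(values=np.full(shape, 2.0), defined=search,
                         fit_flags=np.zeros(shape, bool))
        hab = compute_habitat(wmap, search)
        assert np.array_equal(hab.voxels, search)
        assert "uniform_washin_map" in hab.flags

    def test_planted_blob_is_contained(self):
        rng = np.random.default_rng(1)
        shape = (10, 10, 5)
        search = np.ones(shape, dtype=bool)
        values = rng.uniform(0.0, 1.0, shape)
        blob = np.zeros(shape, dtype=bool)
        blob[2:6, 2:7, 1:4] = True  # 20% of the region, all values > max
        values[blob] = rng.uniform(5.0, 6.0, int(blob.sum()))
        wmap = WashInMap(values=values, defined=search,
                         fit_flags=np.zeros(shape, bool))
        hab = compute_habitat(wmap, search)
        assert (blob <= hab.voxels).all()

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        shape = (6, 6, 3)
        search = np.ones(shape, dtype=bool)
        values = rng.normal(size=shape)
        wmap1 = WashInMap(values=values, defined=search,
                          fit_flags=np.zeros(shape, bool))
        wmap2 = WashInMap(values=np.exp(values), defined=search,
                          fit_flags=np.zeros(shape, bool))
        h1 = compute_habitat(wmap1, search)
        h2 = compute_habitat(wmap2, search)
        assert np.array_equal(h1.voxels, h2.voxels)


class TestRepresentativeCurveAndDice:
    def _tiny_series(self):
        rng = np.random.default_rng(0)
        data = rng.random((3, 3, 1, 8))
        return DCESeries(intensities=data, times=np.arange(8) * 7.0,
                         voxel_spacing=(1, 1, 1), temporal_resolution=7.0)

    def _habitat_of(self, mask):
        from dcehabitat.habitat import Habitat
        return Habitat(voxels=mask, search_region=mask, threshold=0.0,
                       bounding_zone="PZ")

    def test_single_voxel_curve(self):
        s = self._tiny_series()
        mask = np.zeros((3, 3, 1), dtype=bool)
        mask[1, 2, 0] = True
        curve = representative_curve(s, self._habitat_of(mask))
        assert np.array_equal(curve.values, s.intensities[1, 2, 0])

    def test_two_voxel_mean(self):
        s = self._tiny_series()
        mask = np.zeros((3, 3, 1), dtype=bool)
        mask[0, 0, 0] = mask[2, 2, 0] = True
        curve = representative_curve(s, self._habitat_of(mask))
        expected = (s.intensities[0, 0, 0] + s.intensities[2, 2, 0]) / 2.0
        assert curve.values == pytest.approx(expected)

    def test_dice_values(self):
        a = np.zeros((10, 10, 1), dtype=bool)
        a[:5] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        b = np.zeros_like(a)
        b[2:7] = True  # |a|=|b|=500? no: 5x10=50 voxels each, overlap 3x10=30
        assert dice(a, b) == pytest.approx(2 * 30 / (50 + 50))
        assert dice(a, b) == dice(b, a)
        assert dice(np.zeros_like(a), np.zeros_like(a)) == 0.0
        with pytest.raises(ValueError, match="grids differ"):
            dice(a, np.zeros((5, 5, 1), dtype=bool))
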