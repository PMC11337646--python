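import math
from datetime import date

import numpy as np
import pytest
from shapely.geometry import box

from canopycalib import (
    PlotState,
    canopy_mask,
    extract_traits,
    geometric_traits,
    otsu_threshold,
    render_scene,
    spectral_traits,
    trait_columns,
)
from canopycalib.traits import GEOMETRIC_TRAITS, CanopyMask


def brute_force_otsu(values, nbins=256):
    """Exhaustive search over histogram cut points maximizing between-class
    variance; the independent oracle for the Otsu routine."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_t = -1.0, centers[0]
    total = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / hist[:k].sum()
        m1 = (hist[k:] * centers[k:]).sum() / hist[k:].sum()
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k - 1]
    return best_t


class TestOtsu:
    def test_bimodal_threshold_separates_classes(self):
        vals = np.concatenate([np.full(50, 0.1), np.full(50, 0.7)])
        t = otsu_threshold(vals)
        assert 0.1 < t < 0.7

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            rng.normal(0.15, 0.05, 5000), rng.normal(0.6, 0.1, 5000)
        ])
        assert otsu_threshold(vals) == pytest.approx(brute_force_otsu(vals), abs=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0.1, 0.03, 500), rng.normal(0.5, 0.05, 500)])
        assert otsu_threshold(vals + 0.25) == pytest.approx(otsu_threshold(vals) + 0.25,
                                                            abs=1e-9)

    def test_constant_raster_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full(100, 0.3))


class TestSpectral:
    def test_exactly_66_spectral_fields(self, mixed_scene):
        mask = canopy_mask(mixed_scene, mixed_scene.roi_permanent)
        out = spectral_traits(mixed_scene, mixed_scene.roi_permanent, mask)
        assert len(out) == 66
        assert sum(k.endswith("_masked_median") for k in out) == 33

    def test_constant_scene_masked_equals_unmasked(self, full_canopy_scene):
        roi = full_canopy_scene.roi_permanent
        mask = canopy_mask(full_canopy_scene, roi)
        out = spectral_traits(full_canopy_scene, roi, mask)
        for vi in ("NDVI", "OSAVI", "GSAVI"):
            assert out[f"{vi}_masked_median"] == pytest.approx(out[f"{vi}_median"])

    def test_masking_raises_ndvi_median_on_mixed_scene(self, mixed_scene):
        roi = mixed_scene.roi_permanent
        mask = canopy_mask(mixed_scene, roi)
        out = spectral_traits(mixed_scene, roi, mask)
        assert out["NDVI_masked_median"] > out["NDVI_median"]

    def test_empty_roi_rejected(self, mixed_scene):
        mask = canopy_mask(mixed_scene, mixed_scene.roi_permanent)
        outside = box(100.0, 100.0, 101.0, 101.0)
        with pytest.raises(ValueError, match="intersect"):
            spectral_traits(mixed_scene, outside, mask)


def enumerate_geometric(chm_values, gsd, roi_area):
    """Direct enumeration oracle over the pixel list."""
    h = sorted(float(v) for v in chm_values)
    n = len(h)

    def pctl(p):  # linear interpolation between order statistics
        rank = p / 100 * (n - 1)
        lo, hi = math.floor(rank), math.ceil(rank)
        return h[lo] + (rank - lo) * (h[hi] - h[lo])

    out = {"height_p50": pctl(50), "height_p75": pctl(75),
           "height_p95": pctl(95), "height_p98": pctl(98)}
    for p in (25, 50, 75):
        thresh = pctl(p)
        out[f"area_below_p{p}"] = sum(1 for v in h if v < thresh) * gsd * gsd
    out["canopy_volume"] = sum(h) * gsd * gsd / roi_area
    return out


class TestGeometric:
    def test_uniform_canopy(self):
        gsd = 0.1
        chm = np.full((20, 20), 0.8)
        roi = box(0, 0, 2.0, 2.0)
        mask = CanopyMask(np.ones_like(chm, bool), 0.2, 1.0)
        out = geometric_traits(chm, roi, mask, gsd)
        for p in (50, 75, 95, 98):
            assert out[f"height_p{p}"] == pytest.approx(0.8)
        for p in (25, 50, 75):
            assert out[f"area_below_p{p}"] == 0.0  # strict inequality
        assert out["canopy_volume"] == pytest.approx(0.8)

    def test_exactly_9_fields(self, mixed_scene):
        mask = canopy_mask(mixed_scene, mixed_scene.roi_permanent)
        out = geometric_traits(mixed_scene.chm, mixed_scene.roi_permanent, mask,
                               mixed_scene.gsd)
        assert set(out) == set(GEOMETRIC_TRAITS)

    def test_matches_enumeration_oracle(self):
        gsd = 0.1
        heights = np.arange(1, 101, dtype=float) / 100  # 1..100 cm
        rng = np.random.default_rng(0)
        chm = rng.permutation(heights).reshape(10, 10)
        roi = box(0, 0, 1.0, 1.0)
        mask = CanopyMask(chm > 0.5, 0.5, float((chm > 0.5).mean()))
        out = geometric_traits(chm, roi, mask, gsd)
        oracle = enumerate_geometric(chm.ravel(), gsd, roi.area)
        for k, v in oracle.items():
            assert out[k] == pytest.approx(v, abs=1e-12), k

    def test_percentile_monotonicity(self, mixed_scene):
        mask = canopy_mask(mixed_scene, mixed_scene.roi_permanent)
        out = geometric_traits(mixed_scene.chm, mixed_scene.roi_permanent, mask,
                               mixed_scene.gsd)
        assert (out["height_p50"] <= out["height_p75"]
                <= out["height_p95"] <= out["height_p98"])

    def test_height_sd_behind_flag(self, mixed_scene):
        mask = canopy_mask(mixed_scene, mixed_scene.roi_permanent)
        out = geometric_traits(mixed_scene.chm, mixed_scene.roi_permanent, mask,
                               mixed_scene.gsd, include_height_sd=True)
        assert "height_sd" in out and len(out) == 10


class TestExtract:
    def test_record_has_75_trait_fields(self, mixed_scene):
        rec = extract_traits(mixed_scene, "permanent")
        assert len(rec.values) == 75
        assert list(rec.to_dict())[4:4 + 75] == trait_columns()

    def test_bare_soil_coverage_zero_and_masked_missing(self, bare_scene):
        rec = extract_traits(bare_scene, "precise", cut_number=1)
        assert rec.values["coverage"] < 0.05
        if rec.values["coverage"] == 0.0:
            assert math.isnan(rec.values["NDVI_masked_median"])

    def test_full_canopy_constant_scene_coverage_one(self, full_canopy_scene):
        rec = extract_traits(full_canopy_scene, "permanent")
        assert rec.values["coverage"] == pytest.approx(1.0)

    def test_precise_requires_cut_number(self, mixed_scene):
        with pytest.raises(ValueError, match="cut number"):
            extract_traits(mixed_scene, "precise")

    def test_unknown_cut_rejected(self, mixed_scene):
        with pytest.raises(KeyError):
            extract_traits(mixed_scene, "precise", cut_number=99)


def test_volume_tracks_biomass_rank_on_noise_free_scenes():
    """Across plots with increasing canopy, volume orders exactly."""
    heights = [0.1, 0.25, 0.4, 0.6, 0.8]
    fracs = [0.2, 0.4, 0.6, 0.8, 0.95]
    volumes = []
    for i, (h, f) in enumerate(zip(heights, fracs)):
        state = PlotState(f"p{i}", date(2021, 8, 1), mean_height=h, green_fraction=f)
        scene = render_scene(state, 1 / 64, seed=31 + i, height_noise_sd=0.0,
                             reflectance_noise_cv=0.0)
        rec = extract_traits(scene, "permanent")
        volumes.append(rec.values["canopy_volume"])
    assert volumes == sorted(volumes)
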