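"""Image-space operations: IDIF, regional TACs, Logan maps, smoothing, clusters."""

import numpy as np
import pytest

from petquant.core import ConfigurationError, DynamicImage, LabelAtlas
from petquant.imaging import (
    ExtractionError,
    extract_idif,
    extract_regional_tacs,
    gaussian_smooth,
    parametric_logan_map,
    voxelwise_group_compare,
)
from petquant.kinetics import logan_vt
from petquant.synthetic import default_phantom_spec, generate_phantom_scan


@pytest.fixture(scope="module")
def noiseless_phantom():
    spec = default_phantom_spec(voxel_noise_scale=0.0)
    image, atlas, truth = generate_phantom_scan(spec, seed=3)
    center_mm = tuple(np.array(spec.blood_pool_center) * spec.voxel_size_mm)
    return spec, image, atlas, truth, center_mm


class TestIDIF:
    def test_noiseless_phantom_recovers_framed_input(self, noiseless_phantom):
        spec, image, atlas, truth, center = noiseless_phantom
        idif = extract_idif(image, center)
        ref = truth["input_tac"].activity
        sig = ref > 0.1
        assert np.all(np.abs(idif.activity[sig] - ref[sig]) / ref[sig] < 0.01)

    def test_full_threshold_keeps_single_voxel(self, noiseless_phantom):
        spec, image, atlas, truth, center = noiseless_phantom
        idif = extract_idif(image, center, threshold_frac=1.0)
        # a single retained voxel reproduces one voxel's series exactly
        match = np.isclose(image.data[atlas.mask("blood_pool"), :], idif.activity[None, :])
        assert np.any(np.all(match, axis=1))

    def test_displaced_hint_raises_extraction_failure(self, noiseless_phantom):
        spec, image, atlas, truth, center = noiseless_phantom
        displaced = (center[0] + 8 * spec.voxel_size_mm, center[1], center[2])
        with pytest.raises(ExtractionError):
            extract_idif(image, displaced)

    def test_sphere_outside_fov_rejected(self, noiseless_phantom):
        spec, image, *_ = noiseless_phantom
        with pytest.raises(ConfigurationError):
            extract_idif(image, (0.0, 0.0, 0.0))


class TestRegionalTACs:
    def test_single_voxel_region_returns_that_series(self, schedule):
        data = np.random.default_rng(0).uniform(1, 2, (4, 4, 4, 39)).astype(np.float32)
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[2, 1, 3] = 1
        image = DynamicImage(data, schedule)
        tacs = extract_regional_tacs(image, LabelAtlas(labels, {1: "spot"}))
        assert np.allclose(tacs["spot"].activity, data[2, 1, 3, :])

    def test_noiseless_phantom_tacs_match_generators(self, noiseless_phantom):
        spec, image, atlas, truth, _ = noiseless_phantom
        tacs = extract_regional_tacs(image, atlas)
        for name, info in truth["regions"].items():
            assert np.allclose(tacs[name].activity, info["tac"].activity, rtol=1e-4, atol=1e-4)

    def test_merging_equal_labels_preserves_tac(self, schedule):
        data = np.ones((4, 4, 4, 39), dtype=np.float32) * 2.5
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0, 0, 0] = 1
        labels[3, 3, 3] = 2
        image = DynamicImage(data, schedule)
        atlas = LabelAtlas(labels, {1: "a", 2: "b"})
        tacs = extract_regional_tacs(image, atlas)
        merged = LabelAtlas((labels > 0).astype(np.int16), {1: "ab"})
        tac_m = extract_regional_tacs(image, merged)["ab"]
        assert np.allclose(tac_m.activity, tacs["a"].activity)

    def test_unknown_region_rejected(self, noiseless_phantom):
        _, image, atlas, *_ = noiseless_phantom
        with pytest.raises(KeyError):
            extract_regional_tacs(image, atlas, ["amygdala"])


class TestParametricMap:
    def test_noiseless_region_means_match_truth(self, noiseless_phantom):
        spec, image, atlas, truth, center = noiseless_phantom
        idif = extract_idif(image, center)
        vt_map = parametric_logan_map(image, idif)
        for name, info in truth["regions"].items():
            est = float(np.nanmean(vt_map[atlas.mask(name)]))
            assert est == pytest.approx(info["true_vt"], rel=0.03)

    def test_background_is_nan_not_zero(self, noiseless_phantom):
        spec, image, atlas, truth, center = noiseless_phantom
        idif = extract_idif(image, center)
        vt_map = parametric_logan_map(image, idif)
        background = (atlas.labels == 0)
        assert np.all(np.isnan(vt_map[background]))

    def test_map_consistent_with_regional_fits_at_low_noise(self):
        spec = default_phantom_spec(voxel_noise_scale=0.3)
        image, atlas, truth = generate_phantom_scan(spec, seed=8)
        center = tuple(np.array(spec.blood_pool_center) * spec.voxel_size_mm)
        idif = extract_idif(image, center)
        vt_map = parametric_logan_map(image, idif)
        tacs = extract_regional_tacs(image, atlas)
        map_means, reg_fits = [], []
        for name in truth["regions"]:
            map_means.append(float(np.nanmean(vt_map[atlas.mask(name)])))
            reg_fits.append(logan_vt(tacs[name], idif).vt)
        r = np.corrcoef(map_means, reg_fits)[0, 1]
        assert r * r > 0.98


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        m = np.random.default_rng(1).normal(size=(8, 8, 8))
        assert np.array_equal(gaussian_smooth(m, 0.0), m)

    def test_uniform_map_unchanged_away_from_border(self):
        m = np.full((12, 12, 12), 4.2)
        out = gaussian_smooth(m, 1.0, 0.776)
        assert np.allclose(out[2:-2, 2:-2, 2:-2], 4.2, rtol=1e-6)

    def test_impulse_kernel_integrates_to_one(self):
        m = np.zeros((15, 15, 15))
        m[7, 7, 7] = 1.0
        out = gaussian_smooth(m, 1.0, 0.776)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_nan_masking_excludes_missing_values(self):
        m = np.full((10, 10, 10), 3.0)
        m[5, 5, 5] = np.nan
        out = gaussian_smooth(m, 1.0, 0.776)
        assert np.isnan(out[5, 5, 5])
        finite = np.isfinite(out)
        assert np.allclose(out[finite], 3.0, rtol=1e-6)


class TestVoxelwiseCompare:
    shape = (16, 16, 12)

    def _smooth_noise_maps(self, rng, n, base=5.0, sd=0.5):
        return [gaussian_smooth(base + rng.normal(0, sd, self.shape), 1.5, 0.776)
                for _ in range(n)]

    def test_identical_groups_yield_no_clusters(self):
        rng = np.random.default_rng(2)
        maps = self._smooth_noise_maps(rng, 6)
        table, tmap = voxelwise_group_compare(maps, [m.copy() for m in maps],
                                              min_extent_voxels=20, n_permutations=99)
        assert len(table) == 0
        assert np.nanmax(np.abs(tmap)) < 1e-6

    def test_planted_effect_detected_in_correct_region(self):
        rng = np.random.default_rng(7)
        maps_a = self._smooth_noise_maps(rng, 8, sd=0.35)
        maps_b = self._smooth_noise_maps(rng, 8, sd=0.35)
        effect = np.zeros(self.shape, dtype=bool)
        effect[5:11, 5:11, 4:9] = True
        for m in maps_b:
            m[effect] *= 1.15
        table, _ = voxelwise_group_compare(maps_a, maps_b, min_extent_voxels=20,
                                           n_permutations=199, seed=3)
        assert len(table) >= 1
        assert set(table.direction) == {"B>A"}
        for _, row in table.iterrows():
            overlap = (row.cluster_mask & effect).sum() / row.n_voxels
            assert overlap > 0.5

    def test_too_few_maps_rejected(self):
        rng = np.random.default_rng(0)
        maps = self._smooth_noise_maps(rng, 2)
        with pytest.raises(ConfigurationError):
            voxelwise_group_compare(maps[:1], maps, n_permutations=19)

    def test_insufficient_permutations_warn(self):
        rng = np.random.default_rng(4)
        maps_a = self._smooth_noise_maps(rng, 3)
        maps_b = self._smooth_noise_maps(rng, 3)
        with pytest.warns(UserWarning):
            voxelwise_group_compare(maps_a, maps_b, n_permutations=5)
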