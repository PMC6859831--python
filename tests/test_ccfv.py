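"""Choriocapillaris flow-void pipeline: threshold, overlay, alignment, measurement."""

import numpy as np
import pytest

from octaquant.ccfv import (
    ArtifactRemovalWarning,
    ccfv_pipeline,
    crop_to_overlap,
    flow_void_threshold,
    measure_cc_scan,
    measure_flow_void,
    register_translation,
    remove_projection_artifacts,
)
from octaquant.images import ScanRecord
from octaquant.synthetic import (
    build_subject_scene,
    CohortConfig,
    generate_cc_slab,
    generate_intravisit_pair,
    generate_vessel_network,
    generate_avascular_slab,
    render_slab,
)

from conftest import make_image


class TestThreshold:
    def test_constant_image(self):
        assert flow_void_threshold(make_image(np.full((32, 32), 100.0))) == 100.0

    def test_direct_formula(self):
        px = np.full((100, 100), 50.0)
        px[:50] = 40.0
        px[50:] = 60.0  # mean 50, SD 10
        assert flow_void_threshold(make_image(px)) == pytest.approx(69.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.uniform(0, 255, (64, 64))
        t = flow_void_threshold(make_image(px))
        flat = list(px.ravel())
        mean = sum(flat) / len(flat)
        var = sum((x - mean) ** 2 for x in flat) / len(flat)
        expected = mean + 1.96 * var**0.5
        assert abs(t - expected) / expected < 1e-9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        px = rng.uniform(0, 255, (64, 64))
        t1 = flow_void_threshold(make_image(px))
        t2 = flow_void_threshold(make_image(rng.permutation(px.ravel()).reshape(64, 64)))
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestMeasureFlowVoid:
    def test_extremes(self):
        img = make_image(np.full((64, 64), 200.0))
        assert measure_flow_void(img, 100.0).void_area_mm2 == 0.0
        res = measure_flow_void(img, 200.0)  # inclusive threshold
        assert res.void_area_mm2 == res.analyzed_area_mm2

    def test_direct_count(self):
        px = np.full((512, 512), 200.0)
        px.ravel()[:1234] = 10.0
        res = measure_flow_void(make_image(px, extent_mm=6.0), 50.0)
        assert res.void_area_mm2 == pytest.approx(1234 * (6.0 / 512) ** 2)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        img = make_image(rng.uniform(0, 255, (128, 128)))
        areas = [measure_flow_void(img, t).void_area_mm2 for t in np.linspace(0, 255, 20)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        px = rng.uniform(0, 255, (64, 64))
        a1 = measure_flow_void(make_image(px), 120.0).void_area_mm2
        shuffled = rng.permutation(px.ravel()).reshape(64, 64)
        a2 = measure_flow_void(make_image(shuffled), 120.0).void_area_mm2
        assert a1 == a2


class TestArtifactRemoval:
    def test_trivial_masks_pass_through(self):
        img = make_image(np.random.default_rng(0).uniform(50, 200, (64, 64)))
        with pytest.warns(ArtifactRemovalWarning):
            out = remove_projection_artifacts(img, np.zeros((64, 64), bool))
        assert np.array_equal(out.pixels, img.pixels)

    def test_constant_image_unchanged(self):
        img = make_image(np.full((64, 64), 100.0))
        mask = np.zeros((64, 64), bool)
        mask[:10] = True
        out = remove_projection_artifacts(img, mask)
        assert np.allclose(out.pixels, 100.0)

    def test_mean_matching(self):
        rng = np.random.default_rng(5)
        px = rng.normal(120, 5, (128, 128))
        mask = np.zeros((128, 128), bool)
        mask[:40] = True
        px[mask] = rng.normal(60, 5, mask.sum())
        out = remove_projection_artifacts(make_image(np.clip(px, 0, 255)), mask)
        assert out.pixels[mask].mean() == pytest.approx(out.pixels[~mask].mean(), abs=1.0)
        assert np.array_equal(out.pixels[~mask], np.clip(px, 0, 255)[~mask])


class TestRegistration:
    def _content(self, seed, n=256):
        mask, _ = generate_vessel_network(n, 0.3, 0.3, 6.0, seed=seed)
        return np.where(mask, 200.0, 40.0)

    def test_identity(self):
        img = make_image(self._content(1))
        assert register_translation(img, img, 10) == (0, 0)

    @pytest.mark.parametrize("shift", [(3, -2), (-7, 5), (0, 9)])
    def test_recovers_known_shift(self, shift):
        dx, dy = shift
        clean = self._content(2, n=296)
        img1 = make_image(clean[20:276, 20:276])
        img2 = make_image(clean[20 - dy : 276 - dy, 20 - dx : 276 - dx])
        assert register_translation(img1, img2, 12) == shift

    def test_constant_images_tiebreak_to_origin(self):
        img = make_image(np.full((64, 64), 99.0))
        assert register_translation(img, img, 5) == (0, 0)


class TestCrop:
    def test_zero_offset_full_frame(self):
        img = make_image(np.random.default_rng(1).uniform(0, 255, (128, 128)))
        pair = crop_to_overlap(img, img, (0, 0))
        assert pair.image1.pixels.shape == (128, 128)
        assert pair.analyzed_area_mm2 == pytest.approx(36.0)

    def test_offset_shrinks_dims(self):
        img = make_image(np.random.default_rng(2).uniform(0, 255, (512, 512)))
        pair = crop_to_overlap(img, img, (3, 0))
        assert pair.image1.pixels.shape == (512, 509)
        assert pair.image2.pixels.shape == (512, 509)
        assert pair.analyzed_area_mm2 == pytest.approx(512 * 509 * (6.0 / 512) ** 2)

    def test_shifted_pair_pixel_identical_after_crop(self):
        clean = np.random.default_rng(3).uniform(0, 255, (150, 150))
        dx, dy = 4, -3
        img1 = make_image(clean[10:138, 10:138])
        img2 = make_image(clean[10 - dy : 138 - dy, 10 - dx : 138 - dx])
        pair = crop_to_overlap(img1, img2, (dx, dy))
        assert np.array_equal(pair.image1.pixels, pair.image2.pixels)

    def test_empty_overlap_rejected(self):
        img = make_image(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            crop_to_overlap(img, img, (64, 0))


def _cc_scene(seed, grid=192, void=0.2, noise=5.0, shift=(3, -2), within=0.0):
    cfg = CohortConfig(
        n_subjects=2, grid_px=grid, max_shift_px=6, seed=seed,
        mean_index=void, between_subject_sd=0.0, within_subject_sd=within,
        noise_sd=noise,
    )
    rng = np.random.default_rng(seed)
    scene = build_subject_scene(
        "S1", cfg, void, (void, void), (0.32, 0.32), (0.40, 0.40),
        0.41, 0.74, rng,
    )
    return generate_intravisit_pair(scene, shift, noise, seed=seed + 1)


class TestPipeline:
    def test_duplicate_scans_equal_areas(self):
        r1, _ = _cc_scene(10, shift=(0, 0), noise=5.0)
        a, b = ccfv_pipeline(r1, r1)
        assert a.void_area_mm2 == b.void_area_mm2
        assert a.analyzed_area_mm2 == b.analyzed_area_mm2

    def test_shift_consistency_noise_free(self):
        s1, s2 = _cc_scene(11, noise=0.0, shift=(4, 2))
        a, b = ccfv_pipeline(s1, s2)
        assert a.void_area_mm2 == pytest.approx(b.void_area_mm2, rel=1e-9)

    def test_ground_truth_recovery(self):
        s1, s2 = _cc_scene(12, void=0.2, noise=5.0)
        a, b = ccfv_pipeline(s1, s2)
        for res in (a, b):
            assert res.void_area_mm2 == pytest.approx(
                0.2 * res.analyzed_area_mm2, rel=0.10)

    def test_artifact_removal_improves_accuracy(self):
        scp_mask, _ = generate_vessel_network(256, 0.3, 0.3, 6.0, seed=13)
        cc, truth = generate_cc_slab(256, 0.2, scp_mask=scp_mask,
                                     artifact_depth=60, noise_sd=5, seed=14)
        scp = render_slab(scp_mask, noise_sd=5, seed=15, extent_mm=6.0)
        avas = generate_avascular_slab(256, noise_sd=5, seed=16)
        rec = ScanRecord(subject_id="S1", slabs={"CC": cc, "SCP": scp, "avascular": avas})
        with_removal = measure_cc_scan(rec, artifact_removal=True)
        without = measure_cc_scan(rec, artifact_removal=False)
        err_with = abs(with_removal.void_fraction - truth.void_fraction)
        err_without = abs(without.void_fraction - truth.void_fraction)
        assert err_with < err_without

    def test_stage_error_propagation(self):
        rec = ScanRecord(subject_id="S1", slabs={})
        with pytest.raises(KeyError):
            ccfv_pipeline(rec, rec)
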