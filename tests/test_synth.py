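"""Determinism, separability oracle, scene/crop and video contracts."""

import numpy as np
import pytest
from PIL import Image

from equipain import (
    REGIONS,
    SceneParams,
    SynthError,
    classify_by_rule,
    generate_cohort,
    generate_face_scene,
    generate_motion_video,
    generate_region_image,
    geometry_parameter,
    ink_statistic,
    motion_floor,
    upper_half_ink_fraction,
)
from equipain.synth import RegionStyle, draw_latent


class TestSceneParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(SynthError):
            SceneParams(3)
        with pytest.raises(SynthError):
            SceneParams(0, separability=1.5)
        with pytest.raises(SynthError):
            SceneParams(0, noise_sd=-1)

    def test_region_style_validation(self):
        with pytest.raises(SynthError):
            RegionStyle("muzzle", 0.5)
        with pytest.raises(SynthError):
            RegionStyle("ears", 1.5)


class TestLatentMapping:
    def test_latent_monotone_in_pain_level(self, rng):
        """Class 0 draws from the low third, class 2 from the high third."""
        for _ in range(50):
            l0 = draw_latent(0, 1.0, rng)
            l1 = draw_latent(1, 1.0, rng)
            l2 = draw_latent(2, 1.0, rng)
            assert 0 <= l0 < 1 / 3 <= l1 < 2 / 3 <= l2 < 1

    def test_geometry_parameter_monotone_with_gaps(self):
        grid = np.linspace(0, 1, 301)
        g = np.array([geometry_parameter(v) for v in grid])
        assert (np.diff(g) > 0).all()
        # the jumps at the class boundaries leave a gap
        assert geometry_parameter(1 / 3) - geometry_parameter(1 / 3 - 1e-9) > 0.1
        assert geometry_parameter(2 / 3) - geometry_parameter(2 / 3 - 1e-9) > 0.1


class TestRegionImages:
    def test_deterministic_by_seed(self):
        p = SceneParams(1, 0.8, 3.0, seed=42)
        a = generate_region_image("eyes", p, (48, 48))
        b = generate_region_image("eyes", p, (48, 48))
        assert np.array_equal(a.pixels, b.pixels)

    def test_unknown_region_rejected(self):
        with pytest.raises(SynthError, match="muzzle"):
            generate_region_image("muzzle", SceneParams(0))

    def test_non_positive_size_rejected(self):
        with pytest.raises(SynthError):
            generate_region_image("ears", SceneParams(0), (0, 32))

    def test_png_round_trip_preserves_pixels(self, tmp_path):
        img = generate_region_image("ears", SceneParams(2, seed=3), (32, 32))
        rec = img.save(tmp_path / "ear.png")
        again = np.asarray(Image.open(tmp_path / "ear.png"))
        assert np.array_equal(again, img.pixels)
        assert rec.region == "ears" and rec.pain_level == 2

    def test_documented_statistics_differ_between_extreme_classes(self):
        lo = generate_region_image("ears", SceneParams(0, 1.0, 0.0, seed=5), (64, 64))
        hi = generate_region_image("ears", SceneParams(2, 1.0, 0.0, seed=5), (64, 64))
        assert ink_statistic(hi.pixels) > ink_statistic(lo.pixels)
        assert upper_half_ink_fraction(hi.pixels) > upper_half_ink_fraction(lo.pixels)

    def test_label_counts_when_cycling_levels(self):
        levels = [i % 3 for i in range(100)]
        counts = np.bincount(levels)
        assert tuple(counts) == (34, 33, 33)

    @pytest.mark.parametrize("region", REGIONS)
    def test_separability_oracle_is_exact(self, region):
        """At separability 1 / noise 0 the closed-form pixel rule is 100%."""
        for seed in range(60):
            level = seed % 3
            img = generate_region_image(region, SceneParams(level, 1.0, 0.0, seed), (32, 32))
            assert classify_by_rule(img.pixels) == level

    def test_zero_separability_renders_identically_across_classes(self):
        a = generate_region_image("eyes", SceneParams(0, 0.0, 0.0, 7), (32, 32))
        b = generate_region_image("eyes", SceneParams(2, 0.0, 0.0, 7), (32, 32))
        assert np.array_equal(a.pixels, b.pixels)

    def test_rgb_option(self):
        img = generate_region_image("eyes", SceneParams(1, seed=1), (16, 16), rgb=True)
        assert img.pixels.shape == (16, 16, 3)
        assert np.array_equal(img.pixels[..., 0], img.pixels[..., 1])


class TestFaceScene:
    def test_crops_are_exact_subrasters(self):
        scene = generate_face_scene(SceneParams(1, seed=8), (96, 96))
        for region, (x, y, w, h) in scene.boxes.items():
            assert np.array_equal(scene.image[y : y + h, x : x + w], scene.crops[region].pixels)
            assert scene.crops[region].pain_level == scene.pain_level

    def test_different_seeds_differ(self):
        a = generate_face_scene(SceneParams(0, seed=1), (48, 48))
        b = generate_face_scene(SceneParams(0, seed=2), (48, 48))
        assert not np.array_equal(a.image, b.image)

    def test_too_small_scene_rejected(self):
        with pytest.raises(SynthError):
            generate_face_scene(SceneParams(0), (10, 10))


class TestCohort:
    def test_slot_and_row_arithmetic(self, tmp_path):
        manifest = generate_cohort(
            tmp_path, 2, 3, 2, (1 / 3, 1 / 3, 1 / 3), SceneParams(0, seed=4),
            scene_size=(48, 48),
        )
        assert len(manifest) == 2 * 3 * 2 * 3  # slots × regions
        assert manifest.frame["source_frame"].nunique() == 12

    def test_degenerate_weights_give_single_class(self, tmp_path):
        manifest = generate_cohort(
            tmp_path, 2, 2, 2, (1, 0, 0), SceneParams(0, seed=4), scene_size=(48, 48)
        )
        assert (manifest.frame["pain_level"] == 0).all()

    def test_manifest_bytes_reproducible(self, tmp_path):
        args = dict(n_animals=2, days=2, timepoints_per_day=1,
                    class_weights=(0.5, 0.3, 0.2), scene_size=(48, 48))
        generate_cohort(tmp_path / "a", params=SceneParams(0, seed=9), **args)
        generate_cohort(tmp_path / "b", params=SceneParams(0, seed=9), **args)
        assert (tmp_path / "a/manifest.csv").read_bytes() == (tmp_path / "b/manifest.csv").read_bytes()

    def test_bad_weights_rejected(self, tmp_path):
        with pytest.raises(SynthError, match="simplex"):
            generate_cohort(tmp_path, 1, 1, 1, (0.5, 0.2, 0.2), SceneParams(0))


class TestMotionVideo:
    def test_no_events_means_static(self):
        frames = generate_motion_video(6, [], 0.5, SceneParams(0, seed=1))
        diffs = [np.abs(frames[i].astype(float) - frames[i - 1]).mean() for i in range(1, 6)]
        assert diffs == [0.0] * 5

    def test_single_event_spikes_once(self):
        frames = generate_motion_video(10, {5}, 0.5, SceneParams(0, seed=1))
        floor = motion_floor(0.5, frames[0].shape)
        diffs = np.array(
            [np.abs(frames[i].astype(float) - frames[i - 1]).mean() for i in range(1, 10)]
        )
        above = np.nonzero(diffs > floor / 2)[0] + 1
        assert list(above) == [5]
        assert diffs[4] >= floor

    def test_deterministic_frames(self):
        a = generate_motion_video(5, {2}, 0.3, SceneParams(0, 1.0, 2.0, seed=6))
        b = generate_motion_video(5, {2}, 0.3, SceneParams(0, 1.0, 2.0, seed=6))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_request_rejected(self):
        with pytest.raises(SynthError):
            generate_motion_video(0, [], 0.5, SceneParams(0))

    def test_event_outside_range_rejected(self):
        with pytest.raises(SynthError):
            generate_motion_video(5, {0}, 0.5, SceneParams(0))
        with pytest.raises(SynthError):
            generate_motion_video(5, {5}, 0.5, SceneParams(0))
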