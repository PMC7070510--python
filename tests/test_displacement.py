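import numpy as np
import pytest

from smileasym import (
    DisplacementProfile,
    LandmarkSet,
    batch_align,
    build_intensity_table,
    displacement_profile,
    neutral_reference,
    normalized_landmark_error,
    region_intensity,
)
from smileasym.displacement import aligned_neutral_reference

from conftest import random_similarity


class TestDisplacementProfile:
    def test_identical_sets_give_zero(self, template):
        prof = displacement_profile(template, template)
        assert np.all(prof.distances == 0)

    def test_three_four_five_triangle(self, template):
        pts = template.points.copy()
        pts[48] += (3.0, 4.0, 0.0)
        prof = displacement_profile(template.with_points(pts), template)
        assert prof.distances[48] == pytest.approx(5.0)
        mask = np.ones(68, bool)
        mask[48] = False
        assert np.all(prof.distances[mask] == 0)

    def test_matches_independent_norms(self, template, rng):
        field = rng.normal(0, 2, (68, 3))
        moved = template.with_points(template.points + field)
        prof = displacement_profile(moved, template)
        expected = np.sqrt((field**2).sum(axis=1))  # independent per-point norm
        assert np.allclose(prof.distances, expected, atol=1e-12)

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            DisplacementProfile(0, -np.ones(68))


class TestNeutralReference:
    def test_single_frame_returned_as_is(self, template):
        ref = neutral_reference([template])
        assert np.allclose(ref.points, template.points)

    def test_median_ignores_outlier_frame(self, template):
        a = template.points
        frames = [
            template.with_points(a),
            template.with_points(a + 0.2),
            template.with_points(a + 1000.0),  # outlier frame
        ]
        ref = neutral_reference(frames)
        # per-coordinate median of {x, x+0.2, x+1000} is x+0.2
        assert np.allclose(ref.points, a + 0.2)

    def test_identical_frames_reproduce_frame(self, template):
        ref = neutral_reference([template] * 3)
        assert np.allclose(ref.points, template.points)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            neutral_reference([])

    def test_aligned_reference_removes_per_frame_pose(self, template, rng):
        frames = []
        for i in range(7):
            R, t, s = random_similarity(rng)
            frames.append(LandmarkSet(i, s * (template.points @ R.T) + t, 0.99))
        ref = aligned_neutral_reference(frames)
        # reference lives in the first frame's coordinate system
        assert np.abs(ref.points - frames[0].points).max() < 1e-6


class TestRegionIntensity:
    def _profile(self, distances):
        return DisplacementProfile(0, distances)

    def test_all_zero_profiles(self, region_map):
        zero = self._profile(np.zeros(68))
        for region in region_map.ANALYSIS_REGIONS:
            assert region_intensity([zero], region_map, region) == 0.0

    def test_sum_over_region(self, region_map):
        d = np.zeros(68)
        idx = region_map.indexes("eyebrow", "left")  # 5 landmarks
        d[idx] = 2.0
        got = region_intensity([self._profile(d)], region_map, "eyebrow", "left")
        assert got == pytest.approx(10.0)

    def test_mean_of_frame_sums(self, region_map):
        idx = region_map.indexes("nose")
        d1, d2 = np.zeros(68), np.zeros(68)
        d1[idx[0]] = 10.0
        d2[idx[0]] = 20.0
        got = region_intensity(
            [self._profile(d1), self._profile(d2)], region_map, "nose"
        )
        assert got == pytest.approx(15.0)

    def test_mean_mode(self, region_map):
        d = np.zeros(68)
        d[region_map.indexes("mouth")] = 3.0
        got = region_intensity(
            [self._profile(d)], region_map, "mouth", per_landmark="mean"
        )
        assert got == pytest.approx(3.0)

    def test_empty_profiles_raise(self, region_map):
        with pytest.raises(ValueError):
            region_intensity([], region_map, "mouth")


class TestNormalizedLandmarkError:
    def test_zero_for_identical_sets(self, template):
        assert normalized_landmark_error(template, template) == 0.0

    def test_uniform_offset_with_custom_scale(self, template):
        moved = template.with_points(template.points + (3.0, 0, 0))
        eps = normalized_landmark_error(
            moved, template, scale_mode="custom", d_scale=10.0
        )
        assert eps == pytest.approx(0.3)

    def test_toy_hand_computed_distances(self, template):
        # landmarks 0..3 offset by 1, 2, 3, 4 mm; mean over 68 of d/10
        pts = template.points.copy()
        for i, d in enumerate((1.0, 2.0, 3.0, 4.0)):
            pts[i, 0] += d
        eps = normalized_landmark_error(
            template.with_points(pts), template, scale_mode="custom", d_scale=10.0
        )
        assert eps == pytest.approx((1 + 2 + 3 + 4) / 68 / 10.0)

    def test_interocular_scale_is_63mm_on_template(self, template):
        moved = template.with_points(template.points + (6.3, 0, 0))
        eps = normalized_landmark_error(moved, template)
        assert eps == pytest.approx(0.1)

    def test_scale_equivariance(self, template, rng):
        noisy = template.with_points(
            template.points + rng.normal(0, 1, (68, 3))
        )
        eps1 = normalized_landmark_error(noisy, template)
        eps2 = normalized_landmark_error(
            noisy.with_points(2 * noisy.points),
            template.with_points(2 * template.points),
        )
        assert eps2 == pytest.approx(eps1, abs=1e-9)

    def test_median_statistic_flag(self, template):
        pts = template.points.copy()
        pts[0] += (100.0, 0, 0)
        med = normalized_landmark_error(
            template.with_points(pts), template,
            scale_mode="custom", d_scale=1.0, statistic="median",
        )
        assert med == 0.0  # 67 of 68 distances are zero

    def test_invalid_scale_raises(self, template):
        with pytest.raises(ValueError):
            normalized_landmark_error(
                template, template, scale_mode="custom", d_scale=0.0
            )


class TestIntensityTable:
    def _cohort(self, template, value=0.0):
        d = np.full(68, value)
        prof = DisplacementProfile(0, d)
        return {
            "S0": {"posed": [prof], "spontaneous": [prof]},
            "S1": {"posed": [prof], "spontaneous": [prof]},
        }

    def test_cardinality(self, template, region_map):
        table = build_intensity_table(self._cohort(template), region_map)
        assert len(table) == 2 * 2 * 7 * 2

    def test_all_zero_displacements(self, template, region_map):
        table = build_intensity_table(self._cohort(template), region_map)
        assert (table["intensity"] == 0).all()

    def test_composite_additivity(self, region_map, rng):
        profiles = [DisplacementProfile(i, rng.uniform(0, 5, 68)) for i in range(4)]
        cohort = {"S0": {"posed": profiles, "spontaneous": profiles}}
        table = build_intensity_table(cohort, region_map)
        t = table.set_index(["condition", "region", "side"])["intensity"]
        for side in ("left", "right"):
            assert t[("posed", "upper_face", side)] == pytest.approx(
                t[("posed", "eyebrow", side)] + t[("posed", "eye", side)]
            )
            assert t[("posed", "lower_face", side)] == pytest.approx(
                t[("posed", "nose", side)]
                + t[("posed", "mouth", side)]
                + t[("posed", "outline", side)]
            )

    def test_subject_missing_condition_excluded(self, template, region_map):
        cohort = self._cohort(template)
        del cohort["S1"]["spontaneous"]
        table = build_intensity_table(cohort, region_map)
        assert set(table["subject_id"]) == {"S0"}


class TestPipelineInvariances:
    def test_rigid_motion_of_smile_frames_cancelled(
        self, template, region_map, fiducials, rng
    ):
        field = rng.normal(0, 1.5, (68, 3))
        field[list(fiducials.indexes)] = 0.0
        smile = template.with_points(template.points + field)

        def intensities(frame):
            aligned = batch_align([frame], template, fiducials)
            prof = displacement_profile(aligned[0][0], template)
            return np.array([
                region_intensity([prof], region_map, r)
                for r in region_map.ANALYSIS_REGIONS
            ])

        base = intensities(smile)
        R, t, _ = random_similarity(rng)
        moved = smile.with_points((smile.points @ R.T) + t)
        assert np.abs(intensities(moved) - base).max() < 1e-6

    def test_field_scaling_scales_intensity_linearly(
        self, template, region_map, fiducials, rng
    ):
        field = rng.normal(0, 1.0, (68, 3))
        field[list(fiducials.indexes)] = 0.0

        def intensity_of(k):
            smile = template.with_points(template.points + k * field)
            aligned = batch_align([smile], template, fiducials)
            prof = displacement_profile(aligned[0][0], template)
            return region_intensity([prof], region_map, "mouth")

        base = intensity_of(1.0)
        assert intensity_of(3.0) == pytest.approx(3.0 * base, rel=1e-9)
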