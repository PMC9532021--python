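"""The synthetic cohort generator: stimuli, kinematics, design, determinism."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from freegaze.auc import auc_per_participant
from freegaze.geometry import validity_filter
from freegaze.kinematics import instantaneous_velocity
from freegaze.synthetic import (
    CohortSpec, generate_images, map_driven_cohort, simulate_recording,
    simulate_session,
)


class TestGenerateImages:
    def test_ranges_and_normalization(self):
        images, maps = generate_images(4, seed=1)
        for img in images:
            assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        for m in maps:
            assert m.values.sum() == pytest.approx(1.0)
            assert (m.values >= 0).all()

    def test_object_region_has_more_texture_than_background(self):
        images, maps = generate_images(3, seed=2)
        for img, m in zip(images, maps):
            mask = m.values > 0.3 * m.values.max()
            mean = uniform_filter(img.pixels, 9)
            mean_sq = uniform_filter(img.pixels ** 2, 9)
            local_sd = np.sqrt(np.clip(mean_sq - mean ** 2, 0, None))
            assert local_sd[mask].mean() > local_sd[~mask].mean()

    def test_seed_determinism_bit_identical(self):
        images_a, maps_a = generate_images(3, seed=9)
        images_b, maps_b = generate_images(3, seed=9)
        for a, b in zip(maps_a, maps_b):
            np.testing.assert_array_equal(a.values, b.values)
        for a, b in zip(images_a, images_b):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_maps_independent_of_pixel_rendering(self):
        _, maps_a = generate_images(2, seed=4, render_pixels=True)
        _, maps_b = generate_images(2, seed=4, render_pixels=False)
        for a, b in zip(maps_a, maps_b):
            np.testing.assert_array_equal(a.values, b.values)


class TestSimulateRecording:
    def test_argmax_limit_when_temperature_vanishes(self, truth_maps):
        spec = CohortSpec(group_sizes={"SC": 1}, tau=1e-6, missing_rate=0.0)
        rec, targets = simulate_recording(truth_maps[0], "fixation_saccade",
                                          spec, seed=0)
        mode = np.unravel_index(truth_maps[0].values.argmax(),
                                truth_maps[0].values.shape)
        assert (targets[:, 0] == mode[1]).all() and (targets[:, 1] == mode[0]).all()
        # dwell samples cluster within jitter range of the mode
        late = slice(300, 2000)
        assert np.median(np.abs(rec.x[late] - mode[1])) < 3 * 0.3 * 40.6

    def test_central_start_anchors_first_samples(self, truth_maps):
        spec = CohortSpec(group_sizes={"SC": 1}, central_start_ms=500)
        rec, _ = simulate_recording(truth_maps[1], "fixation_saccade", spec, seed=3)
        first = slice(0, 250)
        assert abs(np.median(rec.x[first]) - 400) < 40.6
        assert abs(np.median(rec.y[first]) - 400) < 40.6

    @pytest.mark.parametrize("rate,survives", [(0.49, True), (0.51, False)])
    def test_missing_rate_boundary_against_inclusion_rule(self, truth_maps,
                                                          rate, survives):
        spec = CohortSpec(group_sizes={"SC": 1}, missing_rate=rate, jitter_deg=0.1)
        rec, _ = simulate_recording(truth_maps[0], "fixation_saccade", spec, seed=5)
        kept, _, _ = validity_filter([rec])
        assert (len(kept) == 1) is survives

    def test_velocity_signatures_order_across_profiles(self, truth_maps):
        spec = CohortSpec(group_sizes={"SC": 1})
        for seed in range(3):
            medians = {}
            for profile in ("fixation_saccade", "multiplanar_irregular",
                            "horizontal_jerk"):
                rec, _ = simulate_recording(truth_maps[0], profile, spec, seed=seed)
                tr = instantaneous_velocity(rec)
                h = tr.horizontal[tr.defined]
                v = tr.vertical[tr.defined]
                medians[profile] = np.median(np.hypot(h, v))
                if profile == "horizontal_jerk":
                    assert np.var(h) / np.var(v) > 3
                if profile == "multiplanar_irregular":
                    assert np.var(h) / np.var(v) < 2
            assert medians["fixation_saccade"] < medians["multiplanar_irregular"] \
                < medians["horizontal_jerk"]

    def test_unknown_profile_rejected(self, truth_maps):
        with pytest.raises(ValueError):
            simulate_recording(truth_maps[0], "smooth_pursuit",
                               CohortSpec(group_sizes={"SC": 1}))


class TestCohortSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"group_sizes": {"SC": 0}},
        {"tau": 0.0},
        {"repeat_concentration": 0.5},
        {"missing_rate": 1.5},
        {"group_profiles": {"SC": "warp_drive"}},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        base = {"group_sizes": {"SC": 2}, "group_profiles": {"SC": "fixation_saccade"}}
        base.update(kwargs)
        with pytest.raises(ValueError):
            CohortSpec(**base)


class TestSimulateSession:
    def test_default_design_pair_mix(self):
        sess = simulate_session(CohortSpec(group_sizes={"SC": 1}),
                                recognition=False)
        counts = {}
        for p in sess.pairs:
            counts[p.pair_type] = counts.get(p.pair_type, 0) + 1
        assert counts == {"same_image": 7, "same_category": 7,
                          "different_category": 14}
        assert len(sess.recordings) == 56
        assert len({(p.block, p.trial_index) for p in sess.pairs}) == 28

    def test_truth_stored_for_every_recording(self, small_session):
        for rec in small_session.recordings:
            key = (rec.participant_id, rec.trial_index, rec.presentation)
            assert key in small_session.truth.target_sequences

    def test_session_determinism(self):
        cohort = map_driven_cohort(2, seed=13)
        a = simulate_session(cohort, pair_mix=(1, 1, 2), recognition=False)
        b = simulate_session(cohort, pair_mix=(1, 1, 2), recognition=False)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.x, rb.x)
            np.testing.assert_array_equal(ra.valid, rb.valid)
        assert a.pairs == b.pairs

    def test_insufficient_images_is_design_error(self):
        images, maps = generate_images(3, seed=1, render_pixels=False)
        with pytest.raises(ValueError, match="images"):
            simulate_session(map_driven_cohort(1, seed=0), images=images,
                             truth_maps=maps)

    def test_tighter_map_following_raises_auc(self):
        # tau smaller -> target draws adhere to the map -> higher AUC
        aucs = []
        for tau in (4.0, 2.0, 1.0, 0.5):
            cohort = map_driven_cohort(2, seed=17, tau=tau)
            sess = simulate_session(cohort, pair_mix=(1, 1, 2), recognition=False)
            res = auc_per_participant(sess.truth.maps, sess.recordings, seed=1)
            aucs.append(np.mean([r.auc for r in res]))
        assert all(np.diff(aucs) > 0)

    def test_recognition_outcomes_follow_truth_auc_model(self, small_session):
        truth = small_session.truth
        assert set(truth.truth_auc) == set(truth.acuity_logmar)
        assert all(0 <= a <= 1 for a in truth.truth_auc.values())
        assert len(truth.recognition_coefs) == 3
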