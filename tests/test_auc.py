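"""Rank-based AUC classification and its bias-controlled sampling scheme."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from freegaze.auc import (
    auc_from_values, auc_per_image, auc_per_participant, derangement,
    sample_gazed_values, sample_nongazed_values, shuffled_control,
    time_binned_auc, velocity_binned_auc,
)
from freegaze.maps import PredictorMap

from conftest import build_recording


def brute_force_auc(gazed, nongazed):
    """Independent oracle: proportion of favorable pairs with half-credit ties."""
    g = np.asarray(gazed, float)[:, None]
    ng = np.asarray(nongazed, float)[None, :]
    wins = (g > ng).sum() + 0.5 * (g == ng).sum()
    return wins / (g.size * ng.size)


def uniform_map(size=100):
    return PredictorMap(values=np.ones((size, size)), provenance="test")


class TestAUCFromValues:
    def test_perfect_separation_is_one(self):
        assert auc_from_values([3, 4, 5], [1, 2]).auc == 1.0

    def test_identical_multisets_are_half(self):
        r = auc_from_values([1, 2, 2, 7], [1, 2, 2, 7])
        assert r.auc == 0.5

    def test_hand_counted_three_quarters(self):
        # pairs: (2>1), (2<3), (4>1), (4>3) -> 3 of 4 favorable
        r = auc_from_values([2, 4], [1, 3])
        assert r.auc == 0.75
        assert r.U == 3.0 and r.n_gazed == 2 and r.n_nongazed == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 20, rng.integers(1, 200)).astype(float)
        ng = rng.integers(0, 20, rng.integers(1, 200)).astype(float)
        assert auc_from_values(g, ng).auc == pytest.approx(
            brute_force_auc(g, ng), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        g, ng = rng.random(50), rng.random(70)
        base = auc_from_values(g, ng).auc
        assert auc_from_values(np.exp(g), np.exp(ng)).auc == pytest.approx(base, abs=1e-12)
        assert auc_from_values(g ** 3, ng ** 3).auc == pytest.approx(base, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auc_from_values([], [1.0])

    def test_exchangeable_null_mean_and_variance(self):
        # same-distribution draws: mean 0.5, variance matching the U-statistic
        rng = np.random.default_rng(9)
        n = 30
        aucs = np.array([
            auc_from_values(rng.random(n), rng.random(n)).auc
            for _ in range(1000)
        ])
        assert abs(aucs.mean() - 0.5) < 0.01
        analytic_var = (n + n + 1) / (12 * n * n)
        assert aucs.var() == pytest.approx(analytic_var, rel=0.10)


class TestValueSampling:
    def test_uniform_map_values(self, small_geom):
        rec = build_recording([10.0, 50.0, 90.0], [10.0, 50.0, 90.0],
                              geometry=small_geom)
        vals = sample_gazed_values(uniform_map(), rec)
        np.testing.assert_allclose(vals, 1 / 10_000)

    def test_invalid_samples_contribute_nothing(self, small_geom):
        rec = build_recording([10.0] * 6, [10.0] * 6,
                              valid=[True, False, True, False, False, True],
                              geometry=small_geom)
        assert sample_gazed_values(uniform_map(), rec).size == 3

    def test_bump_center_has_maximal_value(self, small_geom):
        vals = np.zeros((100, 100))
        vals[40, 60] = 1.0
        pmap = PredictorMap(values=vals, provenance="test")
        rec = build_recording([60.0], [40.0], geometry=small_geom)
        assert sample_gazed_values(pmap, rec)[0] == pmap.values.max()

    def test_single_pixel_pool(self, small_geom):
        other = build_recording(np.full(30, 25.0), np.full(30, 75.0),
                                geometry=small_geom, image_id="other")
        vals = np.arange(10_000, dtype=float).reshape(100, 100)
        pmap = PredictorMap(values=vals, provenance="test")
        drawn, replaced = sample_nongazed_values(pmap, [other], 10, seed=0)
        assert np.unique(drawn).size == 1
        assert not replaced

    def test_seed_reproducibility_and_uniqueness(self, small_geom):
        rng = np.random.default_rng(5)
        other = build_recording(rng.permutation(100).astype(float),
                                rng.permutation(100).astype(float),
                                geometry=small_geom, image_id="other")
        # injective map values let us check location uniqueness
        vals = np.arange(1, 10_001, dtype=float).reshape(100, 100)
        pmap = PredictorMap(values=vals, provenance="test")
        a, _ = sample_nongazed_values(pmap, [other], 50, seed=42)
        b, _ = sample_nongazed_values(pmap, [other], 50, seed=42)
        c, _ = sample_nongazed_values(pmap, [other], 50, seed=43)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.unique(a).size == 50  # drawn without replacement

    def test_oversized_request_switches_to_replacement(self, small_geom):
        other = build_recording([10.0, 20.0, 30.0], [10.0, 20.0, 30.0],
                                geometry=small_geom, image_id="other")
        _, replaced = sample_nongazed_values(uniform_map(), [other], 10, seed=1)
        assert replaced

    def test_empty_pool_rejected(self, small_geom):
        other = build_recording([10.0], [10.0], valid=[False],
                                geometry=small_geom, image_id="other")
        with pytest.raises(ValueError):
            sample_nongazed_values(uniform_map(), [other], 5, seed=0)


class TestDerangement:
    @pytest.mark.parametrize("n", [2, 3, 7, 20])
    def test_no_fixed_points_and_bijective(self, n):
        items = [f"img{i}" for i in range(n)]
        d = derangement(items, np.random.default_rng(0))
        assert set(d) == set(d.values()) == set(items)
        assert all(k != v for k, v in d.items())

    def test_two_items_must_swap(self):
        d = derangement(["a", "b"], np.random.default_rng(1))
        assert d == {"a": "b", "b": "a"}


class TestPooledAUC:
    def test_map_driven_gaze_beats_chance(self, small_session):
        res = auc_per_participant(small_session.truth.maps,
                                  small_session.recordings, seed=0)
        assert len(res) == 4
        assert all(r.auc > 0.5 for r in res)

    def test_uniform_map_is_exactly_chance(self, small_session):
        flat = {img: PredictorMap(values=np.ones((800, 800)), provenance="uniform")
                for img in small_session.truth.maps}
        res = auc_per_participant(flat, small_session.recordings, seed=0)
        assert all(r.auc == 0.5 for r in res)

    def test_single_participant_dataset_per_image_pooling(self, small_session):
        pid = small_session.recordings[0].participant_id
        solo = [r for r in small_session.recordings if r.participant_id == pid]
        per_img = auc_per_image(small_session.truth.maps, solo, seed=0)
        assert all(r.pooling == "per_image" for r in per_img)
        assert all(0 <= r.auc <= 1 for r in per_img)

    def test_participant_with_one_image_skipped(self, small_session, small_geom):
        rec = build_recording([50.0] * 20, [50.0] * 20, geometry=small_geom,
                              participant_id="lonely", image_id="only")
        with pytest.warns(UserWarning, match="lonely"):
            res = auc_per_participant({"only": uniform_map()}, [rec], seed=0)
        assert res == []

    def test_identical_maps_make_shuffle_a_no_op(self, small_session):
        flat_vals = next(iter(small_session.truth.maps.values())).values
        same = {img: PredictorMap(values=flat_vals.copy(), provenance="same")
                for img in small_session.truth.maps}
        actual = auc_per_participant(same, small_session.recordings, seed=3)
        shuffled = shuffled_control(same, small_session.recordings, seed=3)
        for a, s in zip(actual, shuffled):
            assert a.auc == pytest.approx(s.auc, abs=1e-12)
            assert s.condition == "shuffled"

    def test_shuffled_control_sits_at_chance(self, small_session):
        res = shuffled_control(small_session.truth.maps,
                               small_session.recordings, seed=1)
        mean = np.mean([r.auc for r in res])
        assert 0.4 < mean < 0.6


class TestPartitionedAUC:
    def test_time_bins_conserve_gazed_counts(self, small_session):
        whole = auc_per_participant(small_session.truth.maps,
                                    small_session.recordings, seed=2)
        binned = time_binned_auc(small_session.truth.maps,
                                 small_session.recordings, seed=2)
        whole_by_pid = {r.participant_id: r.n_gazed for r in whole}
        for pid, total in whole_by_pid.items():
            parts = sum(r.n_gazed for r in binned if r.participant_id == pid)
            assert parts == total

    def test_central_start_suppresses_first_interval(self, small_session):
        binned = time_binned_auc(small_session.truth.maps,
                                 small_session.recordings, seed=2)
        i1 = np.mean([r.auc for r in binned if r.partition == "interval_1"])
        i2 = np.mean([r.auc for r in binned if r.partition == "interval_2"])
        assert abs(i1 - 0.5) < 0.05
        assert i2 > 0.55

    def test_foveation_samples_predicted_best(self, nystagmus_session):
        # with jerk nystagmus the slow phase starts on target, so low-velocity
        # samples sit nearer map peaks and AUC falls with the velocity quantile
        res = velocity_binned_auc(nystagmus_session.truth.maps,
                                  nystagmus_session.recordings, seed=2)
        means = []
        for q in range(1, 11):
            vals = [r.auc for r in res if r.partition == f"velocity_q{q}"]
            means.append(np.mean(vals))
        rho, _ = spearmanr(np.arange(1, 11), means)
        assert rho < -0.5

    def test_velocity_independent_placement_has_no_trend(self, truth_maps, geom):
        # positions drawn iid from the map: every sample shares one marginal,
        # so no quantile can be better than another beyond sampling noise
        rng = np.random.default_rng(11)
        recs = []
        for pid in ("a", "b", "c", "d"):
            for m in truth_maps:
                flat = m.values.ravel().cumsum()
                idx = np.searchsorted(flat / flat[-1], rng.random(4000))
                iy, ix = np.unravel_index(np.minimum(idx, flat.size - 1),
                                          m.values.shape)
                recs.append(build_recording(
                    ix.astype(float), iy.astype(float), geometry=geom,
                    participant_id=pid, image_id=m.image_id))
        maps = {m.image_id: m for m in truth_maps}
        res = velocity_binned_auc(maps, recs, seed=4)
        means = [np.mean([r.auc for r in res if r.partition == f"velocity_q{q}"])
                 for q in range(1, 11)]
        assert max(means) - min(means) < 0.05

    def test_velocity_quantiles_near_equal_sizes(self, nystagmus_session):
        res = velocity_binned_auc(nystagmus_session.truth.maps,
                                  nystagmus_session.recordings, seed=2)
        pid = res[0].participant_id
        counts = [r.n_gazed for r in res if r.participant_id == pid]
        # equal-size quantiles minus validity masking at trace edges
        assert max(counts) - min(counts) < 0.2 * max(counts)
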