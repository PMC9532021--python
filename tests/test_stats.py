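"""Group-level model contracts: robust contrasts, mixed models, tests."""

import numpy as np
import pandas as pd
import pytest

from freegaze.stats import (
    best_recognition_model, compare_correlations, mixed_model, one_sample_test,
    paired_test, pearson_correlation, recognition_model, robust_group_contrasts,
)


def four_group_data(rng, offsets=(0, 0, 0, 0), n=8, sd=1.0):
    values, groups = [], []
    for g, off in zip(("CC", "SC", "DC", "NC"), offsets):
        values.extend(rng.normal(off, sd, n))
        groups.extend([g] * n)
    return np.array(values), np.array(groups)


class TestRobustContrasts:
    def test_noiseless_fit_matches_group_means_exactly(self):
        values = np.array([1.0] * 5 + [3.0] * 5 + [7.0] * 5)
        groups = np.array(["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        results = {c.contrast: c for c in robust_group_contrasts(values, groups)}
        assert results["A-B"].estimate == pytest.approx(-2.0, abs=1e-6)
        assert results["A-C"].estimate == pytest.approx(-6.0, abs=1e-6)
        assert results["B-C"].estimate == pytest.approx(-4.0, abs=1e-6)

    def test_four_groups_give_six_contrasts_at_bonferroni_level(self):
        rng = np.random.default_rng(0)
        values, groups = four_group_data(rng)
        results = robust_group_contrasts(values, groups)
        assert len(results) == 6
        assert all(c.corrected_alpha == pytest.approx(0.05 / 6) for c in results)

    @pytest.mark.parametrize("seed", range(3))
    def test_large_offset_detected(self, seed):
        rng = np.random.default_rng(seed)
        values, groups = four_group_data(rng, offsets=(0, 5, 0, 0))
        results = {c.contrast: c for c in robust_group_contrasts(values, groups)}
        assert results["CC-SC"].significant

    def test_null_groups_mostly_quiet(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            values, groups = four_group_data(rng)
            res = robust_group_contrasts(values, groups)
            hits += all(abs(c.estimate) < 2.5 * c.se for c in res)
        assert hits >= 4

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            robust_group_contrasts([1.0, 2.0, 3.0], ["A", "A", "B"])


def interval_frame(rng, slopes=(0.0, -0.02), n_per_group=6, re_sd=0.05,
                   noise_sd=0.02):
    rows = []
    for g, slope in zip(("A", "B"), slopes):
        for p in range(n_per_group):
            intercept = 0.7 + rng.normal(0, re_sd)
            for interval in range(2, 9):
                rows.append({
                    "participant": f"{g}{p}", "group": g, "interval": interval,
                    "value": intercept + slope * interval + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_interaction_slope_recovered_with_correct_sign(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            frame = interval_frame(rng)
            res = mixed_model(frame, "value ~ C(group) * interval")
            assert res["C(group)[T.B]:interval"] < 0
            assert res.pvalues["C(group)[T.B]:interval"] < 0.05

    def test_null_covariate_confidence_covers_zero(self):
        covered = 0
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            frame = interval_frame(rng, slopes=(0.0, 0.0))
            res = mixed_model(frame, "value ~ interval")
            est, se = res["interval"], float(res.se["interval"])
            covered += abs(est) < 2 * se
        assert covered >= 4

    def test_zero_between_participant_variance_flags_singular(self):
        rows = [{"participant": f"p{p}", "interval": i,
                 "value": 0.1 * i + 1e-6 * ((p + i) % 3)}
                for p in range(4) for i in range(6)]
        res = mixed_model(pd.DataFrame(rows), "value ~ interval")
        assert res.singular or res.random_intercept_var < 1e-6

    def test_participants_need_two_rows(self):
        frame = pd.DataFrame({"participant": ["a", "b"], "value": [1.0, 2.0],
                              "interval": [1, 1]})
        with pytest.raises(ValueError):
            mixed_model(frame, "value ~ interval")


class TestLocationTests:
    def test_exact_equality_branch(self):
        res = one_sample_test([0.5, 0.5, 0.5, 0.5])
        assert res.exact_equality and res.statistic is None

    def test_shifted_aucs_reject_chance(self):
        rejections = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            res = one_sample_test(rng.normal(0.55, 0.02, 10))
            rejections += res.pvalue < 0.05
        assert rejections >= 4

    def test_paired_identical_vectors_are_zero(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean == 0.0 and res.exact_equality


class TestCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_independent_draws_stay_weak(self):
        weak = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            r, _ = pearson_correlation(rng.normal(size=49), rng.normal(size=49))
            weak += abs(r) < 0.4
        assert weak >= 4

    def test_equal_correlations_compare_nonsignificant(self):
        quiet = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x1 = rng.normal(size=40)
            y1 = 0.5 * x1 + rng.normal(size=40)
            x2 = rng.normal(size=40)
            y2 = 0.5 * x2 + rng.normal(size=40)
            r1, _ = pearson_correlation(x1, y1)
            r2, _ = pearson_correlation(x2, y2)
            quiet += compare_correlations(r1, 40, r2, 40).pvalue > 0.05
        assert quiet >= 4


def simulate_recognition(rng, b_auc=5.0, n_participants=12, n_images=28):
    acuity = {f"p{i}": rng.uniform(0, 1.4) for i in range(n_participants)}
    auc = {f"p{i}": rng.normal(0.6, 0.1) for i in range(n_participants)}
    pid, y = [], []
    for p in acuity:
        logit = -1.0 - 1.5 * acuity[p] + b_auc * auc[p]
        prob = 1 / (1 + np.exp(-logit))
        for _ in range(n_images):
            pid.append(p)
            y.append(int(rng.random() < prob))
    return y, pid, acuity, auc


class TestRecognitionModel:
    def test_all_correct_outcomes_flag_separation(self):
        y = [1] * 20
        pid = [f"p{i % 4}" for i in range(20)]
        acuity = {f"p{i}": 0.5 for i in range(4)}
        auc = {f"p{i}": 0.6 for i in range(4)}
        res = recognition_model(y, pid, acuity, auc)
        assert all(r.separation for r in res.values())

    def test_both_predictors_win_when_both_matter(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y, pid, acuity, auc = simulate_recognition(rng)
            res = recognition_model(y, pid, acuity, auc)
            wins += best_recognition_model(res) == "both"
            assert res["both"].tjur_r2 == res["both"].tjur_r2  # finite, not NaN
        assert wins >= 3

    def test_null_auc_effect_is_quiet(self):
        quiet = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            y, pid, acuity, auc = simulate_recognition(rng, b_auc=0.0)
            res = recognition_model(y, pid, acuity, auc)
            if not res["both"].separation:
                quiet += res["both"].pvalues["auc"] > 0.05
            else:
                quiet += 1
        assert quiet >= 4
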