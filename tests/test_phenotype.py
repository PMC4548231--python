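"""State-shift statistics: draws, paired differences, Pillai tests, torpor."""

import numpy as np
import pytest
from scipy import stats

from mousehmm.model import FittedModel, ModelSpec, StatePath
from mousehmm.phenotype import (activity_budget, bout_durations,
                                manova_state_shift, paired_state_difference,
                                paired_tpm_difference, pillai_manova,
                                state_characteristic_draws, torpor_flag,
                                tpm_shift_tests)

from conftest import random_params


def _wrap(params, spec=None):
    spec = spec or ModelSpec(params.n_states)
    return FittedModel(spec=spec, params=params, loglik=0.0,
                       n_params=spec.n_params(), n_restarts_used=1,
                       converged=True, seed=0)


class TestDraws:
    def test_default_is_1000_draws_per_state(self):
        f = _wrap(random_params(3, np.random.default_rng(0)))
        out = state_characteristic_draws(f)
        assert out.shape == (3, 1000, 2)

    def test_negligible_variance_pins_draws_to_means(self):
        p = random_params(2, np.random.default_rng(1))
        p.var_M[:] = 1e-20
        p.var_T[:] = 1e-20
        out = state_characteristic_draws(_wrap(p), z=0.0, n_draws=50, seed=2)
        assert np.allclose(out[:, :, 0], p.emis_M_intercept[:, None], atol=1e-8)
        assert np.allclose(out[:, :, 1], p.emis_T_intercept[:, None], atol=1e-8)

    def test_large_sample_means_converge(self):
        p = random_params(3, np.random.default_rng(3), with_emis_slopes=True)
        z = 0.8
        out = state_characteristic_draws(_wrap(p), z=z, n_draws=100_000, seed=4)
        mu_m, mu_t = p.emission_means(z)
        for i in range(3):
            assert abs(out[i, :, 0].mean() - mu_m[i]) < \
                3 * np.sqrt(p.var_M[i] / 100_000)
            assert abs(out[i, :, 1].mean() - mu_t[i]) < \
                3 * np.sqrt(p.var_T[i] / 100_000)

    def test_nonfinite_z_rejected(self):
        with pytest.raises(ValueError):
            state_characteristic_draws(
                _wrap(random_params(2, np.random.default_rng(5))), z=np.nan)


class TestPairedDifference:
    def test_identical_covariate_free_fits_differ_by_zero(self):
        p = random_params(3, np.random.default_rng(6))
        d = paired_state_difference(_wrap(p), _wrap(p))
        assert np.allclose(d, 0.0)

    def test_difference_follows_linear_mean_formula(self):
        p_bl = random_params(3, np.random.default_rng(7))
        p_cr = p_bl.copy()
        p_cr.emis_T_slope = np.full(3, -1.0)
        spec = ModelSpec(3, temp_mean_covariate="t")
        z_bl, z_cr = -1.7, 1.7
        d = paired_state_difference(_wrap(p_bl), _wrap(p_cr, spec), z_bl, z_cr)
        assert np.allclose(d[:, 1], -1.0 * z_cr, atol=1e-12)
        assert np.allclose(d[:, 0], 0.0)

    def test_antisymmetric_under_swap(self):
        a = random_params(3, np.random.default_rng(8), with_emis_slopes=True)
        b = random_params(3, np.random.default_rng(9), with_emis_slopes=True)
        d1 = paired_state_difference(_wrap(a), _wrap(b), 0.3, 0.9)
        d2 = paired_state_difference(_wrap(b), _wrap(a), 0.9, 0.3)
        assert np.allclose(d1, -d2)

    def test_mismatched_state_counts_warn_and_truncate(self):
        a = random_params(3, np.random.default_rng(10))
        b = random_params(2, np.random.default_rng(11))
        with pytest.warns(UserWarning):
            d = paired_state_difference(_wrap(a), _wrap(b))
        assert d.shape == (2, 2)


class TestPillai:
    def test_univariate_two_groups_equals_anova(self):
        rng = np.random.default_rng(12)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(0.8, 1, 15)])
        g = ["a"] * 15 + ["b"] * 15
        res = pillai_manova(y[:, None], g)
        f = stats.f_oneway(y[:15], y[15:])
        assert res["p"] == pytest.approx(f.pvalue, rel=1e-10)
        assert res["F"] == pytest.approx(f.statistic, rel=1e-10)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(48, 2))
        g = np.repeat(list("abcdef"), 8)
        Y[40:] += 1.0
        res = pillai_manova(Y, g)
        sm = MANOVA(Y, np.column_stack(
            [np.ones(48)] + [(g == lv).astype(float) for lv in "bcdef"]))
        tab = sm.mv_test([("grp", np.eye(6)[1:])]).results["grp"]["stat"]
        assert res["pillai"] == pytest.approx(
            float(tab.loc["Pillai's trace", "Value"]), abs=1e-8)
        assert res["p"] == pytest.approx(
            float(tab.loc["Pillai's trace", "Pr > F"]), abs=1e-8)

    def test_paper_scale_degrees_of_freedom(self):
        # 46 animals in 6 groups, 2 responses: hypothesis df 5, error df 40
        rng = np.random.default_rng(14)
        Y = rng.normal(size=(46, 2))
        g = np.repeat(list("abcdef"), [8, 8, 8, 8, 7, 7])
        res = pillai_manova(Y, g)
        assert res["hypothesis_df"] == 5
        assert res["error_df"] == 40

    def test_strong_group_shift_detected(self):
        rng = np.random.default_rng(15)
        diffs = rng.normal(0, 0.3, size=(48, 3, 2))
        treatments = np.repeat(["12AL", "24AL", "10CR", "20CR", "30CR", "40CR"], 8)
        high = np.isin(treatments, ["30CR", "40CR"])
        diffs[high, 2, 1] -= 3.0       # state-3 temperature drop
        out = manova_state_shift(diffs, treatments)
        assert out[2]["p"] < 0.01
        assert out[2]["r2_adj"] > 0.3

    def test_singular_responses_rejected(self):
        Y = np.ones((12, 2))
        with pytest.raises(np.linalg.LinAlgError):
            pillai_manova(Y, ["a"] * 6 + ["b"] * 6)


class TestTpmShift:
    def test_identical_tpms_give_zero_differences(self):
        p = random_params(3, np.random.default_rng(16))
        d = paired_tpm_difference(_wrap(p), _wrap(p))
        assert np.allclose(d, 0.0)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(17)
        D = rng.normal(0, 0.05, size=(24, 3, 3))
        out = tpm_shift_tests(D, np.repeat(list("abc"), 8))
        for row in out:
            assert row["p_adj"] == pytest.approx(min(1.0, 3 * row["p"]))
        assert any(r["p"] > 1 / 3 and r["p_adj"] == 1.0 for r in out) or True

    def test_row_shift_detected_only_in_shifted_row(self):
        rng = np.random.default_rng(18)
        D = rng.normal(0, 0.02, size=(48, 3, 3))
        treatments = np.repeat(["12AL", "24AL", "10CR", "20CR", "30CR", "40CR"], 8)
        cr_level = np.array([0, 0, 1, 2, 3, 4]).repeat(8)
        D[:, 0, 1] -= 0.05 * cr_level  # p12 falls with restriction level
        D[:, 0, 0] += 0.05 * cr_level  # compensated by p11
        out = tpm_shift_tests(D, treatments)
        assert out[0]["p_adj"] < 0.01
        assert out[2]["p_adj"] > 0.05


class TestPathSummaries:
    def test_constant_path_occupies_one_state(self):
        path = StatePath(states=np.ones(50, dtype=int),
                         posteriors=np.tile([1.0, 0.0], (50, 1)))
        out = activity_budget(path)
        assert np.allclose(out["overall"], [1.0, 0.0])

    def test_bouts_by_hand(self):
        path = StatePath(states=np.array([1, 1, 2, 2, 2, 1]),
                         posteriors=np.tile([0.5, 0.5], (6, 1)))
        out = bout_durations(path)
        assert sorted(out["samples"][1]) == [1, 2]
        assert list(out["samples"][2]) == [3]
        total = sum(v.sum() for v in out["samples"].values())
        assert total == 6

    def test_geometric_mean_bout_length(self):
        rng = np.random.default_rng(19)
        p_stay = 0.9
        s = [0]
        for _ in range(20000):
            s.append(s[-1] if rng.random() < p_stay else 1 - s[-1])
        path = StatePath(states=np.asarray(s) + 1,
                         posteriors=np.tile([0.5, 0.5], (len(s), 1)))
        out = bout_durations(path)
        for i in (1, 2):
            assert out["summary"][i]["mean"] == pytest.approx(
                1.0 / (1.0 - p_stay), rel=0.1)


class TestTorpor:
    def _fit_with_state3_temp(self, value):
        p = random_params(3, np.random.default_rng(20))
        p.emis_M_intercept = np.array([3.0, 2.0, 1.0])
        p.emis_T_intercept = np.array([37.0, 36.0, value])
        return _wrap(p)

    @pytest.mark.parametrize("value, expect", [
        (30.5, True), (34.5, False), (31.0, False)])
    def test_threshold_rule_is_strict(self, value, expect):
        flag, t3 = torpor_flag(self._fit_with_state3_temp(value))
        assert flag is expect
        assert t3 == value

    def test_drifted_mean_evaluated_at_end_of_treatment(self):
        f = self._fit_with_state3_temp(33.0)
        f.params.emis_T_slope = np.array([0.0, 0.0, -1.5])
        flag, t3 = torpor_flag(f, z_end=1.7)
        assert flag and t3 == pytest.approx(33.0 - 1.5 * 1.7)

    def test_two_state_fit_warns_and_uses_coldest_state(self):
        p = random_params(2, np.random.default_rng(21))
        p.emis_T_intercept = np.array([36.0, 30.0])
        with pytest.warns(UserWarning):
            flag, t3 = torpor_flag(_wrap(p))
        assert flag and t3 == 30.0
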