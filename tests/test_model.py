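"""Core model types: transforms, tpm link, emission density, serialisation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mousehmm.model import (FittedModel, HMMParameters, ModelSpec,
                            ValidationError, destandardize_covariate,
                            emission_logpdf, log_movement,
                            standardize_covariate, tpm_at)

from conftest import make_series, random_params


class TestLogMovement:
    def test_zero_count_maps_to_zero(self):
        assert log_movement(0) == 0.0

    def test_natural_log_of_count_plus_one(self):
        assert log_movement(6) == pytest.approx(np.log(7.0), abs=1e-12)
        assert log_movement(6) == pytest.approx(1.9459, abs=1e-4)

    def test_missing_propagates(self):
        assert np.isnan(log_movement(np.nan))
        out = log_movement([1.0, np.nan, 0.0])
        assert np.isnan(out[1]) and out[2] == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            log_movement(-1)


class TestStandardize:
    def test_symmetric_case(self):
        z, c, s = standardize_covariate([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert (c, s) == (2.0, 1.0)

    def test_two_points_use_sample_sd(self):
        z, _, s = standardize_covariate([10.0, 20.0])
        assert np.allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)])
        assert s == pytest.approx(np.sqrt(50.0))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            standardize_covariate([5.0, 5.0, 5.0])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_zero_mean_and_roundtrip(self, vals):
        if np.std(vals, ddof=1) < 1e-9:
            return
        z, c, s = standardize_covariate(vals)
        assert abs(np.mean(z)) < 1e-9
        assert np.allclose(destandardize_covariate(z, c, s), vals, atol=1e-8)


class TestTpm:
    def test_zero_logits_give_uniform_rows(self):
        p = random_params(3, np.random.default_rng(0))
        p.trans_intercepts[:] = 0.0
        p.trans_slopes[:] = 0.0
        assert np.allclose(tpm_at(p, 0.7), np.full((3, 3), 1 / 3))

    def test_covariate_free_matrix_ignores_z(self):
        p = random_params(3, np.random.default_rng(1))
        assert np.allclose(tpm_at(p, -5.0), tpm_at(p, 5.0))

    def test_two_state_softmax_by_hand(self):
        # diagonal (self-transition) is the reference: off-diagonal logit
        # -log 4 makes staying 4x as likely as leaving
        p = random_params(2, np.random.default_rng(2))
        p.trans_intercepts[0, 0] = -np.log(4.0)
        P = tpm_at(p, 0.0)
        assert P[0, 0] == pytest.approx(0.8, abs=1e-12)
        assert P[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_rows_sum_to_one_over_random_draws(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(2, 4))
            p = random_params(n, rng, with_tpm_slopes=True)
            P = tpm_at(p, float(rng.normal(0, 2)))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)


class TestEmission:
    def test_density_at_means_unit_variance(self):
        p = random_params(2, np.random.default_rng(3))
        p.var_M[:] = 1.0
        p.var_T[:] = 1.0
        val = emission_logpdf(p, 1, p.emis_M_intercept[0], p.emis_T_intercept[0])
        assert val == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)), abs=1e-12)

    def test_both_channels_missing_contribute_log_one(self):
        p = random_params(2, np.random.default_rng(4))
        assert emission_logpdf(p, 2, np.nan, np.nan) == 0.0

    def test_closed_form_matches_scipy(self):
        p = random_params(2, np.random.default_rng(5))
        p.emis_M_intercept[0], p.emis_T_intercept[0] = 1.5, 36.5
        p.var_M[0] = p.var_T[0] = 0.25
        expected = (stats.norm.logpdf(1.0, 1.5, 0.5)
                    + stats.norm.logpdf(36.0, 36.5, 0.5))
        assert emission_logpdf(p, 1, 1.0, 36.0, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_maximised_exactly_at_state_means(self):
        p = random_params(3, np.random.default_rng(6), with_emis_slopes=True)
        for z in (-1.0, 0.0, 2.0):
            mu_m = p.emis_M_intercept[1] + p.emis_M_slope[1] * z
            mu_t = p.emis_T_intercept[1] + p.emis_T_slope[1] * z
            peak = emission_logpdf(p, 2, mu_m, mu_t, z)
            for dm in np.linspace(-2, 2, 9):
                for dt in np.linspace(-2, 2, 9):
                    if dm == 0 and dt == 0:
                        continue
                    assert emission_logpdf(p, 2, mu_m + dm, mu_t + dt, z) < peak

    def test_invalid_state_rejected(self):
        p = random_params(2, np.random.default_rng(7))
        with pytest.raises(ValidationError):
            emission_logpdf(p, 3, 1.0, 36.0)


class TestModelSpec:
    def test_mixed_covariates_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(3, tpm_covariate="t", movement_mean_covariate="BW")

    @pytest.mark.parametrize("kw, cls", [
        (dict(), "HMM1"),
        (dict(movement_mean_covariate="t"), "HMM2"),
        (dict(temp_mean_covariate="BW"), "HMM3"),
        (dict(tpm_covariate="t"), "HMM4"),
        (dict(tpm_covariate="BW"), "HMM5"),
        (dict(tpm_covariate="t", temp_mean_covariate="t"), "HMM2+4"),
        (dict(tpm_covariate="BW", movement_mean_covariate="BW"), "HMM3+5"),
    ])
    def test_model_class_from_placement(self, kw, cls):
        assert ModelSpec(3, **kw).model_class == cls

    def test_parameter_count_three_state_base(self):
        # 2 (pi) + 6 (trans logits) + 3*(2 means + 2 vars) = 20
        assert ModelSpec(3).n_params() == 20

    def test_parameter_count_with_covariates(self):
        assert ModelSpec(3, tpm_covariate="t").n_params() == 20 + 6
        assert ModelSpec(2, movement_mean_covariate="BW",
                         temp_mean_covariate="BW").n_params() == \
            1 + 2 + 2 * (2 + 2 + 2)


class TestSeriesInvariants:
    def test_nonuniform_grid_rejected(self):
        s = make_series([1, 2, 3], [36, 36, 36])
        ts = s.timestamps.copy()
        ts[2] += np.timedelta64(5, "m")
        with pytest.raises(ValidationError):
            make_series([1, 2, 3], [36, 36, 36]).__class__(
                animal_id="x", treatment="12AL", period="BL", timestamps=ts,
                movement_count=s.movement_count, temp_median=s.temp_median,
                body_weight=s.body_weight, light_phase=s.light_phase)

    def test_negative_movement_rejected(self):
        with pytest.raises(ValidationError):
            make_series([-1, 2, 3], [36, 36, 36])


class TestFittedModelJSON:
    def test_roundtrip_preserves_everything(self):
        p = random_params(3, np.random.default_rng(8), with_tpm_slopes=True,
                          with_emis_slopes=True)
        spec = ModelSpec(3, tpm_covariate="t", movement_mean_covariate="t",
                         temp_mean_covariate="t", name="HMM3.12")
        fm = FittedModel(spec=spec, params=p, loglik=-123.45,
                         n_params=spec.n_params(), n_restarts_used=10,
                         converged=True, seed=7, covariate_center=4319.5,
                         covariate_scale=2494.0)
        back = FittedModel.from_json(fm.to_json())
        assert back.spec == fm.spec
        assert back.aic == pytest.approx(fm.aic)
        for f in ("pi", "trans_intercepts", "trans_slopes", "emis_M_intercept",
                  "var_T"):
            assert np.allclose(getattr(back.params, f), getattr(p, f))

    def test_aic_identity(self):
        p = random_params(2, np.random.default_rng(9))
        fm = FittedModel(spec=ModelSpec(2), params=p, loglik=-50.0,
                         n_params=11, n_restarts_used=1, converged=True, seed=0)
        assert fm.aic == -2 * (-50.0) + 2 * 11
        assert json.loads(fm.to_json())["aic"] == fm.aic
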