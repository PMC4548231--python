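"""Post-fit model checking.

Two complementary checks are implemented.  First, forecast pseudo-residuals:
each observation is passed through its one-step-ahead forecast CDF — the
forward-filtered (past-only) state-probability mixture of that channel's
normal CDFs — and mapped to the normal quantile scale.  Under a correct
model these residuals are iid standard normal, which quantile-quantile
summaries make inspectable.  Second, an emergent-diurnality check: the
fitted models are phase-blind, so any light/dark difference in the decoded
activity budget must come from structure the model recovered from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (FittedModel, TelemetrySeries, ValidationError,
                    emission_loglik_matrix, tpm_sequence)
from .inference import _forward
from .model import StatePath

__all__ = ["pseudo_residuals", "qq_summary", "diurnal_budget_check",
           "PseudoResiduals"]

_CLAMP = 1e-12


@dataclass
class PseudoResiduals:
    """Per-channel forecast pseudo-residuals (NaN at missing steps)."""

    movement: np.ndarray
    temperature: np.ndarray
    clamped: int          # how many forecast CDF values hit the [eps, 1-eps] clamp


def _forecast_weights(fitted: FittedModel, series: TelemetrySeries):
    """(T, n) predicted state probabilities before seeing each observation."""
    spec = fitted.spec
    params = fitted.params
    raw = series.covariate_values(spec.covariate)
    z = fitted.standardize(raw) if spec.covariate != "none" else raw
    logb = emission_loglik_matrix(params, series.log_movement,
                                  series.temp_median, z)
    tpms = tpm_sequence(params, z if spec.tpm_covariate != "none"
                        else np.zeros(len(series)))
    alpha, _, _, _ = _forward(logb, tpms, params.pi)
    w = np.empty_like(alpha)
    w[0] = params.pi
    if len(series) > 1:
        w[1:] = np.einsum("ti,tij->tj", alpha[:-1], tpms[1:])
    return w, z


def pseudo_residuals(fitted: FittedModel, series: TelemetrySeries) -> PseudoResiduals:
    """Normal-quantile residuals of each channel's one-step forecast CDF.

    Residuals use filtered probabilities only, so an outlier late in the
    series cannot alter earlier residuals.  CDF values that are numerically
    0 or 1 are clamped and counted.
    """
    params = fitted.params
    w, z = _forecast_weights(fitted, series)
    out = {}
    clamped = 0
    mu_m, mu_t = params.emission_means(z)
    for key, x, mu, var in (("movement", series.log_movement, mu_m, params.var_M),
                            ("temperature", series.temp_median, mu_t, params.var_T)):
        u = np.full(len(series), np.nan)
        obs = np.isfinite(x)
        if obs.any():
            zscore = (x[obs, None] - mu[obs]) / np.sqrt(var)[None, :]
            cdf = np.sum(w[obs] * stats.norm.cdf(zscore), axis=1)
            n_clamp = int(np.sum((cdf < _CLAMP) | (cdf > 1 - _CLAMP)))
            clamped += n_clamp
            u[obs] = stats.norm.ppf(np.clip(cdf, _CLAMP, 1 - _CLAMP))
        out[key] = u
    return PseudoResiduals(movement=out["movement"],
                           temperature=out["temperature"], clamped=clamped)


def qq_summary(residuals: np.ndarray) -> dict:
    """Quantile-quantile pairing of residuals against N(0, 1).

    Uses plotting positions (k - 0.5)/n and reports the QQ correlation as a
    scalar goodness summary.  Requires at least 30 non-missing residuals.
    """
    r = np.asarray(residuals, dtype=float)
    r = np.sort(r[np.isfinite(r)])
    if r.size < 30:
        raise ValidationError("need at least 30 non-missing residuals")
    theo = stats.norm.ppf((np.arange(1, r.size + 1) - 0.5) / r.size)
    corr = float(np.corrcoef(theo, r)[0, 1])
    return {"theoretical": theo, "empirical": r, "correlation": corr}


def diurnal_budget_check(path: StatePath, series: TelemetrySeries) -> dict:
    """Decoded state budgets by light phase and their total-variation distance.

    The fitted models carry no light/dark structure, so a clear phase
    difference in the decoded budget is emergent evidence the states are
    biologically meaningful.
    """
    n = path.posteriors.shape[1]
    light = series.light_phase.astype(bool)
    budgets = {}
    for name, mask in (("light", light), ("dark", ~light)):
        if not mask.any():
            raise ValidationError(f"series has no {name}-phase steps")
        s = path.states[mask]
        budgets[name] = np.array([(s == i + 1).mean() for i in range(n)])
    tv = 0.5 * float(np.abs(budgets["light"] - budgets["dark"]).sum())
    return {"light": budgets["light"], "dark": budgets["dark"],
            "tv_distance": tv}
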