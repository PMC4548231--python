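"""Maximum-likelihood fitting by EM with random restarts.

The E-step is the exact forward-backward recursion; the M-step maximises the
expected complete-data log-likelihood separately for the prior (initial
distribution), the transition parameters, and the response (emission)
parameters.  With a covariate on the transition matrix the row-wise M-step is
a weighted multinomial-logit regression on the expected transition counts,
solved by damped Newton iterations; without one it reduces to row-normalised
expected counts.  Emission means are gamma-weighted least squares on
``[1, z]`` per state and channel; variances are gamma-weighted mean squared
residuals with a small floor guarding against degenerate spikes.
"""

from __future__ import annotations

import numpy as np

from .model import (FittedModel, HMMParameters, ModelSpec, TelemetrySeries,
                    ValidationError, emission_loglik_matrix,
                    standardized_covariate_for, tpm_sequence)
from .inference import _forward_backward_arrays, _forward

__all__ = ["init_params", "em_fit", "relabel_states", "EMFailure"]

VAR_FLOOR = 1e-6
DEGENERATE_MASS = 1e-6


class EMFailure(RuntimeError):
    """All restarts of an EM fit failed."""


def _restart_seed(seed: int, r: int) -> int:
    return int((seed * 100003 + 7919 * r + 1) % (2 ** 31))


def init_params(spec: ModelSpec, series: TelemetrySeries, seed: int) -> HMMParameters:
    """Random, symmetry-breaking starting values.

    Emission intercepts are drawn around channel quantiles spread across the
    states (so a 3-state start straddles low/middle/high observations),
    slopes start at zero, variances at the channel sample variance, and the
    transition logits at small random values.  The same seed always yields
    the same start.
    """
    n = spec.n_states
    if len(series) < 10 * n:
        raise ValidationError(f"series too short to fit {n} states")
    rng = np.random.default_rng(seed)
    logm = series.log_movement
    temp = series.temp_median
    params = {}
    for key, x in (("M", logm), ("T", temp)):
        obs = x[np.isfinite(x)]
        if obs.size < 2:
            raise ValidationError("a channel has fewer than 2 observations")
        q = (np.arange(n) + 0.5) / n + rng.uniform(-0.4 / n, 0.4 / n, size=n)
        q = np.clip(q, 0.02, 0.98)
        params[key] = (np.quantile(obs, q), np.full(n, max(np.var(obs), 10 * VAR_FLOOR)))
    order = rng.permutation(n)
    return HMMParameters(
        n_states=n,
        pi=np.full(n, 1.0 / n),
        trans_intercepts=rng.normal(0.0, 0.3, size=(n, n - 1)),
        trans_slopes=np.zeros((n, n - 1)),
        emis_M_intercept=params["M"][0][order],
        emis_M_slope=np.zeros(n),
        emis_T_intercept=params["T"][0][order],
        emis_T_slope=np.zeros(n),
        var_M=params["M"][1],
        var_T=params["T"][1],
    )


def _logits_from_tpm(P: np.ndarray):
    """Off-diagonal multinomial logits (diagonal reference) from a tpm."""
    n = P.shape[0]
    P = np.clip(P, 1e-10, None)
    out = np.empty((n, n - 1))
    for i in range(n):
        cols = [j for j in range(n) if j != i]
        out[i] = np.log(P[i, cols]) - np.log(P[i, i])
    return out


def _row_probs(a, b, z):
    """Off-diagonal destination probs p_j(z) for one row; also p_ref.

    a, b: (K,) logits; z: (T,).  Returns (T, K) off-diagonal probs and (T,)
    reference (self-transition) probs.
    """
    logits = a[None, :] + np.outer(z, b)             # (T, K)
    m = np.maximum(logits.max(axis=1), 0.0)
    e = np.exp(logits - m[:, None])
    e0 = np.exp(-m)
    denom = e0 + e.sum(axis=1)
    return e / denom[:, None], e0 / denom


def _fit_trans_row(a0, b0, z, w_off, w_ref, fit_slope,
                   tol=1e-9, max_iter=50):
    """Weighted multinomial-logit M-step for one transition row.

    ``w_off`` (T, K) are expected off-diagonal transition counts at each
    step, ``w_ref`` (T,) the expected self-transitions.  Maximises
    sum_t sum_j w_tj log p_j(z_t) by damped Newton; returns (a, b).
    """
    K = len(a0)
    a, b = a0.copy(), b0.copy()
    W = w_off.sum(axis=1) + w_ref                    # (T,)

    def objective(a, b):
        p_off, p_ref = _row_probs(a, b, z)
        return (np.sum(w_off * np.log(np.clip(p_off, 1e-300, None)))
                + np.sum(w_ref * np.log(np.clip(p_ref, 1e-300, None))))

    obj = objective(a, b)
    npar = 2 * K if fit_slope else K
    for _ in range(max_iter):
        p_off, _ = _row_probs(a, b, z)
        resid = w_off - W[:, None] * p_off           # (T, K)
        g_a = resid.sum(axis=0)
        grad = np.concatenate([g_a, z @ resid]) if fit_slope else g_a
        # Hessian blocks: -sum_t W_t x x' (x) (diag(p) - p p')
        Wp = W[:, None] * p_off
        S0 = np.diag(Wp.sum(axis=0)) - p_off.T @ Wp
        if fit_slope:
            zp = z[:, None] * p_off
            S1 = np.diag((z[:, None] * Wp).sum(axis=0)) - zp.T @ Wp
            S2 = np.diag((z[:, None] ** 2 * Wp).sum(axis=0)) - zp.T @ (z[:, None] * Wp)
            H = np.block([[S0, S1], [S1.T, S2]])
        else:
            H = S0
        H = H + 1e-10 * np.eye(npar)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _half in range(20):
            a_new = a + scale * step[:K]
            b_new = b + scale * step[K:] if fit_slope else b
            obj_new = objective(a_new, b_new)
            if obj_new >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            break
        improved = obj_new - obj
        a, b, obj = a_new, b_new, obj_new
        if improved < tol * (abs(obj) + 1.0) and np.abs(grad).max() < 1e-6:
            break
        if improved < tol:
            break
    return a, b


def _m_step(params: HMMParameters, spec: ModelSpec, gamma, xi, z,
            logm, temp) -> HMMParameters:
    n = spec.n_states
    new = params.copy()
    new.pi = gamma[0] / gamma[0].sum()

    # -- transitions ---------------------------------------------------------
    if spec.tpm_covariate == "none":
        counts = xi.sum(axis=0)
        counts = np.clip(counts, 1e-12, None)
        P = counts / counts.sum(axis=1, keepdims=True)
        new.trans_intercepts = _logits_from_tpm(P)
        new.trans_slopes = np.zeros_like(new.trans_intercepts)
    else:
        zt = z[1:]                                   # covariate governing t-1 -> t
        for i in range(n):
            cols = [j for j in range(n) if j != i]
            a, b = _fit_trans_row(params.trans_intercepts[i],
                                  params.trans_slopes[i], zt,
                                  xi[:, i, cols], xi[:, i, i], fit_slope=True)
            new.trans_intercepts[i] = a
            new.trans_slopes[i] = b

    # -- emissions -----------------------------------------------------------
    for key, x, cov in (("M", logm, spec.movement_mean_covariate),
                        ("T", temp, spec.temp_mean_covariate)):
        obs = np.isfinite(x)
        xo, zo = x[obs], z[obs]
        go = gamma[obs]
        ic = np.empty(n)
        sl = np.zeros(n)
        var = np.empty(n)
        for i in range(n):
            w = go[:, i]
            sw = w.sum()
            if cov == "none":
                mu = (w @ xo) / sw
                resid = xo - mu
                ic[i] = mu
            else:
                X = np.column_stack([np.ones_like(zo), zo])
                XtW = X.T * w
                beta = np.linalg.solve(XtW @ X, XtW @ xo)
                ic[i], sl[i] = beta
                resid = xo - X @ beta
            var[i] = max((w @ resid ** 2) / sw, VAR_FLOOR)
        setattr(new, f"emis_{key}_intercept", ic)
        setattr(new, f"emis_{key}_slope", sl)
        setattr(new, f"var_{key}", var)
    return new


def _run_em(params: HMMParameters, spec: ModelSpec, z, logm, temp,
            tol: float, max_iter: int):
    """One EM run; returns (params, loglik, trace, converged) or None if degenerate."""
    trace = []
    tpms_z = z if spec.tpm_covariate != "none" else np.zeros_like(z)
    prev_ll = -np.inf
    converged = False
    for _it in range(max_iter):
        logb = emission_loglik_matrix(params, logm, temp, z)
        tpms = tpm_sequence(params, tpms_z)
        post = _forward_backward_arrays(logb, tpms, params.pi)
        trace.append(post.loglik)
        if np.any(post.gamma.sum(axis=0) < DEGENERATE_MASS):
            return None
        if np.isfinite(prev_ll) and \
                abs(post.loglik - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            converged = True
            params_final, ll_final = params, post.loglik
            break
        prev_ll = post.loglik
        params = _m_step(params, spec, post.gamma, post.xi, z, logm, temp)
    else:
        logb = emission_loglik_matrix(params, logm, temp, z)
        tpms = tpm_sequence(params, tpms_z)
        _, _, _, ll_final = _forward(logb, tpms, params.pi)
        trace.append(float(ll_final))
        params_final = params
    return params_final, float(trace[-1]), trace, converged


def em_fit(spec: ModelSpec, series: TelemetrySeries, seed: int = 0,
           tol: float = 1e-8, max_iter: int = 500,
           n_restarts: int = 10) -> FittedModel:
    """Best-of-``n_restarts`` EM fit of one model to one series.

    Returns the restart with the highest final log-likelihood, relabelled so
    state 1 has the highest movement-mean intercept.  Raises
    :class:`EMFailure` if every restart collapses a state.
    """
    z, center, scale = standardized_covariate_for(series, spec.covariate)
    logm = series.log_movement
    temp = series.temp_median
    best = None
    n_used = 0
    for r in range(n_restarts):
        n_used += 1
        start = init_params(spec, series, _restart_seed(seed, r))
        out = _run_em(start, spec, z, logm, temp, tol, max_iter)
        if out is None:
            continue
        params, ll, trace, conv = out
        if best is None or ll > best[1]:
            best = (params, ll, trace, conv)
    if best is None:
        raise EMFailure(f"all {n_restarts} restarts failed for {spec.name or spec}")
    params, ll, trace, conv = best
    fitted = FittedModel(spec=spec, params=params, loglik=ll,
                         n_params=spec.n_params(), n_restarts_used=n_used,
                         converged=conv, seed=seed, covariate_center=center,
                         covariate_scale=scale, loglik_trace=trace)
    return relabel_states(fitted)


def _permute_params(params: HMMParameters, order: np.ndarray) -> HMMParameters:
    """Relabel states by ``order`` (new state k = old state order[k]).

    Because the transition logits use the row's own diagonal as reference,
    a symmetric row/column permutation maps diagonal to diagonal and the
    off-diagonal logits permute without re-referencing.
    """
    n = params.n_states
    full_a = np.zeros((n, n))
    full_b = np.zeros((n, n))
    for i in range(n):
        cols = [j for j in range(n) if j != i]
        full_a[i, cols] = params.trans_intercepts[i]
        full_b[i, cols] = params.trans_slopes[i]
    full_a = full_a[np.ix_(order, order)]
    full_b = full_b[np.ix_(order, order)]
    ai = np.empty((n, n - 1))
    bi = np.empty((n, n - 1))
    for i in range(n):
        cols = [j for j in range(n) if j != i]
        ai[i] = full_a[i, cols]
        bi[i] = full_b[i, cols]
    return HMMParameters(
        n_states=n, pi=params.pi[order], trans_intercepts=ai, trans_slopes=bi,
        emis_M_intercept=params.emis_M_intercept[order],
        emis_M_slope=params.emis_M_slope[order],
        emis_T_intercept=params.emis_T_intercept[order],
        emis_T_slope=params.emis_T_slope[order],
        var_M=params.var_M[order], var_T=params.var_T[order])


def relabel_states(fitted: FittedModel) -> FittedModel:
    """Canonical state order: movement-mean intercept descending.

    State 1 is the most active; exact movement ties break by temperature
    intercept descending.  The likelihood is invariant to the relabelling.
    """
    p = fitted.params
    key = np.lexsort((-p.emis_T_intercept, -p.emis_M_intercept))
    order = np.asarray(key)
    if np.array_equal(order, np.arange(p.n_states)):
        return fitted
    fitted.params = _permute_params(p, order)
    return fitted
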