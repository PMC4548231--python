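"""Shared fixtures and independent brute-force oracles.

The enumeration oracles compute HMM quantities by summing or maximising over
every state path explicitly, using only the elementary model functions
(``tpm_at``, ``emission_logpdf``), so they share no code with the scaled
recursions they check.
"""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from mousehmm.model import (HMMParameters, ModelSpec, TelemetrySeries,
                            emission_logpdf, standardized_covariate_for,
                            tpm_at)


def make_series(movement, temp, body_weight=None, light=None,
                animal_id="m1", treatment="12AL", period="BL"):
    """Build a TelemetrySeries from raw channel arrays on a 15-min grid."""
    movement = np.asarray(movement, dtype=float)
    T = len(movement)
    ts = np.datetime64("2015-01-01T00:00:00") + \
        np.arange(T) * np.timedelta64(15, "m")
    if body_weight is None:
        body_weight = np.full(T, 30.0)
    if light is None:
        mins = (ts - ts.astype("datetime64[D]")).astype("timedelta64[m]").astype(int)
        light = ((mins >= 390) & (mins < 1110)).astype(int)
    return TelemetrySeries(animal_id=animal_id, treatment=treatment,
                           period=period, timestamps=ts,
                           movement_count=movement,
                           temp_median=np.asarray(temp, dtype=float),
                           body_weight=body_weight, light_phase=light)


def random_params(n, rng, with_tpm_slopes=False, with_emis_slopes=False):
    pi = rng.dirichlet(np.ones(n))
    return HMMParameters(
        n_states=n,
        pi=pi,
        trans_intercepts=rng.normal(0, 1.0, (n, n - 1)),
        trans_slopes=rng.normal(0, 0.5, (n, n - 1)) if with_tpm_slopes
        else np.zeros((n, n - 1)),
        emis_M_intercept=rng.uniform(0.2, 3.0, n),
        emis_M_slope=rng.normal(0, 0.3, n) if with_emis_slopes else np.zeros(n),
        emis_T_intercept=rng.uniform(33.0, 38.0, n),
        emis_T_slope=rng.normal(0, 0.3, n) if with_emis_slopes else np.zeros(n),
        var_M=rng.uniform(0.1, 1.0, n),
        var_T=rng.uniform(0.1, 1.0, n),
    )


def random_instance(seed, n, T, spec=None, with_missing=True):
    """A random (params, series, spec) triple for oracle comparisons."""
    rng = np.random.default_rng(seed)
    if spec is None:
        options = [
            ModelSpec(n),
            ModelSpec(n, movement_mean_covariate="t", temp_mean_covariate="t"),
            ModelSpec(n, tpm_covariate="t"),
        ]
        spec = options[rng.integers(len(options))]
    params = random_params(n, rng,
                           with_tpm_slopes=spec.tpm_covariate != "none",
                           with_emis_slopes=spec.movement_mean_covariate != "none"
                           or spec.temp_mean_covariate != "none")
    movement = rng.integers(0, 30, T).astype(float)
    temp = rng.normal(36.0, 1.5, T)
    if with_missing and T >= 4:
        movement[rng.integers(0, T)] = np.nan
        temp[rng.integers(0, T)] = np.nan
    return params, make_series(movement, temp), spec


def _oracle_terms(params, series, spec):
    z, _, _ = standardized_covariate_for(series, spec.covariate)
    T, n = len(series), params.n_states
    logm = series.log_movement
    tpms = [tpm_at(params, z[t] if spec.tpm_covariate != "none" else 0.0)
            for t in range(T)]
    logb = np.array([[emission_logpdf(params, i + 1, logm[t],
                                      series.temp_median[t], z[t])
                      for i in range(n)] for t in range(T)])
    return z, tpms, logb


def _path_logprob(params, tpms, logb, path):
    lp = np.log(params.pi[path[0]]) + logb[0, path[0]]
    for t in range(1, len(path)):
        lp += np.log(tpms[t][path[t - 1], path[t]]) + logb[t, path[t]]
    return lp


def enum_loglik(params, series, spec):
    """Marginal log-likelihood by explicit summation over all n**T paths."""
    _, tpms, logb = _oracle_terms(params, series, spec)
    T, n = logb.shape
    lps = [_path_logprob(params, tpms, logb, path)
           for path in itertools.product(range(n), repeat=T)]
    return float(logsumexp(lps))


def enum_posteriors(params, series, spec):
    """Per-step state posteriors by explicit path summation."""
    _, tpms, logb = _oracle_terms(params, series, spec)
    T, n = logb.shape
    num = np.zeros((T, n))
    for path in itertools.product(range(n), repeat=T):
        p = np.exp(_path_logprob(params, tpms, logb, path))
        for t, s in enumerate(path):
            num[t, s] += p
    return num / num.sum(axis=1, keepdims=True)


def enum_viterbi(params, series, spec):
    """Most probable path by explicit argmax; ties to the lower-index path."""
    _, tpms, logb = _oracle_terms(params, series, spec)
    T, n = logb.shape
    best, best_lp = None, -np.inf
    for path in itertools.product(range(n), repeat=T):
        lp = _path_logprob(params, tpms, logb, path)
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
    return np.asarray(best) + 1, best_lp


def enum_all(params, series, spec):
    """Log-lik, posteriors and best path from one sweep over all paths."""
    _, tpms, logb = _oracle_terms(params, series, spec)
    T, n = logb.shape
    num = np.zeros((T, n))
    lps = []
    best, best_lp = None, -np.inf
    for path in itertools.product(range(n), repeat=T):
        lp = _path_logprob(params, tpms, logb, path)
        lps.append(lp)
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
        p = np.exp(lp)
        for t, s in enumerate(path):
            num[t, s] += p
    loglik = float(logsumexp(lps))
    gamma = num / num.sum(axis=1, keepdims=True)
    return loglik, gamma, np.asarray(best) + 1


@pytest.fixture(scope="session")
def short_series():
    rng = np.random.default_rng(42)
    return make_series(rng.integers(0, 40, 200).astype(float),
                       rng.normal(36.0, 1.0, 200))
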