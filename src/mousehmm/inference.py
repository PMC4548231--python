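"""Exact HMM inference: forward likelihood, forward-backward, Viterbi.

All recursions run on a precomputed (T, n) emission log-likelihood matrix and
a (T, n, n) stack of transition matrices, so covariate-dependent switching and
missing observations (emission log-lik 0) need no special-casing here.  The
transition matrix at index ``t`` governs the move from step ``t-1`` to ``t``
(index 0 is unused).  Per-step normalisation keeps ~10,000-step series far
from underflow; the log-normalisers accumulate into the marginal
log-likelihood.  The hot loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import (FittedModel, HMMParameters, ModelSpec, StatePath,
                    TelemetrySeries, emission_loglik_matrix,
                    standardized_covariate_for, tpm_sequence)

__all__ = ["PosteriorSet", "forward_loglik", "forward_backward", "viterbi",
           "decode"]


@dataclass
class PosteriorSet:
    """Smoothed posteriors: gamma (T, n), xi (T-1, n, n), and the log-lik."""

    gamma: np.ndarray
    xi: np.ndarray
    loglik: float


@njit(cache=True)
def _forward(logb, tpms, pi):
    T, n = logb.shape
    alpha = np.empty((T, n))
    c = np.empty(T)
    # subtract the row max before exponentiating the emission log-liks
    loglik = 0.0
    bmax = np.empty(T)
    b = np.empty((T, n))
    for t in range(T):
        m = logb[t, 0]
        for i in range(1, n):
            if logb[t, i] > m:
                m = logb[t, i]
        bmax[t] = m
        for i in range(n):
            b[t, i] = np.exp(logb[t, i] - m)
    for i in range(n):
        alpha[0, i] = pi[i] * b[0, i]
    s = alpha[0].sum()
    c[0] = s
    alpha[0] /= s
    loglik += np.log(s) + bmax[0]
    for t in range(1, T):
        for j in range(n):
            acc = 0.0
            for i in range(n):
                acc += alpha[t - 1, i] * tpms[t, i, j]
            alpha[t, j] = acc * b[t, j]
        s = alpha[t].sum()
        c[t] = s
        alpha[t] /= s
        loglik += np.log(s) + bmax[t]
    return alpha, c, b, loglik


@njit(cache=True)
def _backward(b, tpms, c):
    T, n = b.shape
    beta = np.empty((T, n))
    for i in range(n):
        beta[T - 1, i] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += tpms[t + 1, i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
    return beta


@njit(cache=True)
def _viterbi(logb, tpms, pi):
    T, n = logb.shape
    delta = np.empty((T, n))
    psi = np.zeros((T, n), dtype=np.int64)
    for i in range(n):
        delta[0, i] = np.log(pi[i] + 1e-300) + logb[0, i]
    for t in range(1, T):
        for j in range(n):
            best = -np.inf
            arg = 0
            for i in range(n):
                v = delta[t - 1, i] + np.log(tpms[t, i, j] + 1e-300)
                if v > best:        # strict: ties resolve to the lower index
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for i in range(n):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


def _prepare(params: HMMParameters, series: TelemetrySeries, spec: ModelSpec):
    z, _, _ = standardized_covariate_for(series, spec.covariate)
    logb = emission_loglik_matrix(params, series.log_movement,
                                  series.temp_median, z)
    tpms = tpm_sequence(params, z if spec.tpm_covariate != "none"
                        else np.zeros(len(series)))
    return logb, tpms


def forward_loglik(params: HMMParameters, series: TelemetrySeries,
                   spec: ModelSpec) -> float:
    """Marginal log-likelihood of the observations, summed over state paths."""
    if len(series) == 0:
        raise ValueError("series is empty")
    logb, tpms = _prepare(params, series, spec)
    _, _, _, ll = _forward(logb, tpms, params.pi)
    return float(ll)


def forward_backward(params: HMMParameters, series: TelemetrySeries,
                     spec: ModelSpec) -> PosteriorSet:
    """Smoothed state posteriors gamma and pairwise posteriors xi."""
    logb, tpms = _prepare(params, series, spec)
    return _forward_backward_arrays(logb, tpms, params.pi)


def _forward_backward_arrays(logb, tpms, pi) -> PosteriorSet:
    alpha, c, b, ll = _forward(logb, tpms, pi)
    beta = _backward(b, tpms, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    T, n = logb.shape
    if T > 1:
        # xi_t(i,j) on transitions t -> t+1, indexed 0..T-2
        xi = (alpha[:-1, :, None] * tpms[1:]
              * (b[1:] * beta[1:])[:, None, :]) / c[1:, None, None]
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.zeros((0, n, n))
    return PosteriorSet(gamma=gamma, xi=xi, loglik=float(ll))


def viterbi(params: HMMParameters, series: TelemetrySeries,
            spec: ModelSpec) -> StatePath:
    """Jointly most probable state sequence (1-based), ties to lower index."""
    logb, tpms = _prepare(params, series, spec)
    path, _ = _viterbi(logb, tpms, params.pi)
    post = _forward_backward_arrays(logb, tpms, params.pi)
    return StatePath(states=path + 1, posteriors=post.gamma)


def decode(fitted: FittedModel, series: TelemetrySeries) -> StatePath:
    """Viterbi decoding with a fitted model's stored standardisation."""
    return viterbi(fitted.params, series, fitted.spec)
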