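"""Downstream state-shift analysis.

Given canonical (activity-ordered) fits for the baseline and treatment
periods of each animal, this module quantifies how the behavioural phenotype
moved: per-state changes in emission characteristics, changes in the
transition matrix rows, activity budgets and bout durations from decoded
paths, multivariate linear models (Pillai's trace) of the paired changes
against treatment level, and a torpor flag at the 31 degC body-temperature
threshold.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import FittedModel, StatePath, TelemetrySeries, tpm_at

__all__ = ["state_characteristic_draws", "covariate_endpoints",
           "paired_state_difference", "paired_tpm_difference",
           "manova_state_shift", "tpm_shift_tests", "pillai_manova",
           "activity_budget", "bout_durations", "torpor_flag",
           "TORPOR_THRESHOLD_C"]

TORPOR_THRESHOLD_C = 31.0


def state_characteristic_draws(fitted: FittedModel, z: float = 0.0,
                               n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Bivariate-normal draws per state, shape (n_states, n_draws, 2).

    Column 0 is log-movement, column 1 temperature; means are evaluated at
    the standardised covariate value ``z`` (start / halfway / end of period).
    The default of 1000 draws per state per animal is what the contour
    summaries accumulate.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    p = fitted.params
    rng = np.random.default_rng(seed)
    mu_m, mu_t = p.emission_means(float(z))
    out = np.empty((p.n_states, n_draws, 2))
    for i in range(p.n_states):
        out[i, :, 0] = rng.normal(mu_m[i], np.sqrt(p.var_M[i]), n_draws)
        out[i, :, 1] = rng.normal(mu_t[i], np.sqrt(p.var_T[i]), n_draws)
    return out


def covariate_endpoints(fitted: FittedModel, series: TelemetrySeries):
    """Standardised covariate value at the first and last observed steps."""
    cov = fitted.spec.covariate
    if cov == "none":
        return 0.0, 0.0
    raw = series.covariate_values(cov)
    obs = np.isfinite(series.movement_count) | np.isfinite(series.temp_median)
    idx = np.nonzero(obs)[0]
    first, last = (0, len(series) - 1) if idx.size == 0 else (idx[0], idx[-1])
    z = fitted.standardize(raw)
    return float(z[first]), float(z[last])


def paired_state_difference(fit_bl: FittedModel, fit_cr: FittedModel,
                            z_bl: float = 0.0, z_cr: float = 0.0) -> np.ndarray:
    """Per-state (d log-movement mean, d temperature mean), CR-end minus BL-start.

    Means are evaluated at each fit's own standardised covariate value
    (``z_cr`` at the end of treatment, ``z_bl`` at the start of baseline).
    If the two fits have different state counts the comparison covers the
    first min(n) canonical states and a warning is issued.
    """
    n_bl, n_cr = fit_bl.params.n_states, fit_cr.params.n_states
    n = min(n_bl, n_cr)
    if n_bl != n_cr:
        warnings.warn("state counts differ; comparing the first "
                      f"{n} canonical states", stacklevel=2)
    mb_m, mb_t = fit_bl.params.emission_means(float(z_bl))
    mc_m, mc_t = fit_cr.params.emission_means(float(z_cr))
    return np.column_stack([mc_m[:n] - mb_m[:n], mc_t[:n] - mb_t[:n]])


def paired_tpm_difference(fit_bl: FittedModel, fit_cr: FittedModel,
                          z_bl: float = 0.0, z_cr: float = 0.0) -> np.ndarray:
    """Elementwise tpm difference, CR tpm at z_cr minus BL tpm at z_bl."""
    return tpm_at(fit_cr.params, float(z_cr)) - tpm_at(fit_bl.params, float(z_bl))


def pillai_manova(Y: np.ndarray, groups: Sequence) -> dict:
    """One-way MANOVA via Pillai's trace with the standard F approximation.

    ``Y`` is (N, p) responses, ``groups`` the factor.  Pillai's trace is
    V = tr(H (H + E)^-1) with H the between-group and E the residual SSCP.
    Also reports the adjusted R^2 averaged over the per-response univariate
    fits.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    N, p = Y.shape
    levels, idx = np.unique(groups, return_inverse=True)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 treatment groups")
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for k in range(g):
        Yk = Y[idx == k]
        d = Yk.mean(axis=0) - grand
        H += len(Yk) * np.outer(d, d)
        R = Yk - Yk.mean(axis=0)
        E += R.T @ R
    try:
        V = float(np.trace(H @ np.linalg.inv(H + E)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular total SSCP matrix (N={N}, p={p}, groups={g})") from exc
    q = g - 1
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (N - g - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (df2 / df1) * V / (s - V) if s > V else np.inf
    pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    # adjusted R^2, averaged over responses of the univariate fits
    ss_res = np.diag(E)
    ss_tot = np.diag(H + E)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (N - 1) / (N - g)
    return {"pillai": V, "F": float(F), "df1": float(df1), "df2": float(df2),
            "p": pval, "r2_adj": float(np.mean(r2_adj)),
            "hypothesis_df": q, "error_df": N - g}


def manova_state_shift(differences: np.ndarray,
                       treatments: Sequence) -> List[dict]:
    """Per-state multivariate linear model of paired phenotype changes.

    ``differences`` is (n_animals, n_states, 2) of per-state
    (d movement, d temperature) changes; ``treatments`` labels the factor.
    Returns one Pillai test per state.
    """
    differences = np.asarray(differences, dtype=float)
    if differences.ndim != 3 or differences.shape[2] < 2:
        raise ValueError("differences must be (animals, states, >=2 responses)")
    out = []
    for i in range(differences.shape[1]):
        res = pillai_manova(differences[:, i, :], treatments)
        res["state"] = i + 1
        out.append(res)
    return out


def tpm_shift_tests(tpm_differences: np.ndarray,
                    treatments: Sequence) -> List[dict]:
    """Row-wise multivariate tests of transition-probability change.

    ``tpm_differences`` is (n_animals, n, n) of paired tpm differences.  For
    each origin state the responses are that row's off-diagonal differences
    (the self-transition column is dropped: rows sum to zero, so it is the
    exact negative of the others).  P-values are Bonferroni-adjusted for the
    n origin-state models, capped at 1.
    """
    D = np.asarray(tpm_differences, dtype=float)
    if D.ndim != 3 or D.shape[1] != D.shape[2]:
        raise ValueError("tpm_differences must be (animals, n, n)")
    n = D.shape[1]
    out = []
    for i in range(n):
        cols = [j for j in range(n) if j != i]
        res = pillai_manova(D[:, i, cols], treatments)
        res["origin_state"] = i + 1
        res["p_adj"] = min(1.0, n * res["p"])
        out.append(res)
    return out


def activity_budget(path: StatePath,
                    series: Optional[TelemetrySeries] = None) -> Dict[str, np.ndarray]:
    """Per-state occupancy proportions, overall and (if possible) by phase."""
    if len(path.states) == 0:
        raise ValueError("empty state path")
    n = path.posteriors.shape[1]
    out = {"overall": np.array([(path.states == i + 1).mean() for i in range(n)])}
    if series is not None:
        light = series.light_phase.astype(bool)
        for name, mask in (("light", light), ("dark", ~light)):
            if mask.any():
                s = path.states[mask]
                out[name] = np.array([(s == i + 1).mean() for i in range(n)])
    return out


def bout_durations(path: StatePath) -> dict:
    """Maximal same-state run lengths (15-min steps) per state, with summaries.

    Under a homogeneous chain the mean bout of state i is 1/(1 - p_ii),
    which serves as a cross-check on decoded dynamics.
    """
    s = np.asarray(path.states)
    n = path.posteriors.shape[1]
    bouts = {i + 1: [] for i in range(n)}
    if s.size:
        change = np.nonzero(np.diff(s) != 0)[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [s.size]])
        for a, b in zip(starts, ends):
            bouts[int(s[a])].append(b - a)
    samples = {i: np.asarray(v, dtype=float) for i, v in bouts.items()}
    summary = {i: {"n": v.size,
                   "mean": float(v.mean()) if v.size else np.nan,
                   "median": float(np.median(v)) if v.size else np.nan}
               for i, v in samples.items()}
    return {"samples": samples, "summary": summary}


def torpor_flag(fitted: FittedModel, z_end: float = 0.0):
    """Torpor call: is the state-3 temperature mean below 31 degC at z_end?

    Uses the canonical labelling (state 3 = least active).  The comparison
    is strict — exactly 31.0 is not torpor.  A two-state fit is evaluated on
    its lowest-temperature state with a warning.
    """
    p = fitted.params
    _, mu_t = p.emission_means(float(z_end))
    if p.n_states >= 3:
        val = float(mu_t[2])
    else:
        warnings.warn("two-state fit: torpor evaluated on the "
                      "lowest-temperature state", stacklevel=2)
        val = float(mu_t.min())
    return val < TORPOR_THRESHOLD_C, val


def state_shift_table(results: List[dict]) -> pd.DataFrame:
    """Tidy table of Pillai test results for export."""
    return pd.DataFrame(results)
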