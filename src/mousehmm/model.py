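"""Core domain types for behavioural-phenotype hidden Markov models.

The observation model is a mixture of bivariate normals over
``log(movement count + 1)`` and median core body temperature, one component
per latent activity state.  Within a state the two channels are conditionally
independent, so each state carries two means and two variances.  State
switching follows a first-order Markov chain whose row-wise transition logits
(self-transition as reference category) may depend linearly on a standardised
covariate — elapsed time ``t`` in 15-minute steps or daily body weight ``BW``
— and the same covariate may enter the emission means linearly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TelemetrySeries",
    "ModelSpec",
    "HMMParameters",
    "FittedModel",
    "StatePath",
    "log_movement",
    "standardize_covariate",
    "destandardize_covariate",
    "tpm_at",
    "emission_logpdf",
]

TREATMENTS = ("12AL", "24AL", "10CR", "20CR", "30CR", "40CR")
PERIODS = ("BL", "CR")
COVARIATES = ("none", "t", "BW")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def log_movement(count):
    """Natural log of (movement count + 1); NaN propagates.

    Accepts a scalar or array.  Negative counts are rejected.
    """
    arr = np.asarray(count, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValidationError("movement counts must be non-negative")
    out = np.log1p(arr)
    if np.ndim(count) == 0:
        return float(out)
    return out


def standardize_covariate(values: Sequence[float]):
    """Centre and scale a covariate to mean 0, sample SD 1 (n-1 denominator).

    Returns ``(standardized, center, scale)``.  NaNs are ignored for the
    moments and preserved in the output.  A constant covariate is rejected
    because its scale would be zero.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise ValidationError("covariate needs at least 2 distinct finite values")
    center = float(np.mean(finite))
    scale = float(np.std(finite, ddof=1))
    return (arr - center) / scale, center, scale


def destandardize_covariate(z, center: float, scale: float):
    return np.asarray(z, dtype=float) * scale + center


@dataclass
class TelemetrySeries:
    """One animal's aligned 15-minute telemetry stream with covariates.

    ``movement_count`` and ``temp_median`` use NaN for missing windows;
    ``body_weight`` is the daily weight in grams broadcast to each step of
    that day; ``light_phase`` is 1 during lights-on, 0 during darkness.
    """

    animal_id: str
    treatment: str
    period: str
    timestamps: np.ndarray  # datetime64[s], uniform 15-min grid
    movement_count: np.ndarray
    temp_median: np.ndarray
    body_weight: np.ndarray
    light_phase: np.ndarray
    step_minutes: int = 15

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.movement_count = np.asarray(self.movement_count, dtype=float)
        self.temp_median = np.asarray(self.temp_median, dtype=float)
        self.body_weight = np.asarray(self.body_weight, dtype=float)
        self.light_phase = np.asarray(self.light_phase, dtype=int)
        n = len(self.timestamps)
        for name in ("movement_count", "temp_median", "body_weight", "light_phase"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length != timestamps length")
        if n >= 2:
            diffs = np.diff(self.timestamps).astype("timedelta64[s]").astype(int)
            if not np.all(diffs == self.step_minutes * 60):
                raise ValidationError("timestamps must be a uniform "
                                      f"{self.step_minutes}-min strictly increasing grid")
        obs = self.movement_count[np.isfinite(self.movement_count)]
        if np.any(obs < 0):
            raise ValidationError("movement_count must be non-negative")
        bw = self.body_weight[np.isfinite(self.body_weight)]
        if bw.size and np.any(bw <= 0):
            raise ValidationError("body_weight must be positive")

    def __len__(self):
        return len(self.timestamps)

    @property
    def log_movement(self) -> np.ndarray:
        return log_movement(self.movement_count)

    def covariate_values(self, which: str) -> np.ndarray:
        """Raw (unstandardised) covariate per step: elapsed steps or daily BW."""
        if which == "none":
            return np.zeros(len(self))
        if which == "t":
            return np.arange(len(self), dtype=float)
        if which == "BW":
            return self.body_weight.astype(float)
        raise ValidationError(f"unknown covariate {which!r}")


def _model_class(tpm_cov: str, move_cov: str, temp_cov: str) -> str:
    emis = {move_cov, temp_cov} - {"none"}
    if tpm_cov == "none" and not emis:
        return "HMM1"
    if tpm_cov == "none":
        return "HMM2" if emis == {"t"} else "HMM3"
    if not emis:
        return "HMM4" if tpm_cov == "t" else "HMM5"
    return "HMM2+4" if tpm_cov == "t" else "HMM3+5"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: state count plus covariate placement."""

    n_states: int
    tpm_covariate: str = "none"
    movement_mean_covariate: str = "none"
    temp_mean_covariate: str = "none"
    name: str = ""

    def __post_init__(self):
        # candidates in the grid use 2 or 3 states; 1 is the degenerate
        # single-state model used for closed-form checks
        if self.n_states not in (1, 2, 3):
            raise ValidationError("n_states must be 1, 2 or 3")
        covs = {self.tpm_covariate, self.movement_mean_covariate,
                self.temp_mean_covariate}
        if not covs <= set(COVARIATES):
            raise ValidationError(f"unknown covariate in {covs}")
        if {"t", "BW"} <= covs:
            raise ValidationError("t and BW may not be mixed within one model")

    @property
    def model_class(self) -> str:
        return _model_class(self.tpm_covariate, self.movement_mean_covariate,
                            self.temp_mean_covariate)

    @property
    def covariate(self) -> str:
        """The single covariate the model uses anywhere ('none' if HMM1)."""
        covs = {self.tpm_covariate, self.movement_mean_covariate,
                self.temp_mean_covariate} - {"none"}
        return covs.pop() if covs else "none"

    def n_params(self) -> int:
        n = self.n_states
        k = (n - 1)                       # initial distribution
        k += n * (n - 1) * (1 + (self.tpm_covariate != "none"))
        per_state = 2 + 2                 # two intercepts, two variances
        per_state += (self.movement_mean_covariate != "none")
        per_state += (self.temp_mean_covariate != "none")
        return k + n * per_state


@dataclass
class HMMParameters:
    """All free parameters of one model.

    ``trans_intercepts``/``trans_slopes`` hold, for each row ``i``, the
    multinomial logits of the off-diagonal destinations (ascending column
    order, the self-transition fixed at logit 0).  Emission means are
    ``intercept + slope * z`` with ``z`` the standardised covariate.
    """

    n_states: int
    pi: np.ndarray                    # (n,)
    trans_intercepts: np.ndarray      # (n, n-1)
    trans_slopes: np.ndarray          # (n, n-1)
    emis_M_intercept: np.ndarray      # (n,)
    emis_M_slope: np.ndarray
    emis_T_intercept: np.ndarray
    emis_T_slope: np.ndarray
    var_M: np.ndarray
    var_T: np.ndarray

    def __post_init__(self):
        n = self.n_states
        for name in ("pi", "trans_intercepts", "trans_slopes", "emis_M_intercept",
                     "emis_M_slope", "emis_T_intercept", "emis_T_slope",
                     "var_M", "var_T"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.pi.shape != (n,) or not np.isclose(self.pi.sum(), 1.0):
            raise ValidationError("pi must be a length-n probability vector")
        if np.any(self.pi < -1e-12):
            raise ValidationError("pi entries must be non-negative")
        if self.trans_intercepts.shape != (n, max(n - 1, 0)):
            raise ValidationError("trans_intercepts must be n x (n-1)")
        if self.trans_slopes.shape != self.trans_intercepts.shape:
            raise ValidationError("trans_slopes must match trans_intercepts")
        if np.any(self.var_M <= 0) or np.any(self.var_T <= 0):
            raise ValidationError("variances must be strictly positive")

    def emission_means(self, z):
        """Per-state (mu_M, mu_T) at standardised covariate value(s) z."""
        z = np.asarray(z, dtype=float)
        mu_m = self.emis_M_intercept + np.multiply.outer(z, self.emis_M_slope)
        mu_t = self.emis_T_intercept + np.multiply.outer(z, self.emis_T_slope)
        return mu_m, mu_t

    def copy(self) -> "HMMParameters":
        return HMMParameters(
            self.n_states, self.pi.copy(), self.trans_intercepts.copy(),
            self.trans_slopes.copy(), self.emis_M_intercept.copy(),
            self.emis_M_slope.copy(), self.emis_T_intercept.copy(),
            self.emis_T_slope.copy(), self.var_M.copy(), self.var_T.copy())


def tpm_at(params: HMMParameters, z: float) -> np.ndarray:
    """Transition probability matrix at standardised covariate value ``z``.

    Row ``i`` is the softmax of logits that are 0 on the diagonal and
    ``intercept + slope * z`` on the off-diagonal destinations, so every row
    sums to one by construction.
    """
    n = params.n_states
    logits = np.zeros((n, n))
    for i in range(n):
        cols = [j for j in range(n) if j != i]
        logits[i, cols] = params.trans_intercepts[i] + params.trans_slopes[i] * z
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    return expl / expl.sum(axis=1, keepdims=True)


def tpm_sequence(params: HMMParameters, z: np.ndarray) -> np.ndarray:
    """Stack of tpms over a standardised covariate path, shape (T, n, n)."""
    z = np.asarray(z, dtype=float)
    if np.all(params.trans_slopes == 0.0):
        P = tpm_at(params, 0.0)
        return np.broadcast_to(P, (len(z),) + P.shape).copy()
    return np.stack([tpm_at(params, zi) for zi in z])


_LOG2PI = float(np.log(2.0 * np.pi))


def emission_logpdf(params: HMMParameters, state: int, m: float, temp: float,
                    z: float = 0.0) -> float:
    """Log-density of one observation under one state's bivariate normal.

    ``state`` is 1-based.  A missing channel (NaN) is marginalised out; with
    both channels missing the contribution is log(1) = 0.
    """
    if not 1 <= state <= params.n_states:
        raise ValidationError(f"state must be in [1, {params.n_states}]")
    i = state - 1
    out = 0.0
    if np.isfinite(m):
        mu = params.emis_M_intercept[i] + params.emis_M_slope[i] * z
        v = params.var_M[i]
        out += -0.5 * (_LOG2PI + np.log(v) + (m - mu) ** 2 / v)
    if np.isfinite(temp):
        mu = params.emis_T_intercept[i] + params.emis_T_slope[i] * z
        v = params.var_T[i]
        out += -0.5 * (_LOG2PI + np.log(v) + (temp - mu) ** 2 / v)
    return float(out)


def emission_loglik_matrix(params: HMMParameters, log_move: np.ndarray,
                           temp: np.ndarray, z: np.ndarray) -> np.ndarray:
    """(T, n) matrix of per-step per-state emission log-densities.

    Missing channels contribute 0 so an all-missing step has log-lik 0 in
    every state (the step is marginalised, never imputed).
    """
    z = np.asarray(z, dtype=float)
    mu_m, mu_t = params.emission_means(z)          # (T, n)
    ll = np.zeros((len(z), params.n_states))
    obs_m = np.isfinite(log_move)
    obs_t = np.isfinite(temp)
    if obs_m.any():
        resid = log_move[obs_m, None] - mu_m[obs_m]
        ll[obs_m] += -0.5 * (_LOG2PI + np.log(params.var_M)[None, :]
                             + resid ** 2 / params.var_M[None, :])
    if obs_t.any():
        resid = temp[obs_t, None] - mu_t[obs_t]
        ll[obs_t] += -0.5 * (_LOG2PI + np.log(params.var_T)[None, :]
                             + resid ** 2 / params.var_T[None, :])
    return ll


@dataclass
class StatePath:
    """Viterbi decoding plus per-step posterior probabilities (1-based states)."""

    states: np.ndarray        # (T,) int, in [1, n]
    posteriors: np.ndarray    # (T, n), rows sum to 1

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        self.posteriors = np.asarray(self.posteriors, dtype=float)


@dataclass
class FittedModel:
    """A converged fit: spec, parameters, likelihood, AIC and provenance."""

    spec: ModelSpec
    params: HMMParameters
    loglik: float
    n_params: int
    n_restarts_used: int
    converged: bool
    seed: int
    covariate_center: float = 0.0
    covariate_scale: float = 1.0
    loglik_trace: Optional[list] = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def standardize(self, raw_values) -> np.ndarray:
        """Map raw covariate values onto the scale used during fitting."""
        return (np.asarray(raw_values, dtype=float) - self.covariate_center) / \
            self.covariate_scale

    # -- JSON round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "spec": asdict(self.spec),
            "params": {k: np.asarray(v).tolist() for k, v in asdict(self.params).items()},
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_restarts_used": self.n_restarts_used,
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "covariate_center": self.covariate_center,
            "covariate_scale": self.covariate_scale,
        }
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = ModelSpec(**d["spec"])
        p = dict(d["params"])
        p["n_states"] = int(p["n_states"])
        params = HMMParameters(**p)
        return cls(spec=spec, params=params, loglik=float(d["loglik"]),
                   n_params=int(d["n_params"]),
                   n_restarts_used=int(d["n_restarts_used"]),
                   converged=bool(d["converged"]), seed=int(d["seed"]),
                   covariate_center=float(d["covariate_center"]),
                   covariate_scale=float(d["covariate_scale"]))

    @classmethod
    def from_json(cls, source) -> "FittedModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        try:
            return cls.from_dict(json.loads(source))
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))


def standardized_covariate_for(series: TelemetrySeries, which: str):
    """Standardise a series' covariate; 'none' yields zeros with scale 1."""
    if which == "none":
        return np.zeros(len(series)), 0.0, 1.0
    raw = series.covariate_values(which)
    return standardize_covariate(raw)
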