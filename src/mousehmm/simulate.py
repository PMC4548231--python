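"""Seeded synthetic telemetry generator for graded calorie-restriction cohorts.

Each scenario emulates one treatment group: a latent 3-state activity chain
with separate dark-phase and light-phase transition matrices (mice are
nocturnal, so the dark tpm favours the active state), bivariate-normal
emissions on (log movement + 1, temperature), a declining body-weight
trajectory under restriction, and — for the severe scenarios — linear drift
of the state means across the treatment period, driven by elapsed time or by
body weight.  Movement is generated on the log scale and discretised to
integer counts, so the Gaussian model on log(count + 1) is approximately
well-specified.  All randomness derives from the scenario seed plus the
animal index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import (HMMParameters, ModelSpec, TelemetrySeries,
                    ValidationError, tpm_at)

__all__ = ["ScenarioConfig", "AnimalRecord", "simulate_mouse",
           "simulate_cohort", "default_scenarios", "simulate_from_params"]

STEPS_PER_DAY = 96          # 15-minute windows
LIGHTS_ON_MIN = 6 * 60 + 30     # 06:30
LIGHTS_OFF_MIN = 18 * 60 + 30   # 18:30

# Diurnal switching: darkness favours the high-activity state, light favours
# the inactive/low state.
DARK_TPM = np.array([[0.85, 0.10, 0.05],
                     [0.15, 0.75, 0.10],
                     [0.10, 0.15, 0.75]])
LIGHT_TPM = np.array([[0.70, 0.18, 0.12],
                      [0.06, 0.75, 0.19],
                      [0.03, 0.07, 0.90]])


@dataclass
class ScenarioConfig:
    """Generative settings for one synthetic treatment group."""

    treatment: str
    n_animals: int = 8
    bl_days: int = 14
    cr_days: int = 90
    n_states: int = 3
    move_means: Tuple[float, ...] = (2.5, 1.2, 0.2)      # log(count+1) scale
    temp_means: Tuple[float, ...] = (37.0, 36.0, 35.5)   # degC
    move_vars: Tuple[float, ...] = (0.30, 0.25, 0.10)
    temp_vars: Tuple[float, ...] = (0.25, 0.25, 0.25)
    drift_covariate: str = "none"        # none | t | BW — what drives the drift
    move_drift: Tuple[float, ...] = (0.0, 0.0, 0.0)      # total change over CR
    temp_drift: Tuple[float, ...] = (0.0, 0.0, 0.0)
    drift_fraction: float = 1.0          # fraction of animals that drift
    tpm_dark: Optional[Sequence] = None
    tpm_light: Optional[Sequence] = None
    bw_start: float = 34.0
    bw_end: float = 34.0
    bw_noise_sd: float = 0.15
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        n = self.n_states
        defaults = self.tpm_dark is None
        self.tpm_dark = np.asarray(DARK_TPM[:n, :n] if self.tpm_dark is None
                                   else self.tpm_dark, dtype=float)
        self.tpm_light = np.asarray(LIGHT_TPM[:n, :n] if self.tpm_light is None
                                    else self.tpm_light, dtype=float)
        if defaults:    # a sliced default needs renormalising for n < 3
            self.tpm_dark = self.tpm_dark / self.tpm_dark.sum(axis=1, keepdims=True)
            self.tpm_light = self.tpm_light / self.tpm_light.sum(axis=1, keepdims=True)
        for P in (self.tpm_dark, self.tpm_light):
            if P.shape != (n, n) or np.any(P < 0) or \
                    not np.allclose(P.sum(axis=1), 1.0):
                raise ValidationError("tpm must be row-stochastic n x n")
        for name in ("move_means", "temp_means", "move_vars", "temp_vars",
                     "move_drift", "temp_drift"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} must have {n} entries")
        if any(v < 0 for v in self.move_vars + self.temp_vars):
            raise ValidationError("variances must be non-negative")
        if self.drift_covariate not in ("none", "t", "BW"):
            raise ValidationError("drift_covariate must be none, t or BW")
        if self.drift_covariate != "none" and self.bw_end > self.bw_start:
            raise ValidationError("bw_end must not exceed bw_start under restriction")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValidationError("drift_fraction must be in [0, 1]")

    def drifts(self, animal_index: int) -> bool:
        """Deterministic subset of drifting animals (lowest indices drift)."""
        return animal_index < int(round(self.drift_fraction * self.n_animals))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tpm_dark"] = np.asarray(self.tpm_dark).tolist()
        d["tpm_light"] = np.asarray(self.tpm_light).tolist()
        return d


def _light_phase(timestamps: np.ndarray) -> np.ndarray:
    mins = (timestamps - timestamps.astype("datetime64[D]")).astype(
        "timedelta64[m]").astype(int)
    return ((mins >= LIGHTS_ON_MIN) & (mins < LIGHTS_OFF_MIN)).astype(int)


def _grid(start: np.datetime64, n_steps: int) -> np.ndarray:
    return start + np.arange(n_steps) * np.timedelta64(15, "m")


def simulate_mouse(config: ScenarioConfig, animal_index: int,
                   period: str = "CR", return_states: bool = False):
    """Simulate one animal's telemetry for one period (BL or CR).

    The latent chain uses the dark or light tpm according to the phase at the
    step being entered; state means drift linearly over the treatment period
    for drifting animals; daily body weight interpolates ``bw_start`` to
    ``bw_end`` with small noise; windows go missing at ``missing_rate``.
    """
    if period not in ("BL", "CR"):
        raise ValidationError("period must be 'BL' or 'CR'")
    n = config.n_states
    days = config.bl_days if period == "BL" else config.cr_days
    n_steps = days * STEPS_PER_DAY
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, animal_index,
                                0 if period == "BL" else 1]))
    start = np.datetime64("2015-01-01T00:00:00") if period == "BL" else \
        np.datetime64("2015-01-01T00:00:00") + np.timedelta64(config.bl_days, "D")
    ts = _grid(start, n_steps)
    light = _light_phase(ts)

    # daily body weight: flat during baseline, declining under restriction
    day_index = np.repeat(np.arange(days), STEPS_PER_DAY)
    if period == "BL" or config.bw_end == config.bw_start:
        bw_daily = np.full(days, config.bw_start)
    else:
        bw_daily = np.linspace(config.bw_start, config.bw_end, days)
    bw_daily = np.maximum(bw_daily + rng.normal(0.0, config.bw_noise_sd, days), 1.0)
    bw = bw_daily[day_index]

    # drift progress in [0, 1] over the CR period
    if period == "CR" and config.drift_covariate != "none" \
            and config.drifts(animal_index):
        if config.drift_covariate == "t":
            frac = np.arange(n_steps) / max(n_steps - 1, 1)
        else:
            denom = config.bw_start - config.bw_end
            frac = np.clip((config.bw_start - bw) / denom, 0.0, 1.0) \
                if denom > 0 else np.zeros(n_steps)
    else:
        frac = np.zeros(n_steps)
    mu_m = np.asarray(config.move_means) + np.outer(frac, config.move_drift)
    mu_t = np.asarray(config.temp_means) + np.outer(frac, config.temp_drift)

    # latent chain: tpm entering step t follows the phase at step t
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.integers(n)
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        P = config.tpm_dark if light[t] == 0 else config.tpm_light
        states[t] = np.searchsorted(np.cumsum(P[states[t - 1]]), u[t])
    sd_m = np.sqrt(config.move_vars)
    sd_t = np.sqrt(config.temp_vars)
    g = mu_m[np.arange(n_steps), states] + rng.normal(size=n_steps) * sd_m[states]
    temp = mu_t[np.arange(n_steps), states] + rng.normal(size=n_steps) * sd_t[states]
    counts = np.maximum(np.round(np.exp(g) - 1.0), 0.0)

    movement = counts.astype(float)
    temp = temp.astype(float)
    if config.missing_rate > 0:
        miss = rng.random(n_steps) < config.missing_rate
        movement[miss] = np.nan
        temp[miss] = np.nan
    series = TelemetrySeries(
        animal_id=f"{config.treatment}_{animal_index + 1:02d}",
        treatment=config.treatment, period=period, timestamps=ts,
        movement_count=movement, temp_median=temp, body_weight=bw,
        light_phase=light)
    if return_states:
        return series, states + 1      # 1-based generating states
    return series


@dataclass
class AnimalRecord:
    """One animal's baseline and treatment-period series."""

    animal_id: str
    treatment: str
    bl: TelemetrySeries
    cr: TelemetrySeries


def simulate_cohort(configs: Sequence[ScenarioConfig]) -> List[AnimalRecord]:
    """Simulate every animal of every scenario, baseline plus treatment."""
    if not configs:
        raise ValidationError("no scenarios given")
    out = []
    seen = set()
    for cfg in configs:
        for a in range(cfg.n_animals):
            bl = simulate_mouse(cfg, a, "BL")
            cr = simulate_mouse(cfg, a, "CR")
            if bl.animal_id in seen:
                raise ValidationError(f"duplicate animal id {bl.animal_id}")
            seen.add(bl.animal_id)
            out.append(AnimalRecord(bl.animal_id, cfg.treatment, bl, cr))
    return out


def default_scenarios(seed: int = 0, n_animals: int = 8,
                      bl_days: int = 14, cr_days: int = 90) -> List[ScenarioConfig]:
    """The six bundled treatment templates (two controls, four CR levels).

    Controls and mild restriction (10/20%) keep their state characteristics;
    30% restriction drifts half the animals and 40% drifts all of them, with
    the state-3 temperature mean declining from 35.5 to 30.0 degC — past the
    31 degC torpor threshold — by the end of treatment.
    """
    common = dict(n_animals=n_animals, bl_days=bl_days, cr_days=cr_days)
    return [
        ScenarioConfig(treatment="12AL", bw_start=34.0, bw_end=34.0,
                       seed=seed * 13 + 1, **common),
        ScenarioConfig(treatment="24AL", bw_start=36.0, bw_end=36.0,
                       seed=seed * 13 + 2, **common),
        ScenarioConfig(treatment="10CR", bw_start=34.0, bw_end=31.5,
                       drift_covariate="BW",
                       move_drift=(-0.05, -0.05, 0.0),
                       temp_drift=(-0.1, -0.1, -0.5),
                       seed=seed * 13 + 3, **common),
        ScenarioConfig(treatment="20CR", bw_start=34.0, bw_end=30.0,
                       drift_covariate="BW",
                       move_drift=(-0.1, -0.05, 0.0),
                       temp_drift=(-0.2, -0.3, -0.8),
                       seed=seed * 13 + 4, **common),
        ScenarioConfig(treatment="30CR", bw_start=35.0, bw_end=28.0,
                       drift_covariate="BW", drift_fraction=0.5,
                       move_drift=(-0.6, -0.2, -0.05),
                       temp_drift=(-0.6, -0.8, -4.8),
                       seed=seed * 13 + 5, **common),
        ScenarioConfig(treatment="40CR", bw_start=35.0, bw_end=26.0,
                       drift_covariate="t", drift_fraction=1.0,
                       move_drift=(-0.8, -0.3, -0.1),
                       temp_drift=(-0.8, -1.0, -5.5),
                       seed=seed * 13 + 6, **common),
    ]


def severe_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The bundled severe-restriction (40% CR analogue) template alone."""
    cfg = default_scenarios(seed)[-1]
    if overrides:
        d = cfg.to_dict()
        d.update(overrides)
        cfg = ScenarioConfig(**d)
    return cfg


def simulate_from_params(params: HMMParameters, spec: ModelSpec, n_steps: int,
                         seed: int = 0, covariate: Optional[np.ndarray] = None):
    """Simulate a series directly from fitted HMM parameters.

    Emissions stay on the model's own continuous Gaussian scale (the movement
    channel is stored as expm1 of the Gaussian draw, not rounded to counts),
    which is what self-consistency residual checks require.  Returns
    ``(series, states)`` with 1-based generating states.
    """
    rng = np.random.default_rng(seed)
    z = np.zeros(n_steps) if covariate is None else np.asarray(covariate, float)
    n = params.n_states
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(n, p=params.pi / params.pi.sum())
    for t in range(1, n_steps):
        P = tpm_at(params, z[t] if spec.tpm_covariate != "none" else 0.0)
        states[t] = rng.choice(n, p=P[states[t - 1]])
    mu_m, mu_t = params.emission_means(z)
    m = mu_m[np.arange(n_steps), states] + \
        rng.normal(size=n_steps) * np.sqrt(params.var_M[states])
    temp = mu_t[np.arange(n_steps), states] + \
        rng.normal(size=n_steps) * np.sqrt(params.var_T[states])
    m = np.maximum(m, 0.0)      # counts cannot be negative; keep means high
    ts = _grid(np.datetime64("2015-01-01T00:00:00"), n_steps)
    series = TelemetrySeries(
        animal_id="selfsim", treatment="12AL", period="BL", timestamps=ts,
        movement_count=np.expm1(m), temp_median=temp,
        body_weight=np.full(n_steps, 30.0), light_phase=_light_phase(ts))
    return series, states + 1
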