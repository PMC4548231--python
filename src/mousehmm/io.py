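"""Delimited-text IO, minute-to-window aggregation, and the pipeline driver.

The on-disk dialect is fixed so round-trips are bit-exact: comma-separated
with a header, ISO-8601 timestamps, and the literal ``NA`` for missing
values.  The pipeline driver runs simulate -> fit/select -> validate ->
analyse for a whole cohort from one config, writing every artifact plus a
manifest recording the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import TelemetrySeries, ValidationError
from .simulate import (LIGHTS_OFF_MIN, LIGHTS_ON_MIN, AnimalRecord,
                       ScenarioConfig, default_scenarios, simulate_cohort)

__all__ = ["write_telemetry", "read_telemetry", "aggregate_windows",
           "run_pipeline"]

log = logging.getLogger("mousehmm")

_COLUMNS = ["animal_id", "treatment", "period", "timestamp", "movement_count",
            "temp_median", "body_weight", "light_phase"]


def _to_frame(series: TelemetrySeries) -> pd.DataFrame:
    return pd.DataFrame({
        "animal_id": series.animal_id,
        "treatment": series.treatment,
        "period": series.period,
        "timestamp": np.datetime_as_string(series.timestamps, unit="s"),
        "movement_count": series.movement_count,
        "temp_median": series.temp_median,
        "body_weight": series.body_weight,
        "light_phase": series.light_phase,
    })


def write_telemetry(series: Union[TelemetrySeries, Sequence[TelemetrySeries]],
                    path) -> None:
    """Write one or many telemetry series to one CSV (NA for missing)."""
    if isinstance(series, TelemetrySeries):
        series = [series]
    pd.concat([_to_frame(s) for s in series]).to_csv(
        path, index=False, na_rep="NA")


def read_telemetry(path) -> List[TelemetrySeries]:
    """Read a telemetry CSV back into per-animal, per-period series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"telemetry file not found: {path}")
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"telemetry file lacks columns {sorted(missing)}")
    out = []
    for (animal, period), grp in df.groupby(["animal_id", "period"], sort=False):
        out.append(TelemetrySeries(
            animal_id=str(animal), treatment=str(grp["treatment"].iloc[0]),
            period=str(period),
            timestamps=grp["timestamp"].to_numpy(dtype="datetime64[s]"),
            movement_count=grp["movement_count"].to_numpy(dtype=float),
            temp_median=grp["temp_median"].to_numpy(dtype=float),
            body_weight=grp["body_weight"].to_numpy(dtype=float),
            light_phase=grp["light_phase"].to_numpy(dtype=int)))
    return out


def aggregate_windows(minutes: pd.DataFrame, animal_id: str = "animal",
                      treatment: str = "12AL", period: str = "BL",
                      body_weight: Optional[pd.Series] = None,
                      lights_on_min: int = LIGHTS_ON_MIN,
                      lights_off_min: int = LIGHTS_OFF_MIN) -> TelemetrySeries:
    """Aggregate minute records into clock-aligned 15-minute windows.

    ``minutes`` needs columns ``timestamp``, ``movement_count`` and
    ``temp_median``.  Movement is summed and temperature is the median over
    each window; a window with a gap (a missing minute) or a NaN on a
    channel gets NA on the affected channel(s) — the telemetry tag failed
    during that window.  ``body_weight`` maps calendar dates to grams; a
    constant 30 g is used when absent.
    """
    df = minutes.copy()
    ts = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
    if len(ts) == 0:
        raise ValidationError("no minute records")
    if np.any(np.diff(ts) <= np.timedelta64(0, "s")):
        order = np.argsort(ts, kind="stable")
        if len(np.unique(ts)) != len(ts):
            raise ValidationError("duplicate minute timestamps")
        raise ValidationError("minute timestamps must be ordered")
    win = ts.astype("datetime64[m]")
    win = win - (win.astype(int) % 15).astype("timedelta64[m]")
    first, last = win[0], win[-1]
    grid = np.arange(first, last + np.timedelta64(15, "m"),
                     np.timedelta64(15, "m"))
    move = np.full(len(grid), np.nan)
    temp = np.full(len(grid), np.nan)
    mv = df["movement_count"].to_numpy(dtype=float)
    tm = df["temp_median"].to_numpy(dtype=float)
    pos = ((win - first) / np.timedelta64(15, "m")).astype(int)
    for k in range(len(grid)):
        sel = pos == k
        if sel.sum() < 15:          # gap: the tag missed minutes
            continue
        m = mv[sel]
        t = tm[sel]
        if np.all(np.isfinite(m)):
            move[k] = m.sum()
        if np.all(np.isfinite(t)):
            temp[k] = float(np.median(t))
    mins_of_day = (grid - grid.astype("datetime64[D]")).astype(
        "timedelta64[m]").astype(int)
    light = ((mins_of_day >= lights_on_min) &
             (mins_of_day < lights_off_min)).astype(int)
    if body_weight is None:
        bw = np.full(len(grid), 30.0)
    else:
        days = pd.Series(grid.astype("datetime64[D]"))
        bw = days.map(lambda d: float(body_weight.get(pd.Timestamp(d), np.nan))
                      ).to_numpy()
    return TelemetrySeries(animal_id=animal_id, treatment=treatment,
                           period=period, timestamps=grid,
                           movement_count=move, temp_median=temp,
                           body_weight=bw, light_phase=light)


# ---------------------------------------------------------------------------
# pipeline driver


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: Union[dict, str, Path], out_dir=None) -> Path:
    """Run simulate/load -> fit grid -> select -> validate -> analyse.

    ``config`` is a dict or a YAML/JSON file with keys ``seed``, ``out_dir``,
    optional ``scenarios`` (list of ScenarioConfig fields; defaults to the
    six bundled templates scaled by ``n_animals``/``cr_days``), optional
    ``input`` (a telemetry CSV instead of simulation), ``grid`` (list of
    candidate names to fit; default all 30) and fit options.  Per-animal
    failures are logged and skipped; a manifest records the config hash and
    seed.  Returns the artifact directory.
    """
    from .em import EMFailure
    from .inference import decode
    from .phenotype import (covariate_endpoints, paired_state_difference,
                            paired_tpm_difference, manova_state_shift,
                            tpm_shift_tests, torpor_flag, activity_budget)
    from .selection import build_model_grid, select_model
    from .validation import pseudo_residuals, qq_summary

    if not isinstance(config, dict):
        text = Path(config).read_text()
        try:
            config = json.loads(text)
        except json.JSONDecodeError:
            import yaml
            config = yaml.safe_load(text)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "mousehmm_out"))
    out.mkdir(parents=True, exist_ok=True)

    if "input" in config:
        all_series = read_telemetry(config["input"])
        animals = {}
        for s in all_series:
            animals.setdefault(s.animal_id, {})[s.period] = s
        cohort = [AnimalRecord(a, d["BL"].treatment, d["BL"], d["CR"])
                  for a, d in animals.items() if {"BL", "CR"} <= set(d)]
    else:
        if "scenarios" in config:
            scenarios = [ScenarioConfig(**sc) for sc in config["scenarios"]]
        else:
            scenarios = default_scenarios(
                seed, n_animals=int(config.get("n_animals", 8)),
                bl_days=int(config.get("bl_days", 14)),
                cr_days=int(config.get("cr_days", 90)))
        cohort = simulate_cohort(scenarios)
        write_telemetry([s for rec in cohort for s in (rec.bl, rec.cr)],
                        out / "telemetry.csv")

    grid = build_model_grid()
    if "grid" in config:
        wanted = set(config["grid"])
        grid = [g for g in grid if g.name in wanted]
    fit_opts = dict(n_restarts=int(config.get("n_restarts", 10)),
                    tol=float(config.get("tol", 1e-8)),
                    max_iter=int(config.get("max_iter", 500)))

    aic_rows, diffs, tpm_diffs, treatments, torpor_rows = [], [], [], [], []
    failures = []
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    for rec in cohort:
        try:
            fits = {}
            for period, series in (("BL", rec.bl), ("CR", rec.cr)):
                sel = select_model(series, grid, seed=seed, **fit_opts)
                sel.table.insert(0, "animal_id", rec.animal_id)
                sel.table.insert(1, "period", period)
                aic_rows.append(sel.table)
                fits[period] = sel.best
                sel.best.to_json(fits_dir / f"{rec.animal_id}_{period}.json")
                res = pseudo_residuals(sel.best, series)
                qq = {ch: qq_summary(getattr(res, ch))["correlation"]
                      for ch in ("movement", "temperature")}
                path = decode(sel.best, series)
                budget = activity_budget(path, series)
                with open(out / f"{rec.animal_id}_{period}_checks.json", "w") as fh:
                    json.dump({"qq_correlation": qq,
                               "budget": {k: v.tolist()
                                          for k, v in budget.items()}}, fh)
            zb, _ = covariate_endpoints(fits["BL"], rec.bl)
            _, zc = covariate_endpoints(fits["CR"], rec.cr)
            n = min(fits["BL"].params.n_states, fits["CR"].params.n_states)
            diffs.append((rec.animal_id, paired_state_difference(
                fits["BL"], fits["CR"], zb, zc)[:n]))
            tpm_diffs.append(paired_tpm_difference(fits["BL"], fits["CR"], zb, zc))
            treatments.append(rec.treatment)
            flag, t3 = torpor_flag(fits["CR"], zc)
            torpor_rows.append({"animal_id": rec.animal_id,
                                "treatment": rec.treatment,
                                "torpor": bool(flag), "state3_temp_end": t3})
        except (EMFailure, ValidationError) as exc:
            log.warning("animal %s failed: %s", rec.animal_id, exc)
            failures.append({"animal_id": rec.animal_id, "error": str(exc)})

    pd.concat(aic_rows).to_csv(out / "aic_table.csv", index=False)
    pd.DataFrame(torpor_rows).to_csv(out / "torpor.csv", index=False)
    results = {}
    n_common = min((d.shape[0] for _, d in diffs), default=0)
    if len(diffs) >= 4 and len(set(treatments)) >= 2 and n_common >= 1:
        arr = np.stack([d[:n_common] for _, d in diffs])
        results["state_shift"] = manova_state_shift(arr, treatments)
        shapes = {d.shape for d in tpm_diffs}
        if len(shapes) == 1:
            results["tpm_shift"] = tpm_shift_tests(np.stack(tpm_diffs), treatments)
        with open(out / "manova.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)
    manifest = {"config_hash": _config_hash(config), "seed": seed,
                "n_animals": len(cohort), "n_failures": len(failures),
                "failures": failures}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
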