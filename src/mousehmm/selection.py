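"""Candidate-model grid and AIC selection.

The grid crosses 2- and 3-state models with all covariate placements that use
a single covariate (elapsed time ``t`` or daily body weight ``BW``) on the
emission means, the transition matrix, or both — 15 placements per state
count, 30 candidates in total.  Each candidate is fitted independently by EM
and the winner is the minimum-AIC fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import pandas as pd

from .em import EMFailure, em_fit
from .model import FittedModel, ModelSpec, TelemetrySeries

__all__ = ["build_model_grid", "select_model", "SelectionResult"]

# (tpm, movement-mean, temperature-mean) covariate placements, grid order
_PLACEMENTS = [
    ("none", "none", "none"),
    ("none", "t", "none"),
    ("none", "none", "t"),
    ("none", "t", "t"),
    ("none", "BW", "none"),
    ("none", "none", "BW"),
    ("none", "BW", "BW"),
    ("t", "none", "none"),
    ("BW", "none", "none"),
    ("t", "t", "none"),
    ("t", "none", "t"),
    ("t", "t", "t"),
    ("BW", "BW", "none"),
    ("BW", "none", "BW"),
    ("BW", "BW", "BW"),
]


def build_model_grid() -> List[ModelSpec]:
    """All 30 candidate specs: HMM2.1-HMM2.15 then HMM3.1-HMM3.15."""
    grid = []
    for n in (2, 3):
        for k, (tpm, move, temp) in enumerate(_PLACEMENTS, start=1):
            grid.append(ModelSpec(n_states=n, tpm_covariate=tpm,
                                  movement_mean_covariate=move,
                                  temp_mean_covariate=temp,
                                  name=f"HMM{n}.{k}"))
    return grid


@dataclass
class SelectionResult:
    best: FittedModel
    table: pd.DataFrame = field(repr=False)
    fits: dict = field(repr=False, default_factory=dict)


def select_model(series: TelemetrySeries,
                 grid: Optional[Sequence[ModelSpec]] = None,
                 seed: int = 0, n_restarts: int = 10,
                 tol: float = 1e-8, max_iter: int = 500,
                 retry_batches: int = 2,
                 keep_fits: bool = False) -> SelectionResult:
    """Fit every candidate and select the minimum-AIC model.

    Ties break toward fewer parameters, then lower grid index.  A candidate
    whose restarts all fail is retried with up to ``retry_batches`` fresh
    restart batches, then recorded as failed and excluded.
    """
    if grid is None:
        grid = build_model_grid()
    if len(grid) == 0:
        raise ValueError("model grid is empty")
    rows = []
    best = None
    best_key = None
    fits = {}
    for idx, spec in enumerate(grid):
        fit = None
        for batch in range(1 + retry_batches):
            try:
                fit = em_fit(spec, series, seed=seed + 1000 * batch,
                             tol=tol, max_iter=max_iter, n_restarts=n_restarts)
                break
            except EMFailure:
                continue
        if fit is None:
            rows.append({"name": spec.name, "loglik": float("nan"),
                         "n_params": spec.n_params(), "aic": float("nan"),
                         "converged": False, "failed": True})
            continue
        rows.append({"name": spec.name, "loglik": fit.loglik,
                     "n_params": fit.n_params, "aic": fit.aic,
                     "converged": fit.converged, "failed": False})
        if keep_fits:
            fits[spec.name] = fit
        key = (fit.aic, fit.n_params, idx)
        if best is None or key < best_key:
            best, best_key = fit, key
    if best is None:
        raise EMFailure("every candidate model failed to fit")
    return SelectionResult(best=best, table=pd.DataFrame(rows), fits=fits)
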