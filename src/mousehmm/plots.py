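"""Diagnostic figures: residual QQ plots and state-characteristic contours."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .validation import qq_summary

__all__ = ["qq_plot", "state_contour_plot"]

_STATE_COLORS = ("tab:blue", "tab:red", "black")


def qq_plot(residuals: np.ndarray, path, title: str = "") -> None:
    """Residuals against standard-normal quantiles, identity line for reference."""
    qq = qq_summary(residuals)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(qq["theoretical"], qq["empirical"], ".", ms=3)
    lim = [qq["theoretical"][0], qq["theoretical"][-1]]
    ax.plot(lim, lim, "k-", lw=0.8)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("residual quantile")
    ax.set_title(title or f"QQ correlation {qq['correlation']:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def state_contour_plot(draws: np.ndarray, path, title: str = "") -> None:
    """Density contours of per-state (log-movement, temperature) draws.

    ``draws`` is (n_states, n_draws, 2) as returned by
    ``state_characteristic_draws`` (possibly concatenated over animals).
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    for i in range(draws.shape[0]):
        m, t = draws[i, :, 0], draws[i, :, 1]
        color = _STATE_COLORS[i % len(_STATE_COLORS)]
        H, xe, ye = np.histogram2d(m, t, bins=40)
        xc = 0.5 * (xe[:-1] + xe[1:])
        yc = 0.5 * (ye[:-1] + ye[1:])
        ax.contour(xc, yc, H.T, levels=4, colors=color, linewidths=0.9)
        ax.plot([], [], color=color, label=f"state {i + 1}")
    ax.set_xlabel("log(movement count + 1)")
    ax.set_ylabel("body temperature (degC)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
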