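"""Sensitive-window detection from a per-lag effect curve.

A sensitive window is a maximal run of contiguous months of life whose
pointwise confidence interval excludes zero — strictly above it (harmful)
or strictly below it (protective).  An interval touching zero does not
exclude it.  Windows are summarized in the reporting style of the
epidemiological literature: bounds as ages ("birth to 7 months",
"4 years 4 months"), peak month and peak effect with its CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dlm import LagEffectCurve


@dataclass
class SensitiveWindow:
    """Maximal run of months whose CI excludes zero on one side."""

    start_month: int
    end_month: int
    direction: str        # "harmful" | "protective"
    peak_month: int
    peak_effect: float
    peak_ci: tuple        # (low, high)

    def __post_init__(self) -> None:
        if self.start_month > self.end_month:
            raise ValueError("window start after end")
        if not self.start_month <= self.peak_month <= self.end_month:
            raise ValueError("peak month outside window")

    @property
    def months(self) -> range:
        return range(self.start_month, self.end_month + 1)


def format_age(months: int) -> str:
    """Age in completed months -> "birth" / "7 months" / "4 years 4 months"."""
    if months <= 0:
        return "birth"
    years, rem = divmod(months, 12)
    if years == 0:
        return f"{rem} month{'s' if rem != 1 else ''}"
    label = f"{years} year{'s' if years != 1 else ''}"
    if rem:
        label += f" {rem} month{'s' if rem != 1 else ''}"
    return label


def format_window(start_month: int, end_month: int) -> str:
    """Window bounds as an age range; month of life m spans ages m-1..m
    months, so the window starts at age start-1 and ends at age end."""
    return f"{format_age(start_month - 1)} to {format_age(end_month)}"


def detect_windows(curve: LagEffectCurve) -> list:
    """Maximal runs of months with ci_low > 0 (harmful) or ci_high < 0
    (protective).  Runs of length one count; opposite directions are never
    merged.  Zero on the boundary is not excluded."""
    if np.any(curve.ci_low > curve.ci_high):
        raise ValueError("curve has ci_low > ci_high")
    state = np.where(curve.ci_low > 0, 1, np.where(curve.ci_high < 0, -1, 0))
    windows = []
    i, L = 0, len(state)
    while i < L:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < L and state[j + 1] == state[i]:
            j += 1
        seg = slice(i, j + 1)
        rel = int(np.argmax(np.abs(curve.beta[seg])))
        peak = i + rel
        windows.append(SensitiveWindow(
            start_month=int(curve.lag[i]), end_month=int(curve.lag[j]),
            direction="harmful" if state[i] > 0 else "protective",
            peak_month=int(curve.lag[peak]),
            peak_effect=float(curve.beta[peak]),
            peak_ci=(float(curve.ci_low[peak]), float(curve.ci_high[peak])),
        ))
        i = j + 1
    return windows


def summarize_peaks(windows: list, curve: LagEffectCurve,
                    scale: str = "") -> pd.DataFrame:
    """One report row per window: formatted bounds, peak month and effect."""
    rows = []
    for w in windows:
        rows.append({
            "scale": scale,
            "start_month": w.start_month,
            "end_month": w.end_month,
            "window": format_window(w.start_month, w.end_month),
            "direction": w.direction,
            "peak_month": w.peak_month,
            "peak_age": format_age(w.peak_month - 1),
            "peak_effect": w.peak_effect,
            "peak_lo": w.peak_ci[0],
            "peak_hi": w.peak_ci[1],
        })
    cols = ["scale", "start_month", "end_month", "window", "direction",
            "peak_month", "peak_age", "peak_effect", "peak_lo", "peak_hi"]
    return pd.DataFrame(rows, columns=cols)


def plot_lag_curve(curve: LagEffectCurve, windows: list | None = None,
                   ax=None, title: str = ""):
    """Lag-effect curve with CI band and shaded sensitive windows."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    years = curve.lag / 12.0
    ax.fill_between(years, curve.ci_low, curve.ci_high, color="0.8",
                    label="95% CI")
    ax.plot(years, curve.beta, color="k", lw=1.5)
    ax.axhline(0.0, color="0.4", lw=0.8, ls="--")
    for w in windows or []:
        color = "tab:red" if w.direction == "harmful" else "tab:blue"
        ax.axvspan((w.start_month - 1) / 12.0, w.end_month / 12.0,
                   color=color, alpha=0.15)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("score change per 1 ng/m$^3$")
    if title:
        ax.set_title(title)
    return ax
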