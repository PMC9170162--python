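"""Radial wave analysis for focal-activation experiments.

After focal activation (e.g. photorelease of IP₃) the Ca²⁺ wave spreads
outward at an approximately constant speed, so distance from the site is a
linear function of activation time. The wave speed is the slope of an
ordinary least-squares fit of distance on time. Cells lying far ahead of
the front — "short-circuit" cells reached through long cellular processes —
are flagged as cells whose distance exceeds the front prediction at their
activation time by more than k (default 3) residual standard deviations;
an alternative per-time-bin rule (distance > bin mean + k × bin SD) is
also provided since either reading is defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class WaveFit:
    """OLS fit of distance (µm) on activation time (s)."""

    slope: float        # µm/s, the wave speed
    intercept: float    # µm
    residual_sd: float  # µm
    n: int

    def predict(self, time_s):
        return self.slope * np.asarray(time_s) + self.intercept


@dataclass(frozen=True)
class WaveResult:
    """Per-cell wave table with shortcut flags and the front fit."""

    table: pd.DataFrame       # cell_id, distance_um, time_s, velocity, shortcut
    fit: WaveFit
    distance_threshold: float  # µm; min distance among flagged cells
    k_sd: float
    mode: str


def wave_fit(distances, times) -> WaveFit:
    """Least-squares line distance = slope × time + intercept."""
    d = np.asarray(distances, dtype=float)
    t = np.asarray(times, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 active cells")
    if np.unique(t).size < 2:
        raise ValueError("degenerate fit: all activation times equal")
    res = stats.linregress(t, d)
    resid = d - (res.slope * t + res.intercept)
    ddof = 2 if d.size > 2 else 0
    sd = float(np.sqrt((resid ** 2).sum() / (d.size - ddof)))
    return WaveFit(slope=float(res.slope), intercept=float(res.intercept),
                   residual_sd=sd, n=d.size)


def detect_shortcuts(activations: pd.DataFrame, fit: WaveFit,
                     k_sd: float = 3.0, mode: str = "residual",
                     time_bin_s: float = 1.0) -> WaveResult:
    """Flag cells activating ahead of the wave front.

    ``activations`` needs columns ``cell_id``, ``distance_um``, ``time_s``.
    In ``residual`` mode (default) a cell is flagged when its distance
    exceeds the fit prediction at its time by more than ``k_sd`` residual
    SDs. In ``time_binned`` mode cells are binned by activation time and
    flagged when their distance exceeds the bin mean by ``k_sd`` bin SDs.
    ``distance_threshold`` is the minimum distance among flagged cells (NaN
    when none are flagged).
    """
    df = activations.copy()
    d = df["distance_um"].to_numpy(dtype=float)
    t = df["time_s"].to_numpy(dtype=float)
    if mode == "residual":
        if fit.residual_sd == 0:
            warnings.warn("zero residual SD: no shortcut cells flagged",
                          stacklevel=2)
            flagged = np.zeros(d.size, dtype=bool)
        else:
            flagged = (d - fit.predict(t)) > k_sd * fit.residual_sd
    elif mode == "time_binned":
        bins = np.floor(t / time_bin_s).astype(int)
        flagged = np.zeros(d.size, dtype=bool)
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < 3:
                continue
            mu, sd = d[sel].mean(), d[sel].std()
            if sd > 0:
                flagged[sel] = d[sel] > mu + k_sd * sd
    else:
        raise ValueError(f"unknown mode {mode!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        velocity = np.where(t > 0, d / t, np.nan)
    df["velocity_um_s"] = velocity
    df["shortcut"] = flagged
    thr = float(d[flagged].min()) if flagged.any() else float("nan")
    return WaveResult(table=df, fit=fit, distance_threshold=thr,
                      k_sd=k_sd, mode=mode)


def analyze_wave(activations: pd.DataFrame, k_sd: float = 3.0,
                 mode: str = "residual") -> WaveResult:
    """Fit the wave front and flag short-circuit cells in one call."""
    fit = wave_fit(activations["distance_um"], activations["time_s"])
    return detect_shortcuts(activations, fit, k_sd=k_sd, mode=mode)
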