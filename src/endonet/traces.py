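"""Trace processing: F/F₀ normalization, event detection, responder selection.

The analysis chain mirrors standard practice for multicellular Ca²⁺
recordings: traces are self-normalized to their baseline mean (F/F₀), the
first difference of each trace is thresholded at a multiple (default five)
of the baseline-noise SD of the derivative to produce a binary event raster,
and activation times are read off the raster. Because agonist sensitivity
varies between preparations, analyses that target the EC₂₅-responsive
population are restricted to the earliest-responding 25% of cells; an
optional initial window after onset (default 5 min) can be excluded to drop
the synchronized onset burst.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CalciumRecording:
    """Cells × timepoints F/F₀ matrix with sampling rate and stimulus onset."""

    values: np.ndarray
    fs: float
    onset: float
    cell_ids: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("values must be a cells x timepoints matrix "
                             "with at least 2 timepoints")
        if not np.isfinite(v).all():
            raise ValueError("values contain missing or non-finite entries")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.cell_ids) != v.shape[0]:
            raise ValueError("cell_ids length does not match values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.fs


@dataclass(frozen=True)
class EventRaster:
    """Binary events from the thresholded derivative.

    Column ``i`` covers the first difference between trace samples ``i`` and
    ``i + 1`` and is stamped at the time of the later sample,
    ``(i + 1) / fs`` (an event is detected at the sample where the rise has
    occurred).
    """

    events: np.ndarray            # bool, cells x (timepoints - 1)
    fs: float
    onset: float
    cell_ids: np.ndarray
    threshold_sd_mult: float = 5.0
    baseline_window: tuple = (0.0, 0.0)

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.events.shape[1]) + 1) / self.fs

    @property
    def n_cells(self) -> int:
        return self.events.shape[0]


def baseline_correct(raw, fs: float, baseline_window, onset: float = 0.0,
                     cell_ids=None) -> CalciumRecording:
    """Divide each trace by its baseline-window mean (F/F₀).

    ``baseline_window`` is a half-open interval [start, end) in seconds; it
    must span at least one second. After correction the baseline-window mean
    of every trace equals 1.
    """
    raw = np.asarray(raw, dtype=float)
    start, end = baseline_window
    if end - start < 1.0:
        raise ValueError("baseline window must span at least 1 s")
    i0, i1 = int(math.ceil(start * fs)), int(math.ceil(end * fs))
    if i1 > raw.shape[1] or i1 <= i0:
        raise ValueError("baseline window outside the recording")
    f0 = raw[:, i0:i1].mean(axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive baseline mean for cell(s) {bad.tolist()}"
        )
    if cell_ids is None:
        cell_ids = np.arange(raw.shape[0])
    return CalciumRecording(values=raw / f0[:, None], fs=fs, onset=onset,
                            cell_ids=np.asarray(cell_ids))


def binarize(rec: CalciumRecording, threshold_sd_mult: float = 5.0,
             baseline_window=None) -> EventRaster:
    """Threshold the first difference of each trace at a multiple of its
    baseline-noise SD.

    The SD is measured on the *derivative* within the baseline window
    (default: everything before onset), because that is the signal the
    threshold is applied to. Output is 1 where the derivative strictly
    exceeds the per-cell threshold.
    """
    if baseline_window is None:
        baseline_window = (0.0, rec.onset)
    start, end = baseline_window
    deriv = np.diff(rec.values, axis=1)
    tmid = (np.arange(deriv.shape[1]) + 1) / rec.fs
    mask = (tmid >= start) & (tmid < end)
    if not mask.any():
        raise ValueError("baseline window contains no derivative samples")
    sd = deriv[:, mask].std(axis=1)
    zero_sd = sd == 0
    if zero_sd.any():
        active_anyway = (deriv[zero_sd] > 0).any(axis=1)
        if active_anyway.any():
            warnings.warn(
                "zero baseline-derivative SD with later activity in "
                f"{int(active_anyway.sum())} cell(s); threshold is 0",
                stacklevel=2,
            )
    events = deriv > (threshold_sd_mult * sd)[:, None]
    return EventRaster(events=events, fs=rec.fs, onset=rec.onset,
                       cell_ids=rec.cell_ids,
                       threshold_sd_mult=threshold_sd_mult,
                       baseline_window=(start, end))


def detect_activation(rec: CalciumRecording, raster: EventRaster) -> pd.DataFrame:
    """Per-cell activation table.

    A cell is active iff it has at least one event at or after onset;
    ``activation_time`` is the time of the first such event and ``peak`` the
    maximum post-onset F/F₀.
    """
    if not 0 <= rec.onset < rec.n_timepoints / rec.fs:
        raise ValueError("onset outside the recording")
    times = raster.times
    post = times >= rec.onset
    ev = raster.events[:, post]
    active = ev.any(axis=1)
    first = np.full(rec.n_cells, np.nan)
    idx = np.argmax(ev, axis=1)
    first[active] = times[post][idx[active]]
    t_post = rec.times >= rec.onset
    peak = rec.values[:, t_post].max(axis=1)
    return pd.DataFrame({
        "cell_id": np.asarray(rec.cell_ids),
        "active": active,
        "activation_time": first,
        "peak": peak,
    })


def select_first_responders(table: pd.DataFrame,
                            fraction: float = 0.25) -> np.ndarray:
    """Ids of the earliest-activating ``ceil(fraction * n_cells)`` cells.

    If fewer cells responded than that quota, all responders are returned.
    Ties in activation time are broken by ascending cell id (deterministic).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    quota = math.ceil(fraction * len(table))
    resp = table[table["active"]].sort_values(
        ["activation_time", "cell_id"], kind="mergesort"
    )
    if len(resp) > quota:
        resp = resp.iloc[:quota]
    return resp["cell_id"].to_numpy()


def exclude_initial_window(raster: EventRaster, skip: float = 300.0) -> EventRaster:
    """Zero all events in [onset, onset + skip).

    Drops the synchronized burst that follows stimulus onset. Events before
    onset or at/after onset + skip are untouched; the operation is
    idempotent.
    """
    if skip < 0:
        raise ValueError("skip must be >= 0")
    if skip == 0:
        return raster
    end = raster.onset + skip
    if end >= raster.times[-1] and not (raster.times < raster.onset).any():
        warnings.warn("exclusion window covers the whole post-onset record",
                      stacklevel=2)
    mask = (raster.times >= raster.onset) & (raster.times < end)
    events = raster.events.copy()
    events[:, mask] = False
    return EventRaster(events=events, fs=raster.fs, onset=raster.onset,
                       cell_ids=raster.cell_ids,
                       threshold_sd_mult=raster.threshold_sd_mult,
                       baseline_window=raster.baseline_window)
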