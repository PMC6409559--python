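"""Editing, cleaning, smoothing and combining of breath-by-breath series.

Exclusion filters (cardiodynamic trim, rolling-SD outlier removal, point
deletion) drop samples and report exactly which indices went; aggregation
filters (box average, moving average, 1-s interpolation, ensemble
averaging) resample the signal.  Every operation appends a replayable
record to the series' edit log, so a processed series can always be
reconstructed bit-exactly from the raw input.

The conventional default pipeline for kinetics fitting is trimming the
first 20 s (cardiodynamic phase) and nothing else — parameter estimates
are best obtained from otherwise raw data, since smoothing deliberately
attenuates the very noise the bootstrap is meant to propagate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import (
    EmptySeriesError,
    InsufficientDataError,
    InvalidInputError,
    InvalidWindowError,
    NoOverlapError,
)
from .series import BreathSeries, EditRecord


@dataclass(frozen=True)
class FilterReport:
    """Audit trail for one filter application."""

    filter_name: str
    parameters: Mapping[str, Any]
    indices_removed: tuple[int, ...]
    n_before: int
    n_after: int


def _report(name, params, removed, n_before, n_after) -> FilterReport:
    return FilterReport(name, dict(params), tuple(int(i) for i in removed),
                        int(n_before), int(n_after))


# ---------------------------------------------------------------------------
# Exclusion filters
# ---------------------------------------------------------------------------

def trim_cardiodynamic(series: BreathSeries, cutoff: float = 20.0) -> BreathSeries:
    """Drop the cardiodynamic (phase I) samples: keep t ≥ cutoff.

    The removal is half-open, [0, cutoff): a breath at exactly the cutoff
    time is retained.
    """
    if cutoff < 0:
        raise InvalidInputError(f"cutoff must be non-negative, got {cutoff}")
    keep = series.time >= cutoff
    if not keep.any():
        raise EmptySeriesError(f"trimming at {cutoff} s removed every sample")
    removed = tuple(int(i) for i in np.flatnonzero(~keep))
    rec = EditRecord("trim_cardiodynamic", {"cutoff": float(cutoff)}, removed)
    return series.with_samples(series.time[keep], series.vo2[keep], rec)


def rolling_sd_exclude(
    series: BreathSeries, window: int = 15, k: float = 4.0
) -> tuple[BreathSeries, FilterReport]:
    """Single-pass errant-breath exclusion.

    For each breath, the mean and SD of a centered window of ``window``
    breaths are computed *excluding the breath itself*; the breath is
    removed when it deviates from that local mean by more than ``k``
    standard deviations.  k = 4 is the conventional low-stringency choice.
    Breaths too close to either end for a full centered window are never
    excluded (an asymmetric window on a curved signal would misread
    curvature as deviation).  A zero local SD never excludes (deviation 0
    is not > 0).
    """
    if window < 3:
        raise InvalidWindowError(f"window must be >= 3 breaths, got {window}")
    if k <= 0:
        raise InvalidInputError(f"k must be positive, got {k}")
    n = series.n
    if window > n:
        raise InvalidWindowError(f"window of {window} breaths exceeds series length {n}")
    half = window // 2
    v = series.vo2
    removed = []
    for i in range(half, n - half):
        neigh = np.concatenate([v[i - half: i], v[i + 1: i + half + 1]])
        m, sd = neigh.mean(), neigh.std(ddof=1)
        if abs(v[i] - m) > k * sd:
            removed.append(i)
    keep = np.ones(n, dtype=bool)
    keep[removed] = False
    report = _report("rolling_sd_exclude", {"window": window, "k": k},
                     removed, n, int(keep.sum()))
    if not keep.any():
        raise EmptySeriesError("rolling-SD exclusion removed every sample")
    rec = EditRecord("rolling_sd_exclude", {"window": window, "k": float(k)},
                     tuple(removed))
    out = series.with_samples(series.time[keep], series.vo2[keep], rec)
    return out, report


def delete_points(
    series: BreathSeries,
    indices: Sequence[int] | None = None,
    time_range: tuple[float, float] | None = None,
) -> BreathSeries:
    """Remove specific breaths by index or by closed time range [t0, t1]."""
    n = series.n
    drop = np.zeros(n, dtype=bool)
    if indices is not None:
        idx = np.asarray(list(indices), dtype=int)
        bad = idx[(idx < 0) | (idx >= n)]
        if bad.size:
            raise InvalidInputError(f"indices out of range [0, {n}): {bad.tolist()}")
        drop[idx] = True
    if time_range is not None:
        t0, t1 = time_range
        drop |= (series.time >= t0) & (series.time <= t1)
    if not drop.any():
        return series
    if drop.all():
        raise EmptySeriesError("deletion would remove every sample")
    removed = tuple(int(i) for i in np.flatnonzero(drop))
    rec = EditRecord(
        "delete_points",
        {"indices": list(indices) if indices is not None else None,
         "time_range": list(time_range) if time_range is not None else None},
        removed,
    )
    return series.with_samples(series.time[~drop], series.vo2[~drop], rec)


# ---------------------------------------------------------------------------
# Aggregation filters
# ---------------------------------------------------------------------------

def box_average(series: BreathSeries, box: float) -> BreathSeries:
    """Average breaths inside consecutive half-open time bins
    [i·box, (i+1)·box); one output sample per non-empty bin, placed at the
    bin midpoint."""
    if box <= 0:
        raise InvalidInputError(f"box duration must be positive, got {box}")
    bins = np.floor(series.time / box).astype(int)
    uniq = np.unique(bins)
    t_out = (uniq + 0.5) * box
    v_out = np.array([series.vo2[bins == b].mean() for b in uniq])
    rec = EditRecord("box_average", {"box": float(box)})
    return series.with_samples(t_out, v_out, rec)


def moving_average(series: BreathSeries, window: int) -> BreathSeries:
    """Centered moving mean over ``window`` breaths (odd), shrinking
    symmetrically at the edges; timestamps unchanged."""
    if window < 1 or window % 2 == 0:
        raise InvalidInputError(
            f"window must be an odd breath count >= 1, got {window}"
        )
    n = series.n
    half = window // 2
    v = series.vo2
    out = np.empty(n)
    for i in range(n):
        r = min(half, i, n - 1 - i)
        out[i] = v[i - r: i + r + 1].mean()
    rec = EditRecord("moving_average", {"window": window})
    return series.with_samples(series.time.copy(), out, rec)


def interpolate_1s(series: BreathSeries) -> BreathSeries:
    """Linear interpolation onto the integer-second grid inside the
    observed span [ceil(t_min), floor(t_max)]; never extrapolates."""
    if series.n < 2:
        raise InsufficientDataError("interpolation requires at least 2 samples")
    t0, t1 = np.ceil(series.t_start), np.floor(series.t_end)
    if t1 < t0:
        raise InsufficientDataError("series spans no integer second")
    grid = np.arange(t0, t1 + 1.0)
    v = np.interp(grid, series.time, series.vo2)
    rec = EditRecord("interpolate_1s", {})
    return series.with_samples(grid, v, rec)


def ensemble_average(transitions: Sequence[BreathSeries]) -> BreathSeries:
    """Time-aligned ensemble average of repeated exercise transitions.

    Each transition (already time-zeroed at its own onset) is interpolated
    to the 1-s grid; the output is the per-second mean over all
    transitions, restricted to their overlapping time range.
    """
    if len(transitions) < 2:
        raise InvalidInputError("ensemble averaging needs at least 2 transitions")
    interp = [interpolate_1s(s) for s in transitions]
    t0 = max(s.t_start for s in interp)
    t1 = min(s.t_end for s in interp)
    if t1 < t0:
        raise NoOverlapError("transitions share no common time range")
    grid = np.arange(t0, t1 + 1.0)
    stack = np.vstack([
        s.vo2[np.searchsorted(s.time, grid)] for s in interp
    ])
    rec = EditRecord("ensemble_average", {"n_transitions": len(transitions)})
    base = transitions[0]
    return BreathSeries(
        grid, stack.mean(axis=0), unit=base.unit, body_mass=base.body_mass,
        label=f"ensemble({len(transitions)})", edits=(rec,),
    )


# ---------------------------------------------------------------------------
# Edit-log replay
# ---------------------------------------------------------------------------

def replay(raw: BreathSeries, edits: Sequence[EditRecord]) -> BreathSeries:
    """Re-apply a recorded edit log to the raw series.

    All operations are deterministic, so replay reproduces the processed
    series bit-exactly.
    """
    s = raw
    for rec in edits:
        if rec.op == "trim_cardiodynamic":
            s = trim_cardiodynamic(s, **rec.params)
        elif rec.op == "rolling_sd_exclude":
            s, _ = rolling_sd_exclude(s, **rec.params)
        elif rec.op == "delete_points":
            s = delete_points(
                s,
                indices=rec.params.get("indices"),
                time_range=tuple(rec.params["time_range"])
                if rec.params.get("time_range") else None,
            )
        elif rec.op == "box_average":
            s = box_average(s, **rec.params)
        elif rec.op == "moving_average":
            s = moving_average(s, **rec.params)
        elif rec.op == "interpolate_1s":
            s = interpolate_1s(s)
        elif rec.op == "to_per_kg":
            s = s.to_per_kg()
        else:
            raise InvalidInputError(f"cannot replay unknown edit {rec.op!r}")
    return s
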