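"""Ingest digitized survival / cumulative-incidence curves and auxiliary tables.

A published Kaplan-Meier (KM) plot, digitized with a tool such as
WebPlotDigitizer, yields a table of (time, survival) coordinates.  Auxiliary
information commonly printed alongside the plot -- numbers at risk below the
time axis, censoring tick marks on the curve, the total number of events --
is what turns curve coordinates into a well-posed reconstruction problem.
This module validates those inputs and assembles them into a
:class:`PreparedProblem`: a single candidate time grid carrying the relative
decrements ``o_i = 1 - s_i/s_{i-1}`` (or, for competing risks, the increment
matrix ``o_ij``), the at-risk period structure and the tick/censoring index
sets consumed by the QP builders.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DigitizedCurve",
    "AtRiskTable",
    "TickSet",
    "PreparedProblem",
    "CurveInputError",
    "load_curve",
    "merge_cif_curves",
    "enforce_monotone",
    "compute_decrements",
    "compute_cif_increments",
    "prepare",
]

#: slack allowed when clipping digitized probabilities into [0, 1]
_CLIP_REJECT = 0.01

MODES = ("km", "cif", "nelson-aalen")


class CurveInputError(ValueError):
    """Raised for invalid or inconsistent digitized inputs."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Time-ordered curve coordinates read from a digitizer export.

    ``values`` holds survival probabilities (KM mode), cumulative hazard
    values (Nelson-Aalen mode) or an ``(n, m)`` matrix of per-cause cumulative
    incidences (CIF mode).
    """

    times: np.ndarray
    values: np.ndarray
    mode: str = "km"
    cause_labels: tuple = ()

    def __post_init__(self):
        if self.mode not in MODES:
            raise CurveInputError(f"unknown curve mode {self.mode!r}")
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise CurveInputError("empty curve")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
            raise CurveInputError("non-finite values in curve")
        if np.any(t < 0):
            raise CurveInputError("negative times in curve")
        if self.mode == "cif":
            v = np.atleast_2d(v.T).T  # (n, m)
            if v.shape[0] != t.size:
                raise CurveInputError("times and values have different lengths")
            labels = self.cause_labels or tuple(str(j + 1) for j in range(v.shape[1]))
            if len(labels) != v.shape[1]:
                raise CurveInputError("cause_labels length mismatch")
            object.__setattr__(self, "cause_labels", tuple(labels))
        else:
            if v.shape != t.shape:
                raise CurveInputError("times and values have different lengths")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_causes(self) -> int:
        return self.values.shape[1] if self.mode == "cif" else 1


@dataclass(frozen=True)
class AtRiskTable:
    """Numbers at risk ``R_j`` reported at times ``tau_j`` (``tau_0 = 0``)."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or t.shape != r.shape or t.size == 0:
            raise CurveInputError("at-risk table must be two equal-length columns")
        order = np.argsort(t, kind="stable")
        t, r = t[order], r[order]
        if t[0] != 0.0:
            raise CurveInputError("at-risk table must include the time-0 count (tau_0 = 0)")
        if np.any(np.diff(t) <= 0):
            raise CurveInputError("at-risk report times must be strictly increasing")
        if np.any(r < 0) or np.any(np.abs(r - np.round(r)) > 1e-9):
            raise CurveInputError("at-risk counts must be non-negative integers")
        if np.any(np.diff(r) > 0):
            raise CurveInputError("at-risk counts must be non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", np.round(r).astype(int))

    @property
    def n_total(self) -> int:
        return int(self.counts[0])


@dataclass(frozen=True)
class TickSet:
    """Marked censoring times; ``force_censoring`` demands >= 1 censoring per tick."""

    times: np.ndarray
    force_censoring: bool = True

    def __post_init__(self):
        t = np.unique(np.asarray(self.times, dtype=float))
        if np.any(t < 0) or np.any(~np.isfinite(t)):
            raise CurveInputError("tick times must be finite and non-negative")
        object.__setattr__(self, "times", t)


@dataclass
class PreparedProblem:
    """Aligned candidate time grid with decrements and constraint bookkeeping.

    ``period[i]`` is the 0-based at-risk period of grid time ``t_i`` under the
    half-open convention ``C_j = {i : tau_{j-1} <= t_i < tau_j}``; ``-1`` marks
    the unconstrained tail beyond the last report time.
    """

    times: np.ndarray
    o: np.ndarray                     # (n,) in KM mode, (n, m) in CIF mode
    values: np.ndarray                # carried-forward curve values on the grid
    mode: str
    n_total: int
    period: np.ndarray                # (n,) int
    leaving: np.ndarray               # (Nr,) per-period leaving counts R_{j-1} - R_j
    at_risk: AtRiskTable | None
    tick_mask: np.ndarray | None      # (n,) bool, None when no tick info
    force_tick_censoring: bool = False
    total_events: object = None       # int, per-cause int array, or None
    cause_labels: tuple = ()

    @property
    def n_causes(self) -> int:
        return self.o.shape[1] if self.o.ndim == 2 else 1

    @property
    def ticks_available(self) -> bool:
        return self.tick_mask is not None

    @property
    def at_risk_available(self) -> bool:
        return self.at_risk is not None

    @property
    def totals_available(self) -> bool:
        return self.total_events is not None

    @property
    def any_decrement(self) -> np.ndarray:
        """Boolean mask of grid points where the curve drops (any cause)."""
        o = self.o if self.o.ndim == 1 else self.o.sum(axis=1)
        return o > 0

    @property
    def c_star(self) -> np.ndarray:
        """Tick-only censoring slots: tick times with no curve decrement."""
        if self.tick_mask is None:
            return np.zeros(self.times.size, dtype=bool)
        return self.tick_mask & ~self.any_decrement

    @property
    def s_star(self) -> np.ndarray:
        """Non-tick indices (censoring forced to zero when ticks are trusted)."""
        if self.tick_mask is None:
            return np.zeros(self.times.size, dtype=bool)
        return ~self.tick_mask


def _read_table(source, expected_cols: int) -> np.ndarray:
    if isinstance(source, pd.DataFrame):
        df = source
    elif isinstance(source, (str, Path, io.IOBase)):
        df = pd.read_csv(source)
    else:
        arr = np.asarray(source, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(-1, 1)
        return arr
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise CurveInputError(f"non-numeric cells in input table: {exc}") from exc
    if arr.shape[0] == 0:
        raise CurveInputError("empty table")
    if arr.shape[1] < expected_cols:
        raise CurveInputError(f"expected {expected_cols} columns, found {arr.shape[1]}")
    return arr[:, :expected_cols]


def load_curve(source, mode: str = "km", cause: str | None = None) -> DigitizedCurve:
    """Read a two-column (time, value) digitizer export into a sorted curve.

    Accepts a CSV path, file object, DataFrame or array of pairs.  Rows are
    sorted by time, exact duplicate rows are collapsed, and values slightly
    outside [0, 1] (by at most 0.01, digitizer jitter) are clipped with a
    warning; larger excursions are rejected.  In CIF mode the table covers a
    single cause; combine causes with :func:`merge_cif_curves`.
    """
    if mode not in MODES:
        raise CurveInputError(f"unknown curve mode {mode!r}")
    arr = _read_table(source, 2)
    if np.any(~np.isfinite(arr)):
        raise CurveInputError("non-numeric or non-finite cells in curve table")
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    arr = np.unique(arr, axis=0)  # collapse exact duplicate rows
    t, v = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) == 0):
        raise CurveInputError("conflicting values digitized at identical times")
    if mode != "nelson-aalen":
        if np.any(v < -_CLIP_REJECT) or np.any(v > 1 + _CLIP_REJECT):
            raise CurveInputError("curve values outside [-0.01, 1.01]; check axis calibration")
        if np.any(v < 0) or np.any(v > 1):
            warnings.warn("curve values slightly outside [0, 1] were clipped", stacklevel=2)
            v = np.clip(v, 0.0, 1.0)
    else:
        if np.any(v < 0):
            raise CurveInputError("cumulative hazard values must be non-negative")
    labels = (cause,) if (mode == "cif" and cause is not None) else ()
    return DigitizedCurve(times=t, values=v if mode != "cif" else v.reshape(-1, 1),
                          mode=mode, cause_labels=labels)


def merge_cif_curves(curves: Sequence[DigitizedCurve]) -> DigitizedCurve:
    """Align single-cause CIF curves on the union time grid (carry forward).

    The published estimate is constant between observed points, so each
    cause's value at an inserted time is the last observed value.
    """
    if not curves:
        raise CurveInputError("no CIF curves supplied")
    labels = []
    for c in curves:
        if c.mode != "cif" or c.values.shape[1] != 1:
            raise CurveInputError("merge_cif_curves expects single-cause CIF curves")
        labels.append(c.cause_labels[0])
    if len(set(labels)) != len(labels):
        raise CurveInputError(f"duplicate cause labels: {labels}")
    grid = np.unique(np.concatenate([c.times for c in curves]))
    vals = np.column_stack([_carry_forward(grid, c.times, c.values[:, 0], fill=0.0)
                            for c in curves])
    return DigitizedCurve(times=grid, values=vals, mode="cif", cause_labels=tuple(labels))


def _carry_forward(grid, times, values, fill):
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.where(idx >= 0, np.asarray(values, dtype=float)[np.clip(idx, 0, None)], fill)
    return out


def enforce_monotone(curve: DigitizedCurve, keep_times=None) -> DigitizedCurve:
    """Repair digitization-induced monotonicity violations by clipping.

    KM values are clipped down to the running minimum; CIF (and cumulative
    hazard) values up to the running maximum.  Points left with a zero
    decrement/increment are dropped unless listed in ``keep_times`` (tick or
    at-risk report times must survive as censoring candidates).
    """
    t = curve.times
    keep = np.zeros(t.size, dtype=bool)
    if keep_times is not None and len(keep_times):
        keep = _match_times(t, np.asarray(keep_times, dtype=float))
    if curve.mode == "km":
        v = np.minimum.accumulate(np.minimum(curve.values, 1.0))
        prev = np.concatenate(([1.0], v[:-1]))
        flat = v == prev
    else:
        v2 = np.maximum.accumulate(np.atleast_2d(curve.values.T).T, axis=0)
        prev = np.vstack([np.zeros((1, v2.shape[1])), v2[:-1]])
        flat = np.all(v2 == prev, axis=1)
        v = v2 if curve.mode == "cif" else v2[:, 0]
    keep_mask = ~flat | keep
    if not keep_mask.any():
        keep_mask[-1] = True      # flat curve: keep a point to anchor the grid
    return DigitizedCurve(times=t[keep_mask], values=v[keep_mask],
                          mode=curve.mode, cause_labels=curve.cause_labels)


def _match_times(grid: np.ndarray, targets: np.ndarray, tol: float | None = None) -> np.ndarray:
    """Boolean mask of grid entries lying within ``tol`` of any target time."""
    if targets.size == 0:
        return np.zeros(grid.size, dtype=bool)
    if tol is None:
        tol = _time_tol(np.concatenate((grid, targets)))
    idx = np.searchsorted(targets, grid)
    mask = np.zeros(grid.size, dtype=bool)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, targets.size - 1)
        mask |= np.abs(grid - targets[j]) <= tol
    return mask


def _time_tol(times: np.ndarray) -> float:
    return 1e-9 * max(1.0, float(np.max(times, initial=0.0)))


def compute_decrements(values: np.ndarray, mode: str = "km") -> np.ndarray:
    """Relative decrements ``o_i = 1 - s_i / s_{i-1}`` (with ``s_0 = 1``).

    In Nelson-Aalen mode the increment of the cumulative hazard is used as
    ``o_i`` directly (capped at 1, since ``d_i <= r_i``).
    """
    v = np.asarray(values, dtype=float)
    if mode == "nelson-aalen":
        prev = np.concatenate(([0.0], v[:-1]))
        return np.clip(v - prev, 0.0, 1.0)
    prev = np.concatenate(([1.0], v[:-1]))
    o = np.zeros_like(v)
    alive = prev > 0
    if np.any(~alive & (v > 0)):
        raise CurveInputError("survival rises above zero after reaching zero")
    o[alive] = 1.0 - v[alive] / prev[alive]
    return np.clip(o, 0.0, 1.0)


def compute_cif_increments(f: np.ndarray) -> np.ndarray:
    """Relative CIF increments ``o_ij = (f_ij - f_{i-1,j}) / (1 - sum_l f_{i-1,l})``.

    With a single cause this reduces to :func:`compute_decrements` applied to
    ``s = 1 - f``.  Rows where the denominator vanishes (everyone has failed)
    get zero increments; a *positive* increment there is invalid.
    """
    f = np.atleast_2d(np.asarray(f, dtype=float).T).T
    prev = np.vstack([np.zeros((1, f.shape[1])), f[:-1]])
    denom = 1.0 - prev.sum(axis=1)
    inc = f - prev
    o = np.zeros_like(f)
    ok = denom > 1e-12
    if np.any(inc[~ok] > 1e-9):
        warnings.warn("CIF increments beyond total incidence 1 were truncated", stacklevel=2)
    o[ok] = inc[ok] / denom[ok, None]
    return np.clip(o, 0.0, 1.0)


def prepare(curve: DigitizedCurve,
            at_risk: AtRiskTable | None = None,
            ticks: TickSet | None = None,
            n_total: int | None = None,
            total_events=None) -> PreparedProblem:
    """Merge curve, at-risk and tick times into one candidate grid.

    The grid is the union of the (monotone-repaired) curve times, the at-risk
    report times ``tau_1..tau_Nr`` and the tick times; curve values are
    carried forward at inserted times so those points have zero decrement.
    Times closer than ``1e-9 x max(time)`` are merged (digitizer exports are
    low precision).
    """
    if at_risk is not None:
        if n_total is not None and n_total != at_risk.n_total:
            raise CurveInputError(
                f"explicit N={n_total} conflicts with at-risk R_0={at_risk.n_total}")
        n_total = at_risk.n_total
    if n_total is None:
        raise CurveInputError("total sample size N is required (at-risk R_0 or explicit)")
    n_total = int(n_total)

    tick_times = ticks.times if ticks is not None else np.empty(0)
    tau = at_risk.times if at_risk is not None else np.zeros(1)
    all_times = np.concatenate((curve.times, tick_times, tau))
    tol = _time_tol(all_times)
    if at_risk is not None and tau.size > 1:
        span = max(curve.times.max(), tick_times.max() if tick_times.size else 0.0)
        if tau[1] > span + tol:
            raise CurveInputError(
                "first at-risk report time lies beyond all curve/tick times; "
                "check time units")

    keep = np.concatenate((tick_times, tau[1:] if at_risk is not None else np.empty(0)))
    curve = enforce_monotone(curve, keep_times=keep)

    # tolerance-merged union grid
    cand = np.sort(np.concatenate((curve.times, tick_times,
                                   tau[1:] if at_risk is not None else np.empty(0))))
    grid = [cand[0]]
    for t in cand[1:]:
        if t - grid[-1] > tol:
            grid.append(t)
    grid = np.asarray(grid)

    if curve.mode == "cif":
        vals = np.column_stack([_carry_forward(grid, curve.times, curve.values[:, j], 0.0)
                                for j in range(curve.n_causes)])
        o = compute_cif_increments(vals)
    else:
        fill = 1.0 if curve.mode == "km" else 0.0
        vals = _carry_forward(grid, curve.times, curve.values, fill)
        o = compute_decrements(vals, mode=curve.mode)
    # quantize far below digitizer precision so the algebraically equivalent
    # KM and single-cause CIF routes yield bitwise-identical programs
    o = np.round(o, 12)

    # period membership, half-open [tau_{j-1}, tau_j); points at tau_j open period j+1
    if at_risk is not None:
        k = np.searchsorted(tau, grid + tol, side="right") - 1
        period = np.where(k >= tau.size - 1, -1, k).astype(int)
        leaving = -np.diff(at_risk.counts)
    else:
        period = np.full(grid.size, -1, dtype=int)
        leaving = np.zeros(0, dtype=int)

    tick_mask = _match_times(grid, tick_times, tol) if ticks is not None else None

    n_required = int(np.count_nonzero(o if o.ndim == 1 else o.sum(axis=1)))
    if n_total < n_required:
        raise CurveInputError(
            f"N={n_total} below the number of decrement points ({n_required})")

    te = total_events
    if te is not None and not np.isscalar(te):
        te = np.asarray(te, dtype=int)
        if curve.mode == "cif" and te.size != curve.n_causes:
            raise CurveInputError("per-cause totals must match the number of causes")

    return PreparedProblem(
        times=grid, o=o, values=vals, mode=curve.mode, n_total=n_total,
        period=period, leaving=leaving, at_risk=at_risk,
        tick_mask=tick_mask,
        force_tick_censoring=(ticks.force_censoring if ticks is not None else False),
        total_events=te, cause_labels=curve.cause_labels)
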