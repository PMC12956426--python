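"""Convert continuous QP solutions into integer pseudo-counts.

Events are integerized by midpoint rounding of the cumulative sum,
``d_hat_i = floor(0.5 + cum_i) - floor(0.5 + cum_{i-1})``, which preserves
the (integer-constrained) total while distributing fractional mass to the
nearest times.  Censorings are then rescaled period-by-period so that the
at-risk equality constraints survive rounding: within period ``j`` the
continuous censorings are multiplied by
``V_j = (R_{j-1} - R_j) / (sum_{i in C_j} d_hat_i + c_tilde_i)`` before the
same cumulative rounding is applied.  Because the scaling only approximately
restores integer period sums, a deterministic repair pass enforces each
period equality exactly afterwards (adjusting the censoring slot carrying the
largest continuous mass); repairs are reported so callers can log them.

A small-instance exhaustive integer oracle is provided for validation against
the heuristic (standing in for a mixed-integer QP solver).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["round_events", "round_censorings", "exhaustive_oracle", "OracleResult"]


def _cum_round(values: np.ndarray) -> np.ndarray:
    """Midpoint rounding of the cumulative sum (half rounds up, deterministically)."""
    cum = np.concatenate(([0.0], np.cumsum(np.asarray(values, dtype=float))))
    return np.diff(np.floor(0.5 + cum)).astype(int)


def round_events(d_tilde: np.ndarray) -> np.ndarray:
    """Integerize continuous event counts by cumulative midpoint rounding."""
    d_tilde = np.asarray(d_tilde, dtype=float)
    if np.any(d_tilde < -1e-9):
        raise ValueError("negative continuous event counts")
    return _cum_round(np.clip(d_tilde, 0.0, None))


def round_censorings(c_tilde: np.ndarray,
                     d_hat: np.ndarray,
                     period: np.ndarray,
                     leaving: np.ndarray,
                     repairs: list | None = None) -> np.ndarray:
    """Integerize censorings with per-period rescaling; period sums are exact.

    Parameters
    ----------
    c_tilde : continuous censoring counts per grid time.
    d_hat : integer event counts per grid time (summed over causes).
    period : 0-based period index per grid time, -1 for the tail beyond the
        last at-risk report time (tail censorings are rounded unscaled).
    leaving : per-period leaving counts ``R_{j-1} - R_j``.
    repairs : optional list collecting human-readable repair records.

    Returns
    -------
    (c_hat, d_hat) : integer censoring counts and the event counts, which the
    repair pass may have decremented when a period's rounded events exceeded
    its leaving count.
    """
    c_tilde = np.clip(np.asarray(c_tilde, dtype=float), 0.0, None)
    d_hat = np.asarray(d_hat, dtype=int).copy()
    period = np.asarray(period, dtype=int)
    leaving = np.asarray(leaving, dtype=int)
    if repairs is None:
        repairs = []

    # a period whose rounded events already exceed its leaving count must be
    # repaired before scaling (move the excess off the smallest rounded-up d)
    for j in range(leaving.size):
        mask = period == j
        excess = int(d_hat[mask].sum()) - int(leaving[j])
        while excess > 0:
            idx = np.where(mask & (d_hat > 0))[0]
            if idx.size == 0:
                raise ValueError(f"period {j}: leaving count {leaving[j]} below event total")
            take = idx[np.argmax(d_hat[idx])]
            d_hat[take] -= 1
            repairs.append(f"period {j}: decremented d_hat at index {int(take)}")
            excess -= 1

    scale = np.ones_like(c_tilde)
    for j in range(leaving.size):
        mask = period == j
        denom = d_hat[mask].sum() + c_tilde[mask].sum()
        if denom > 0:
            scale[mask] = leaving[j] / denom
    c_hat = _cum_round(scale * c_tilde)

    # enforce the period equalities exactly (rounding of the scaled cumulative
    # sum can still be off by one when boundary sums are not integral)
    for j in range(leaving.size):
        mask = period == j
        diff = int(leaving[j]) - int(d_hat[mask].sum() + c_hat[mask].sum())
        while diff != 0:
            idx = np.where(mask)[0]
            if idx.size == 0:
                raise ValueError(f"period {j}: no censoring slot available for repair")
            if diff > 0:
                take = idx[np.argmax(c_tilde[idx] - c_hat[idx])]
                c_hat[take] += 1
                diff -= 1
            else:
                cand = idx[c_hat[idx] > 0]
                if cand.size == 0:
                    raise ValueError(f"period {j}: cannot reduce censorings below zero")
                take = cand[np.argmin(c_tilde[cand] - c_hat[cand])]
                c_hat[take] -= 1
                diff += 1
            repairs.append(f"period {j}: adjusted c_hat at index {int(take)}")
    return np.clip(c_hat, 0, None), d_hat


@dataclass
class OracleResult:
    x: np.ndarray | None
    objective: float
    feasible: bool
    n_evaluated: int = 0


def exhaustive_oracle(Q, q, A_eq, b_eq, lb, ub, A_in=None, b_in=None,
                      max_vars: int = 12) -> OracleResult:
    """Globally optimal *integer* solution by depth-first enumeration.

    Enumerates integer points of the box ``[lb, ub]`` satisfying
    ``A_eq x = b_eq`` exactly, pruning branches whose partial equality sums
    can no longer reach the right-hand side (only +/-0/1 equality
    coefficients are supported, which covers the reconstruction constraints).
    Intended as a test oracle standing in for a mixed-integer QP solver on
    tiny instances; refuses more than ``max_vars`` variables.
    """
    Q = np.asarray(Q, dtype=float)
    q = np.asarray(q, dtype=float)
    A_eq = np.atleast_2d(np.asarray(A_eq, dtype=float)) if A_eq is not None else np.zeros((0, q.size))
    b_eq = np.atleast_1d(np.asarray(b_eq, dtype=float)) if A_eq.size else np.zeros(0)
    lb = np.ceil(np.asarray(lb, dtype=float) - 1e-9).astype(int)
    ub = np.floor(np.asarray(ub, dtype=float) + 1e-9).astype(int)
    n = q.size
    if n > max_vars:
        raise ValueError(f"{n} integer variables exceeds the oracle limit of {max_vars}")
    if np.any(lb > ub):
        return OracleResult(None, np.inf, False)

    best = {"obj": np.inf, "x": None}
    count = [0]
    x = lb.astype(float).copy()
    # per-row remaining attainable range beyond position k (for pruning)
    pos = np.clip(A_eq, 0, None)
    neg = np.clip(A_eq, None, 0)
    rem_hi = np.column_stack([ (pos[:, k:] * ub[k:] + neg[:, k:] * lb[k:]).sum(axis=1)
                               for k in range(n + 1)]) if A_eq.size else np.zeros((0, n + 1))
    rem_lo = np.column_stack([ (pos[:, k:] * lb[k:] + neg[:, k:] * ub[k:]).sum(axis=1)
                               for k in range(n + 1)]) if A_eq.size else np.zeros((0, n + 1))

    def rec(k: int, partial: np.ndarray):
        if A_eq.size:
            lo = partial + rem_lo[:, k]
            hi = partial + rem_hi[:, k]
            if np.any(b_eq < lo - 1e-9) or np.any(b_eq > hi + 1e-9):
                return
        if k == n:
            if A_in is not None and np.any(np.asarray(A_in) @ x > np.asarray(b_in) + 1e-9):
                return
            count[0] += 1
            obj = 0.5 * x @ Q @ x + q @ x
            if obj < best["obj"] - 1e-12:
                best["obj"] = obj
                best["x"] = x.copy()
            return
        for v in range(lb[k], ub[k] + 1):
            x[k] = v
            rec(k + 1, partial + A_eq[:, k] * v if A_eq.size else partial)
        x[k] = lb[k]

    rec(0, np.zeros(A_eq.shape[0]))
    if best["x"] is None:
        return OracleResult(None, np.inf, False, count[0])
    return OracleResult(best["x"].astype(int), float(best["obj"]), True, count[0])
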