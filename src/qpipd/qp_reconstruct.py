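"""Kaplan-Meier pseudo-IPD reconstruction as a quadratic program.

Given decrements ``o_i`` on a candidate time grid, a perfect reconstruction
with event counts ``d_i`` and censoring counts ``c_i`` satisfies
``o_i (N - sum_{j<i} (d_j + c_j)) - d_i = 0`` at every grid time.  The
reconstruction therefore minimizes

    W = sum_i [ o_i (N - sum_{j<i} (d_j + c_j)) - d_i ]^2

over non-negative continuous counts, subject to the linear equality
constraints implied by the numbers-at-risk table (per-period leaving counts),
the total number of events when reported, and the tick-mark restrictions on
where censoring may occur.  Because each bracket is linear in the unknowns,
W is a quadratic form and the relaxed problem is a convex QP; a small
``epsilon * sum c_i^2`` term (default ``epsilon = 0.001``) regularizes the
otherwise indeterminate allocation of censorings between adjacent tick marks
and makes the objective positive definite.  The continuous optimum is then
integerized (:mod:`qpipd.integerize`) and expanded into per-subject rows.

The same machinery serves the competing-risks extension
(:mod:`qpipd.cif_reconstruct`); here the increment "matrix" simply has a
single cause column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curve_inputs import (AtRiskTable, DigitizedCurve, PreparedProblem,
                           TickSet, prepare)
from .integerize import round_censorings, round_events
from .qpsolver import QPInfeasibleError, QPResult, solve_qp

__all__ = [
    "ReconstructionOptions",
    "QuadraticProgram",
    "ContinuousSolution",
    "Reconstruction",
    "InfeasibleReconstructionError",
    "build_km_qp",
    "solve_continuous",
    "reconstruct_km",
]


class InfeasibleReconstructionError(RuntimeError):
    """The equality constraints conflict even after all permitted relaxations."""


@dataclass
class ReconstructionOptions:
    """Tunable settings for the reconstruction pipeline.

    ``force_tick_censoring=None`` defers to the tick set's own flag;
    ``midpoint_censoring=None`` enables midpoint placement exactly when no
    tick information is available (censoring is then only known up to the
    interval between candidate times, and the midpoint is the conventional
    representative).
    """

    epsilon: float = 1e-3
    ridge: float = 1e-8
    force_tick_censoring: bool | None = None
    midpoint_censoring: bool | None = None
    refine: bool = True
    max_relaxations: int | None = None


@dataclass
class QuadraticProgram:
    """Assembled QP over stacked (d, c) variables, zero-fixed variables eliminated."""

    Q: np.ndarray
    q: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    A_in: np.ndarray
    b_in: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    R: np.ndarray                 # residual matrix: residuals = R x + k
    k: np.ndarray
    d_time: np.ndarray            # grid index of each event variable
    d_cause: np.ndarray           # cause index of each event variable
    c_time: np.ndarray            # grid index of each censoring variable
    problem: PreparedProblem
    epsilon: float = 1e-3
    relaxations: list = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return self.q.size

    def objective(self, x: np.ndarray) -> float:
        return float(0.5 * x @ self.Q @ x + self.q @ x)

    def raw_W(self, x: np.ndarray) -> float:
        """Unregularized residual sum of squares at ``x``."""
        r = self.R @ x + self.k
        return float(r @ r)

    def pack(self, d: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Stack full-grid (d, c) arrays into the eliminated variable vector."""
        d = np.atleast_2d(np.asarray(d, dtype=float).T).T
        x = np.empty(self.n_vars)
        nd = self.d_time.size
        x[:nd] = d[self.d_time, self.d_cause]
        x[nd:] = np.asarray(c, dtype=float)[self.c_time]
        return x

    def unpack(self, x: np.ndarray):
        """Scatter a variable vector back onto the full grid (zeros elsewhere)."""
        n = self.problem.times.size
        m = self.problem.n_causes
        d = np.zeros((n, m))
        c = np.zeros(n)
        nd = self.d_time.size
        d[self.d_time, self.d_cause] = x[:nd]
        c[self.c_time] = x[nd:]
        return (d[:, 0] if m == 1 else d), c


@dataclass
class ContinuousSolution:
    d_tilde: np.ndarray           # full grid, (n,) or (n, m)
    c_tilde: np.ndarray           # full grid
    objective: float              # regularized QP objective (constant dropped)
    W: float                      # raw residual sum of squares
    qp: QuadraticProgram
    solver: QPResult


@dataclass
class Reconstruction:
    """Integerized reconstruction with per-subject pseudo-IPD rows."""

    ipd: pd.DataFrame             # columns: time, status (0 = censored)
    d_hat: np.ndarray             # full grid, (n,) or (n, m)
    c_hat: np.ndarray
    continuous: ContinuousSolution
    problem: PreparedProblem
    relaxations: list
    repairs: list
    n_tail_censored: int          # subjects never observed to leave
    W_integer: float              # raw residual sum of squares at the counts
    objective_integer: float = np.nan   # regularized QP objective at the counts

    @property
    def counts(self) -> pd.DataFrame:
        d = np.atleast_2d(self.d_hat.T).T
        cols = {"time": self.problem.times}
        labels = self.problem.cause_labels or tuple(
            str(j + 1) for j in range(d.shape[1]))
        for j, lab in enumerate(labels):
            cols[f"d_{lab}" if d.shape[1] > 1 else "d"] = d[:, j]
        cols["c"] = self.c_hat
        return pd.DataFrame(cols)


def _build_qp(problem: PreparedProblem, options: ReconstructionOptions) -> QuadraticProgram:
    o = np.atleast_2d(problem.o.T).T          # (n, m)
    n, m = o.shape
    N = problem.n_total

    d_time, d_cause = np.nonzero(o > 0)
    order = np.lexsort((d_time, d_cause))     # cause-major blocks, time-ordered
    d_time, d_cause = d_time[order], d_cause[order]
    if problem.ticks_available:
        c_time = np.nonzero(problem.tick_mask)[0]
    else:
        c_time = np.arange(n)
    nd, nc = d_time.size, c_time.size
    p = nd + nc

    # residual rows: one per (time, cause) with o_ij > 0
    R = np.zeros((nd, p))
    k = np.empty(nd)
    for row in range(nd):
        i, j = d_time[row], d_cause[row]
        R[row, :nd][d_time < i] = -o[i, j]
        R[row, nd:][c_time < i] = -o[i, j]
        R[row, row] += -1.0
        k[row] = o[i, j] * N
    Q = 2.0 * (R.T @ R)
    Q[np.arange(nd, p), np.arange(nd, p)] += 2.0 * options.epsilon
    Q[np.arange(p), np.arange(p)] += 2.0 * options.ridge
    q = 2.0 * (R.T @ k)

    eq_rows, eq_rhs = [], []
    for j, leave in enumerate(problem.leaving):
        row = np.zeros(p)
        row[:nd] = problem.period[d_time] == j
        row[nd:] = problem.period[c_time] == j
        eq_rows.append(row)
        eq_rhs.append(float(leave))
    te = problem.total_events
    if te is not None:
        if np.isscalar(te):
            row = np.zeros(p)
            row[:nd] = 1.0
            eq_rows.append(row)
            eq_rhs.append(float(te))
        else:
            for j in range(m):
                row = np.zeros(p)
                row[:nd] = d_cause == j
                eq_rows.append(row)
                eq_rhs.append(float(te[j]))
    A_eq = np.vstack(eq_rows) if eq_rows else np.zeros((0, p))
    b_eq = np.asarray(eq_rhs)

    required = sum(b for b in problem.leaving)
    if required > N:
        raise InfeasibleReconstructionError(
            f"at-risk table implies {required} departures for N={N}")

    lb = np.zeros(p)
    lb[:nd] = 1.0                              # d_i >= 1 wherever the curve drops
    force = problem.force_tick_censoring if options.force_tick_censoring is None \
        else options.force_tick_censoring
    if problem.ticks_available and force:
        lb[nd:] = problem.c_star[c_time].astype(float)
    ub = np.full(p, float(N))
    A_in = np.ones((1, p))                     # total departures cannot exceed N
    b_in = np.array([float(N)])

    return QuadraticProgram(Q=Q, q=q, A_eq=A_eq, b_eq=b_eq, A_in=A_in, b_in=b_in,
                            lb=lb, ub=ub, R=R, k=k, d_time=d_time, d_cause=d_cause,
                            c_time=c_time, problem=problem, epsilon=options.epsilon)


def build_km_qp(problem: PreparedProblem,
                options: ReconstructionOptions | None = None) -> QuadraticProgram:
    """Assemble the KM reconstruction QP from a prepared problem."""
    if problem.n_causes != 1:
        raise ValueError("use build_cif_qp for competing-risks problems")
    return _build_qp(problem, options or ReconstructionOptions())


def solve_continuous(qp: QuadraticProgram,
                     options: ReconstructionOptions | None = None) -> ContinuousSolution:
    """Solve the continuous QP, relaxing constraints stepwise if infeasible.

    Relaxation ladder: (1) drop the optional ``c >= 1`` tick constraints;
    (2) relax ``d >= 1`` to ``d >= 0`` one variable at a time, smallest
    decrement first; (3) as a last resort admit censoring at all candidate
    times.  Conflicting equality rows remain a hard failure.
    """
    options = options or ReconstructionOptions()
    nd = qp.d_time.size
    budget = options.max_relaxations
    while True:
        try:
            res = solve_qp(qp.Q, qp.q, qp.A_eq, qp.b_eq, qp.A_in, qp.b_in, qp.lb, qp.ub)
            break
        except QPInfeasibleError as exc:
            if np.any(qp.lb[nd:] > 0):
                qp.lb[nd:] = 0.0
                qp.relaxations.append("dropped c>=1 tick constraints")
                continue
            relaxable = np.nonzero(qp.lb[:nd] > 0)[0]
            if relaxable.size and (budget is None or len(qp.relaxations) < budget):
                o = np.atleast_2d(qp.problem.o.T).T
                key = o[qp.d_time[relaxable], qp.d_cause[relaxable]]
                drop = relaxable[np.argmin(key)]
                qp.lb[drop] = 0.0
                qp.relaxations.append(
                    f"relaxed d>=1 at t={qp.problem.times[qp.d_time[drop]]:g}")
                continue
            if qp.problem.ticks_available and qp.c_time.size < qp.problem.times.size:
                widened = _widen_censoring(qp)
                widened.relaxations = qp.relaxations + ["admitted censoring at all times"]
                qp = widened
                continue
            raise InfeasibleReconstructionError(
                f"equality constraints conflict: {exc}") from exc
    d_t, c_t = qp.unpack(res.x)
    return ContinuousSolution(d_tilde=d_t, c_tilde=c_t, objective=res.objective,
                              W=qp.raw_W(res.x), qp=qp, solver=res)


def _widen_censoring(qp: QuadraticProgram) -> QuadraticProgram:
    prob = qp.problem
    relaxed = PreparedProblem(
        times=prob.times, o=prob.o, values=prob.values, mode=prob.mode,
        n_total=prob.n_total, period=prob.period, leaving=prob.leaving,
        at_risk=prob.at_risk, tick_mask=None, force_tick_censoring=False,
        total_events=prob.total_events, cause_labels=prob.cause_labels)
    opts = ReconstructionOptions()
    new = _build_qp(relaxed, opts)
    new.lb[:new.d_time.size] = qp.lb[:qp.d_time.size]   # keep earlier d relaxations
    return new


def refine_integer(qp: QuadraticProgram, x: np.ndarray, max_pass: int = 30) -> np.ndarray:
    """Greedy descent on the integer QP objective by unit reallocation.

    Moves one event (within the same cause) or one censoring between two
    candidate times of the same at-risk period -- moves that preserve every
    equality constraint -- whenever the move lowers the regularized objective
    ``W + epsilon sum c^2``.  This closes most of the gap between the
    midpoint-rounding heuristic and the exact mixed-integer optimum at a cost
    of a few matrix-vector products.
    """
    prob = qp.problem
    nd = qp.d_time.size
    x = x.copy()
    lb, ub = qp.lb, qp.ub
    eps = qp.epsilon
    var_period = np.concatenate([prob.period[qp.d_time], prob.period[qp.c_time]])
    # moves allowed within (period, cause) for events; (period,) for censorings
    var_class = np.concatenate([qp.d_cause, np.full(qp.c_time.size, -1)])
    R, k = qp.R, qp.k
    groups = []
    for per in np.unique(var_period):
        for cls in np.unique(var_class):
            idx = np.where((var_period == per) & (var_class == cls))[0]
            if idx.size > 1:
                groups.append(idx)
    for _ in range(max_pass):
        r = R @ x + k
        improved = False
        for idx in groups:
            for a in idx:
                for b in idx:
                    if b == a:
                        continue
                    if x[a] - 1 < lb[a] - 1e-9 or x[b] + 1 > ub[b] + 1e-9:
                        continue
                    dcol = R[:, b] - R[:, a]
                    dW = 2 * r @ dcol + dcol @ dcol
                    if a >= nd:  # censoring move: include the regularizer
                        dW += 2 * eps * (x[b] - x[a] + 1)
                    if dW < -1e-12:
                        x[a] -= 1
                        x[b] += 1
                        r = r + dcol
                        improved = True
        if not improved:
            return x
    return x


def integerize_solution(sol: ContinuousSolution,
                        options: ReconstructionOptions | None = None) -> Reconstruction:
    """Round the continuous solution to integer counts and expand to rows."""
    options = options or ReconstructionOptions()
    qp = sol.qp
    prob = qp.problem
    n = prob.times.size
    d_t = np.atleast_2d(sol.d_tilde.T).T
    m = d_t.shape[1]

    d_hat = np.column_stack([round_events(d_t[:, j]) for j in range(m)])
    repairs: list = []
    c_hat, d_tot = round_censorings(sol.c_tilde, d_hat.sum(axis=1),
                                    prob.period, prob.leaving, repairs)
    # map any repair decrements back onto a cause (largest count at that time)
    deficit = d_hat.sum(axis=1) - d_tot
    for i in np.nonzero(deficit > 0)[0]:
        for _ in range(int(deficit[i])):
            d_hat[i, int(np.argmax(d_hat[i]))] -= 1

    if options.refine and _within_layout(qp, d_hat, c_hat):
        x_ref = refine_integer(qp, qp.pack(d_hat, c_hat))
        d_ref, c_ref = qp.unpack(x_ref)
        d_hat = np.atleast_2d(d_ref.T).T.astype(int)
        c_hat = c_ref.astype(int)

    if _within_layout(qp, d_hat, c_hat):
        x_int = qp.pack(d_hat, c_hat)
        W_int = qp.raw_W(x_int)
        obj_int = qp.objective(x_int)
    else:
        W_int = obj_int = np.nan

    ipd, n_tail = _expand(prob, d_hat, c_hat, sol)
    return Reconstruction(ipd=ipd, d_hat=d_hat[:, 0] if m == 1 else d_hat,
                          c_hat=c_hat, continuous=sol, problem=prob,
                          relaxations=list(qp.relaxations), repairs=repairs,
                          n_tail_censored=n_tail, W_integer=W_int,
                          objective_integer=obj_int)


def _within_layout(qp: QuadraticProgram, d_hat, c_hat) -> bool:
    d = np.atleast_2d(np.asarray(d_hat).T).T
    mask = np.ones(d.shape, dtype=bool)
    mask[qp.d_time, qp.d_cause] = False
    cmask = np.ones(c_hat.size, dtype=bool)
    cmask[qp.c_time] = False
    return not (np.any(d[mask] != 0) or np.any(np.asarray(c_hat)[cmask] != 0))


def _expand(prob: PreparedProblem, d_hat: np.ndarray, c_hat: np.ndarray,
            sol: ContinuousSolution):
    times = prob.times
    n = times.size
    opts_midpoint = not prob.ticks_available
    rows_t, rows_s = [], []
    for i in range(n):
        for j in range(d_hat.shape[1]):
            if d_hat[i, j] > 0:
                rows_t.extend([times[i]] * int(d_hat[i, j]))
                rows_s.extend([j + 1] * int(d_hat[i, j]))
        if c_hat[i] > 0:
            if opts_midpoint and i + 1 < n:
                t_c = 0.5 * (times[i] + times[i + 1])
            else:
                t_c = times[i]
            rows_t.extend([t_c] * int(c_hat[i]))
            rows_s.extend([0] * int(c_hat[i]))
    assigned = int(d_hat.sum() + c_hat.sum())
    n_tail = prob.n_total - assigned
    if n_tail < 0:
        raise InfeasibleReconstructionError("assigned more subjects than N")
    if n_tail > 0:
        t_last = float(times[-1])
        rows_t.extend([t_last] * n_tail)
        rows_s.extend([0] * n_tail)
    ipd = pd.DataFrame({"time": rows_t, "status": rows_s}).sort_values(
        ["time", "status"], kind="stable", ignore_index=True)
    return ipd, n_tail


def reconstruct_km(curve,
                   at_risk: AtRiskTable | None = None,
                   ticks: TickSet | None = None,
                   n_total: int | None = None,
                   total_events: int | None = None,
                   options: ReconstructionOptions | None = None) -> Reconstruction:
    """End-to-end KM reconstruction: prepare, solve, integerize, expand.

    ``curve`` may be a :class:`DigitizedCurve` (KM or Nelson-Aalen mode) or an
    already-prepared problem.  Requires the sample size ``N`` either from the
    at-risk table's time-zero count or explicitly.
    """
    options = options or ReconstructionOptions()
    if isinstance(curve, PreparedProblem):
        problem = curve
    else:
        problem = prepare(curve, at_risk=at_risk, ticks=ticks,
                          n_total=n_total, total_events=total_events)
    if problem.n_causes != 1:
        raise ValueError("use reconstruct_cif for competing-risks problems")
    if options.force_tick_censoring is not None and problem.ticks_available:
        problem.force_tick_censoring = options.force_tick_censoring
    qp = _build_qp(problem, options)
    sol = solve_continuous(qp, options)
    rec = integerize_solution(sol, options)
    if options.midpoint_censoring is False and not problem.ticks_available:
        # re-expand with censorings kept at grid times
        rec = _reexpand_at_grid(rec)
    return rec


def _reexpand_at_grid(rec: Reconstruction) -> Reconstruction:
    prob = rec.problem
    d = np.atleast_2d(rec.d_hat.T).T
    rows_t, rows_s = [], []
    for i, t in enumerate(prob.times):
        for j in range(d.shape[1]):
            rows_t.extend([t] * int(d[i, j]))
            rows_s.extend([j + 1] * int(d[i, j]))
        rows_t.extend([t] * int(rec.c_hat[i]))
        rows_s.extend([0] * int(rec.c_hat[i]))
    n_tail = rec.n_tail_censored
    rows_t.extend([float(prob.times[-1])] * n_tail)
    rows_s.extend([0] * n_tail)
    rec.ipd = pd.DataFrame({"time": rows_t, "status": rows_s}).sort_values(
        ["time", "status"], kind="stable", ignore_index=True)
    return rec
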