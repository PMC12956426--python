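"""Dense convex quadratic programming by a primal active-set method.

Solves ``min 0.5 x'Qx + q'x`` subject to ``A_eq x = b_eq``,
``A_in x <= b_in`` and box bounds, for strictly convex (positive-definite)
``Q``.  The reconstruction QPs are small and dense (a few hundred variables,
equality rows per at-risk period, bound constraints on every count), which a
textbook primal active-set iteration handles in milliseconds; a feasible
starting point is obtained from a phase-1 linear program (HiGHS via
``scipy.optimize.linprog``).  ``scipy.optimize.minimize(trust-constr)`` is
kept as a slow-path fallback for degenerate instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

__all__ = ["QPInfeasibleError", "QPResult", "solve_qp"]

_FEAS_TOL = 1e-9
_LAMBDA_TOL = 1e-9
_STEP_TOL = 1e-11


class QPInfeasibleError(RuntimeError):
    """The constraint system admits no feasible point."""


@dataclass
class QPResult:
    x: np.ndarray
    objective: float
    status: str          # "optimal" | "fallback"
    iterations: int


def _feasible_point(A_eq, b_eq, G, h, lb, ub):
    n = lb.size
    res = scipy.optimize.linprog(
        c=np.zeros(n), A_ub=G if G.size else None, b_ub=h if G.size else None,
        A_eq=A_eq if A_eq.size else None, b_eq=b_eq if A_eq.size else None,
        bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0 or res.x is None:
        raise QPInfeasibleError(f"no feasible point: {res.message}")
    return np.clip(res.x, lb, ub)


def solve_qp(Q, q, A_eq=None, b_eq=None, A_in=None, b_in=None,
             lb=None, ub=None, max_iter=None) -> QPResult:
    """Minimize ``0.5 x'Qx + q'x`` under linear equality/inequality constraints.

    ``Q`` must be symmetric positive definite (the reconstruction objective is
    ridge-regularized before it reaches the solver).
    """
    Q = np.asarray(Q, dtype=float)
    q = np.asarray(q, dtype=float)
    n = q.size
    lb = np.full(n, -np.inf) if lb is None else np.asarray(lb, dtype=float)
    ub = np.full(n, np.inf) if ub is None else np.asarray(ub, dtype=float)
    A_eq = np.zeros((0, n)) if A_eq is None else np.atleast_2d(np.asarray(A_eq, dtype=float))
    b_eq = np.zeros(0) if b_eq is None else np.atleast_1d(np.asarray(b_eq, dtype=float))
    A_in = np.zeros((0, n)) if A_in is None else np.atleast_2d(np.asarray(A_in, dtype=float))
    b_in = np.zeros(0) if b_in is None else np.atleast_1d(np.asarray(b_in, dtype=float))

    # stack general inequalities and finite bounds as rows of G x <= h
    rows = [A_in]
    rhs = [b_in]
    eye = np.eye(n)
    fin_ub = np.isfinite(ub)
    fin_lb = np.isfinite(lb)
    rows += [eye[fin_ub], -eye[fin_lb]]
    rhs += [ub[fin_ub], -lb[fin_lb]]
    G = np.vstack(rows)
    h = np.concatenate(rhs)

    x = _feasible_point(A_eq, b_eq, G, h, lb, ub)
    m_eq = A_eq.shape[0]
    work: list[int] = []          # indices into G currently treated as equalities
    if max_iter is None:
        max_iter = 100 + 20 * (n + m_eq)

    scale = max(1.0, np.abs(h).max() if h.size else 1.0,
                np.abs(b_eq).max() if b_eq.size else 1.0)
    for it in range(max_iter):
        g = Q @ x + q
        C = np.vstack([A_eq, G[work]]) if (m_eq or work) else np.zeros((0, n))
        k = C.shape[0]
        KKT = np.block([[Q, C.T], [C, np.zeros((k, k))]])
        r = np.concatenate([-g, np.zeros(k)])
        try:
            sol = np.linalg.solve(KKT, r)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(KKT, r, rcond=None)[0]
        p, lam = sol[:n], sol[n:]
        if np.max(np.abs(p), initial=0.0) <= _STEP_TOL * scale:
            lam_in = lam[m_eq:]
            if lam_in.size == 0 or lam_in.min() >= -_LAMBDA_TOL:
                obj = 0.5 * x @ Q @ x + q @ x
                return QPResult(x=x, objective=float(obj), status="optimal", iterations=it)
            work.pop(int(np.argmin(lam_in)))
            continue
        # longest feasible step along p
        Gp = G @ p
        slack = h - G @ x
        blocking = -1
        alpha = 1.0
        cand = np.where((Gp > _FEAS_TOL) & ~np.isin(np.arange(G.shape[0]), work))[0]
        if cand.size:
            ratios = slack[cand] / Gp[cand]
            j = int(np.argmin(ratios))
            if ratios[j] < alpha:
                alpha = max(ratios[j], 0.0)
                blocking = int(cand[j])
        x = x + alpha * p
        if blocking >= 0:
            work.append(blocking)

    # degenerate cycling: fall back to an interior-point style solve
    return _fallback(Q, q, A_eq, b_eq, G, h, lb, ub, x)


def _fallback(Q, q, A_eq, b_eq, G, h, lb, ub, x0) -> QPResult:
    constraints = []
    if A_eq.size:
        constraints.append(scipy.optimize.LinearConstraint(A_eq, b_eq, b_eq))
    if G.size:
        constraints.append(scipy.optimize.LinearConstraint(G, -np.inf, h))
    res = scipy.optimize.minimize(
        lambda x: 0.5 * x @ Q @ x + q @ x, x0,
        jac=lambda x: Q @ x + q, hess=lambda x: Q,
        method="trust-constr", constraints=constraints,
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000})
    x = np.clip(res.x, lb, ub)
    return QPResult(x=x, objective=float(0.5 * x @ Q @ x + q @ x),
                    status="fallback", iterations=int(res.niter))
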