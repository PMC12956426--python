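"""Competing-risks pseudo-IPD reconstruction from cumulative incidence curves.

With ``m`` competing causes the published information is one cumulative
incidence curve per cause.  On the shared candidate grid the relative
increments

    o_ij = (f_ij - f_{i-1,j}) / (1 - sum_l f_{i-1,l})

satisfy ``o_ij r_i = d_ij`` under the Aalen-Johansen estimator, so the
objective generalizes the KM case to

    W = sum_i sum_j [ o_ij (N - sum_{k<i} (sum_l d_kl + c_k)) - d_ij ]^2

with the same at-risk period equalities (events summed over causes), either
per-cause or pooled total-event constraints, and ``d_ij >= 1`` wherever curve
``j`` rises.  With a single cause the program coincides exactly with the KM
program on ``s = 1 - f``.  Integerization rounds each cause's events
independently (cumulative midpoint rounding) before rescaling censorings.
"""

from __future__ import annotations

import numpy as np

from .curve_inputs import (AtRiskTable, DigitizedCurve, PreparedProblem,
                           TickSet, merge_cif_curves, prepare)
from .qp_reconstruct import (QuadraticProgram, Reconstruction,
                             ReconstructionOptions, _build_qp,
                             integerize_solution, solve_continuous)

__all__ = ["build_cif_qp", "reconstruct_cif"]


def build_cif_qp(problem: PreparedProblem,
                 options: ReconstructionOptions | None = None) -> QuadraticProgram:
    """Assemble the competing-risks QP (m event blocks + one censoring block)."""
    return _build_qp(problem, options or ReconstructionOptions())


def reconstruct_cif(curves,
                    at_risk: AtRiskTable | None = None,
                    ticks: TickSet | None = None,
                    n_total: int | None = None,
                    total_events=None,
                    options: ReconstructionOptions | None = None) -> Reconstruction:
    """End-to-end competing-risks reconstruction.

    ``curves`` may be a multi-cause CIF :class:`DigitizedCurve`, a sequence of
    single-cause CIF curves (aligned by carrying values forward onto the union
    grid), or a prepared problem.  ``total_events`` accepts either a pooled
    count or one count per cause.  The returned pseudo-IPD codes status ``k``
    for an event of cause ``k`` (1-based) and 0 for censoring.
    """
    options = options or ReconstructionOptions()
    if isinstance(curves, PreparedProblem):
        problem = curves
    else:
        if isinstance(curves, DigitizedCurve):
            curve = curves
        else:
            curve = merge_cif_curves(list(curves))
        if curve.mode != "cif":
            raise ValueError("reconstruct_cif expects CIF-mode curves")
        problem = prepare(curve, at_risk=at_risk, ticks=ticks,
                          n_total=n_total, total_events=total_events)
    if options.force_tick_censoring is not None and problem.ticks_available:
        problem.force_tick_censoring = options.force_tick_censoring
    qp = build_cif_qp(problem, options)
    sol = solve_continuous(qp, options)
    return integerize_solution(sol, options)
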