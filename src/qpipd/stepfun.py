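"""Right-continuous step functions and exact piecewise-constant integration.

Survival curves, cumulative incidence curves and at-risk processes are all
piecewise-constant in time, so discrepancy integrals such as
``int |S1(t) - S2(t)| dt`` can be evaluated exactly by merging the two jump
grids; no quadrature is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous step function ``f(t) = y[k]`` for ``x[k] <= t < x[k+1]``.

    Parameters
    ----------
    x : array
        Strictly increasing jump times.
    y : array
        Value attained *at and after* each jump time.
    y0 : float
        Value on ``[0, x[0])`` (e.g. 1 for a survivor function, 0 for a CIF).
    """

    x: np.ndarray
    y: np.ndarray
    y0: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if x.size and np.any(np.diff(x) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="right")
        vals = np.concatenate(([self.y0], self.y))
        out = vals[idx]
        return out if out.ndim else float(out)

    def integrate(self, upper: float, lower: float = 0.0) -> float:
        """Exact integral of the step function over ``[lower, upper]``."""
        if upper < lower:
            raise ValueError("upper < lower")
        knots = np.concatenate(([lower], self.x[(self.x > lower) & (self.x < upper)], [upper]))
        widths = np.diff(knots)
        vals = self(knots[:-1])
        return float(np.sum(widths * np.atleast_1d(vals)))

    def abs_diff_integral(self, other: "StepFunction", upper: float, lower: float = 0.0) -> float:
        """Exact integral of ``|self - other|`` over ``[lower, upper]``."""
        if upper < lower:
            raise ValueError("upper < lower")
        knots = np.unique(np.concatenate(([lower], self.x, other.x, [upper])))
        knots = knots[(knots >= lower) & (knots <= upper)]
        if knots[0] != lower:
            knots = np.concatenate(([lower], knots))
        if knots[-1] != upper:
            knots = np.concatenate((knots, [upper]))
        widths = np.diff(knots)
        left = knots[:-1]
        diff = np.abs(np.atleast_1d(self(left)) - np.atleast_1d(other(left)))
        return float(np.sum(widths * diff))
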