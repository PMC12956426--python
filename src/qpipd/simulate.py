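"""Synthetic survival data emulating the published-curve reporting pipeline.

Three generators are provided:

* a single-arm Weibull cohort with hazard ``h(t) = lambda^alpha alpha
  t^{alpha-1}`` (shape 0.8, rate 0.2 by default -- an early-hazard shape that
  produces many tied events once times are coarsened) under independent
  Unif(2, 8) censoring: ~39% censored, ~76 events per 125 subjects;
* a two-arm version with a shared shape (proportional hazards) and a lower
  treatment hazard (log hazard ratio -0.5 for arm 1);
* a two-arm, two-cause competing-risks design in which cause 1 follows a
  proportional subdistribution-hazards (Fine-Gray) model,
  ``F1(t; Z) = 1 - (1 - kappa(1 - exp(-lambda01 t^alpha1)))^{exp(beta1 Z)}``,
  and cause 2 takes the complementary-mass Weibull form
  ``F2(t; Z) = (1 - p1(Z)) (1 - exp(-lambda02 t^alpha2 exp(beta2 Z)))`` with
  ``p1(Z) = 1 - (1 - kappa)^{exp(beta1 Z)}`` -- so the cause-1 Fine-Gray
  model is correctly specified while cause-2 and both cause-specific Cox
  models are not.  Censoring is Unif(1, 6).

Reporting is emulated in two steps: observed times are *coarsened* by
rounding up to the next multiple of the reporting resolution (default 0.05,
creating ties as real reporting grids do), and curve values supplied to the
reconstruction are rounded to a fixed number of decimals (default 3,
standing in for digitization error).  Tick marks are the exact censoring
times; numbers at risk are reported on an integer time grid; totals are the
exact event counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve_inputs import AtRiskTable, DigitizedCurve, TickSet
from .estimators import aalen_johansen, kaplan_meier

__all__ = ["ScenarioConfig", "simulate_base", "simulate_two_arm",
           "simulate_competing", "simulate_truth", "coarsen",
           "emulate_digitization"]

#: default (kappa, lambda01, alpha1, lambda02, alpha2, beta1, beta2)
COMPETING_PARAMS = (0.6, 0.4, 1.2, 0.2, 1.5, -0.3, 0.3)


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully-specified simulation scenario.

    ``censor_bounds`` and ``at_risk_times`` default per scenario: Unif(2, 8)
    censoring with at-risk reporting at t = 0..8 for the Weibull scenarios,
    Unif(1, 6) with reporting at t = 0..5 for competing risks.
    """

    scenario: str = "base"                  # base | two_arm | competing
    n_per_arm: int = 125
    weibull_shape: float = 0.8
    weibull_rate: float = 0.2
    log_hr: float = -0.5                    # arm-1 log hazard ratio (lower hazard)
    competing_params: tuple = COMPETING_PARAMS
    censor_bounds: tuple | None = None
    resolution: float | None = 0.05         # None = keep continuous times
    decimals: int | None = 3                # None = no value rounding
    at_risk_times: tuple | None = None
    at_risk_at_events: bool = False         # report at-risk at every event time
    use_ticks: bool = True
    use_at_risk: bool = True
    use_totals: bool = True
    replicates: int = 1000
    base_seed: int = 0

    def resolved_censor_bounds(self) -> tuple:
        if self.censor_bounds is not None:
            return self.censor_bounds
        return (1.0, 6.0) if self.scenario == "competing" else (2.0, 8.0)

    def resolved_at_risk_times(self) -> np.ndarray:
        if self.at_risk_times is not None:
            return np.asarray(self.at_risk_times, dtype=float)
        hi = 5 if self.scenario == "competing" else 8
        return np.arange(0.0, hi + 1)

    def rng(self, rep: int) -> np.random.Generator:
        return np.random.default_rng(self.base_seed + rep)


def _weibull_times(rng, n, shape, rate, log_hr=0.0):
    # H(t) = exp(log_hr) (rate t)^shape  =>  t = (-log U / exp(log_hr))^(1/shape)/rate
    u = rng.uniform(size=n)
    return (-np.log(u) * np.exp(-log_hr)) ** (1.0 / shape) / rate


def _censor(rng, n, bounds):
    return rng.uniform(bounds[0], bounds[1], size=n)


def simulate_base(config: ScenarioConfig, rep: int) -> pd.DataFrame:
    """Single-arm Weibull cohort; continuous times, status 1 = event."""
    rng = config.rng(rep)
    n = config.n_per_arm
    t_event = _weibull_times(rng, n, config.weibull_shape, config.weibull_rate)
    t_cens = _censor(rng, n, config.resolved_censor_bounds())
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "status": status})


def simulate_two_arm(config: ScenarioConfig, rep: int) -> pd.DataFrame:
    """Two-arm Weibull trial with shared shape; ``group`` 1 has the lower hazard."""
    rng = config.rng(rep)
    n = config.n_per_arm
    frames = []
    for arm in (0, 1):
        t_event = _weibull_times(rng, n, config.weibull_shape, config.weibull_rate,
                                 log_hr=config.log_hr * arm)
        t_cens = _censor(rng, n, config.resolved_censor_bounds())
        frames.append(pd.DataFrame({
            "time": np.minimum(t_event, t_cens),
            "status": (t_event <= t_cens).astype(int),
            "group": arm}))
    return pd.concat(frames, ignore_index=True)


def simulate_competing(config: ScenarioConfig, rep: int) -> pd.DataFrame:
    """Two-arm, two-cause competing risks under the Fine-Gray cause-1 design."""
    rng = config.rng(rep)
    kappa, l01, a1, l02, a2, b1, b2 = config.competing_params
    n = config.n_per_arm
    frames = []
    for arm in (0, 1):
        g1 = np.exp(b1 * arm)
        p1 = 1.0 - (1.0 - kappa) ** g1              # P(cause 1 | Z) as t -> inf
        is1 = rng.uniform(size=n) < p1
        u = rng.uniform(size=n)
        # invert F1(t; Z) = u * p1(Z)
        inner = 1.0 - (1.0 - (1.0 - u * (1.0 - (1.0 - kappa) ** g1)) ** (1.0 / g1)) / kappa
        t1 = (-np.log(inner) / l01) ** (1.0 / a1)
        u2 = rng.uniform(size=n)
        t2 = (-np.log(1.0 - u2) / (l02 * np.exp(b2 * arm))) ** (1.0 / a2)
        t_event = np.where(is1, t1, t2)
        cause = np.where(is1, 1, 2)
        t_cens = _censor(rng, n, config.resolved_censor_bounds())
        frames.append(pd.DataFrame({
            "time": np.minimum(t_event, t_cens),
            "status": np.where(t_event <= t_cens, cause, 0),
            "group": arm}))
    return pd.concat(frames, ignore_index=True)


_SIMULATORS = {"base": simulate_base, "two_arm": simulate_two_arm,
               "competing": simulate_competing}


def coarsen(times, resolution: float = 0.05) -> np.ndarray:
    """Round times *up* to the next multiple of the reporting resolution."""
    t = np.asarray(times, dtype=float)
    k = np.ceil(t / resolution - 1e-9)
    return np.round(np.maximum(k, 1) * resolution, 10)


def simulate_truth(config: ScenarioConfig, rep: int) -> pd.DataFrame:
    """The 'true IPD' as reported: simulated then coarsened to the resolution."""
    ipd = _SIMULATORS[config.scenario](config, rep)
    if config.resolution is None:
        return ipd
    out = ipd.copy()
    out["time"] = coarsen(ipd["time"].to_numpy(), config.resolution)
    return out


def _round_vals(v, decimals):
    return v if decimals is None else np.round(v, decimals)


def emulate_digitization(truth: pd.DataFrame, config: ScenarioConfig) -> dict:
    """Emit the published-information channels for one (arm's) true IPD.

    Returns a dict with keys ``curve`` (KM mode) or ``curves`` (list, CIF
    mode), and -- per the scenario's information flags -- ``ticks``,
    ``at_risk`` and ``total_events``.
    """
    t = truth["time"].to_numpy()
    s = truth["status"].to_numpy().astype(int)
    n = t.size
    out: dict = {}
    if config.scenario == "competing":
        m = 2
        cifs = aalen_johansen(t, s, m)
        curves = []
        for j, f in enumerate(cifs, start=1):
            jt = np.unique(t[s == j])
            vals = _round_vals(np.atleast_1d(f(jt)), config.decimals)
            curves.append(DigitizedCurve(times=jt, values=vals.reshape(-1, 1),
                                         mode="cif", cause_labels=(str(j),)))
        out["curves"] = curves
        totals = np.array([int((s == j).sum()) for j in range(1, m + 1)])
    else:
        km = kaplan_meier(t, s)
        if km.times.size:
            vals = _round_vals(km.sf.y, config.decimals)
            out["curve"] = DigitizedCurve(times=km.times, values=vals, mode="km")
        else:  # no events at all: a flat curve up to the last follow-up time
            out["curve"] = DigitizedCurve(times=np.array([t.max()]),
                                          values=np.array([1.0]), mode="km")
        totals = int((s > 0).sum())
    if config.use_ticks:
        out["ticks"] = TickSet(times=np.unique(t[s == 0]))
    if config.use_at_risk:
        if config.at_risk_at_events:
            tau = np.concatenate(([0.0], np.unique(t[s > 0])))
        else:
            tau = config.resolved_at_risk_times()
        counts = np.array([(t >= x - 1e-12).sum() for x in tau])
        out["at_risk"] = AtRiskTable(times=tau, counts=counts)
    if config.use_totals:
        out["total_events"] = totals
    out["n_total"] = n
    return out
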