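# qpipd — pseudo individual-patient data from published survival curves

Meta-analyses, evidence syntheses and cost-effectiveness models frequently
need patient-level time-to-event data that the original investigators cannot
share.  A published Kaplan–Meier plot, however, carries most of that
information: the curve itself, the numbers-at-risk table printed beneath it,
censoring tick marks, and the reported total number of events.  `qpipd`
reconstructs per-subject `(time, status)` records — *pseudo-IPD* — from
those ingredients, for ordinary right-censored survival data and for
competing-risks cumulative incidence curves, by solving a constrained
quadratic program.  It is aimed at biostatisticians and health-economic
modellers who digitize published curves (e.g., with WebPlotDigitizer) and
need data that downstream estimators (Weibull/Cox fits, RMST, Fine–Gray
models) can consume.

## The optimization at the core

Let `s_i` be the digitized survival values at times `t_i`, and
`o_i = 1 − s_i / s_{i−1}` the relative decrements (with `s_0 = 1`).  If
`d_i` subjects had events and `c_i` were censored at `t_i`, the Kaplan–Meier
estimator satisfies `o_i · r_i = d_i` with `r_i = N − Σ_{j<i}(d_j + c_j)`.
The reconstruction therefore minimizes

```
W = Σ_i [ o_i (N − Σ_{j<i}(d̃_j + c̃_j)) − d̃_i ]²  +  ε Σ_i c̃_i²
```

subject to linear constraints: each at-risk period `[τ_{j−1}, τ_j)` must
lose exactly `R_{j−1} − R_j` subjects, the events must total `N_E` when it
is reported, `d̃_i ≥ 1` wherever the curve visibly drops, and censoring is
confined to the tick-mark times when ticks are trusted.  Each bracket is
linear in the unknowns, so `W` is a convex quadratic and the relaxed problem
is a standard QP; the small ridge `ε` (default 0.001) resolves the otherwise
indeterminate split of censorings between adjacent ticks.  The continuous
solution is converted to integer counts by midpoint rounding of cumulative
sums with per-period rescaling, then polished by a greedy within-period
reallocation that lowers the integer objective further (approaching the
exact mixed-integer optimum).  For competing risks the same machinery runs
on the Aalen–Johansen increments
`o_ij = (f_ij − f_{i−1,j}) / (1 − Σ_l f_{i−1,l})` with one event block per
cause; with a single cause it reduces exactly to the Kaplan–Meier program.

## Worked example

Four subjects: events at t = 1, 2, 3 and one censoring at t = 1.5.  The
digitized curve is `(1, 0.75), (2, 0.375), (3, 0.0)`, one tick at 1.5, and
numbers at risk 4 at t = 0 and 1 at t = 2.5:

```
$ qpipd km --curve curve.csv --ticks ticks.csv --at-risk at_risk.csv \
        --out - --report report.json
time,status
1.0,1
1.5,0
2.0,1
3.0,1
```

The report shows a perfect fit — the residual objective `W` is zero both
for the continuous solution and after integer rounding, three events and
one censoring were placed, and no constraint had to be relaxed:

```
{ "objective_W": 0.0, "objective_W_integer": 0.0,
  "n_events": 3, "n_censored": 1, "n_tail_censored": 0,
  "relaxations": [], "repairs": [], "solver": "optimal" }
```

The same pipeline can be exercised on simulated data.  `evaluate` draws
Weibull cohorts (shape 0.8, rate 0.2, n = 125, Unif(2, 8) censoring), rounds
the reported times up to a 0.05 grid and the survival values to three
decimals, reconstructs each replicate, and compares analyses of the
pseudo-IPD with the same analyses of the underlying truth:

```
$ qpipd evaluate --scenario base --variant ticks_full --reps 50 --seed 1 --out r.csv
     metric      mean    mc_se     rmse  n  n_failed
    delta_S  0.001781 0.000175 0.002162 50         0
    delta_Y  0.966000 0.069582 1.081850 50         0
 d_log_rate -0.000199 0.000232 0.001635 50         0
d_log_shape -0.000145 0.000138 0.000975 50         0
```

`delta_S` is the integrated absolute difference between the reconstructed
and true Kaplan–Meier curves (survival × time units): about 0.002 here,
i.e., the curves are nearly indistinguishable.  `delta_Y` is the same
integral for the number-at-risk process (person × time units — about one
subject misplaced for one time unit across the whole study), and the
`d_log_*` rows show that Weibull parameters refitted on the pseudo-IPD
deviate from the true-data fits only in the third decimal.

## Library surface

```python
from qpipd import load_curve, AtRiskTable, TickSet, reconstruct_km, reconstruct_cif

curve = load_curve("curve.csv")                       # time,value CSV
rec = reconstruct_km(curve,
                     at_risk=AtRiskTable(times=[0, 20, 40], counts=[286, 240, 190]),
                     ticks=TickSet(times=tick_times),
                     total_events=177)
rec.ipd          # DataFrame: time, status (0 = censored)
rec.counts       # per-time integer event/censoring counts
rec.continuous.W # attained continuous objective
```

Estimators used in the evaluation loop (`qpipd.estimators`) are available
directly: Kaplan–Meier with Greenwood log-scale intervals, Nelson–Aalen,
Aalen–Johansen, Weibull MLE, Cox partial likelihood (Breslow ties), the
Grambsch–Therneau proportionality test, RMST differences, cause-specific
Cox and IPCW Fine–Gray fits.

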