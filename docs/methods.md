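# Methods

## Problem and model

A digitized survival curve provides pairs `(t_i, s_i)`; auxiliary published
information provides numbers at risk `R_j` at report times `τ_j` (with
`τ_0 = 0`, `R_0 = N`), marked censoring times ("ticks"), and possibly a
total event count `N_E`.  Writing `o_i = 1 − s_i/s_{i−1}` (Kaplan–Meier
mode; the increment of the cumulative hazard in Nelson–Aalen mode), a
reconstruction with integer event counts `d_i` and censoring counts `c_i`
is perfect when `o_i (N − Σ_{j<i}(d_j + c_j)) − d_i = 0` for every `i`.
The package minimizes the sum of squares of these residuals over
non-negative continuous counts — a convex quadratic, since each residual is
linear in the unknowns — under:

* **period equalities**: `Σ_{i∈C_j}(d_i + c_i) = R_{j−1} − R_j` with
  `C_j = {i : τ_{j−1} ≤ t_i < τ_j}` (half-open on the right; a grid point
  exactly at `τ_j` opens period `j+1`).  The at-risk convention is
  `R_j = #{T ≥ τ_j}`, which is exactly consistent with that half-open
  membership rule;
* **total events**: `Σ d_i = N_E` when reported (per cause in the
  competing-risks case, or pooled);
* **visibility**: `d_i ≥ 1` wherever the curve drops (`o_i > 0`); `d_i = 0`
  elsewhere (those variables are eliminated, not constrained);
* **tick restrictions** (when ticks are trusted): censoring variables exist
  only at tick times; optionally `c_i ≥ 1` at every tick that does not
  coincide with a drop (on by default — a drawn tick means at least one
  subject was censored there).  A tick at a drop time keeps both `d_i` and
  `c_i` active;
* **bounds and budget**: `d_i, c_i ≤ N` and `Σ(d_i + c_i) ≤ N`.

The candidate grid is the union of curve times, at-risk report times and
tick times; values are carried forward at inserted times so they have zero
decrement.  A regularizer `ε Σ c_i²` (`ε = 0.001`) makes the objective
strictly convex: without it, any split of censorings between ticks lying
between the same two events gives the same fit.  A further uniform ridge of
`1e-8` guards positive definiteness of the event block.  The integerized
result is insensitive to `ε` across 1e-4…1e-2 (tested).

### Competing risks

With `m` causes and digitized cumulative incidences `f_ij`, the relative
increments `o_ij = (f_ij − f_{i−1,j}) / (1 − Σ_l f_{i−1,l})` satisfy
`o_ij r_i = d_ij` under the Aalen–Johansen estimator, and the objective
generalizes term-by-term with one event block per cause.  Cause curves are
aligned on the union grid by carrying each `f_j` forward (the published
estimate is constant between observed points).  With `m = 1` the program is
bit-for-bit the Kaplan–Meier program on `s = 1 − f` (decrements are
quantized at 1e-12 — far below digitizer precision — so the two
algebraically equivalent routes produce identical arithmetic).

## Solving

No QP library is assumed: the continuous program is solved by a dense
primal active-set method (`qpipd.qpsolver`) with a phase-1 linear program
(HiGHS via `scipy.optimize.linprog`) supplying the feasible start, KKT
systems solved directly, and `scipy.optimize.minimize(trust-constr)` as a
fallback for degenerate cycling (not observed in practice).  Solutions
satisfy constraints to ~1e-12 and admit no improving feasible perturbation
(property-tested against scipy).

If the phase-1 LP proves the constraints infeasible, a relaxation ladder is
applied, logging each step: (1) drop the optional `c ≥ 1` tick constraints;
(2) relax `d ≥ 1` to `d ≥ 0` one variable at a time, smallest decrement
first (a tiny printed drop is the most plausible digitization artefact);
(3) as a last resort, admit censoring at all candidate times.  Conflicting
equality rows remain a hard error with a structured message.

## Integerization

Events are rounded by the cumulative-midpoint rule
`d̂_i = ⌊0.5 + Σ_{j≤i} d̃_j⌋ − ⌊0.5 + Σ_{j<i} d̃_j⌋` (half always rounds
up; deterministic), which preserves integer totals and is
translation-consistent.  Censorings are then rescaled within each period by
`V_j = (R_{j−1} − R_j) / Σ_{i∈C_j}(d̂_i + c̃_i)` and rounded the same way.
Because the scaled boundary sums need not be integral, a deterministic
repair pass afterwards enforces each period equality exactly, adjusting the
censoring slot with the largest continuous mass (and, if a period's rounded
events alone exceed its leaving count, decrementing its largest event
count).  All repairs are recorded on the result object.

**Refinement.**  Midpoint rounding can land one or two units away from the
best integer solution.  A greedy pass therefore moves single units between
two times of the same period (events within the same cause, or censorings)
whenever the move lowers the full integer objective `W + ε Σ c²` — moves
that by construction preserve every equality constraint.  This runs in a
few matrix-vector products and closes most of the gap to the exact
mixed-integer optimum: on 100 random tiny instances it matches an
exhaustive enumeration oracle 100/100 (and provably never beats it).  It is
on by default (`ReconstructionOptions(refine=False)` disables it).  A
branch-and-bound MIQP is deliberately out of scope; the enumeration oracle
exists only for validation on instances with ≤ 12 free variables.

## Expansion to subject rows

Events become rows at their grid times.  Censorings are placed at tick
times when ticks are available; without ticks the assignment time is only
known up to the interval to the next candidate time, so rows are placed at
the interval midpoint `0.5 (t_i + t_{i+1})` by default (`midpoint_censoring`
option; the last grid point uses its own time).  Subjects never observed to
leave (`N` minus all assigned counts) are censored at the last grid time
and counted in `n_tail_censored`.  Grid points beyond the last report time
form an unconstrained tail: the published table says nothing about them, so
they carry no equality, only the global `Σ ≤ N` budget.  This tail rule and
the span check on report times (an at-risk table whose *first* interior
report time lies beyond every curve/tick time is rejected as a unit
mismatch, while trailing report times beyond the last drop are routine) are
this package's choices where published practice is silent.

## Estimators

All estimators live in `qpipd.estimators`, take plain `(time, status[,
group])` arrays, and use these conventions: status 0 is censored, `k ≥ 1`
an event of cause `k`; at tied times events precede censorings; ties use
the Breslow approximation throughout (coarsened reporting grids make ties
the norm, and Breslow keeps the partial-likelihood arithmetic exactly
checkable against reference implementations).

* Kaplan–Meier with Greenwood variance of `log S` and
  `S · exp(±1.96 SE)` intervals; Nelson–Aalen; Aalen–Johansen.
* Weibull MLE under `h(t) = λ^α α t^{α−1}` (so `H(t) = (λt)^α`), BFGS with
  analytic gradient, covariance from the finite-difference Hessian; an
  optional fixed shape gives the closed-form exponential-family solution.
* Cox partial likelihood for one covariate by Newton iteration; monotone
  likelihoods are detected and raised, not silently returned.
* Proportional-hazards test: score test for a linear-in-time coefficient
  drift computed from per-event Schoenfeld residuals and per-event risk-set
  variances (the expanded-model form modern `survival::cox.zph` uses, with
  the identity time transform; verified to 7 digits against R on tie-free
  data — under ties R discretizes the risk set slightly differently).
* RMST differences by exact step-function integration of each arm's KM.
* Cause-specific Cox (other causes recoded as censoring) and Fine–Gray via
  inverse-probability-of-censoring weights `G(t−)/G(T_i−)` from the pooled
  censoring Kaplan–Meier — verified to 6 digits against
  `survival::finegray` + `coxph` on a frozen fixture.

## Synthetic data

The generators state the evaluation world explicitly:

* **base**: n = 125 per dataset, Weibull shape 0.8 / rate 0.2 (an early
  hazard, maximizing ties after coarsening), independent Unif(2, 8)
  censoring → ~39% censored, ~76 events per dataset (checked empirically).
* **two-arm**: n = 125/arm, shared shape, arm-1 hazard multiplied by
  `exp(−0.5)` (proportional hazards; the evaluation compares paired
  differences, so the sign convention cannot bias the metrics).
* **competing**: two causes, two arms (n = 125/arm), parameters
  `(κ, λ01, α1, λ02, α2, β1, β2) = (0.6, 0.4, 1.2, 0.2, 1.5, −0.3, 0.3)`;
  cause 1 follows a proportional subdistribution-hazards model
  `F1(t;Z) = 1 − (1 − κ(1 − e^{−λ01 t^{α1}}))^{exp(β1 Z)}`, whose
  all-time mass is `p1(Z) = 1 − (1−κ)^{exp(β1 Z)}` (0.6 and ≈0.493);
  cause 2 takes `F2(t;Z) = (1 − p1(Z))(1 − e^{−λ02 t^{α2} exp(β2 Z)})` —
  the standard complementary-mass design under which the cause-1 Fine–Gray
  model is correctly specified and the cause-2 / cause-specific models are
  not.  Censoring Unif(1, 6).

Reporting error is emulated in two stated steps: observed times are
*coarsened* up to the next multiple of 0.05 (ties, as with day/week
reporting), and curve values are rounded to 3 decimals (digitization
error).  Tick marks are the exact (coarsened) censoring times, including
those tied with events; numbers at risk are reported on the integer time
grid (0…8, or 0…5 for competing risks); totals are exact.  The emulator
does **not** model time-axis digitizer jitter, missed or spurious ticks,
or misread at-risk numbers — so a green evaluation establishes robustness
to value rounding and coarsening, not to arbitrary digitization failure.
Per-replicate seeds are `base_seed + rep`; identical seeds give
byte-identical datasets.

## Evaluation metrics

`delta_S = ∫₀^τ |Ŝ_recon − Ŝ_true| dt` and
`delta_Y = ∫₀^τ |Y_recon − Y_true| dt` with `τ` the maximum follow-up in
the true data, both computed as exact piecewise-constant integrals (no
quadrature).  Parameter-level accuracy is always the *paired* difference
against the estimate from the true IPD of the same replicate, aggregated as
bias and RMSE over replicates.  Failed replicates (solver or estimator
non-convergence) are excluded and counted; none occur in the default
scenarios.  The test suite runs the scenarios at 80–150 replicates with
±3 Monte-Carlo-SE bands (one-sided — no worse than the published heuristic
value — for the discrepancy and RMSE metrics, since the refinement step
legitimately improves on midpoint rounding; two-sided for the paired
biases); `scripts/acceptance.py` reruns everything at the full 1000
replicates.

## Known limitations

* Regression estimators support a single (binary or numeric) covariate —
  all the evaluation harness needs; they are not general modelling tools.
* One at-risk table shared by all causes; left truncation, total-time-at-
  risk constraints and confidence-interval-derived information are not
  implemented.
* The relaxation ladder is heuristic; with grossly inconsistent inputs the
  result is feasible-but-arbitrary, flagged via the relaxation log.
* Curve extraction from plot images is out of scope; inputs are digitizer
  exports.
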