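# Methods

This note records the statistical model, the algorithmic choices, and the
known limitations of `stablevar`. It is the "why" companion to the API
reference in the docstrings.

## Model

A panel of N genes observed over T ordered conditions (a time course, or a
sequence of perturbation experiments treated in experiment order) is
modelled as a first-order vector autoregression

    y_t = v + A y_{t-1} + u_t,

where `A[i, j] != 0` is read as a directed regulatory edge gene_j → gene_i
with sign `sign(A[i, j])` (activation/inhibition). The orientation follows
the Granger principle: the lagged value of the regulator predicts the
target. The intercept is handled by row-centering each gene's series and
adding the means back when forecasting.

Two biological priors become constraints on the least-squares fit:

1. **Sparsity.** Regulatory networks are loosely connected, so the fit is
   restricted to an entrywise L1 budget, `sum_jk |A_jk| <= lambda`.
2. **Stability.** Expression returns to equilibrium after small
   perturbations. Stability is imposed through weighted Geršgorin discs:
   for positive weights v_1..v_N, every row must satisfy

       g_i = a_ii + sum_{j != i} (v_j / v_i) |a_ij| <= 0.

   All margins non-positive certifies that every eigenvalue of A has
   non-positive real part, and the constraint is convex in A.

Note the certificate is a *half-plane* (Hurwitz-style) condition, while
the textbook VAR(1) stationarity condition is `|eigenvalue| < 1`. The
package implements the half-plane constraint as the primary one — it is
what the weighted-disc construction naturally certifies — and reports both
notions (`is_stable(mode="halfplane")` and `mode="modulus"`) in every run
report so the distinction is never silent. In practice the fitted matrices
in this package's experiments are also modulus-stable, but only the
half-plane property is guaranteed.

### Weight iteration

Uniform discs over-penalise rows that are already strongly diagonally
dominant. The weights are therefore re-estimated from the current fit:
with per-row dominance margins `m_i = |a_ii| - R_i(A)` (R_i the deleted
absolute row sum) and their mean `beta`,

    v_i = 1 + (m_i - beta) / (delta + (m_i - beta))   if m_i > beta
    v_i = delta / (delta - (m_i - beta))              otherwise,

with `delta` in (0, 1] (default 0.5) controlling saturation. Values lie in
(0, 2); dominant rows get large weights (their radius contribution to
other rows shrinks), weak rows get small ones. Equality `m_i = beta` falls
in the second branch, where the formula gives exactly 1, so the schedule
is continuous. The fit alternates {constrained solve, weight update} until
the weights change by less than `weight_tol` (default 1e-4). This
fixed-point iteration has no convergence guarantee; it is capped
(`max_outer_iters`, default 20) and the convergence flag is reported.

The raw weight iteration tends to *alternate* around its fixed point, so
the implementation applies a damped update `v <- 0.4 v + 0.6 v_new`.
Damping changes the iteration path, not the fixed point: convergence is
declared on the undamped residual `max |v_new - v|`.

## Solver

The inner problem (fixed weights) is a convex QP over the intersection of
the L1 ball and the per-row weighted-Geršgorin cones. It is solved by
two-block consensus ADMM:

- The A-update is a linear solve against the Cholesky factor of
  `Z Z' + 2 rho I`.
- The L1 ball has the classical sort-based Euclidean projection.
- Each Geršgorin row cone has an exact projection: the row's dual step
  length solves a strictly decreasing piecewise-linear equation whose
  kinks are the sorted values `|a_ij| / w_ij`, so it is found exactly by
  sorting, with the diagonal entry shifted and the off-diagonals
  soft-thresholded.

`rho` defaults to `trace(Z Z')/N` and is re-balanced every 200 iterations
to keep primal and dual residuals comparable. Because ADMM iterates are
only feasible in the limit, the returned matrix is polished onto the exact
constraint intersection (Dykstra alternating projections, finishing with
the Geršgorin projection and a radial shrink that cannot break the
margins). Every reported solution is therefore *exactly* feasible:
`||A||_1 <= lambda`, all margins <= 0, all diagonal entries <= 0, and all
eigenvalue real parts <= 0, up to ~1e-9 arithmetic noise rather than up to
a solver tolerance.

## Budget selection

`lambda` is chosen by rolling one-step-ahead forecast error. With
`T1 = floor(T/3)` and `T2 = floor(2T/3)`, for each window end
t = T1..T2-1 the model is fitted on observations 1..t and forecasts
observation t+1 as `mean + A_hat (y_t - mean)` (training-window row means
added back). The score is

    MSFE(lambda) = sum_t ||forecast error||^2 / (T2 - T1 - 1).

The sum has `T2 - T1` terms but the normaliser is `T2 - T1 - 1`; the
definition is kept exactly as stated in the method this package
implements. It only rescales all scores equally, so the argmin is
unaffected. Ties break toward the smaller (sparser) budget. The final
third of the data is untouched by selection and can be scored separately
(`evaluate_final=True`).

Rolling fits warm-start from the previous window/budget and use loosened
inner tolerances (1e-6 solver, 1e-3 weight) — forecasts are insensitive
below that level and the rolling scan dominates the cost. The final fit at
the winning budget uses the caller's full tolerances.

The CLI default grid is {0.0, 0.1, ..., 1.0}. For synthetic studies whose
generating matrices have `||A||_1` well above 1, `default_recovery_grid`
builds a scale-free grid of fractions {0, 1/8, ..., 1} of the OLS
estimate's L1 norm.

## Evaluation

Each ordered gene pair (self-pairs included) falls in exactly one
confusion cell, so TP+FP+TN+FN = N². A recovered edge with the wrong sign
counts as a false positive (the inferred interaction does not exist in the
reference), not a false negative. False positives subdivide into false
activations/inhibitions by the inferred sign. Metrics with zero
denominators are reported as NaN and flagged, never coerced. Genes acting
as one regulatory unit can be collapsed into complexes before scoring:
intra-complex edges are dropped, inter-complex member edges deduplicate to
one edge whose sign comes from the largest-magnitude contributor (majority
with ties → + when magnitudes are unavailable).

## Synthetic benchmark

The generator draws sparse off-diagonal support (Bernoulli `density`,
magnitudes uniform in [0.5, 1.5]·`coeff_scale`, random signs) and sets
each diagonal to `-(R_i + slack)` so the ground truth is strictly feasible
for the stability constraint ("gershgorin" regime). Trajectory simulation
additionally needs eigenvalues inside the unit circle, so draws with
spectral radius > 0.95 are rejected and redrawn from a sub-seeded stream;
the "modulus" regime instead rescales to spectral radius 0.9. Data come as
noise-driven trajectories (burn-in 50) or as short-horizon responses to
sparse perturbations of the equilibrium. The generator emulates the
statistical structure the method assumes, not microarray platform noise
or transcription biophysics.

`recovery_experiment` runs the full pipeline (generate → select budget by
MSFE → fit → extract edges → score against truth). Support is called at
`max(2 * SE_ij, edge_threshold)` where `SE_ij` is the classical OLS
per-coefficient standard error on the same lag regression. The reason is
statistical, not numerical: at a forecast-optimal budget the L1 constraint
is barely active, so the exact solution carries many tiny nonzero entries
that are genuine least-squares signal but statistically indistinguishable
from zero — reading support at numerical zero would score noise. For
trajectory data the per-entry standard error is approximately
`1/sqrt(1.5 T)` *independently of the innovation scale* (signal and noise
variance both scale with it), ≈0.06 at T=200, which is why a
conventional ~2-standard-error call is the meaningful "small threshold".
The 20-replicate default benchmark (N=6, density 0.2, coeff_scale 0.3,
noise_sd 0.05, T=200, seeds 0..19) achieves mean support sensitivity 0.84
and specificity 1.00 in ≈2.5 minutes on one CPU.

## Numerical and API choices

- Single-series lag convention: Z = observations 1..T-1, Y = 2..T; no
  presample.
- All matrix writers emit full double precision (`%.17g`) and the readers
  parse with round-trip float precision, so constraint checks hold on
  re-loaded artifacts bit-for-bit.
- Expression containers accept N = 1 (useful for univariate utilities);
  network inference itself requires N >= 2.
- Everything is deterministic for fixed inputs, configuration and seeds;
  generator sub-streams are seeded as `(seed, attempt)` so rejection
  resampling stays reproducible.

## Known limitations and documented discrepancies

- The half-plane/modulus stability mismatch described above is inherent
  to the disc construction; both are reported.
- The weight fixed point is a heuristic; convergence is observed, not
  proven, and the flag is surfaced everywhere.
- Published reference points retained as documentation only (they require
  external datasets and are not reconstructible at desk scale): an MSFE
  of 5.20 at lambda 0.3 on a 9-gene bacterial SOS panel — reported
  alongside a contradictory selection of lambda 0.4 — and a yeast
  cell-cycle analysis quoted at 65%/94% sensitivity/specificity without
  full counts. The same source quotes "25" missed interactions where its
  own table implies 26, and a "37%" net connectivity inconsistent with
  the table's 50/81; this package fixes net connectivity = inferred
  interaction fraction (TP+FP)/N² and documents the discrepancy rather
  than resolving it.
- The evaluation treats the reference network as ground truth; biological
  references are themselves incomplete, so "false positives" on real data
  may be undiscovered regulation.
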