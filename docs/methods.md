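# Methods

## The model

The package treats gene expression as a discrete-time linear dynamical
system over G genes. Writing x(t) for the vector of (normalized) expression
levels at sampling time t,

    x(t+1) = A x(t) + b + η_t,      η_t ~ N(0, σ_p² I),

where the off-diagonal entries of A are the signed regulatory coefficients
(the network), the diagonal entries are self-persistence terms, b is a
basal production vector, and η is process noise ("nominal production").
Sparsity is structural: each gene has at most k regulators. No Δt term
appears — consecutive sampling times are treated as one model step even
when the clock-time gaps differ, because the model class is defined on the
sampling grid, not on physical time. Conditions (genotype × treatment
combinations) share A and b and differ only in their state trajectories;
this is what gives the regression leverage with as few as three time
points: every condition contributes lagged observation pairs to one shared
regression.

### The virtual time shift

With samples at times t_1 < … < t_T inside a single day, each condition
contributes the T−1 consecutive transitions. The optional virtual time
shift adds the wrapped pair (t_T → t_1) *within the same condition*,
treating the first morning sample as a stand-in for the sample that would
follow the last evening one. This buys one extra observation row per
condition and lets regulation acting overnight enter the regression; its
cost is the assumption that the day's first sample approximates the
steady rhythm of the next morning. It is on by default and controllable
per run.

## Stage I: best-subset lagged regression

For each target gene the design for one row is [1, own lag, k regulator
lags]; all C(|candidates|, k) subsets of size exactly k are enumerated and
the minimum-RSS subset kept. Exactly-k search (not ≤ k) is deliberate:
Stage II, not Stage I, decides how many regulators survive. The target's
own lag is always present, absorbs autocorrelation, and is never reported
as an edge (no self-loops in the output).

Implementation: the Gram matrix X'X of all G+1 design columns and the
cross-products X'y for all targets are computed once per (possibly
perturbed) dataset; each subset then costs one (k+2)×(k+2) solve with
RSS = y'y − β'X'y, batched across all subsets with stacked LAPACK solves.
The winning subset is refit by QR-based least squares for an accurate
coefficient vector and a rank check. Ties in RSS (relative 1e−12) resolve
to the earliest subset in canonical gene order, making results
deterministic. A greedy forward-selection mode exists for gene sets where
enumeration is infeasible; it is a heuristic (tests assert it never beats
the exhaustive optimum and coincides with it at k = 1) and is off by
default.

Two modeling switches are exposed rather than asserted, since either
choice is defensible for normalized expression data: the intercept
(default on — the nonzero-mean basal production term needs somewhere to
go) and per-gene standardization of predictors (default off — coefficients
and their signs should refer to the user's scale).

## Stage II: Granger pruning

Each of the k selected regulators is tested marginally: the reduced model
refits the other k−1 regulators (plus own lag and intercept) and

    F = (RSS_reduced − RSS_full) / (RSS_full / df),  df = n − (k+2),

with p from the upper tail of F(1, df). A regulator is kept iff p < α
(default α = 0.05): keeping the regulators that significantly reduce
prediction error is what "removing false positives" means in the Granger
framework. Because the procedure is sometimes described with the opposite
phrasing (rejecting the regulator when p is *below* the level), a
`granger_literal` flag implements that reading too; the default follows
the internally consistent convention. Tests are simultaneous, not
stepwise, and there is no multiple-testing correction — one preset level,
as in the study design the package reproduces.

Degenerate cases: if the full model fits perfectly (RSS_full numerically
zero, relative floor 1e−12) but the reduced does not, the perfect fit is
attributed to the regulator (F = +∞ sentinel, p = 0, kept); if both RSS
are numerically zero there is no information to attribute and the
regulator is removed. Reduced-model RSS is clamped to be ≥ RSS_full
(nesting can be violated only by rounding).

Note on calibration: the type-I guarantee (a true-zero regulator kept at
rate ≈ α) holds for a *fixed* regulator set, which is how the acceptance
test checks it. After Stage I's data-driven subset selection the tests are
post-selection and the nominal level is not exact — a known property of
this two-stage design, shared with the procedure it implements.

## Stage III: perturbation analysis

Each perturbation draws one value per (gene, condition, time) cell from a
Gaussian centered at the cell's replicate mean, truncated below at zero
(skipped for signed data), and reruns Stages I–II. The default variance is
s²/n (squared standard error): the perturbed quantity stands in for the
*replicate mean* the regression consumes, and s²/n is the unique variance
under which the scheme has the same mean and variance as bootstrapping the
mean with resampling size 2 from n = 3 replicates
(Var = Σ(x_i−x̄)²/6 = s²/3). Modes `sample` (s²) and `population`
((n−1)/n · s²) are selectable because the prose description of such
schemes is often ambiguous about the scaling. Zero-variance cells
reproduce their mean exactly, so a noise-free dataset yields B identical
runs and all weights in {0, 1}.

Aggregation over B runs (default 100): existence weight = occurrences/B,
consensus sign = majority sign ("ambiguous" on an exact tie), sign
weight = majority fraction (≥ 0.5 by construction). Weights are reported
as fractions in [0, 1]; typical reporting cut-offs are 0.1, 0.2, and 0.6.
The unperturbed point-estimate network is computed and reported separately
and never enters the weights. Replicates feed *only* the variance model:
Stage I always regresses on per-cell means, because biological replicates
at different time points are unpaired individuals and any pairing across
times would be arbitrary.

Determinism: each perturbation uses an independent substream spawned from
the master seed (`numpy` SeedSequence), so a fixed seed gives bit-identical
networks and the aggregate is invariant to run order. Runs are independent
by construction and could execute in parallel provided aggregation keeps
index order.

## The simulator

`sample_network` draws exactly k_true off-diagonal regulators per row,
magnitudes uniform in [0.5, 1.0] (sign negative with probability 0.5),
self-persistence uniform in [0.1, 0.5], then rescales A to spectral radius
≤ 0.95 so trajectories are bounded; draws whose rescaled effect sizes fall
below 0.3 are rejected so every true edge remains statistically visible at
T = 3 — recovery failures should reflect the method, not vanishing
effects. Cycles and feedback loops are permitted throughout; nothing
forces acyclicity, since feedback is exactly what such networks contain.

`simulate_dataset` starts each condition at N(fixed point (I−A)⁻¹b,
init_sd² I) — cross-condition diversity standing in for genotype and
photoperiod contrasts — runs the dynamics, and adds independent
N(0, σ_m²) measurement noise per replicate. Nonnegativity is obtained by a
per-gene constant shift (default, margin 0.01), which preserves the linear
dynamics exactly (only b changes); hard clipping at zero exists but breaks
linearity and is off by default.

What the simulator does *not* emulate: nonlinear (Hill-type) kinetics,
mRNA/protein layers, circadian forcing, condition-dependent networks, and
non-Gaussian measurement error. Passing recovery tests therefore shows the
inference is correct *for its own model class* at the study's data
geometry — not that real transcriptome data satisfy that model.

## Problem sizes and numerical choices

The test suite and acceptance script use: 50 random instances (G ≤ 10,
k ≤ 3) for brute-force equivalence at 1e−9 relative; 100 noiseless
instances (G = 8–12, k_true = 2, C = 8 so observations ≥ 4(k+2)) for exact
recovery; 1,000 simulated datasets for Granger calibration (3 binomial SE
around α); 10,000 draws per cell against closed-form truncated-normal
moments (3 SE); a full study-geometry run (74 genes, 6 conditions, T = 3,
R = 3, k = 3, B = 100, virtual shift) as the tractability check, which
completes in a few minutes on one CPU; and a 3-level measurement-noise
ladder (σ_m ∈ {0.05, 0.4, 1.2}) over 10 repetitions for AUPR
monotonicity, allowing one stochastic inversion.

Other conventions: expression input must be nonnegative unless loaded in
signed mode; incomplete (gene, condition, time, replicate) grids are
rejected at load with the first offending cell named; recovery precision
with an empty prediction set is `None` (a distinguished null), never a
silent 0 or 1; AUPR uses the step-wise average-precision sum over observed
weight thresholds.

## Limitations

- First-order lags only; no multi-lag models, no Δt weighting for uneven
  sampling gaps.
- Stage II p values are nominal after Stage I selection (see above).
- With T = 3 and few conditions, distinct networks can be
  observationally near-equivalent; confidence weights quantify resampling
  stability, not identifiability.
- The perturbation scheme treats cells independently; correlated replicate
  noise across genes or times is not modeled.
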