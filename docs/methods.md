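# Methods

## Model and estimand

The package treats the observed d-variate, equally spaced series
`X_1 .. X_d` as one realisation of a linear stochastic differential
equation

    dX = (f + A X) dt + B dW,

with constant drift matrix `A = (a_ij)`, intercept `f`, diagonal noise
amplitude `B` (`g_ii = b_ii^2`), and standard Wiener forcing.  Within the
information-flow formalism, the rate at which component `X_j` contributes
Shannon entropy to the marginal entropy of `X_i` has, for this linear
family, the closed form

    T_{j->i} = a_ij * sigma_ij / sigma_ii        [nats per unit time],

where `sigma` is the stationary covariance.  Causality is *defined* by
nonzero flow; two consequences shape everything downstream:

* **Nil causality.**  If `a_ij = 0` (equation `i` does not involve `X_j`),
  the flow is exactly zero — even when `sigma_ij` is large because a third
  component drives both.  Confounding is therefore resolved structurally,
  not by post-processing.
* **Causation implies correlation, not conversely.**  `sigma_ij = 0`
  forces `T_{j->i} = 0`, but zero flow places no constraint on the
  correlation.

For discrete-time maps (`dt = 1`) the same formulas apply with the drift
read as `A_map − I` and flows in nats per step.

## Maximum-likelihood estimation

With the Euler–Bernstein approximation of the transition density, the
log-likelihood of the data separates per target component `i`.  Writing
the span-k forward difference `Xdot_{i,n} = (X_{i,n+k} − X_{i,n})/(k dt)`,
maximising the Gaussian likelihood is the least-squares problem
`Xdot_i ≈ f_i + sum_j a_ij X_j`, whose normal equations involve only
sample moments:

    C a_i = Cdot[:, i],
    f_i   = mean(Xdot_i) − a_i · mean(X),
    Q_i   = n_eff (var(Xdot_i) − 2 a_i·Cdot[:,i] + a_i·C a_i),
    g_ii  = Q_i * dt_eff / n_eff .

Plugging `a_hat` and the sample covariance ratio into the closed form
gives `T_hat[j->i] = (C_ji/C_ii) a_hat_ij`; the self-influence estimate is
`dH*_i/dt = a_hat_ii`; the noise contribution is `g_hat_ii/(2 C_ii)`.
The marginal-entropy budget `dH_i/dt = self + flows + noise` motivates the
normaliser

    Z_i = |a_hat_ii| + sum_{j != i} |T_hat[j->i]| + g_hat_ii/(2 C_ii),

and `tau = T_hat / Z` in [−1, 1] is the relative flow.  `Z` sums *all*
estimated flows, significant or not; `tau` carries the sign of `T_hat`
(only magnitudes are usually reported).

Conventions adopted where more than one reading is defensible:

* All sample statistics (means, `C`, `Cdot`, `var(Xdot)`) are computed on
  the common support `n = 1..N−k`: the raw series truncated to the derived
  series' length.  Mismatched supports would bias `Cdot`.
* Covariances use the MLE `1/n_eff` normalisation.  It cancels in every
  flow (ratios of covariances) and enters only `g_hat`.
* The noise estimate uses `n_eff = N−k` and the effective likelihood step
  `dt_eff = k dt` (the difference spans k raw steps), reducing to the
  textbook `Q dt / N` for `k = 1` at large N.
* Coefficients are obtained by a symmetric linear solve of `C a = Cdot`
  column; the algebraically identical determinant/cofactor expansion is
  kept in `infoflow.oracle` as an O(d!) brute-force cross-check (d ≤ 6),
  not as the production path.
* `T[i][i]` is stored as 0; self-influence lives in its own vector, and
  exported matrices mark the diagonal `-`.
* Signed flows are computed and stored; absolute values are a
  presentation choice.

### Differencing span k

`k = 1` (default) is the accurate choice for stochastic data.  For
deterministic chaos sampled at the integrator's own resolution, the
1-step difference of a smooth trajectory is nearly noiseless and the
regression degenerates; `k = 2` decorrelates the difference from the
evaluation point and is used for the chaotic-oscillator benchmark.

## Significance

Per target, `theta = (f_i, a_i1..a_id, b_i)` with `b_i = sqrt(g_ii)`.  The
empirical Fisher information `I` is the averaged negative Hessian of the
per-step Gaussian transition log-density, assembled in closed form
(regressor second moments for the `(f,a)` block, `2/g` for the `b,b`
entry at the MLE, near-zero cross terms); `(n_eff I)^{-1}` is the
asymptotic covariance of `theta_hat`.  Then

    se(T_hat[j->i]) = |C_ji / C_ii| * sd(a_hat_ij),
    se(dH*_i/dt)    = sd(a_hat_ii),

with two-sided normal p-values and `T_hat ± z_{1−alpha/2} se` confidence
intervals.  Large-N asymptotics are used throughout (no small-sample t
correction; below N ≈ 200 the intervals should be read qualitatively).
The Hessian is exposed through `transition_loglik` so tests can verify it
against finite differences.  Numerically, the information matrix is
inverted after diagonal preconditioning — its blocks differ by orders of
magnitude when `g` is small — and `g` inside the Fisher matrix is tied to
the residual sum so the `b` curvature stays positive even for
deterministic, near-perfectly fit targets.

Graph reconstruction is significance-gated: starting from isolated
vertices, the edge `j -> i` is added when `p_{j->i} < alpha` (default
alpha = 0.10, per-edge, mirroring the original algorithm), and node `i`
is flagged as a self-loop when its self-influence passes the same z-test —
a formalisation of reading the reported `dH*/dt ± se` error bars as a
test.  Because `d(d−1)` hypotheses are tested simultaneously, the
expected number of false edges under the per-edge rule is about
`alpha·d(d−1)`; Bonferroni and Benjamini–Hochberg corrections (via
statsmodels) are available behind the `correction` option for users who
prefer family-wise or FDR control.  Directed cycles are deliberately
allowed; absence of edges between confounded nodes is an output of the
method, not a rule.

### Known limitations of the error bars

* The flow variance treats the covariance ratio `C_ji/C_ii` as fixed.
  Testing *zero* flow is then exact (the statistic reduces to the t-test
  on `a_hat_ij`), and the type-I error is calibrated — the Monte-Carlo
  suite confirms a rejection rate ≈ alpha on null systems and nominal
  interval coverage on a confounded zero-flow edge.  For strongly nonzero
  flows, however, the neglected sampling variability of the ratio can
  dominate, and the nominal interval then under-covers (on the six-node
  benchmark's strongest edge the empirical spread is ~3x the nominal se).
  Significance decisions — the package's main product — are unaffected;
  interval widths around large flows should be read as lower bounds.
* Stationarity is assumed.  On integrated (unit-root) series such as a
  random walk, the self-coefficient's t-statistic follows the
  Dickey–Fuller, not the normal, law, and the self-loop test
  over-rejects; difference or detrend such series first.
* For noise-free deterministic input the residual variance collapses and
  standard errors shrink toward zero, so even physically negligible flows
  test "significant".  On such systems read the flow *magnitudes*
  (relative to the resolved flows, or via `tau`) rather than p-values;
  this is how the oscillator benchmark below is assessed.

## Built-in study systems

**Six-node noisy VAR network.**  `X(n+1) = alpha + A X(n) + B e(n+1)` with
independent standard-normal shocks; the preset coefficient matrix wires
two directed cycles, X1→X2→X3→X1 and X4⇄X5, both driven by a confounder
X6, with every diagonal entry away from 1 so that all six nodes are
self-loops.  Study conditions: noise amplitude 1 or 100 (a noise-to-signal
ratio above 100 — the flows are invariant to this rescaling), N = 10,000
or 500 steps, dt = 1, k = 1, alpha = 0.10, random standard-normal initial
state, no burn-in (the map is contractive; transients decay in tens of
steps and are negligible at these lengths).

**Coupled Rössler triad.**  Nine ODEs: a master oscillator X
(frequency 1.015) driving two slaves Y (0.985) and Z (0.95) through their
first components with strength eps; a=0.15, b=0.2, c=10 for each
oscillator.  Integrated with fixed-step Heun (second-order Runge–Kutta;
the midpoint variant would serve equally — targets are qualitative),
dt = 0.001, 50,000 steps, first 10,000 discarded, initial state uniform
in [−1,1]^9 (blow-ups from unlucky initial states raise an error that
suggests re-seeding).  For eps > 0.15 the slaves nearly synchronise with
the master (y1–z1 correlation above 0.9 at eps = 0.25).  Estimation for
this benchmark uses the **full 9-dimensional state** with k = 2, and
oscillator-level flows are read between the first components (x1, y1,
z1).  This matters: each first-component equation is exactly linear in
the full state, so the fit recovers the true wiring (flow X→Y grows from
≈0.0075 at eps = 0.05 to ≈0.25 at eps = 0.25 while all other oscillator
pairs stay near zero).  A 40-time-unit window of only the three
representative series cannot work — the phase-coherent oscillators
(beat period ≈ 200 time units) remain strongly correlated across any
such window, and the 3-variable regression returns O(1) artefacts in
both directions.  `simulate_rossler` therefore exposes `full_state=True`,
and the sweep tests estimate at d = 9.

What the generators do *not* emulate: observation noise on top of the
dynamics, irregular sampling, missing data, nonstationary parameters, and
non-diagonal noise coupling.  Passing tests demonstrate recovery under
the model's own assumptions plus the two stress regimes (heavy dynamical
noise, synchronisation); they do not certify performance on data that
violate stationarity or linearity beyond those regimes.

## Validation oracles

`infoflow.oracle` supplies the references the tests compare against: the
stationary covariance from the continuous Lyapunov equation
`A Sigma + Sigma A' + B B' = 0` (scipy's solver), the exact flow matrix
`T_true[j,i] = a_ij sigma_ij / sigma_ii`, and the cofactor estimator.
The reference 3-D system for convergence checks is the cyclic drift
`A = [[−1,0,0.8],[0.8,−1,0],[0,0.8,−1]]`, `B = I` — couplings strong
enough that the 10% relative-error check measures estimator accuracy
rather than sampling noise.  The confounded configuration
(`X2 -> X1`, `X2 -> X3`, no 1–3 coupling) doubles as the
correlation-without-causation demonstration and as the
interval-coverage study system.

## Problem sizes in the test suite

Monte-Carlo checks use 40–500 replicates of 500–2,200-step series
(type-I calibration: 200 replicates; coverage: 500; consistency: 50 per
sample size across N = 1e3..1e5); benchmark runs use the study conditions
above averaged over three seeds.  The full suite runs in well under a
minute on one CPU; the Rössler sweep (18 integrations of 50,000 steps)
dominates.
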