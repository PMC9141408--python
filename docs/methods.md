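# Methods

## Setting

A central server aggregates messages (gradients or parameter updates) from
`m` clients into one vector in `R^p`. Some clients may be Byzantine: they
send arbitrary or adversarial vectors rather than honest gradient
information. The aggregation rule is therefore a robust location estimation
problem: given rows `x_1 … x_m`, estimate the centre of the honest
distribution while bounding — ideally extinguishing — the influence of a
contaminating fraction.

## The gamma-mean

The core estimator is the minimum gamma-divergence fit of a Gaussian working
model `N(mu, Sigma)`. The gamma-divergence is a density-power divergence
indexed by `gamma > 0` that reduces to Kullback–Leibler as `gamma -> 0`;
minimizing it against the empirical distribution yields estimating equations
whose solution satisfies the fixed-point system

    d_i = exp(-gamma/2 (x_i - mu)' Sigma^{-1} (x_i - mu)),   w_i = d_i / sum_j d_j,
    mu    = sum_i w_i x_i,
    Sigma = (1 + gamma) sum_i w_i (x_i - mu)(x_i - mu)'.

The estimator is a weighted mean whose weights decay exponentially in
squared Mahalanobis distance, so gross outliers receive essentially zero
weight; the `(1 + gamma)` factor in the scatter update undoes the shrinkage
the weighting would otherwise induce, making the scatter Fisher-consistent
at the Gaussian model. Two variants are implemented:

* **gamma-mean** (`gamma_mean`): full `(mu, Sigma)` fit by alternating the
  three updates above.
* **simple gamma-mean** (`simple_gamma_mean`): the working model is the
  standard Gaussian, so `Sigma = I` is never estimated and any data scale
  `sigma^2` is absorbed into `gamma`. This is the variant of choice in high
  dimension, where a full scatter cannot be estimated from `m` rows.

Comparison aggregators: coordinate-wise mean and median, the geometric
median (Weiszfeld iteration), and the coordinate-wise `beta`-trimmed mean.

### Numerical choices

* **Convergence.** A sweep updates `mu` first, then `Sigma`. The iteration
  stops when the sup-norm change of `mu` falls below `tol` (default `1e-8`)
  *and* a plug-back evaluation of the stationary equations at the final
  iterate has sup-norm residual below `tol`; the second condition makes the
  reported `stationarity_residual` a guarantee rather than a heuristic.
  Default iteration cap `S = 100`. Non-convergence is reported via
  `converged=False`, not an exception.
* **Initialization.** `mu` starts at the marginal median (selectable: mean
  or user-supplied); `Sigma` starts at the identity scaled by the median
  squared distance to the initial `mu`, which keeps the initial weights in a
  usable dynamic range regardless of the data scale.
* **Scatter inversion.** The full `Sigma` is inverted (via Cholesky, with a
  ridge of `1e-10 * trace/p`) only when `m >= max(5p, p+1)`; below that —
  or always, under `scatter_policy='diagonal_fallback'` — the inverse of
  `diag(Sigma)` is used. A rank-deficient scatter (condition number above
  `1e8` after the ridge) raises an error advising the diagonal fallback.
* **gamma selection.** The helper `gamma_rule(c, p) = c/p` implements the
  dimension-scaled choice used throughout the simulations (default
  `c = 2`); a fixed `gamma = 0.5` is the default elsewhere. Data-driven
  selection of `gamma` is out of scope.
* **Known degeneracy.** For `gamma` well above the operating range (roughly
  `gamma * p` of order several units on standardized data) the unpenalized
  full fit can collapse: weights concentrate on a near-degenerate cluster
  and the scatter loses rank. This is a property of the estimating
  equations, not of the implementation; the collapse surfaces as the
  singular-scatter error. The simple variant does not collapse this way.
* **Weiszfeld.** Initialized at the (weighted) mean; stops when the
  (sub)gradient norm is below `tol`. The objective is provably non-increasing
  and is recorded per iteration. If an iterate lands on a data point the
  classical optimality certificate is tested there (stop if the pooled
  weight of coincident points dominates the pull of the rest, else restart
  with a `1e-8` jitter along the pull direction). A two-point batch with
  equal weights has a segment of minimizers; the midpoint is returned and
  flagged non-unique. With unequal weights the heavier point (the exact
  minimizer) is returned.
* **Trimmed mean.** `k = floor(beta m)` rows are removed from each tail per
  coordinate (so `beta < 0.5` can never remove everything). With per-row
  weights the L-statistic form `(1-2 beta)^{-1} \int_beta^{1-beta} Q(u) du`
  over the interpolated weighted quantile function is used instead.
* **Weighted quantiles.** Midpoint plotting positions with linear
  interpolation; at uniform weights this reproduces the numpy median
  convention (midpoint of the central pair at even `m`).

## Influence functions

The influence function `IF_T(x0; G)` — the Gateaux derivative of the
estimator functional toward a point mass at `x0` — is provided in closed
form at an elliptical reference for all five aggregators:

* mean: `x0 - mu` (unbounded);
* gamma-mean at its Gaussian working model:
  `(gamma+1)^{(p+2)/2} exp(-gamma/2 Mahalanobis^2) (x0 - mu)` —
  *redescending*, with maximal norm along any ray at Mahalanobis radius
  `1/sqrt(gamma)`;
* coordinate-wise median: `sign(x0_j - mu_j) / (2 g_j(mu_j))` (bounded; the
  undefined sign at the median is set to 0 by odd symmetry);
* trimmed mean: linear inside the central `(beta, 1-beta)` quantile band,
  clipped to a nonzero constant outside; the centring constant
  `W_j = E[t 1_band] + beta (q_lo + q_hi)` is fixed by Fisher consistency
  (`E_G[IF] = 0`), with the band integral in closed form for Gaussian
  marginals and adaptive quadrature (abs. tol `1e-10`) otherwise;
* geometric median: `A^{-1} u`, `u` the unit direction of `x0 - mu`, with
  `A = E[ r^{-1} I - r^{-3} zz' ]` estimated by antithetic Monte Carlo
  (default `10^6` draws, mandatory seed) since no closed form is available
  in general.

`gateaux_numeric` is the independent check: it evaluates
`[T((1-e) F_n + e delta_{x0}) - T(F_n)] / e` on a weighted empirical
distribution (default `e = 1e-6`, optional Richardson extrapolation). Two
practical points. First, the derivative of a *quantile-based* functional at
an i.i.d. sample is dominated by the O(1) relative noise of local
order-statistic spacings, so the median and trimmed-mean checks use a
deterministic stratified Gaussian sample (`Phi^{-1}((k-1/2)/n)` per
coordinate) as the reference; smooth functionals (mean, gamma-mean,
geometric median) are checked on i.i.d. references. Second, the oracle
differentiates the functional at `F_n`, so the closed form it is compared
with is evaluated at the functional's parameters *of that sample* (for the
gamma-mean, the fitted `(mu_gamma, Sigma_gamma)`); comparing against
population parameters adds an `O(n^{-1/2})` mismatch that is not part of
the formula being verified.

## Contamination simulations

`generate_gradients` draws honest rows from a centred standard Gaussian or
Student-t (5 df) and makes exactly `round(alpha m)` rows Byzantine by adding
a location shift `Delta` (default 100) to every coordinate — defaults
`m = 200`, `gamma = 2/p`, 100 replicates. `run_scenario` applies every
requested aggregator to the same batches (common random numbers) and
reports, per cell, the exact decomposition `mse = bias^2 + variance` with
norms summed over coordinates. Only comparisons between aggregators at a
common cell are meaningful; absolute values scale with `p`. Truth is the
zero vector. Replicate streams derive from `(seed, p, alpha, replicate)` so
any cell is reproducible in isolation and grids parallelize
deterministically.

Desk-scale defaults used by the shipped checks — dimension sweep at
`p = 100` with 20 replicates, variance-vs-`c` at 50 replicates, the
contamination law at `p = 10` with 100 replicates — were chosen so each
quantity's Monte-Carlo error is far smaller than the effects asserted
(orderings are separated by factors of 3 to 10^4), while a full run at the
original grids remains available through `ScenarioSpec`.

## Federated harness

`run_federated` implements the broadcast / local-update / aggregate cycle
on two synthetic convex tasks (quadratic, logistic on Gaussian
class-conditional data). Honest clients run `k` full-batch gradient epochs
at the half-cosine learning rate `lr_t = lr_0 (1 + cos(pi t/T))/2` (pinned
formula; any decreasing cosine variant would fit the description "cosine
decay") and return their parameter change; Byzantine clients return i.i.d.
`N(5, 1)` vectors. The server aggregates the deltas, clips the *aggregated*
vector to `clip_norm` if configured, and applies it with a unit server
step. Client sizes follow Lognormal(1.5, 3.45^2) -> Dirichlet ->
multinomial with a 512-sample floor. An optional per-epoch subsampling
fraction (default 1.0) mimics partial-data local epochs.

The logistic task puts the class-mean separation on a single coordinate
axis on purpose: the `N(5, 1)` attack drags the mean-aggregated model along
the all-ones direction, and if the discriminant direction were also
all-ones the corrupted model would classify well by coincidence, hiding the
failure the harness is meant to expose. With `dim = 10` and separation 2
(Bayes accuracy ~0.977), a mean-aggregated run under 10% attack plateaus
near 75–80% accuracy while the simple gamma-mean reaches ~97%.

## What the synthetic data does and does not show

The generators emulate the canonical Byzantine abstractions: location-shift
contamination of elliptical gradient distributions, and a fixed-variance
random attack in the federated loop. They do not emulate heterogeneous
(non-i.i.d.) honest clients, collusive or adaptive attacks that mimic honest
statistics, gradient distributions from deep networks, or client dropout.
Passing tests therefore certify the estimators' statistical behaviour under
the stated contamination models, not end-to-end robustness of any
production federated system.

## Limitations

* `gamma` must be chosen by the user; the `c/p` rule is a heuristic, and the
  full fit degrades (and can collapse) when `gamma` is far above the
  operating range.
* The closed-form gamma-mean influence function is stated at the Gaussian
  working model only; for t references use `gateaux_numeric`.
* The trimmed mean inherits its known blind spots (one-sided outliers,
  contamination above `beta`), which the simulations exhibit rather than
  correct.
* Client weights are uniform: under Byzantine behaviour, client-reported
  sample sizes are unreliable, so size-proportional weighting is not
  offered.
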