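"""Server-side aggregation rules for Byzantine-robust federated learning.

Every aggregator maps an ``(m, p)`` batch of client vectors (one row per
client) to a single point in R^p.  Alongside the classical robust rules
(coordinate-wise median, geometric median via Weiszfeld iteration, trimmed
mean), this module implements the gamma-mean: the location (and scatter)
estimate obtained by minimum gamma-divergence estimation under a Gaussian
working model.  The gamma-mean is a weighted average whose weights decay
exponentially in the squared Mahalanobis distance from the current centre,

    d_i = exp(-gamma/2 * (x_i - mu)' Sigma^{-1} (x_i - mu)),
    w_i = d_i / sum_j d_j,

so distant (e.g. Byzantine) rows are smoothly down-weighted; ``gamma`` trades
robustness against statistical efficiency, and gamma -> 0 recovers the sample
mean (the Kullback-Leibler limit of the divergence).

All aggregators accept optional nonnegative per-row weights, which makes them
usable as statistical functionals of weighted empirical distributions (needed
by the numerical influence-function oracle in :mod:`robustagg.influence`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "GammaConfig",
    "LocationScatterEstimate",
    "WeiszfeldInfo",
    "DegenerateWeightsError",
    "SingularScatterError",
    "gamma_rule",
    "gamma_weights",
    "gamma_mean",
    "simple_gamma_mean",
    "mean_aggregate",
    "marginal_median",
    "trimmed_mean",
    "geometric_median",
    "weiszfeld",
    "weighted_quantile",
    "weighted_band_mean",
]


class DegenerateWeightsError(ValueError):
    """All down-weighting factors underflowed to zero (every point is extremely far)."""


class SingularScatterError(np.linalg.LinAlgError):
    """Full scatter matrix is numerically singular."""


def _as_batch(x, min_rows: int = 1) -> np.ndarray:
    """Validate and return an (m, p) float batch; 1-D input becomes a column."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"batch must be 2-dimensional, got shape {arr.shape}")
    m, p = arr.shape
    if m < min_rows or p < 1:
        raise ValueError(f"batch must have at least {min_rows} row(s) and 1 column, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("batch contains non-finite entries")
    return arr


def _row_weights(weights, m: int) -> np.ndarray:
    """Normalized nonnegative per-row weights; uniform when None."""
    if weights is None:
        return np.full(m, 1.0 / m)
    w = np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise ValueError(f"weights must have shape ({m},), got {w.shape}")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and nonnegative")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not all be zero")
    return w / s


def gamma_rule(c: float, p: int) -> float:
    """Dimension-scaled robustness parameter gamma = c / p."""
    if p < 1:
        raise ValueError("p must be positive")
    return float(c) / p


# --------------------------------------------------------------------------
# gamma-mean family
# --------------------------------------------------------------------------

@dataclass
class GammaConfig:
    """Controls for the gamma-mean fixed-point iterations.

    Parameters
    ----------
    gamma
        Robustness hyper-parameter, >= 0.  Larger values down-weight outliers
        more aggressively; gamma -> 0 recovers the sample mean.
    working_model
        ``full_gaussian`` fits both location and scatter (Algorithm with a
        general N(mu, Sigma) working model); ``standard_gaussian`` keeps the
        scatter fixed at the identity (the *simple* gamma-mean, suitable for
        very high dimension, where any sigma^2 scale merges into gamma).
    max_iters
        Cap on fixed-point sweeps.
    tol
        Convergence threshold: sup-norm change of successive mu iterates, and
        the plug-back stationarity residual at exit.
    init_policy
        ``marginal_median`` (default), ``mean`` or ``user_supplied`` (then set
        ``mu0``).
    scatter_policy
        ``full`` inverts the full scatter whenever the batch is large enough;
        ``diagonal_fallback`` always uses {diag(Sigma)}^{-1}.
    diagonal_fallback_threshold
        Minimum m required before the full scatter is inverted; below it the
        diagonal inverse is used regardless of ``scatter_policy='full'``.
        ``None`` means the default 5*p.
    """

    gamma: float = 0.5
    working_model: Literal["full_gaussian", "standard_gaussian"] = "full_gaussian"
    max_iters: int = 100
    tol: float = 1e-8
    init_policy: Literal["marginal_median", "mean", "user_supplied"] = "marginal_median"
    mu0: Optional[Sequence[float]] = None
    scatter_policy: Literal["full", "diagonal_fallback"] = "full"
    diagonal_fallback_threshold: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.init_policy == "user_supplied" and self.mu0 is None:
            raise ValueError("init_policy='user_supplied' requires mu0")


@dataclass
class LocationScatterEstimate:
    """Result of a gamma-mean fit.

    ``sigma`` is the (p, p) scatter for the full working model, or a length-p
    diagonal (ones for the standard-Gaussian model).  ``weights`` are the
    final normalized per-row weights w_i.  ``stationarity_residual`` is the
    sup-norm defect of the stationary equations evaluated at (mu, sigma).
    """

    mu: np.ndarray
    sigma: np.ndarray
    weights: np.ndarray
    n_iters: int
    converged: bool
    stationarity_residual: float


def _mahalanobis_sq(x: np.ndarray, mu: np.ndarray, sigma_inv) -> np.ndarray:
    """Row-wise squared Mahalanobis distances; sigma_inv is (p,p), (p,) or scalar."""
    diff = x - mu
    si = np.asarray(sigma_inv, dtype=float)
    if si.ndim == 2:
        return np.einsum("ij,jk,ik->i", diff, si, diff)
    return (diff * diff * si).sum(axis=1)


def gamma_weights(batch, mu, sigma_inv, gamma: float, row_weights=None) -> np.ndarray:
    """Normalized exponential down-weights w_i for one gamma-mean sweep.

    w_i is proportional to exp(-gamma/2 * Mahalanobis^2(x_i; mu, sigma_inv))
    (times any prior row weight), normalized to the simplex.  gamma = 0 gives
    the uniform (or prior) weights.

    Raises
    ------
    DegenerateWeightsError
        If every factor underflows to zero, i.e. all points are extremely far
        from ``mu``; the message names the smallest squared distance.
    """
    x = _as_batch(batch)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if not np.all(np.isfinite(mu)):
        raise ValueError("mu contains non-finite entries")
    si = np.asarray(sigma_inv, dtype=float)
    if not np.all(np.isfinite(si)):
        raise ValueError("sigma_inv contains non-finite entries")
    if si.ndim == 1 and np.any(si <= 0):
        raise ValueError("diagonal sigma_inv must be strictly positive")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    base = _row_weights(row_weights, x.shape[0])
    maha = _mahalanobis_sq(x, mu, si)
    d = base * np.exp(-0.5 * gamma * maha)
    s = d.sum()
    if s <= 0.0:
        raise DegenerateWeightsError(
            "all gamma-weights underflowed to zero; smallest squared "
            f"Mahalanobis distance is {maha.min():.6g}"
        )
    return d / s


def _init_mu(x: np.ndarray, config: GammaConfig, row_weights) -> np.ndarray:
    if config.init_policy == "user_supplied":
        mu0 = np.asarray(config.mu0, dtype=float)
        if mu0.shape != (x.shape[1],):
            raise ValueError(f"mu0 must have shape ({x.shape[1]},)")
        return mu0
    if config.init_policy == "mean":
        return mean_aggregate(x, weights=row_weights)
    return marginal_median(x, weights=row_weights)


def gamma_mean(batch, config: GammaConfig, row_weights=None) -> LocationScatterEstimate:
    """Minimum gamma-divergence location/scatter fit (full Gaussian working model).

    Alternates the stationary-equation updates

        mu    <- sum_i w_i x_i
        Sigma <- (1 + gamma) * sum_i w_i (x_i - mu)(x_i - mu)'

    with weights recomputed from the current (mu, Sigma) each sweep, starting
    from the configured initial location and a scatter initialized to the
    identity scaled by the median squared distance to the initial mu.  When
    the batch is too small to invert the full scatter stably (m below
    ``diagonal_fallback_threshold``, default 5*p) — or always, under
    ``scatter_policy='diagonal_fallback'`` — the inverse of diag(Sigma) is
    used in the weight computation instead.

    Convergence requires both the sup-norm change of mu below ``tol`` and the
    plug-back stationarity residual at the final iterate below ``tol``;
    non-convergence within ``max_iters`` returns ``converged=False`` rather
    than raising.
    """
    if config.working_model != "full_gaussian":
        raise ValueError("gamma_mean requires working_model='full_gaussian'")
    x = _as_batch(batch, min_rows=2)
    m, p = x.shape
    base_w = _row_weights(row_weights, m)
    gamma = config.gamma

    threshold = config.diagonal_fallback_threshold
    if threshold is None:
        threshold = 5 * p
    use_diag = config.scatter_policy == "diagonal_fallback" or m < max(threshold, p + 1)

    mu = _init_mu(x, config, row_weights)
    scale = float(np.median(((x - mu) ** 2).sum(axis=1)))
    if scale <= 0:
        scale = 1.0
    sigma = np.full(p, scale) if use_diag else np.eye(p) * scale

    def invert(sig):
        if use_diag:
            d = sig if sig.ndim == 1 else np.diag(sig)
            ridge = 1e-10 * d.sum() / p
            return 1.0 / (d + ridge)
        ridge = 1e-10 * np.trace(sig) / p
        sig_r = sig + ridge * np.eye(p)
        try:
            cho = np.linalg.cholesky(sig_r)
        except np.linalg.LinAlgError as exc:
            raise SingularScatterError(
                "full scatter matrix is singular; use scatter_policy="
                "'diagonal_fallback' or supply more clients"
            ) from exc
        d = np.diag(cho)
        # rank deficiency survives the tiny ridge as extreme conditioning
        if (d.max() / d.min()) ** 2 > 1e8:
            raise SingularScatterError(
                "full scatter matrix is numerically singular (condition "
                f"number ~{(d.max() / d.min()) ** 2:.2g}); use scatter_policy="
                "'diagonal_fallback' or supply more clients"
            )
        inv = np.linalg.inv(cho)
        return inv.T @ inv

    def sweep(mu_c, sigma_c):
        w = gamma_weights(x, mu_c, invert(sigma_c), gamma, row_weights=base_w)
        mu_n = w @ x
        diff = x - mu_n
        if use_diag:
            sigma_n = (1.0 + gamma) * (w @ (diff * diff))
        else:
            sigma_n = (1.0 + gamma) * ((w[:, None] * diff).T @ diff)
        return w, mu_n, sigma_n

    w = base_w
    converged = False
    residual = np.inf
    n_iters = 0
    for n_iters in range(1, config.max_iters + 1):
        w, mu_new, sigma_new = sweep(mu, sigma)
        delta = np.max(np.abs(mu_new - mu))
        mu, sigma = mu_new, sigma_new
        if delta < config.tol:
            # plug-back check of the stationary equations at the new iterate
            w_chk, mu_chk, sigma_chk = sweep(mu, sigma)
            residual = max(
                float(np.max(np.abs(mu - mu_chk))),
                float(np.max(np.abs(sigma - sigma_chk))),
            )
            if residual <= config.tol:
                w = w_chk
                converged = True
                break
    if not converged and np.isinf(residual):
        _, mu_chk, sigma_chk = sweep(mu, sigma)
        residual = max(
            float(np.max(np.abs(mu - mu_chk))),
            float(np.max(np.abs(sigma - sigma_chk))),
        )
    return LocationScatterEstimate(
        mu=mu, sigma=sigma, weights=w, n_iters=n_iters,
        converged=converged, stationarity_residual=float(residual),
    )


def simple_gamma_mean(batch, config: GammaConfig, row_weights=None) -> LocationScatterEstimate:
    """Simple gamma-mean: standard-Gaussian working model, identity scatter.

    Iterates mu <- sum_i w_i x_i with w_i proportional to
    exp(-gamma/2 ||x_i - mu||^2).  Any data scale sigma^2 is absorbed into
    gamma, so no scatter is estimated; the ``sigma`` field reports the
    identity (as a length-p vector of ones).
    """
    x = _as_batch(batch, min_rows=1)
    m, p = x.shape
    base_w = _row_weights(row_weights, m)
    gamma = config.gamma
    ones = np.ones(p)

    mu = _init_mu(x, config, row_weights)
    converged = False
    residual = np.inf
    w = base_w
    n_iters = 0
    for n_iters in range(1, config.max_iters + 1):
        w = gamma_weights(x, mu, ones, gamma, row_weights=base_w)
        mu_new = w @ x
        delta = np.max(np.abs(mu_new - mu))
        mu = mu_new
        if delta < config.tol:
            w_chk = gamma_weights(x, mu, ones, gamma, row_weights=base_w)
            residual = float(np.max(np.abs(mu - w_chk @ x)))
            if residual <= config.tol:
                w = w_chk
                converged = True
                break
    if not converged and np.isinf(residual):
        w_chk = gamma_weights(x, mu, ones, gamma, row_weights=base_w)
        residual = float(np.max(np.abs(mu - w_chk @ x)))
    return LocationScatterEstimate(
        mu=mu, sigma=ones.copy(), weights=w, n_iters=n_iters,
        converged=converged, stationarity_residual=float(residual),
    )


# --------------------------------------------------------------------------
# classical aggregators
# --------------------------------------------------------------------------

def mean_aggregate(batch, weights=None) -> np.ndarray:
    """Coordinate-wise (weighted) arithmetic mean."""
    x = _as_batch(batch)
    w = _row_weights(weights, x.shape[0])
    return w @ x


def weighted_quantile(values, q: float, weights=None) -> float:
    """Interpolated weighted quantile of a 1-D sample.

    Uses midpoint plotting positions: after sorting, the k-th value sits at
    cumulative position (sum of weights before it) + w_k/2, and the quantile
    function interpolates linearly between these knots (flat beyond the
    extremes).  At uniform weights this reproduces the numpy sample median
    (midpoint of the two central order statistics at even m).
    """
    v = np.asarray(values, dtype=float).ravel()
    w = _row_weights(weights, v.size)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    pos = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, pos, v))


def weighted_band_mean(values, a: float, b: float, weights=None) -> float:
    """Mean of the interpolated weighted quantile function over [a, b].

    Integrates the piecewise-linear quantile function exactly; this is the
    L-statistic form of the trimmed mean, T = (b-a)^{-1} \\int_a^b Q(u) du.
    """
    if not 0.0 <= a < b <= 1.0:
        raise ValueError("need 0 <= a < b <= 1")
    v = np.asarray(values, dtype=float).ravel()
    w = _row_weights(weights, v.size)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    pos = np.cumsum(w) - 0.5 * w
    # knots of Q: flat extensions to u=0 and u=1
    u = np.concatenate(([0.0], pos, [1.0]))
    q = np.concatenate(([v[0]], v, [v[-1]]))
    total = 0.0
    for k in range(len(u) - 1):
        lo, hi = u[k], u[k + 1]
        seg_lo, seg_hi = max(lo, a), min(hi, b)
        if seg_hi <= seg_lo:
            continue
        if hi > lo:
            q_lo = q[k] + (q[k + 1] - q[k]) * (seg_lo - lo) / (hi - lo)
            q_hi = q[k] + (q[k + 1] - q[k]) * (seg_hi - lo) / (hi - lo)
        else:
            q_lo = q_hi = q[k]
        total += 0.5 * (q_lo + q_hi) * (seg_hi - seg_lo)
    return total / (b - a)


def marginal_median(batch, weights=None) -> np.ndarray:
    """Coordinate-wise sample median (midpoint convention at even m)."""
    x = _as_batch(batch)
    if weights is None:
        return np.median(x, axis=0)
    return np.array([weighted_quantile(x[:, j], 0.5, weights) for j in range(x.shape[1])])


def trimmed_mean(batch, beta: float, weights=None) -> np.ndarray:
    """Coordinate-wise beta-trimmed mean.

    Removes floor(beta*m) values from each tail of every coordinate and
    averages the rest.  With per-row weights the L-statistic form is used
    instead: the mean of the interpolated weighted quantile function over
    [beta, 1-beta].
    """
    x = _as_batch(batch)
    if not 0.0 <= beta < 0.5:
        raise ValueError("beta must lie in [0, 0.5)")
    m = x.shape[0]
    if weights is None:
        if 2 * int(beta * m) >= m:
            raise ValueError(f"trimming fraction beta={beta} removes all {m} rows")
        return _stats.trim_mean(x, beta, axis=0)
    if beta == 0.0:
        return mean_aggregate(x, weights=weights)
    return np.array(
        [weighted_band_mean(x[:, j], beta, 1.0 - beta, weights) for j in range(x.shape[1])]
    )


# --------------------------------------------------------------------------
# geometric median (Weiszfeld iteration)
# --------------------------------------------------------------------------

@dataclass
class WeiszfeldInfo:
    """Diagnostics of a Weiszfeld run: convergence flag, iterations,
    per-iteration objective values, and whether the minimizer is non-unique
    (two-point batches with equal weights)."""

    converged: bool
    n_iters: int
    objective: list = field(default_factory=list)
    nonunique: bool = False


def weiszfeld(batch, weights=None, max_iters: int = 1000, tol: float = 1e-10):
    """Geometric median argmin_y sum_i w_i ||y - x_i||_2 by Weiszfeld iteration.

    Returns ``(point, WeiszfeldInfo)``.  The objective is non-increasing
    across iterations; the run stops when the (sub)gradient norm drops below
    ``tol``.  If an iterate lands on a data point, the optimality certificate
    ||sum_{i != k} w_i (x_i - x_k)/||x_i - x_k|| || <= w_k is tested there: it
    either certifies the data point as the minimizer or the iterate is
    restarted with a small jitter away from it.
    """
    x = _as_batch(batch)
    m, p = x.shape
    w = _row_weights(weights, m)
    info = WeiszfeldInfo(converged=True, n_iters=0)

    if m == 1:
        return x[0].copy(), info
    if m == 2:
        if abs(w[0] - w[1]) <= 1e-15:
            info.nonunique = True
            return 0.5 * (x[0] + x[1]), info
        return x[int(np.argmax(w))].copy(), info

    def objective(y):
        return float(w @ np.linalg.norm(x - y, axis=1))

    y = mean_aggregate(x, weights=w)
    info.objective.append(objective(y))
    anchor_eps = 1e-12
    for it in range(1, max_iters + 1):
        info.n_iters = it
        d = np.linalg.norm(x - y, axis=1)
        near = d < anchor_eps
        if np.any(near):
            k = int(np.argmax(near))
            # duplicate rows at the anchor pool their weight
            coincident = np.linalg.norm(x - x[k], axis=1) < anchor_eps
            w_k = w[coincident].sum()
            others = ~coincident
            if not np.any(others):
                info.objective.append(objective(x[k]))
                return x[k].copy(), info
            dk = np.linalg.norm(x[others] - x[k], axis=1)
            r_vec = ((w[others] / dk)[:, None] * (x[others] - x[k])).sum(axis=0)
            r = np.linalg.norm(r_vec)
            if r <= w_k + 1e-15:
                # the data point itself is optimal
                y = x[k].copy()
                info.objective.append(objective(y))
                return y, info
            y = y + 1e-8 * r_vec / r
            d = np.linalg.norm(x - y, axis=1)
        inv = w / d
        grad = ((y - x) * inv[:, None]).sum(axis=0)
        if np.linalg.norm(grad) <= tol:
            info.objective.append(objective(y))
            return y, info
        y = (inv @ x) / inv.sum()
        info.objective.append(objective(y))
    info.converged = False
    return y, info


def geometric_median(batch, max_iters: int = 1000, tol: float = 1e-10, weights=None) -> np.ndarray:
    """Geometric median point (see :func:`weiszfeld` for diagnostics)."""
    point, _ = weiszfeld(batch, weights=weights, max_iters=max_iters, tol=tol)
    return point
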