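"""A minimal federated-learning loop on synthetic convex tasks.

The loop exercises any aggregator end-to-end under the Byzantine attack used
throughout this package: each round the server broadcasts the current
parameter, honest clients run ``local_epochs`` full-batch gradient-descent
epochs on their own data at the cosine-decayed round learning rate and
return the resulting *parameter change*; Byzantine clients instead return
vectors with i.i.d. N(5, 1) coordinates.  The server aggregates the deltas,
optionally clips the aggregated vector to a maximum 2-norm, and adds it to
the parameter.

Client sample sizes are imbalanced: a Lognormal(1.5, 3.45^2) draw feeds a
Dirichlet, whose probabilities allocate the samples beyond a guaranteed
per-client floor ``min_client_size`` (default 512) by a multinomial draw.

Two tasks are provided: a quadratic (each client holds Gaussian draws around
the optimum, so the local gradient is theta minus the local sample mean) and
logistic regression on Gaussian class-conditional data with class means
+/- delta * e_1.  The class-mean direction is deliberately a single
coordinate axis, far from the all-ones direction an N(5, 1) attack pushes
toward, so a corrupted model cannot classify well by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import special

from .aggregators import (
    GammaConfig,
    gamma_mean,
    geometric_median,
    marginal_median,
    mean_aggregate,
    simple_gamma_mean,
    trimmed_mean,
)

__all__ = [
    "FLConfig",
    "FLTask",
    "FLDivergenceError",
    "sample_client_sizes",
    "clip_gradient",
    "cosine_lr",
    "run_federated",
    "make_quadratic_task",
    "make_logistic_task",
]


class FLDivergenceError(RuntimeError):
    """Training produced a non-finite iterate; carries the failing round index."""

    def __init__(self, round_index: int):
        self.round_index = round_index
        super().__init__(f"non-finite parameter iterate at round {round_index}")


@dataclass
class FLConfig:
    """Server/client configuration for :func:`run_federated`."""

    n_clients: int = 20
    n_byzantine: int = 2
    rounds: int = 200
    local_epochs: int = 1
    init_lr: float = 0.5
    decay_steps: Optional[int] = None  # defaults to `rounds`
    clip_norm: Optional[float] = None
    aggregator: str = "simple_gamma_mean"
    gamma: float = 0.5
    trim_beta: float = 0.1
    seed: int = 0
    min_client_size: int = 512
    total_n: int = 12288
    lognormal_params: tuple = (1.5, 3.45)
    subsample_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_byzantine < self.n_clients / 2:
            raise ValueError("need n_byzantine < n_clients / 2")
        if self.total_n < self.n_clients * self.min_client_size:
            raise ValueError("total_n must cover n_clients * min_client_size")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.decay_steps is None:
            self.decay_steps = self.rounds


@dataclass
class FLTask:
    """A differentiable training task with per-client synthetic datasets.

    ``grad(theta, data)`` returns the mean gradient of the client loss;
    ``loss(theta, data)`` its value; ``accuracy`` is optional (classification
    tasks only).  ``truth`` is the target parameter used for the
    distance-to-truth diagnostic.
    """

    theta_dim: int
    client_data: list
    grad: Callable
    loss: Callable
    truth: np.ndarray
    eval_data: object = None
    accuracy: Optional[Callable] = None


def sample_client_sizes(config: FLConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Imbalanced client sample sizes: lognormal -> Dirichlet -> multinomial.

    Every client receives at least ``min_client_size`` samples; the remaining
    ``total_n - m * min_client_size`` samples are split by a multinomial with
    Dirichlet probabilities whose concentration vector is Lognormal(1.5,
    3.45^2).  Sizes always sum exactly to ``total_n``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_clients
    mu_log, sigma_log = config.lognormal_params
    a = rng.lognormal(mean=mu_log, sigma=sigma_log, size=m)
    eta = rng.dirichlet(a)
    if not np.all(np.isfinite(eta)) or eta.sum() <= 0:
        # extreme lognormal draws can underflow the Dirichlet; fall back to
        # all mass on the largest concentration
        eta = np.zeros(m)
        eta[int(np.argmax(a))] = 1.0
    extra = rng.multinomial(config.total_n - m * config.min_client_size, eta)
    return config.min_client_size + extra


def clip_gradient(g, clip_norm: float) -> np.ndarray:
    """Scale g to 2-norm ``clip_norm`` if it is longer; direction preserved."""
    if clip_norm <= 0:
        raise ValueError("clip_norm must be positive")
    g = np.asarray(g, dtype=float)
    nrm = float(np.linalg.norm(g))
    if nrm <= clip_norm or nrm == 0.0:
        return g.copy()
    return g * (clip_norm / nrm)


def cosine_lr(round_t: int, init_lr: float, decay_steps: int) -> float:
    """Half-cosine decay: init_lr * (1 + cos(pi * t / T)) / 2, floored at 0 for t >= T."""
    if round_t < 0:
        raise ValueError("round_t must be nonnegative")
    t = min(round_t, decay_steps)
    return init_lr * (1.0 + np.cos(np.pi * t / decay_steps)) / 2.0


# --------------------------------------------------------------------------
# synthetic tasks
# --------------------------------------------------------------------------

def make_quadratic_task(config: FLConfig, dim: int = 10, theta_star: Optional[np.ndarray] = None,
                        rng: Optional[np.random.Generator] = None) -> FLTask:
    """Strongly convex task: l(theta; z) = 0.5 ||theta - z||^2, z ~ N(theta*, I)."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    if theta_star is None:
        theta_star = np.zeros(dim)
    sizes = sample_client_sizes(config, rng)
    data = [theta_star + rng.standard_normal((n, dim)) for n in sizes]

    def grad(theta, z):
        return theta - z.mean(axis=0)

    def loss(theta, z):
        return 0.5 * float(np.mean(np.sum((theta - z) ** 2, axis=1)))

    pooled = np.vstack(data)
    # fixed point of attack-free mean aggregation: the average of client means
    truth = np.mean([z.mean(axis=0) for z in data], axis=0)
    return FLTask(theta_dim=dim, client_data=data, grad=grad, loss=loss,
                  truth=truth, eval_data=pooled)


def make_logistic_task(config: FLConfig, dim: int = 10, separation: float = 2.0,
                       n_test: int = 4000, rng: Optional[np.random.Generator] = None) -> FLTask:
    """Binary logistic regression, x | y ~ N(y * separation * e_1, I), y = +/-1."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    mean_vec = np.zeros(dim)
    mean_vec[0] = separation

    def draw(n, gen):
        y = gen.choice([-1.0, 1.0], size=n)
        x = gen.standard_normal((n, dim)) + y[:, None] * mean_vec
        return x, y

    sizes = sample_client_sizes(config, rng)
    data = [draw(n, rng) for n in sizes]
    x_test, y_test = draw(n_test, rng)

    def grad(theta, d):
        x, y = d
        z = y * (x @ theta)
        s = special.expit(-z)
        return -np.mean((y * s)[:, None] * x, axis=0)

    def loss(theta, d):
        x, y = d
        return float(np.mean(np.logaddexp(0.0, -y * (x @ theta))))

    def accuracy(theta, d):
        x, y = d
        return float(np.mean(np.sign(x @ theta) == y))

    # population-optimal direction for diagnostics: minimize risk on a large
    # held-out sample along the closed Bayes direction family
    from scipy.optimize import minimize

    ref = draw(20000, np.random.default_rng([config.seed, 3]))
    res = minimize(lambda th: loss(th, ref), np.zeros(dim), jac=lambda th: grad(th, ref),
                   method="L-BFGS-B")
    return FLTask(theta_dim=dim, client_data=data, grad=grad, loss=loss,
                  truth=res.x, eval_data=(x_test, y_test), accuracy=accuracy)


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _resolve_aggregator(config: FLConfig):
    name = config.aggregator
    if name == "mean":
        return mean_aggregate
    if name == "marginal_median":
        return lambda x: marginal_median(x)
    if name == "geometric_median":
        return lambda x: geometric_median(x, max_iters=2000, tol=1e-10)
    if name == "trimmed_mean":
        return lambda x: trimmed_mean(x, config.trim_beta)
    if name in ("gamma_mean", "simple_gamma_mean"):
        cfg = GammaConfig(
            gamma=config.gamma,
            working_model="full_gaussian" if name == "gamma_mean" else "standard_gaussian",
            max_iters=200,
            tol=1e-12,
        )
        fit = gamma_mean if name == "gamma_mean" else simple_gamma_mean
        return lambda x: fit(x, cfg).mu
    raise ValueError(f"unknown aggregator {name!r}")


def run_federated(task: FLTask, config: FLConfig) -> pd.DataFrame:
    """Run the federated loop; returns the per-round history.

    Columns: round, lr, loss, dist_to_truth and (for classification tasks)
    accuracy.  Clients ``0 .. n_byzantine-1`` are Byzantine and return
    N(5, 1) vectors each round.  Raises :class:`FLDivergenceError` if the
    parameter iterate becomes non-finite (the expected failure mode of the
    mean aggregator under attack without clipping).
    """
    rng = np.random.default_rng([config.seed, 4])
    aggregate = _resolve_aggregator(config)
    theta = np.zeros(task.theta_dim)
    history = []
    for t in range(config.rounds):
        lr = cosine_lr(t, config.init_lr, config.decay_steps)
        deltas = np.empty((config.n_clients, task.theta_dim))
        for i in range(config.n_clients):
            if i < config.n_byzantine:
                deltas[i] = rng.normal(5.0, 1.0, size=task.theta_dim)
                continue
            d = task.client_data[i]
            theta_local = theta.copy()
            for _ in range(config.local_epochs):
                if config.subsample_fraction < 1.0:
                    d_use = _subsample(d, config.subsample_fraction, rng)
                else:
                    d_use = d
                theta_local -= lr * task.grad(theta_local, d_use)
            deltas[i] = theta_local - theta
        update = np.asarray(aggregate(deltas), dtype=float)
        if config.clip_norm is not None:
            update = clip_gradient(update, config.clip_norm)
        theta = theta + update
        if not np.all(np.isfinite(theta)):
            raise FLDivergenceError(t)
        row = dict(
            round=t,
            lr=lr,
            loss=task.loss(theta, task.eval_data),
            dist_to_truth=float(np.linalg.norm(theta - task.truth)),
        )
        if task.accuracy is not None:
            row["accuracy"] = task.accuracy(theta, task.eval_data)
        history.append(row)
    return pd.DataFrame(history)


def _subsample(d, fraction: float, rng: np.random.Generator):
    if isinstance(d, tuple):
        x, y = d
        n = max(1, int(fraction * x.shape[0]))
        idx = rng.choice(x.shape[0], size=n, replace=False)
        return x[idx], y[idx]
    n = max(1, int(fraction * d.shape[0]))
    idx = rng.choice(d.shape[0], size=n, replace=False)
    return d[idx]
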