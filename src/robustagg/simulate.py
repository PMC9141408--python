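"""Monte-Carlo study of aggregators under Byzantine contamination.

Each replicate draws an (m, p) batch of client gradient vectors: honest rows
from a centred standard Gaussian or Student-t (5 df) distribution, and a
fixed fraction ``alpha`` of Byzantine rows from the same family shifted by
``shift`` in every coordinate (default 100).  Every requested aggregator is
applied to the same batch, and across replicates the mean squared error to
the true centre (zero) is decomposed as

    mse = ||mean_r(est_r) - truth||^2 + (1/R) sum_r ||est_r - mean_r(est_r)||^2
        = bias^2 + variance,

an exact algebraic identity.  Norms are summed over coordinates, so reported
values scale with p; comparisons across aggregators at fixed (m, p, alpha)
are the meaningful output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .aggregators import (
    GammaConfig,
    gamma_mean,
    gamma_rule,
    geometric_median,
    marginal_median,
    mean_aggregate,
    simple_gamma_mean,
    trimmed_mean,
)

__all__ = [
    "ScenarioSpec",
    "generate_gradients",
    "mse_decomposition",
    "run_scenario",
    "scenario_from_yaml",
    "plot_scenario",
    "AGGREGATOR_NAMES",
]

AGGREGATOR_NAMES = (
    "mean",
    "marginal_median",
    "geometric_median",
    "trimmed_mean",
    "gamma_mean",
    "simple_gamma_mean",
)

#: aggregators whose gamma is set by the c/p rule and that occupy a `c` grid cell
_GAMMA_AGGS = ("gamma_mean", "simple_gamma_mean")


@dataclass
class ScenarioSpec:
    """One contamination experiment (possibly over grids of p, alpha, c).

    ``gamma_c`` sets gamma = c/p for the gamma-mean aggregators (a scalar or a
    grid of constants); ``gamma`` instead fixes gamma directly and overrides
    the rule.  ``shift`` is the per-coordinate location shift of Byzantine
    rows.  The number of Byzantine rows is round(alpha * m).
    """

    family: str = "gaussian"  # or "student_t5"
    m: int = 200
    p: Union[int, Sequence[int]] = 100
    alpha: Union[float, Sequence[float]] = 0.1
    shift: float = 100.0
    gamma_c: Union[float, Sequence[float]] = 2.0
    gamma: Optional[float] = None
    replicates: int = 100
    seed: int = 0
    aggregators: Sequence = field(default_factory=lambda: list(AGGREGATOR_NAMES[:5]))
    trim_beta: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "student_t5"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.m < 1 or self.replicates < 1:
            raise ValueError("m and replicates must be positive")
        for a in np.atleast_1d(np.asarray(self.alpha, dtype=float)):
            if not 0.0 <= a <= 0.5:
                raise ValueError("alpha must lie in [0, 0.5]")
        if not 0.0 <= self.trim_beta < 0.5:
            raise ValueError("trim_beta must lie in [0, 0.5)")


def _replicate_rng(spec: ScenarioSpec, p: int, alpha: float, replicate_index: int):
    # deterministic per-cell stream: master seed plus integer-encoded cell key
    return np.random.default_rng(
        [spec.seed, int(p), int(round(alpha * 10**6)), int(replicate_index)]
    )


def generate_gradients(spec: ScenarioSpec, replicate_index: int, p: Optional[int] = None,
                       alpha: Optional[float] = None):
    """One contaminated batch and its Byzantine-row mask.

    Returns ``(batch, mask)`` with exactly round(alpha*m) Byzantine rows
    (placed first; all aggregators here are permutation-invariant), shifted
    by ``spec.shift`` in every coordinate.  Reproducible from
    (seed, p, alpha, replicate_index).
    """
    p = int(np.atleast_1d(spec.p)[0]) if p is None else int(p)
    alpha = float(np.atleast_1d(spec.alpha)[0]) if alpha is None else float(alpha)
    rng = _replicate_rng(spec, p, alpha, replicate_index)
    m = spec.m
    if spec.family == "gaussian":
        x = rng.standard_normal((m, p))
    else:
        x = rng.standard_t(5, size=(m, p))
    n_byz = int(round(alpha * m))
    mask = np.zeros(m, dtype=bool)
    mask[:n_byz] = True
    x[mask] += spec.shift
    return x, mask


def mse_decomposition(estimates, truth):
    """(mse, bias_sq, variance) of replicate estimates against the truth.

    bias_sq = ||mean_r est_r - truth||^2, variance = mean_r ||est_r - mean_r est_r||^2,
    mse = mean_r ||est_r - truth||^2 = bias_sq + variance exactly.
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim == 1:
        est = est[:, None]
    if est.shape[0] < 2:
        raise ValueError("variance undefined: need at least 2 replicate estimates")
    truth = np.atleast_1d(np.asarray(truth, dtype=float))
    center = est.mean(axis=0)
    bias_sq = float(np.sum((center - truth) ** 2))
    variance = float(np.mean(np.sum((est - center) ** 2, axis=1)))
    mse = float(np.mean(np.sum((est - truth) ** 2, axis=1)))
    return mse, bias_sq, variance


def _make_aggregator(entry, spec: ScenarioSpec, p: int, c: Optional[float]):
    """Resolve an aggregator entry (name or (label, callable)) to (label, fn)."""
    if isinstance(entry, tuple):
        return entry[0], entry[1]
    name = entry
    if name == "mean":
        return name, mean_aggregate
    if name == "marginal_median":
        return name, lambda x: marginal_median(x)
    if name == "geometric_median":
        return name, lambda x: geometric_median(x, max_iters=2000, tol=1e-8)
    if name == "trimmed_mean":
        return name, lambda x: trimmed_mean(x, spec.trim_beta)
    if name in _GAMMA_AGGS:
        gamma = spec.gamma if spec.gamma is not None else gamma_rule(c, p)
        cfg = GammaConfig(
            gamma=gamma,
            working_model="full_gaussian" if name == "gamma_mean" else "standard_gaussian",
            max_iters=200,
            tol=1e-10,
        )
        fit = gamma_mean if name == "gamma_mean" else simple_gamma_mean
        return name, lambda x: fit(x, cfg).mu
    raise ValueError(f"unknown aggregator {name!r}")


def run_scenario(spec: ScenarioSpec) -> pd.DataFrame:
    """Run the full replicate grid and return a tidy results table.

    One row per (family, aggregator, m, p, alpha, c) cell with columns mse,
    bias_sq, variance, replicates, n_failures, seed.  All aggregators see the
    same batches within a cell (common random numbers), and gamma-mean cells
    are repeated for every constant in ``gamma_c``.  Truth is the zero
    vector (honest gradients are centred).  An aggregator raising on a
    replicate is recorded as a failure for that cell and the run continues.
    """
    p_grid = [int(v) for v in np.atleast_1d(spec.p)]
    alpha_grid = [float(v) for v in np.atleast_1d(np.asarray(spec.alpha, dtype=float))]
    c_grid = [float(v) for v in np.atleast_1d(np.asarray(spec.gamma_c, dtype=float))]
    rows = []
    for p in p_grid:
        truth = np.zeros(p)
        for alpha in alpha_grid:
            batches = [
                generate_gradients(spec, r, p=p, alpha=alpha)[0]
                for r in range(spec.replicates)
            ]
            cells = []
            for entry in spec.aggregators:
                label = entry[0] if isinstance(entry, tuple) else entry
                if label in _GAMMA_AGGS and spec.gamma is None:
                    cells.extend((entry, c) for c in c_grid)
                else:
                    cells.append((entry, np.nan))
            for entry, c in cells:
                label, fn = _make_aggregator(entry, spec, p, None if np.isnan(c) else c)
                estimates, failures = [], 0
                for batch in batches:
                    try:
                        est = np.asarray(fn(batch), dtype=float)
                        if not np.all(np.isfinite(est)):
                            raise FloatingPointError("non-finite aggregate")
                        estimates.append(est)
                    except Exception:
                        failures += 1
                if len(estimates) >= 2:
                    mse, bias_sq, variance = mse_decomposition(np.array(estimates), truth)
                else:
                    mse = bias_sq = variance = np.nan
                rows.append(
                    dict(
                        family=spec.family, aggregator=label, m=spec.m, p=p,
                        alpha=alpha, c=c, mse=mse, bias_sq=bias_sq,
                        variance=variance, replicates=len(estimates),
                        n_failures=failures, seed=spec.seed,
                    )
                )
    return pd.DataFrame(rows)


def scenario_from_yaml(path) -> ScenarioSpec:
    """Load a ScenarioSpec from a structured key-value (YAML) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in ScenarioSpec.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
    return ScenarioSpec(**data)


def plot_scenario(results: pd.DataFrame, x: str = "p", out=None):
    """MSE / squared-bias / variance panels against ``x``, one line per aggregator.

    Returns the matplotlib figure; saves to ``out`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["mse", "bias_sq", "variance"]
    fig, axes = plt.subplots(1, 3, figsize=(14, 4), sharex=True)
    for ax, metric in zip(axes, metrics):
        for (label, c), sub in results.groupby(["aggregator", "c"], dropna=False):
            sub = sub.sort_values(x)
            name = label if np.isnan(c) else f"{label} (c={c:g})"
            ax.plot(sub[x], sub[metric], marker="o", label=name)
        ax.set_xlabel(x)
        ax.set_ylabel(metric)
        ax.set_yscale("log")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
    return fig
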