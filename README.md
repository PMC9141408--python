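# robustagg

Byzantine-robust aggregation for federated learning by minimum
gamma-divergence estimation.

In federated learning a central server repeatedly aggregates model updates
from `m` clients. The plain average is fragile: a single *Byzantine* client
sending arbitrary values can bias or destroy training. `robustagg`
implements the **gamma-mean**, a robust aggregator obtained by fitting a
Gaussian working model `N(mu, Sigma)` by minimum gamma-divergence. The fit
solves the fixed-point system

    d_i = exp(-γ/2 (x_i - μ̂)ᵀ Σ̂⁻¹ (x_i - μ̂)),    w_i = d_i / Σ_j d_j,
    μ̂ = Σ_i w_i x_i,
    Σ̂ = (1 + γ) Σ_i w_i (x_i - μ̂)(x_i - μ̂)ᵀ,

a weighted average whose weights decay exponentially in Mahalanobis
distance, so outlying rows are smoothly ignored. The tuning parameter
`γ ≥ 0` trades robustness against efficiency (`γ → 0` recovers the sample
mean). A *simple* variant fixes `Σ = I` and scales to very high dimension.

The package also provides:

* the standard competing aggregators — coordinate-wise mean/median,
  geometric median (Weiszfeld), trimmed mean — all accepting per-row
  weights;
* closed-form influence functions for all five estimators plus a numerical
  Gateaux-derivative oracle (the gamma-mean's influence *redescends*:
  extreme points have vanishing effect, unlike the clipped trimmed mean or
  the bounded-but-flat medians);
* a Monte-Carlo contamination suite (location-shifted Byzantine rows in
  Gaussian or t₅ gradient batches, MSE = bias² + variance decomposition);
* a minimal federated loop on synthetic convex tasks with imbalanced
  lognormal–Dirichlet client sizes, `N(5, 1)` Byzantine clients, gradient
  clipping and a cosine learning-rate schedule.

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

Aggregate a 20×5 gradient batch in which two clients were replaced by an
`N(5, 1)` attack:

```sh
robustagg fixtures --out fx --seed 1
robustagg aggregate --method mean --input fx/attack_n51.csv
# 0.73733712275224195,0.21709850259370939,0.64789483360230793,0.69613564578530196,0.43271187019003193
robustagg aggregate --method simple-gamma-mean --gamma 0.5 --input fx/attack_n51.csv
# 0.18950406302534373,-0.40570064335245143,0.17013148281822305,0.033669844541243069,0.168585063615208
```

The honest rows are standard normal, so the true centre is 0. The two
attacked rows (10% of clients at distance ≈ 11 from the centre) drag every
coordinate of the mean upward by ≈ 0.5, while the gamma-mean assigns them
weight `exp(-γ/2 ‖x‖²) ≈ e⁻³⁰` and stays near the honest average.

The same contrast end-to-end, on a logistic-regression federated task with
2 Byzantine clients out of 20:

```sh
robustagg fl-run --task logistic --aggregator simple_gamma_mean --gamma 0.5 \
    --clients 20 --byzantine 2 --rounds 200 --seed 1 --out fl_gm
robustagg fl-run --task logistic --aggregator mean \
    --clients 20 --byzantine 2 --rounds 200 --seed 1 --out fl_mean
```

The written histories (`history.csv`: round, lr, loss, dist_to_truth,
accuracy) end near 97% test accuracy for the simple gamma-mean versus
~77% for the mean, whose parameter is dragged toward the attack vector.

Library use mirrors the CLI:

```python
import numpy as np
from robustagg import GammaConfig, gamma_mean

rng = np.random.default_rng(0)
x = rng.standard_normal((200, 10))
x[:20] += 100.0                     # 10% Byzantine rows
est = gamma_mean(x, GammaConfig(gamma=0.2))
est.mu                              # ≈ 0, Byzantine weight ≈ 0
est.weights[:20].max()              # ~1e-300
```

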