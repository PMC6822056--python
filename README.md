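# scrselect

Bayesian model selection for **partial-identity spatial capture–recapture
(SCR)** models, for statistical ecologists estimating animal density from
paired camera-trap (two-detector) surveys.

Camera-trap stations photograph both flanks of passing animals, but cameras
misfire: many capture histories come from one detector only, and matching a
left-flank history to a right-flank history is only certain when the animal
was photographed by both cameras simultaneously. `scrselect` implements four
competing models for such bilateral data and — its main purpose — the full
toolbox for deciding *which* model the data support.

## Models

All models augment the observed histories to `M` pseudo-individuals with
inclusion indicators `z_i ~ Bernoulli(ψ)` (population size `N = Σ z_i`),
latent activity centers `s_i ~ Uniform(V)`, and a latent permutation `L`
matching detector-2 rows to individuals:

| model | trap entry and detection separated? | sex-specific σ? |
|-------|-------------------------------------|-----------------|
| M1    | yes — entry `η_j(s) = ω₀ exp(−d²/2σ²)`, then detection `φ` per detector | yes |
| M2    | no — direct detection `p_j(s) = p₀ exp(−d²/2σ²)` | yes |
| M3    | yes | no |
| M4    | no  | no |

## Model-selection toolbox (25 variants)

* **Bayes factors** via the Gelfand–Dey marginal-likelihood estimator, with
  the high-dimensional latents handled by a **MAP approximation** (an
  iterative alternating-scan search over the posterior draws) or by an
  **integrated likelihood** (`z` and missing sexes summed analytically,
  activity centers by Riemann sum) — each with nine tuning densities
  (normal, t with df 10–10000, truncated normal at 0.90/0.95/0.99);
* the **harmonic mean** estimator;
* **DIC** with `p_DIC1`/`p_DIC2` at the searched MAP;
* **WAIC** partitioned by augmented individual with `p_WAIC1`/`p_WAIC2` and
  an absolute-error variant `p_WAIC3`;
* **posterior predictive loss** `D_∞` (squared bias + predictive variance
  over all `2MJK` binary cells).

A seeded simulator reproduces the reference study design (10×16 traps on a
5×7 state space, K=50, N=100 with 40 males, M=400, 12 scenarios), and an
evaluation harness computes true-model selection proportions and average
RMSE of `N` across replicates.

## Worked example

```python
import numpy as np
from scrselect import PartialIdentitySCR
from scrselect.evaluation import scaled_down_design
from scrselect.simulator import simulate_dataset

d = scaled_down_design()                       # desk-scale study design
data, identity, truth = simulate_dataset(d.scenario, d.traps, d.space, seed=1)
model = PartialIdentitySCR(data, identity, d.traps, d.space, model="M1")
res = model.fit(n_iter=5000, burn_in=1000, seed=11)
print(res.summary())
```

```
Partial-identity SCR fit: model M1
retained draws: 4000   M = 100   J = 49   K = 15

                mean         sd       q2.5     median      q97.5
parameter
psi           0.3192     0.0594     0.2175     0.3145     0.4476
theta         0.3811     0.0801     0.2395     0.3820     0.5380
phi           0.9123     0.0199     0.8674     0.9144     0.9461
omega0        0.0502     0.0066     0.0379     0.0501     0.0635
sigma_m       0.2835     0.0226     0.2466     0.2814     0.3360
sigma_f       0.1359     0.0126     0.1142     0.1350     0.1638
N            31.7918     3.1512    27.0000    31.0000    39.0000
```

The simulated truth was ψ≈0.3 (N=30 of M=100), θ=0.4, φ=0.9, ω₀=0.05,
σ_m=0.3, σ_f=0.15 — every posterior interval covers its generating value,
and the posterior median of the population size is 31 against a truth of 30.

Model comparison:

```python
print(res.log_marginal("gd_map").value)   # -1277.9
m4 = PartialIdentitySCR(data, identity, d.traps, d.space, model="M4")
res4 = m4.fit(n_iter=5000, burn_in=1000, seed=11)
print(res4.log_marginal("gd_map").value)  # -1677.2
```

The evidence favours the true entry-detection sex model by ~400 log units.
`res.criteria()` returns all 25 criterion variants as a table.

A thin CLI wraps the same functionality:

```bash
scrselect simulate --scenario 9 --scale scaled_down --seed 1 --out sim/
scrselect fit --data sim/ --model M1 --k 15 --m 100 \
    --space 0,1.4,0,1.4,0.2 --out fit_m1/
scrselect criteria --draws fit_m1/ --data sim/ --k 15 --m 100 \
    --space 0,1.4,0,1.4,0.2 --out criteria.csv
scrselect experiment --config exp.yaml
```

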