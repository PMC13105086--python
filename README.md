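# deepHTL

Testing and estimating **heterogeneous treatment effects (HTE)** from
observational data with complex confounding — the setting of clinical
registries, where treatment assignment depends nonlinearly on many
recipient and donor characteristics, and where the question is not only
*"does the treatment help on average?"* but *"for whom does it help, and is
the apparent variation real?"*

The package is aimed at biostatisticians analyzing observational cohorts
with a continuous outcome `Y`, a binary treatment `Z` and covariates `X`,
under the partially linear model

```
Y = τ(X)·Z + f(X) + ε,          E[ε | X, Z] = 0,
```

with both the effect surface `τ(X)` and the confounding surface `f(X)`
unspecified. It provides:

* **Estimation** — a *revised* R-learner: nuisances `e(X) = E[Z|X]` and
  `μ(X) = E[Y|X]` are cross-fitted with bagged, filtered neural-network
  ensembles; the constant effect `τ₀` is removed first
  (`Y* = Y − τ₀Z`), the outcome regression is re-fit on the centered
  scale, and only the residual heterogeneity `r(X)` is learned:
  `τ*(X) = τ₀ + r(X)`. Centering repairs the bias that plain R-learners
  suffer when `|τ|` is large (the residual `Y − μ(X)` becomes bimodal and
  the outcome model degrades).
* **Testing** — two global tests of `H₀: Var{τ(X)} = 0`:
  an analytic **kernel score test** (`Q = s̃ᵀKs̃`, null law a weighted
  mixture of χ²₁ variables given by the eigenvalues of the projected
  kernel, tail probability by the Davies characteristic-function
  inversion) and a cross-fitted **within-arm permutation test** on the
  held-out prediction loss.
* **Simulation** — a generator of registry-like confounded data (nonlinear
  propensity and outcome surfaces, four effect scenarios) plus experiment
  drivers for Type I error, power and estimation-accuracy grids.

## Worked example

```python
import numpy as np
from deephtl import (SimulationConfig, simulate_dataset, LearnerConfig,
                     cross_fit, fit_revised, kernel_score_test,
                     permutation_test)

# a simulated observational study with a strongly heterogeneous effect
ds = simulate_dataset(SimulationConfig(n=2000, p=5, sigma=1.0,
                                       tau_scenario="simple_hte", seed=7))

learner = LearnerConfig(hidden_layer_sizes=(16,), solver="lbfgs",
                        max_epochs=100, n_members=3, n_folds=3)
nuis = cross_fit(ds, targets=("e", "mu"), config=learner, seed=1)
est = fit_revised(ds, nuis, learner, seed=2)

print(f"tau0          = {est.tau0:.3f}")
print(f"tau* (global) = {est.tau_star_global:.3f}")
print(f"corr(tau*, truth) = "
      f"{np.corrcoef(est.tau_star, ds.tau_true)[0, 1]:.3f}")

score = kernel_score_test(ds, nuis, variant="revised")
perm = permutation_test(ds, nuis, est.tau_star, B=999, seed=3,
                        variant="revised", tau0=est.tau0)
print(f"kernel score Q = {score.Q:.1f}, p = {score.p_value:.2e}, "
      f"k_eff = {score.k_eff:.1f}")
print(f"permutation p  = {perm.p_value:.4f}")
```

Output:

```
tau0          = 1.227
tau* (global) = 1.268
corr(tau*, truth) = 0.951
kernel score Q = 100998.6, p = 0.00e+00, k_eff = 9.1
permutation p  = 0.0010
```

`tau0`/`tau*` estimate the constant component of the effect (the sample
mean of the true effects in this draw is 1.24); the out-of-fold
estimates track the true effect surface closely (correlation 0.95); both
tests reject homogeneity emphatically — correctly, since this scenario's
effect variance is ≈ 6. `k_eff` is the effective degrees of freedom of the
detected heterogeneity: values near 1 indicate a single dominant covariate
direction, larger values a diffuse, multidirectional pattern.

The same workflow is available from the shell:

```bash
deephtl simulate --n 2000 --p 5 --scenario simple_hte --seed 7 --out study.csv
deephtl fit study.csv --seed 1                  # tau0, tau*, ATE as JSON
deephtl test study.csv --seed 1 -B 999          # p_davies, p_perm, Q, k_eff
deephtl experiment grid.json --out report.csv   # replicated simulation grids
```

## Documentation

`docs/methods.md` documents the model, the centering revision, the score
and permutation tests, the generator, all tunable parameters and the
package's numerical choices.
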