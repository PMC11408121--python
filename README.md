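# bandcorr

Simulation and Bayesian hierarchical estimation of the correlation between
hunting and natural mortality hazards from band-recovery (dead-recovery)
data, with machinery for prior-sensitivity and coverage studies.

## The problem

Ecologists use band-recovery data — cohorts of marked birds released each
year, with bands from hunter-killed birds reported in later years — to ask
whether hunting mortality and natural mortality move together over time.
The quantity of interest is the correlation ρ between annual hunting and
natural log mortality hazard rates.  Estimating ρ requires a prior on a
2×2 covariance matrix, and the choice matters: the conjugate inverse-Wishart
prior builds in a dependency between the standard deviations and the
correlation, and mis-specified "precision-matrix" parameterizations that
have circulated in the applied literature silently flip or distort ρ.  This
package implements the *separation strategy* — independent priors on each
standard deviation and on the correlation — and the tooling to demonstrate
that it recovers ρ accurately while quantifying what goes wrong with the
alternatives.

## The model

Annual hazards follow a bivariate log-normal random-effects model

```
ln h_κ,t = μ_κ + ε_κ,t        ln h_η,t = μ_η + ε_η,t
(ε_κ,t, ε_η,t) ~ BVN(0, Σ),   Σ = [[σ_κ², σ_κσ_η ρ], [σ_κσ_η ρ, σ_η²]]
```

with competing-risks transforms to annual survival and recovery
probabilities

```
S_t = exp(−(h_κ,t + h_η,t))          κ_t = (1 − S_t) · h_κ,t / (h_κ,t + h_η,t)
f_t = κ_t (1 − c) b                  (crippling loss c = .2, reporting b = .5)
```

Each release cohort's recoveries form one row of an m-array, multinomial
over cell probabilities `P_tj = (∏_{k=t}^{j−1} S_k) f_j` with a final
never-recovered cell.  Fitting priors: σ ~ uniform(0, 5) or σ ~ gamma(1, 1)
(the two separation-strategy variants), ρ ~ uniform(−1, 1),
μ ~ normal(−1, 1); c and b are fixed.  Posteriors are sampled with the
package's dynamic Hamiltonian Monte Carlo sampler (No-U-Turn trajectories,
hand-coded analytic gradients, numba-compiled), with rank-normalized split
R̂ and bulk ESS diagnostics via ArviZ.

## Worked example

```
$ bandcorr simulate --seed 4 --out sim/
$ bandcorr fit --marray sim/marray_0001.csv --prior uniform --profile desk \
      --seed 11 --out fit.json
rho median -0.4519 CrI (-0.6971, -0.1165)
```

The simulated replicate (36 years × 10,000 releases/year) had generating
ρ = −0.306 and a realized hazard correlation of −0.493 over its 36 simulated
years; the posterior summaries in `fit.json` are

```
mu_kappa     median=-1.0196  95% CrI (-1.1057, -0.9332)  Rhat=1.002 ESS=2626
mu_eta       median=-1.0273  95% CrI (-1.1102, -0.9470)  Rhat=1.003 ESS=2669
sigma_kappa  median=+0.2595  95% CrI (+0.2046, +0.3376)  Rhat=1.000 ESS=3202
sigma_eta    median=+0.2423  95% CrI (+0.1880, +0.3236)  Rhat=1.001 ESS=1892
rho          median=-0.4519  95% CrI (-0.6971, -0.1165)  Rhat=1.002 ESS=2168
```

The interval tracks the realized correlation (the finite-sample correlation
of the 36 simulated hazard pairs) and contains the generating value; the
hazard means and standard deviations recover their truths (−1 and ≈0.22).
The prior diagnostic shows why the inverse-Wishart is avoided:

```
$ bandcorr priors --family inverse_wishart --n 20000 --seed 2 --out iw.csv
dependency diagnostic corr(log sigma1, |rho|) = +0.5197
```

versus ≈ 0 for the `uniform_sd` and `gamma_sd` families.  A full
replication study (coverage and bias of ρ̂ over many simulated datasets,
both priors fit to each dataset, convergence-based exclusions, and a
three-panel recovery figure) runs with

```
$ bandcorr study --n-sims 100 --profile desk --base-seed 1 --out study/
```

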