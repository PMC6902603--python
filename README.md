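# bayesam

Bayesian estimation of genetic parameters and breeding values with a
pedigree-based **animal model**, fitted by three interchangeable MCMC
samplers — **Gibbs sampling**, **Hamiltonian Monte Carlo (HMC)** and the
**No-U-Turn Sampler (NUTS)** with dual-averaging step-size adaptation —
plus an infinitesimal-model pedigree simulator and the chain-quality
diagnostics (ESS, autocorrelation, MCSE, skewness, EBV accuracy) needed to
compare them.

It is written for quantitative geneticists and animal breeders who want a
self-contained, scriptable way to study *sampler quality* on the standard
univariate evaluation model

```
y = Xb + Za + e,   a | σ²ₐ ~ N(0, A σ²ₐ),   e ~ N(0, I σ²ₑ),
h² = σ²ₐ / (σ²ₐ + σ²ₑ)
```

where `A` is the additive relationship matrix built from the pedigree
(tabular method) and `b` carries fixed effects such as sex.  Priors are
flat on `b` and on both variances.  The gradient-based samplers run on a
non-centered unconstrained parameterization `(b, u, log σ²ₐ, log σ²ₑ)` with
`a = σₐ L u`, `A = LL'` — see `docs/methods.md` for the model, the
algorithms and every numerical choice.

## Worked example

```python
import bayesam as bs

# a population of 1120 animals: 20♂ + 100♀ base, then 5 generations of
# 1 sire × 10 dams × 20 offspring, true h² = 0.3, phenotypic variance 1
sim = bs.simulate(bs.SimConfig(h2_true=0.3, seed=1))

est = bs.NUTSAnimalModel(n_iter=3000, burn_in=1000, seed=11,
                         adapt_mass=True)
est.fit(sim.phenotypes, sim.pedigree, factor=sim.factor)
print(f"h2 = {est.h2_mean_:.3f} +/- {est.h2_mcse_:.4f} (MCSE)")

report = est.diagnose(true_bv=sim.true_bv)
row = report.table.loc["h2"]
print(f"ESS = {row['ess']:.0f}, lag-1 acf = {row['lag1']:.2f}, "
      f"EBV accuracy r = {report.ebv_correlation:.2f}")
```

Output (exact numbers from this seed):

```
h2 = 0.294 +/- 0.0060 (MCSE)
ESS = 167, lag-1 acf = 0.77, EBV accuracy r = 0.68
```

The posterior mean recovers the simulated heritability (0.3); the MCSE
says that estimate is stable to ~0.006; the ESS says the 2000 stored draws
are worth ~167 independent ones for the h² chain; and the correlation of
0.68 between true and estimated breeding values is what this family
structure supports at h² = 0.3.  Swap in `GibbsAnimalModel` or
`HMCAnimalModel(epsilon=0.01, n_leapfrog=100)` for the same posterior with
very different sampling quality — the point of the package.  All estimators
follow scikit-learn conventions (`get_params`/`set_params`/`clone`,
fitted attributes with trailing underscores, `predict` returns EBVs).

## Command line

```bash
bayesam simulate --h2 0.3 --seed 1 --out simdata
bayesam fit --pedigree simdata/pedigree.csv --phenotypes simdata/phenotypes.csv \
            --sampler nuts --iters 3000 --burnin 1000 --seed 11 \
            --true-bv simdata/true_bv.csv --out fit_out
bayesam diagnose --store fit_out
bayesam replicate-study --h2 0.1 --h2 0.3 --h2 0.5 --replicates 5 --out study
```

`fit` writes the draws, a diagnostics report (JSON) and a run manifest;
`replicate-study` produces replicate-averaged tables of heritability
estimates/EBV accuracy and of ESS/autocorrelations per sampler × scenario.
Every artifact records its seed and regenerates byte-identically.

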