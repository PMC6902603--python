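# Methods

## Model

`bayesam` fits the univariate animal model

    y = X b + Z a + e,    a | σ²ₐ ~ N(0, A σ²ₐ),    e ~ N(0, I σ²ₑ)

where `y` (n records) carries one phenotype per record, `X` is a 0/1
fixed-effect incidence (treatment coding, first level of each factor dropped
when an intercept is present so `X` has full column rank), `Z` assigns each
record to one of `q` animals, and `A` is the additive (numerator)
relationship matrix implied by the pedigree — twice the kinship matrix, with
diagonal `1 + F` (F = inbreeding coefficient).  `A` is built by the tabular
method in topological order (`a_ij = (a_{j,s} + a_{j,d})/2`,
`a_ii = 1 + a_{sd}/2`, unknown-parent terms zero) and stored dense: at the
package's design scale (q ≈ 1120) it is ~10 MB and its Cholesky factor
`L` (A = LL') is computed once.

Priors are improper flats: uniform on `b` and on both variances over the
positive half-line.  This is the prior under which the analytic score
equations implemented in `grad_log_posterior` are exactly the derivatives of
likelihood × genetic prior, and under which the Gibbs variance conditionals
are Inverse-Gamma(q/2−1, a'A⁻¹a/2) and Inverse-Gamma(n/2−1, e'e/2)
(shape/rate convention: density ∝ x^(−shape−1) e^(−rate/x)).  Flat variance
priors are proper only for q > 2 and n > 2; smaller problems are rejected.
The reported summary is heritability h² = σ²ₐ/(σ²ₐ+σ²ₑ), computed per draw.

## Samplers

Three interchangeable MCMC engines produce draws from the same posterior.

**Gibbs** sweeps single-site full conditionals in the order b → a → σ²ₐ →
σ²ₑ, with `A⁻¹` formed once from `L` and the residual and `A⁻¹a` vectors
maintained incrementally (O(q²) per sweep).  Single-site updates are the
classical scheme for this model and are deliberately retained: their high
autocorrelation at low heritability is part of what the diagnostics are
meant to expose.  Default initialization: b = 0, a = 0, each variance half
the phenotypic variance.  The sweep is JIT-compiled (numba); equivalent
NumPy conditionals are kept as the tested reference.

**HMC** runs on the unconstrained parameterization (below) with the
leapfrog integrator (half-step momentum, full-step position, half-step
momentum), kinetic energy p'M⁻¹p/2 with diagonal `M` (identity by default),
and the Metropolis correction α = min{1, exp(H − H*)}.  ε and the step
count L are fixed by the user; ε = 0.01, L = 100 are the defaults used in
the study replication.  Trajectories with |ΔH| > 1000 or non-finite
energies are divergent and always rejected (counted in the run report);
a post-burn-in acceptance rate under 1% triggers an explicit warning, since
badly tuned (ε, L) is this sampler's characteristic failure mode.

**NUTS** chooses the trajectory length automatically.  Each iteration
refreshes p ~ N(0, M), draws a slice variable
u ~ Uniform(0, exp(log f(θ) − p'M⁻¹p/2)) — held as log u = joint +
log U(0,1) for numerical safety — and doubles the trajectory in a random
direction until the U-turn criterion (θ⁺−θ⁻)'p⁻ < 0 or (θ⁺−θ⁻)'p⁺ < 0
fires; the check runs at every subtree merge, which the stopping rule's
correctness requires.  States enter the candidate set when u ≤ exp(joint);
a slice violation by more than 1000 nats stops the trajectory as divergent.
Proposals move between doubling halves by the memory-efficient kernel T
(accept the new half with probability |C_new|/|C_old|, then pick one of its
valid states uniformly), so only boundary states and per-subtree summaries
are kept — O(depth · dim) memory.  Tree depth is capped at 10 by default.

During warm-up, ε follows dual averaging in the running-sum form

    log ε_{j+1} = μ − (√j/γ) · (1/(j+j₀)) · Σ_{i≤j} (δ − α_i)
    log ε̄_{j+1} = j^{−κ} log ε_{j+1} + (1 − j^{−κ}) log ε̄_j

with γ = 0.05, j₀ = 10, κ = 0.75, target acceptance δ = 0.6, and
μ = log(10 ε₁) where ε₁ comes from a coarse doubling/halving search for a
one-step Metropolis ratio near 0.5.  α_j is the mean Metropolis ratio over
the states explored during the final doubling of iteration j.  After
warm-up, ε is frozen at exp(log ε̄).  δ = 0.6 is the default here (the
balance recommended for this sampler family); it is configurable, as is an
optional diagonal mass-matrix adaptation that estimates coordinate-wise
posterior variances in three expanding warm-up windows (at 25/50/75% of
warm-up) and sets M = diag(1/var), re-initializing the step-size search
after each update.  Mass adaptation is off by default so that default
behaviour is fully specified, and on in the study replication, whose
reference results come from a sampler that adapts a diagonal metric during
warm-up.

## Parameterization for the gradient samplers

HMC and NUTS sample θ = (b, u, log σ²ₐ, log σ²ₑ) with a = σₐ·L·u.  This is
the non-centered (whitened and standardized) form: u is a-priori standard
normal and independent of σ²ₐ, the log transform enforces positivity with
Jacobian terms +log σ²ₐ +log σ²ₑ, and the unconstrained density is

    log f = −(n/2)·log σ²ₑ − ‖y − Xb − σₐ Z L u‖²/(2σ²ₑ) − u'u/2
            + log σ²ₐ + log σ²ₑ  (+ const).

The centered alternative (a = L·u with u ~ N(0, I σ²ₐ)) was measured to mix
an order of magnitude worse for the h² chain at this design scale — the
classic funnel between a variance and the effects it scales — and is not
used.  On the constrained scale the package exposes exactly the four
analytic score equations (∂/∂b, ∂/∂a, ∂/∂σ²ₐ, ∂/∂σ²ₑ) of the model, which
the tests verify against finite differences together with their
unconstrained counterparts.  Initial θ for both gradient samplers is
Uniform(0, 1) per coordinate on the unconstrained scale.

## Simulator

`simulate()` reproduces the study design it is benchmarked against: a base
population of 20 males and 100 females with breeding values N(0, h²σ²_P);
five discrete generations, each produced by one randomly chosen sire of the
previous generation mated to 10 randomly chosen dams (without replacement),
each mating yielding 10 male + 10 female offspring — 200 animals per
generation, 1000 in total, 1120 with the base.  Offspring breeding value =
mid-parent + Mendelian deviation N(0, σ²ₐ(1 − (F_s+F_d)/2)/2) with parental
F taken exactly from diag(A).  Phenotype = sex mean + BV + N(0, (1−h²)σ²_P),
with σ²_P = 1 and sex effects (0, 0) by default — sex is modeled but truly
null, matching a design whose phenotypes carry no fixed-effect signal;
non-null values are configurable for power checks.  Base animals are
phenotyped by default (all records are used in the analysis); a toggle
removes them.  True h² ∈ {0.1, 0.3, 0.5} are the scenario values.

What the generator does **not** emulate: genome/marker structure (linkage,
QTL, drift in a historical population), selection (the sire is chosen at
random), overlapping generations, maternal or permanent-environment
effects, and heterogeneous residual variance.  Passing tests therefore show
that the samplers recover parameters of a correctly specified
infinitesimal-model dataset — not robustness to model misspecification in
real livestock data.

## Diagnostics

ESS follows the AR-spectral estimator of the coda R package: Yule–Walker
(Levinson–Durbin) AR fits up to order 10·log10(n), order chosen by AIC with
coda's small-sample variance correction, spectral density at zero
s(0) = σ²_pred/(1 − Σφ)², ESS = n·var/s(0), deliberately uncapped.  A
batch-means ESS (30 batches) is reported alongside as a robustness column —
a different, coarser estimator.  MCSE = posterior SD/√ESS.  Autocorrelation
is the standard overall-mean-centred estimate, reported at lags 1, 5, 10
and 50.  Skewness is adjusted Fisher–Pearson (bias-corrected g₁).  EBV
accuracy is Pearson's r between true and posterior-mean breeding values;
unbiasedness is the OLS slope of truth on estimate.  The EBV is the
posterior mean of each animal's `a` (accumulated as a running mean, so no
per-draw effect storage is needed unless requested).

## Numerical choices and degenerate inputs

Cholesky failure reports the offending leading minor; a cyclic pedigree,
duplicate ids or unknown parent ids are rejected at load with structural
errors.  Constant chains yield ESS 0 and missing autocorrelation; an EBV
vector with zero variance yields missing accuracy metrics.  Constant terms
of all log densities are dropped consistently — only differences matter to
any accept/reject decision.  Non-finite energies or gradients inside a
trajectory are divergences, never exceptions.  Reproducibility: every
sampler consumes a single integer seed; identical seed and configuration
reproduce draws bit for bit (the Gibbs kernel uses numba's MT19937, the
gradient samplers numpy's PCG64).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full 1120-animal design.
Iteration budgets are scaled to keep a complete run on one CPU inside a few
minutes per scenario.  In the test suite: Gibbs chains use the full 10,000
iterations (1,000 burn-in) on five replicate datasets per scenario; NUTS
runs 3,000 iterations (1,000 warm-up) on the first replicate and 1,500
(750 warm-up) on the others — five replicates at h² = 0.1 and 0.3, three
at h² = 0.5; HMC runs 1,000 iterations (250 burn-in) at
ε = 0.01, L = 100 on two replicates.  The ESS comparison between samplers
uses chains at an identical 3,000-iteration budget (1,000 warm-up/burn-in)
on the same dataset, since an ESS ratio is only meaningful at matched draw
counts; the acceptance script uses a matched 4,000-iteration budget and
averages the per-scenario ratio over two replicate datasets.
Replicated quantities are compared as replicate averages, as in the
reference study.  Posterior-mean Monte Carlo error at these budgets is well
under the tolerances being checked (MCSE of h̄² ≲ 0.01 for every sampler);
data-level variation between replicate datasets, not chain noise, is the
dominant uncertainty, which is why averages over replicates are compared.

## Known limitations

Single-trait, single random effect, homogeneous residual variance; no
maternal effects; no genomic relationships; single chains (no R-hat);
A-inverse is never formed by Henderson's rules (dense solves through L are
adequate at desk scale, O(q²) memory bounds the practical q); the flat
variance priors preclude very small datasets and can, in principle, be
dominated by likelihood ridges in pathological designs.  The Gibbs sampler's
draws are generated by a numba-compiled kernel whose RNG stream differs
from the NumPy-based reference conditionals, so kernel correctness is
established statistically (exact analytic marginal on a small problem,
distributional tests of the conditionals) rather than draw by draw.
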