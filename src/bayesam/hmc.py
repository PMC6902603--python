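"""Fixed-hyperparameter Hamiltonian Monte Carlo.

The sampler works on the unconstrained parameterization of the model (or any
user-supplied ``target(theta) -> (log density, gradient)``).  With potential
``U(theta) = -log f(theta)`` and kinetic energy ``K(p) = p'M^{-1}p / 2`` the
leapfrog integrator alternates half-step momentum, full-step position and
half-step momentum updates; a Metropolis correction with
``alpha = min{1, exp(H(theta, p) - H(theta*, p*))}`` removes the
discretization bias.  ``M`` is a positive diagonal mass matrix (identity by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import SampleStore
from .model import ModelData, heritability, make_target
from .pedigree import RelationshipFactor

#: |delta H| beyond which a trajectory is declared divergent and rejected.
DIVERGENCE_THRESHOLD = 1000.0


class DivergenceSignal(Exception):
    """Non-finite energy or gradient during integration; carries the state."""

    def __init__(self, theta, p):
        self.theta = theta
        self.p = p
        super().__init__("divergent trajectory")


@dataclass(frozen=True)
class PhaseState:
    """Point in phase space with cached log density, gradient and energy."""

    theta: np.ndarray
    p: np.ndarray
    logp: float
    grad: np.ndarray

    def __post_init__(self):
        if len(self.theta) != len(self.p):
            raise ValueError("theta and p must have equal length")

    def hamiltonian(self, m_diag: np.ndarray | None = None) -> float:
        return -self.logp + kinetic_energy(self.p, m_diag)


@dataclass(frozen=True)
class HMCConfig:
    epsilon: float = 0.01
    n_leapfrog: int = 100
    n_iter: int = 10000
    burn_in: int = 1000
    seed: int = 0
    mass_diag: np.ndarray | None = None  # identity when None

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.n_leapfrog < 1:
            raise ValueError("n_leapfrog must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")


def kinetic_energy(p: np.ndarray, m_diag: np.ndarray | None = None) -> float:
    """K(p) = p' M^{-1} p / 2 for diagonal M (inf on overflow, not an error)."""
    with np.errstate(over="ignore"):
        if m_diag is None:
            return 0.5 * float(p @ p)
        return 0.5 * float(p @ (p / m_diag))


def leapfrog(
    theta: np.ndarray,
    p: np.ndarray,
    target,
    epsilon: float,
    n_steps: int,
    grad: np.ndarray | None = None,
    m_diag: np.ndarray | None = None,
) -> PhaseState:
    """``n_steps`` leapfrog steps of size ``epsilon``.

    Position update is ``theta <- theta + eps * M^{-1} p`` (identity mass
    reduces to ``+ eps * p``).  Raises :class:`DivergenceSignal` on
    non-finite log density or gradient.
    """
    theta = np.array(theta, dtype=float)
    p = np.array(p, dtype=float)
    if grad is None:
        _, grad = target(theta)
    m_inv = 1.0 / m_diag if m_diag is not None else None
    logp = np.nan
    for _ in range(n_steps):
        p = p + 0.5 * epsilon * grad
        theta = theta + epsilon * (p * m_inv if m_inv is not None else p)
        logp, grad = target(theta)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            raise DivergenceSignal(theta, p)
        p = p + 0.5 * epsilon * grad
    return PhaseState(theta=theta, p=p, logp=float(logp), grad=grad)


def hmc_step(
    theta: np.ndarray,
    logp: float,
    grad: np.ndarray,
    target,
    epsilon: float,
    n_leapfrog: int,
    rng: np.random.Generator,
    m_diag: np.ndarray | None = None,
):
    """One proposal: fresh momentum, leapfrog trajectory, Metropolis test.

    Returns ``(theta, logp, grad, accepted, alpha, diverged)``; divergent
    trajectories have ``alpha = 0`` and are always rejected.
    """
    dim = len(theta)
    scale = np.sqrt(m_diag) if m_diag is not None else 1.0
    p0 = rng.standard_normal(dim) * scale
    h0 = -logp + kinetic_energy(p0, m_diag)
    try:
        end = leapfrog(theta, p0, target, epsilon, n_leapfrog, grad, m_diag)
        h1 = end.hamiltonian(m_diag)
        delta_h = h0 - h1
    except DivergenceSignal:
        return theta, logp, grad, False, 0.0, True
    if not np.isfinite(delta_h) or -delta_h > DIVERGENCE_THRESHOLD:
        return theta, logp, grad, False, 0.0, True
    alpha = min(1.0, float(np.exp(min(delta_h, 0.0))))
    if rng.uniform() < alpha:
        return end.theta, end.logp, end.grad, True, alpha, False
    return theta, logp, grad, False, alpha, False


def initial_theta(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Independent Uniform(0, 1) coordinates on the unconstrained scale."""
    return rng.uniform(0.0, 1.0, size=dim)


def _assemble_store(
    kept_theta_scalars, scaled_u_mean, data: ModelData, factor: RelationshipFactor, meta
) -> SampleStore:
    """Map unconstrained per-draw scalars back to the constrained scale.

    ``scaled_u_mean`` is the posterior mean of ``sigma_a u``, so the EBV
    vector (posterior mean of ``a = sigma_a L u``) is one matvec with L.
    """
    b_cols, log_s2a, log_s2e = kept_theta_scalars
    s2a = np.exp(log_s2a)
    s2e = np.exp(log_s2e)
    names = list(data.fixed_names) or [f"b{j}" for j in range(data.p)]
    draws = pd.DataFrame(b_cols, columns=names)
    draws["sigma2_a"] = s2a
    draws["sigma2_e"] = s2e
    draws["h2"] = heritability(s2a, s2e)
    ebv = factor.L @ scaled_u_mean
    return SampleStore(draws=draws, ebv=ebv, meta=meta)


def hmc_run(
    data: ModelData, factor: RelationshipFactor, config: HMCConfig
) -> SampleStore:
    """Full HMC run on the animal model; draws returned on the constrained
    scale with per-draw heritability.  Emits a warning when the post-burn-in
    acceptance rate falls below 1% (the pathological-hyperparameter regime)."""
    rng = np.random.default_rng(config.seed)
    target = make_target(data, factor)
    p_, q_ = data.p, data.q
    dim = p_ + q_ + 2
    theta = initial_theta(dim, rng)
    logp, grad = target(theta)
    n_kept = config.n_iter - config.burn_in
    b_out = np.empty((n_kept, p_))
    la_out = np.empty(n_kept)
    le_out = np.empty(n_kept)
    u_mean = np.zeros(q_)
    n_accept = 0
    n_diverge = 0
    for it in range(config.n_iter):
        theta, logp, grad, accepted, _, diverged = hmc_step(
            theta,
            logp,
            grad,
            target,
            config.epsilon,
            config.n_leapfrog,
            rng,
            config.mass_diag,
        )
        if it >= config.burn_in:
            kept = it - config.burn_in
            b_out[kept] = theta[:p_]
            la_out[kept] = theta[p_ + q_]
            le_out[kept] = theta[p_ + q_ + 1]
            u_mean += np.exp(0.5 * theta[p_ + q_]) * theta[p_ : p_ + q_]
            n_accept += accepted
            n_diverge += diverged
    u_mean /= n_kept
    accept_rate = n_accept / n_kept
    meta = {
        "sampler": "hmc",
        "epsilon": config.epsilon,
        "n_leapfrog": config.n_leapfrog,
        "n_iter": config.n_iter,
        "burn_in": config.burn_in,
        "seed": config.seed,
        "accept_rate": accept_rate,
        "n_divergent": int(n_diverge),
    }
    if accept_rate < 0.01:
        warnings.warn(
            f"HMC acceptance rate {accept_rate:.4f} < 1% after burn-in; "
            "the chain has effectively not moved — retune epsilon/L",
            RuntimeWarning,
        )
    return _assemble_store((b_out, la_out, le_out), u_mean, data, factor, meta)
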