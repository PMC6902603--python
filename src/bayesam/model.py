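"""The univariate animal model: likelihood, priors, gradients, transforms.

Model: ``y = X b + Z a + e`` with ``y | b, a, sigma2_e ~ N(Xb + Za, I sigma2_e)``
and ``a | sigma2_a ~ N(0, A sigma2_a)``.  Priors: flat (improper uniform) on
``b`` and on both variances over the positive half-line, so the log posterior
(up to a constant) is likelihood plus the genetic-effect prior.

Gradient-based samplers work on an unconstrained vector
``theta = (b, u, log sigma2_a, log sigma2_e)`` where ``a = sigma_a L u``
whitens the genetic effects through the Cholesky factor of ``A`` and
standardizes their scale (non-centered parameterization), and the
log-variance transform contributes the Jacobian terms
``+log sigma2_a + log sigma2_e``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelationshipFactor


class DomainError(ValueError):
    """Parameter outside its support (non-positive variance)."""


@dataclass(frozen=True)
class ModelData:
    """Phenotypes with fixed- and random-effect incidence.

    ``rec_animal[i]`` is the column of ``Z`` carrying the single 1 of record
    ``i`` (each record belongs to exactly one animal), so ``Z a`` is
    ``a[rec_animal]`` and ``Z' v`` is a bincount — ``Z`` is never stored
    densely except on demand for small examples.
    """

    y: np.ndarray
    X: np.ndarray
    rec_animal: np.ndarray
    q: int
    fixed_names: tuple = ()

    def __post_init__(self):
        if self.X.shape[0] != len(self.y) or len(self.rec_animal) != len(self.y):
            raise ValueError("y, X and rec_animal must have matching rows")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient; drop redundant levels")
        if self.rec_animal.min() < 0 or self.rec_animal.max() >= self.q:
            raise ValueError("record points at an animal outside the pedigree")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def z_matrix(self) -> np.ndarray:
        """Dense n x q incidence matrix (for small worked examples only)."""
        Z = np.zeros((self.n, self.q))
        Z[np.arange(self.n), self.rec_animal] = 1.0
        return Z

    def zt(self, v: np.ndarray) -> np.ndarray:
        """``Z' v``."""
        return np.bincount(self.rec_animal, weights=v, minlength=self.q)


def build_design(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    trait: str = "trait",
    fixed: Sequence[str] = ("sex",),
    intercept: bool = True,
) -> ModelData:
    """Assemble ModelData from a phenotype table and a pedigree.

    Fixed factors are treatment-coded: with an intercept the first level of
    each factor is dropped so that ``X`` has full column rank (required for
    the flat prior on ``b`` to give a proper posterior).
    """
    missing = set(phenotypes["animal"]) - set(pedigree.animal.tolist())
    if missing:
        raise ValueError(
            f"phenotyped animals missing from pedigree: {sorted(missing)[:5]}"
        )
    rec_animal = phenotypes["animal"].map(pedigree.index).to_numpy(dtype=np.int64)
    y = phenotypes[trait].to_numpy(dtype=float)
    cols = []
    names = []
    if intercept:
        cols.append(np.ones(len(y)))
        names.append("intercept")
    for factor in fixed:
        dummies = pd.get_dummies(
            phenotypes[factor].astype("category"), drop_first=intercept, dtype=float
        )
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy())
            names.append(f"{factor}[{level}]")
    X = np.column_stack(cols) if cols else np.ones((len(y), 1))
    return ModelData(
        y=y, X=X, rec_animal=rec_animal, q=pedigree.q, fixed_names=tuple(names)
    )


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a CSV with columns ``animal``, fixed factor(s), ``trait``."""
    df = pd.read_csv(path)
    for col in ("animal", "trait"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df


@dataclass(frozen=True)
class ParameterState:
    """One point ``theta = (b, a, sigma2_a, sigma2_e)`` of the animal model.

    ``u`` (standardized whitened effects, ``a = sigma_a L u``) is populated
    lazily when the state travels through the unconstrained
    parameterization.
    """

    b: np.ndarray
    a: np.ndarray
    sigma2_a: float
    sigma2_e: float
    u: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise DomainError(
                f"variances must be positive (got sigma2_a={self.sigma2_a}, "
                f"sigma2_e={self.sigma2_e})"
            )

    @property
    def h2(self) -> float:
        """Heritability sigma2_a / (sigma2_a + sigma2_e), in (0, 1)."""
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def heritability(sigma2_a, sigma2_e):
    """h2 = sigma2_a / (sigma2_a + sigma2_e) (vectorized)."""
    return np.asarray(sigma2_a) / (np.asarray(sigma2_a) + np.asarray(sigma2_e))


@dataclass(frozen=True)
class Gradient:
    """Gradient of the log posterior over the four constrained blocks."""

    b: np.ndarray
    a: np.ndarray
    sigma2_a: float
    sigma2_e: float


def residual(state: ParameterState, data: ModelData) -> np.ndarray:
    return data.y - data.X @ state.b - state.a[data.rec_animal]


def log_posterior(
    state: ParameterState, data: ModelData, factor: RelationshipFactor
) -> float:
    """Log posterior density up to an additive constant.

    ``log N(y | Xb + Za, I s2e) + log N(a | 0, A s2a)`` dropping terms that
    do not involve the parameters (including -log|A|/2, constant in theta).
    """
    r = residual(state, data)
    ainv_a = factor.solve_a_inverse(state.a)
    return float(
        -0.5 * data.n * np.log(state.sigma2_e)
        - 0.5 * (r @ r) / state.sigma2_e
        - 0.5 * data.q * np.log(state.sigma2_a)
        - 0.5 * (state.a @ ainv_a) / state.sigma2_a
    )


def grad_log_posterior(
    state: ParameterState, data: ModelData, factor: RelationshipFactor
) -> Gradient:
    """Analytic gradient on the constrained scale.

    d/db   = X'(y - Xb - Za) / s2e
    d/da   = -A^{-1} a / s2a + Z'(y - Xb - Za) / s2e
    d/ds2a = -q / (2 s2a) + a' A^{-1} a / (2 s2a^2)
    d/ds2e = -n / (2 s2e) + r'r / (2 s2e^2)

    ``A^{-1} a`` is computed via two triangular solves with ``L``.
    """
    r = residual(state, data)
    ainv_a = factor.solve_a_inverse(state.a)
    s2a, s2e = state.sigma2_a, state.sigma2_e
    return Gradient(
        b=data.X.T @ r / s2e,
        a=-ainv_a / s2a + data.zt(r) / s2e,
        sigma2_a=float(-0.5 * data.q / s2a + 0.5 * (state.a @ ainv_a) / s2a**2),
        sigma2_e=float(-0.5 * data.n / s2e + 0.5 * (r @ r) / s2e**2),
    )


# ---------------------------------------------------------------------------
# Unconstrained parameterization: theta = (b, u, log s2a, log s2e) with
# a = sigma_a L u (non-centered: u is a priori standard normal, independent
# of sigma2_a, which removes the funnel between the genetic variance and the
# breeding values that cripples gradient samplers on the centered scale).
# ---------------------------------------------------------------------------

def to_unconstrained(state: ParameterState, factor: RelationshipFactor) -> np.ndarray:
    u = (
        state.u
        if state.u is not None
        else factor.whiten(state.a) / np.sqrt(state.sigma2_a)
    )
    return np.concatenate(
        [state.b, u, [np.log(state.sigma2_a)], [np.log(state.sigma2_e)]]
    )


def from_unconstrained(
    theta: np.ndarray, p: int, factor: RelationshipFactor
) -> ParameterState:
    q = factor.q
    b = theta[:p]
    u = theta[p : p + q]
    s2a = float(np.exp(theta[p + q]))
    return ParameterState(
        b=b.copy(),
        a=np.sqrt(s2a) * factor.unwhiten(u),
        sigma2_a=s2a,
        sigma2_e=float(np.exp(theta[p + q + 1])),
        u=u.copy(),
    )


def unconstrained_log_posterior(
    theta: np.ndarray, data: ModelData, factor: RelationshipFactor
) -> float:
    """Log density on the unconstrained scale, Jacobian included.

    The change of variables a -> u turns the genetic prior into the standard
    normal ``-u'u / 2`` (the factors sigma_a^q |L| cancel against the prior
    normalization) and the log-variance transform adds
    ``+log s2a + log s2e``.
    """
    logp, _ = _unconstrained_logp_grad(theta, data, factor)
    return logp


def unconstrained_grad(
    theta: np.ndarray, data: ModelData, factor: RelationshipFactor
) -> np.ndarray:
    _, grad = _unconstrained_logp_grad(theta, data, factor)
    return grad


def _unconstrained_logp_grad(theta, data, factor):
    n, p, q = data.n, data.p, data.q
    b = theta[:p]
    u = theta[p : p + q]
    log_s2a, log_s2e = theta[p + q], theta[p + q + 1]
    # run silent under over/underflow: extreme exploratory states produce
    # non-finite energies, which the samplers treat as divergences
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        s2e = np.exp(log_s2e)
        sigma_a = np.exp(0.5 * log_s2a)
        lu = factor.L @ u
        za = lu[data.rec_animal]  # Z L u
        r = data.y - data.X @ b - sigma_a * za
        rr = r @ r
        logp = (
            -0.5 * n * log_s2e
            - 0.5 * rr / s2e
            - 0.5 * (u @ u)
            + log_s2a
            + log_s2e
        )
        ztr = data.zt(r)
        grad = np.empty_like(theta)
        grad[:p] = data.X.T @ r / s2e
        grad[p : p + q] = sigma_a * (factor.L.T @ ztr) / s2e - u
        grad[p + q] = 0.5 * sigma_a * (r @ za) / s2e + 1.0
        grad[p + q + 1] = -0.5 * n + 0.5 * rr / s2e + 1.0
    return float(logp), grad


def make_target(data: ModelData, factor: RelationshipFactor):
    """Callable ``theta -> (log density, gradient)`` on the unconstrained scale.

    This is the single oracle the gradient-based samplers consume; they never
    see the model directly, which also lets tests drive them with analytic
    Gaussian targets.  The two triangular matvecs with ``L`` dominate the
    cost of every leapfrog step, so they go through BLAS ``trmv`` on a
    Fortran-ordered copy of ``L``; the result is numerically identical to
    :func:`_unconstrained_logp_grad` (asserted in the tests).
    """
    import scipy.linalg.blas as blas

    Lf = np.asfortranarray(factor.L)
    trmv = blas.get_blas_funcs("trmv", (Lf,))
    n, p, q = data.n, data.p, data.q
    y, X, rec = data.y, data.X, data.rec_animal
    Xt = np.ascontiguousarray(X.T)

    def target(theta: np.ndarray):
        b = theta[:p]
        u = theta[p : p + q]
        log_s2a, log_s2e = theta[p + q], theta[p + q + 1]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            s2e = np.exp(log_s2e)
            sigma_a = np.exp(0.5 * log_s2a)
            lu = trmv(Lf, u, lower=1)
            za = lu[rec]
            r = y - X @ b - sigma_a * za
            rr = r @ r
            logp = (
                -0.5 * n * log_s2e
                - 0.5 * rr / s2e
                - 0.5 * (u @ u)
                + log_s2a
                + log_s2e
            )
            ztr = np.bincount(rec, weights=r, minlength=q)
            grad = np.empty_like(theta)
            grad[:p] = Xt @ r / s2e
            grad[p : p + q] = sigma_a * trmv(Lf, ztr, lower=1, trans=1) / s2e - u
            grad[p + q] = 0.5 * sigma_a * (r @ za) / s2e + 1.0
            grad[p + q + 1] = -0.5 * n + 0.5 * rr / s2e + 1.0
        return float(logp), grad

    return target
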