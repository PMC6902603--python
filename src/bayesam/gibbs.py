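"""Gibbs sampler for the animal model (single-site, flat variance priors).

Each sweep updates, in order, every fixed effect, every breeding value and
the two variances from their full conditionals.  Under flat priors on the
variances the conditionals are

* ``b_j | rest  ~ N(x_j'(y - X_{-j} b_{-j} - Za) / x_j'x_j, s2e / x_j'x_j)``
* ``a_i | rest  ~ N(m_i, 1 / prec_i)`` with
  ``prec_i = z_i'z_i / s2e + (A^{-1})_{ii} / s2a`` (the mixed-model-equation
  single-site update)
* ``s2a | rest ~ InvGamma(q/2 - 1, a'A^{-1}a / 2)``
* ``s2e | rest ~ InvGamma(n/2 - 1, e'e / 2)``

Inverse-Gamma is parameterized shape/rate: density ∝ x^{-shape-1} e^{-rate/x}.
The sweep is JIT-compiled with numba; the NumPy functions below it are the
readable reference for the same conditionals and are what the tests probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from numba import njit

from .diagnostics import SampleStore
from .model import ModelData, ParameterState, heritability
from .pedigree import RelationshipFactor


class PriorProprietyError(ValueError):
    """Flat variance priors give a proper conditional only for q > 2, n > 2."""


@dataclass(frozen=True)
class GibbsConfig:
    n_iter: int = 10000
    burn_in: int = 1000
    seed: int = 0
    init: ParameterState | str = "default"
    store_effects: bool = False

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")


class InverseGammaParams(NamedTuple):
    shape: float
    rate: float


def variance_conditionals(
    a: np.ndarray, ainv_a: np.ndarray, e: np.ndarray, n: int, q: int
) -> tuple[InverseGammaParams, InverseGammaParams]:
    """Shape/rate of the two Inverse-Gamma full conditionals."""
    if q <= 2 or n <= 2:
        raise PriorProprietyError(
            f"Inverse-Gamma shape would be <= 0 (q={q}, n={n}); "
            "flat variance priors need q > 2 and n > 2"
        )
    return (
        InverseGammaParams(q / 2.0 - 1.0, float(a @ ainv_a) / 2.0),
        InverseGammaParams(n / 2.0 - 1.0, float(e @ e) / 2.0),
    )


def draw_inverse_gamma(params: InverseGammaParams, rng: np.random.Generator):
    """x ~ InvGamma(shape, rate) via rate / Gamma(shape, 1)."""
    return params.rate / rng.gamma(params.shape)


def a_conditional_moments(
    i: int,
    a: np.ndarray,
    e_with_own: np.ndarray,
    n_rec: int,
    ainv_row: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
) -> tuple[float, float]:
    """Mean/variance of the single-site conditional of ``a_i``.

    ``e_with_own`` is the residual with animal i's own effect added back in
    on its records; ``n_rec = z_i'z_i``.  With no records and ``A = I`` this
    collapses to the prior ``N(0, sigma2_a)``.
    """
    c = ainv_row @ a - ainv_row[i] * a[i]
    prec = n_rec / sigma2_e + ainv_row[i] / sigma2_a
    mean = (e_with_own / sigma2_e - c / sigma2_a) / prec
    return float(mean), float(1.0 / prec)


@njit(cache=True)
def _gibbs_kernel(
    y,
    X,
    indptr,
    rec_idx,
    Ainv,
    n_iter,
    burn_in,
    b,
    a,
    s2a,
    s2e,
    seed,
    store_effects,
):  # pragma: no cover - exercised via gibbs_run
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    q = a.shape[0]
    xtx = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        xtx[j] = acc
    # residual e = y - Xb - Za and s = Ainv @ a, maintained incrementally
    e = y.copy()
    for j in range(p):
        if b[j] != 0.0:
            for i in range(n):
                e[i] -= X[i, j] * b[j]
    for k in range(q):
        if a[k] != 0.0:
            for t in range(indptr[k], indptr[k + 1]):
                e[rec_idx[t]] -= a[k]
    s = Ainv @ a
    n_kept = n_iter - burn_in
    b_out = np.empty((n_kept, p))
    s2a_out = np.empty(n_kept)
    s2e_out = np.empty(n_kept)
    a_mean = np.zeros(q)
    a_out = np.empty((n_kept if store_effects else 1, q))
    for it in range(n_iter):
        # fixed effects
        for j in range(p):
            num = xtx[j] * b[j]
            for i in range(n):
                num += X[i, j] * e[i]
            newb = np.random.normal(num / xtx[j], np.sqrt(s2e / xtx[j]))
            delta = newb - b[j]
            if delta != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * delta
            b[j] = newb
        # breeding values, single site
        for k in range(q):
            ri = 0.0
            for t in range(indptr[k], indptr[k + 1]):
                ri += e[rec_idx[t]]
            nk = indptr[k + 1] - indptr[k]
            ri += nk * a[k]
            ck = s[k] - Ainv[k, k] * a[k]
            prec = nk / s2e + Ainv[k, k] / s2a
            mean = (ri / s2e - ck / s2a) / prec
            newa = np.random.normal(mean, np.sqrt(1.0 / prec))
            delta = newa - a[k]
            if delta != 0.0:
                for t in range(indptr[k], indptr[k + 1]):
                    e[rec_idx[t]] -= delta
                for j in range(q):
                    s[j] += delta * Ainv[j, k]
                a[k] = newa
        # variances
        aAa = 0.0
        for k in range(q):
            aAa += a[k] * s[k]
        s2a = (aAa / 2.0) / np.random.gamma(q / 2.0 - 1.0, 1.0)
        ee = 0.0
        for i in range(n):
            ee += e[i] * e[i]
        s2e = (ee / 2.0) / np.random.gamma(n / 2.0 - 1.0, 1.0)
        if it >= burn_in:
            kept = it - burn_in
            for j in range(p):
                b_out[kept, j] = b[j]
            s2a_out[kept] = s2a
            s2e_out[kept] = s2e
            for k in range(q):
                a_mean[k] += a[k]
            if store_effects:
                for k in range(q):
                    a_out[kept, k] = a[k]
    a_mean /= n_kept
    return b_out, s2a_out, s2e_out, a_mean, a_out


def _record_csr(data: ModelData) -> tuple[np.ndarray, np.ndarray]:
    """Records grouped by animal as CSR (indptr, record indices)."""
    order = np.argsort(data.rec_animal, kind="stable")
    counts = np.bincount(data.rec_animal, minlength=data.q)
    indptr = np.zeros(data.q + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, order.astype(np.int64)


def default_init(data: ModelData) -> ParameterState:
    """b = 0, a = 0, each variance half the phenotypic variance."""
    half = float(np.var(data.y)) / 2.0
    return ParameterState(
        b=np.zeros(data.p), a=np.zeros(data.q), sigma2_a=half, sigma2_e=half
    )


def gibbs_run(
    data: ModelData, factor: RelationshipFactor, config: GibbsConfig
) -> SampleStore:
    """Run the Gibbs sampler and return post-burn-in draws with per-draw h2."""
    if data.q <= 2 or data.n <= 2:
        raise PriorProprietyError(
            f"flat variance priors need q > 2 and n > 2 (q={data.q}, n={data.n})"
        )
    init = config.init if isinstance(config.init, ParameterState) else default_init(data)
    indptr, rec_idx = _record_csr(data)
    b_out, s2a_out, s2e_out, a_mean, a_out = _gibbs_kernel(
        data.y.astype(np.float64),
        data.X.astype(np.float64),
        indptr,
        rec_idx,
        factor.a_inverse(),
        config.n_iter,
        config.burn_in,
        init.b.astype(np.float64).copy(),
        init.a.astype(np.float64).copy(),
        float(init.sigma2_a),
        float(init.sigma2_e),
        config.seed,
        config.store_effects,
    )
    names = list(data.fixed_names) or [f"b{j}" for j in range(data.p)]
    draws = pd.DataFrame(b_out, columns=names)
    draws["sigma2_a"] = s2a_out
    draws["sigma2_e"] = s2e_out
    draws["h2"] = heritability(s2a_out, s2e_out)
    return SampleStore(
        draws=draws,
        ebv=a_mean,
        effect_draws=a_out if config.store_effects else None,
        meta={
            "sampler": "gibbs",
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "seed": config.seed,
        },
    )
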