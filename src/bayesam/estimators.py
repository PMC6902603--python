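"""Estimator interface to the samplers, scikit-learn conventions.

Each estimator wraps one MCMC engine.  ``fit(phenotypes, pedigree)`` runs the
chain; fitted attributes follow the trailing-underscore convention
(``h2_mean_``, ``ebv_``, ``samples_``, ...), ``predict`` returns estimated
breeding values, and ``get_params``/``set_params``/``clone`` work as usual so
the classes compose with scikit-learn tooling.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import diagnostics as diag
from .gibbs import GibbsConfig, gibbs_run
from .hmc import HMCConfig, hmc_run
from .model import ModelData, build_design
from .nuts import NUTSConfig, nuts_run
from .pedigree import Pedigree, RelationshipFactor


class BaseAnimalModel(BaseEstimator):
    """Shared fit machinery; subclasses supply ``_run(data, factor)``."""

    def __init__(self, n_iter=10000, burn_in=1000, seed=0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.seed = seed

    def fit(
        self,
        phenotypes: pd.DataFrame | ModelData,
        pedigree: Pedigree | None = None,
        trait: str = "trait",
        fixed: Sequence[str] = ("sex",),
        factor: RelationshipFactor | None = None,
    ):
        """Fit the animal model by MCMC.

        ``phenotypes`` may be a table (columns ``animal``, fixed factor(s),
        ``trait``) with a pedigree, or a ready-made :class:`ModelData` with a
        precomputed :class:`RelationshipFactor`.
        """
        if isinstance(phenotypes, ModelData):
            data = phenotypes
            if factor is None:
                raise ValueError("factor is required when passing ModelData")
        else:
            if pedigree is None:
                raise ValueError("pedigree is required when passing a phenotype table")
            data = build_design(phenotypes, pedigree, trait=trait, fixed=fixed)
            if factor is None:
                factor = RelationshipFactor.from_pedigree(pedigree)
        store = self._run(data, factor)
        self.pedigree_ = pedigree
        self.data_ = data
        self.factor_ = factor
        self.samples_ = store
        self.ebv_ = store.ebv
        h2 = store.draws["h2"].to_numpy()
        self.h2_mean_ = float(h2.mean())
        self.h2_mcse_ = float(diag.mcse(h2)) if len(h2) >= 100 else float("nan")
        self.sigma2_a_mean_ = float(store.draws["sigma2_a"].mean())
        self.sigma2_e_mean_ = float(store.draws["sigma2_e"].mean())
        self.b_mean_ = store.draws[list(data.fixed_names)].mean().to_numpy()
        return self

    def predict(self, animal_ids: Sequence[int] | None = None) -> np.ndarray:
        """Posterior-mean breeding values, optionally for selected animals."""
        if not hasattr(self, "ebv_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        if animal_ids is None:
            return self.ebv_
        return self.ebv_[[self._index_of(a) for a in animal_ids]]

    def _index_of(self, animal_id: int) -> int:
        index = getattr(self.pedigree_, "index", None)
        if index is None:
            raise ValueError("no pedigree id map available")
        return index[animal_id]

    def diagnose(
        self,
        true_bv: np.ndarray | None = None,
        lags: Sequence[int] = diag.DEFAULT_LAGS,
        params: Sequence[str] | None = None,
    ) -> diag.DiagnosticsReport:
        """Sampling-quality report for the fitted chain."""
        if not hasattr(self, "samples_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        return diag.diagnose(self.samples_, lags=lags, true_bv=true_bv, params=params)

    def _run(self, data, factor):  # pragma: no cover - abstract
        raise NotImplementedError


class GibbsAnimalModel(BaseAnimalModel):
    """Single-site Gibbs sampler (flat variance priors)."""

    def __init__(self, n_iter=10000, burn_in=1000, seed=0, store_effects=False):
        super().__init__(n_iter=n_iter, burn_in=burn_in, seed=seed)
        self.store_effects = store_effects

    def _run(self, data, factor):
        return gibbs_run(
            data,
            factor,
            GibbsConfig(
                n_iter=self.n_iter,
                burn_in=self.burn_in,
                seed=self.seed,
                store_effects=self.store_effects,
            ),
        )


class HMCAnimalModel(BaseAnimalModel):
    """Hamiltonian Monte Carlo with fixed step size and path length."""

    def __init__(
        self, n_iter=10000, burn_in=1000, seed=0, epsilon=0.01, n_leapfrog=100
    ):
        super().__init__(n_iter=n_iter, burn_in=burn_in, seed=seed)
        self.epsilon = epsilon
        self.n_leapfrog = n_leapfrog

    def _run(self, data, factor):
        return hmc_run(
            data,
            factor,
            HMCConfig(
                epsilon=self.epsilon,
                n_leapfrog=self.n_leapfrog,
                n_iter=self.n_iter,
                burn_in=self.burn_in,
                seed=self.seed,
            ),
        )


class NUTSAnimalModel(BaseAnimalModel):
    """No-U-Turn Sampler with dual-averaging step-size adaptation.

    ``burn_in`` is the warm-up phase: epsilon adapts during those iterations
    and is frozen afterwards; warm-up draws are discarded.
    """

    def __init__(
        self,
        n_iter=10000,
        burn_in=1000,
        seed=0,
        delta=0.6,
        max_tree_depth=10,
        adapt_mass=False,
    ):
        super().__init__(n_iter=n_iter, burn_in=burn_in, seed=seed)
        self.delta = delta
        self.max_tree_depth = max_tree_depth
        self.adapt_mass = adapt_mass

    def _run(self, data, factor):
        return nuts_run(
            data,
            factor,
            NUTSConfig(
                n_iter=self.n_iter,
                warmup=self.burn_in,
                delta=self.delta,
                max_tree_depth=self.max_tree_depth,
                seed=self.seed,
                adapt_mass=self.adapt_mass,
            ),
        )


_ESTIMATORS = {
    "gibbs": GibbsAnimalModel,
    "hmc": HMCAnimalModel,
    "nuts": NUTSAnimalModel,
}


def make_estimator(name: str, **params) -> BaseAnimalModel:
    """Factory by sampler name: 'gibbs', 'hmc' or 'nuts'."""
    try:
        cls = _ESTIMATORS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown sampler '{name}'; choose from {sorted(_ESTIMATORS)}"
        ) from None
    return cls(**params)
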