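"""MCMC-quality diagnostics: ESS, autocorrelation, MCSE, skewness, EBV accuracy.

ESS follows the AR-spectral estimator of R's coda package
(``effectiveSize`` / ``spectrum0.ar``): fit an autoregressive model to the
chain with Yule-Walker/Levinson-Durbin, pick the order by AIC, and take the
spectral density at frequency zero ``s(0) = sigma2_pred / (1 - sum phi)^2``;
then ``ESS = n var(chain) / s(0)``.  By that convention ESS can exceed the
draw count for antithetic chains and is deliberately not capped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.tsa.stattools import acovf

DEFAULT_LAGS = (1, 5, 10, 50)


@dataclass
class SampleStore:
    """Post-burn-in draws of an MCMC run plus run metadata.

    ``draws`` has one row per stored iteration with columns for the fixed
    effects, both variances and the derived per-draw heritability ``h2``;
    ``ebv`` holds the running posterior mean of each animal's breeding value
    (the EBV), and ``effect_draws`` optionally the full breeding-value chain.
    """

    draws: pd.DataFrame
    ebv: np.ndarray | None = None
    effect_draws: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "h2" in self.draws:
            h2 = self.draws["h2"].to_numpy()
            if len(h2) and not ((h2 > 0) & (h2 < 1)).all():
                raise ValueError("stored h2 draws must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.draws)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(directory / "draws.csv", index=False)
        if self.ebv is not None:
            pd.DataFrame({"ebv": self.ebv}).to_csv(
                directory / "ebv.csv", index=False
            )
        (directory / "meta.json").write_text(
            json.dumps(self.meta, indent=2, default=_json_default)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "SampleStore":
        directory = Path(directory)
        draws = pd.read_csv(directory / "draws.csv")
        ebv_path = directory / "ebv.csv"
        ebv = (
            pd.read_csv(ebv_path)["ebv"].to_numpy() if ebv_path.exists() else None
        )
        meta = json.loads((directory / "meta.json").read_text())
        return cls(draws=draws, ebv=ebv, meta=meta)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def autocorr(chain: np.ndarray, lag: int) -> float:
    """Sample autocorrelation at ``lag`` (overall-mean centred, lag-0 normed)."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if lag >= n:
        raise ValueError(f"lag {lag} >= chain length {n}")
    x = x - x.mean()
    denom = x @ x
    if denom == 0.0:
        return np.nan
    return float(x[: n - lag] @ x[lag:] / denom)


def _ar_spectrum0(x: np.ndarray) -> float:
    """Spectral density at zero from a Yule-Walker AR fit, AIC order choice.

    Levinson-Durbin on the biased autocovariances; AIC(k) = n log(sigma2_k)
    + 2k with the same small-sample variance correction R's ``ar.yw`` applies.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    order_max = int(min(n - 1, np.floor(10.0 * np.log10(n))))
    gamma = acovf(x, demean=True, fft=True, nlag=order_max)
    sigma = gamma[0]
    if sigma <= 0:
        return 0.0
    phi = np.zeros(order_max + 1)
    best = (n * np.log(sigma * n / (n - 1)), sigma, 0.0)  # (aic, sigma2, sum phi)
    prev = np.zeros(order_max + 1)
    for k in range(1, order_max + 1):
        acc = gamma[k] - prev[1:k] @ gamma[1:k][::-1]
        refl = acc / sigma
        phi[1:k] = prev[1:k] - refl * prev[1:k][::-1]
        phi[k] = refl
        sigma = sigma * (1.0 - refl**2)
        if sigma <= 0:
            break
        var_pred = sigma * n / (n - k - 1) if n > k + 1 else sigma
        aic = n * np.log(var_pred) + 2.0 * k
        if aic < best[0]:
            best = (aic, var_pred, float(phi[1 : k + 1].sum()))
        prev[1 : k + 1] = phi[1 : k + 1]
    _, sigma2, phi_sum = best
    denom = (1.0 - phi_sum) ** 2
    return float(sigma2 / denom) if denom > 0 else np.inf


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS = n var(chain) / s(0), coda's AR-spectral convention (uncapped)."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for a stable ESS estimate (need >= 100)")
    v = x.var(ddof=1)
    if v == 0.0:
        return 0.0
    s0 = _ar_spectrum0(x)
    if s0 <= 0:
        return 0.0
    return float(n * v / s0)


def ess_batch_means(chain: np.ndarray, n_batches: int = 30) -> float:
    """Batch-means ESS, reported alongside the AR-spectral value as a
    robustness column (a different, coarser estimator)."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    b = n // n_batches
    if b < 2:
        raise ValueError("chain too short for batch means")
    means = x[: b * n_batches].reshape(n_batches, b).mean(axis=1)
    v = x.var(ddof=1)
    vb = means.var(ddof=1)
    if vb == 0.0:
        return 0.0
    return float(n * v / (b * vb))


def mcse(chain: np.ndarray) -> float:
    """Monte Carlo standard error: posterior SD / sqrt(ESS)."""
    ess = effective_sample_size(chain)
    if ess == 0.0:
        return np.nan
    return float(np.std(chain, ddof=1) / np.sqrt(ess))


def ebv_metrics(
    estimated: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Accuracy and unbiasedness of breeding-value estimates.

    Returns Pearson's r(truth, estimate) and the OLS slope of truth on the
    estimate (1 = unbiased prediction).
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if len(est) != len(tru) or len(est) < 3:
        raise ValueError("need >= 3 paired values")
    if est.std() == 0.0:
        return np.nan, np.nan
    r = scipy.stats.pearsonr(tru, est).statistic
    slope = np.cov(tru, est, ddof=1)[0, 1] / est.var(ddof=1)
    return float(r), float(slope)


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    skewness: float
    density_x: np.ndarray
    density_y: np.ndarray


def posterior_summary(chain: np.ndarray, n_grid: int = 200) -> PosteriorSummary:
    """Mean, SD, adjusted Fisher-Pearson skewness, and a KDE trace for plots."""
    x = np.asarray(chain, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 draws to summarize")
    grid = np.linspace(x.min(), x.max(), n_grid)
    if x.std() > 0:
        dens = scipy.stats.gaussian_kde(x)(grid)
    else:
        dens = np.zeros(n_grid)
    return PosteriorSummary(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=float(scipy.stats.skew(x, bias=False)),
        density_x=grid,
        density_y=dens,
    )


@dataclass
class DiagnosticsReport:
    """Per-parameter sampling-quality metrics for one SampleStore."""

    table: pd.DataFrame  # rows = parameters; ESS, acf lags, mean, sd, mcse, skew
    ebv_correlation: float | None = None
    ebv_regression: float | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "parameters": self.table.to_dict(orient="index"),
            "ebv_correlation": self.ebv_correlation,
            "ebv_regression": self.ebv_regression,
            "meta": self.meta,
        }
        return json.dumps(payload, indent=2, default=_json_default)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def diagnose(
    store: SampleStore,
    lags: Sequence[int] = DEFAULT_LAGS,
    true_bv: np.ndarray | None = None,
    params: Sequence[str] | None = None,
) -> DiagnosticsReport:
    """Full report: ESS (AR-spectral and batch-means), autocorrelation at the
    requested lags, posterior mean/SD, MCSE and skewness per parameter; EBV
    correlation/regression when true breeding values are supplied."""
    params = list(params) if params is not None else list(store.draws.columns)
    rows = {}
    for name in params:
        x = store.draws[name].to_numpy()
        if x.std() == 0.0:
            rows[name] = {"ess": 0.0, "ess_batch": 0.0}
            continue
        row = {
            "mean": x.mean(),
            "sd": x.std(ddof=1),
            "ess": effective_sample_size(x),
            "ess_batch": ess_batch_means(x),
            "mcse": mcse(x),
            "skewness": scipy.stats.skew(x, bias=False),
        }
        for lag in lags:
            row[f"lag{lag}"] = autocorr(x, lag)
        rows[name] = row
    corr = slope = None
    if true_bv is not None and store.ebv is not None:
        corr, slope = ebv_metrics(store.ebv, true_bv)
    return DiagnosticsReport(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        ebv_correlation=corr,
        ebv_regression=slope,
        meta=dict(store.meta),
    )


def plot_trace_density(
    store: SampleStore, param: str = "h2", path: str | Path | None = None
):
    """Trace plot and marginal posterior density for one parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = store.draws[param].to_numpy()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3))
    ax1.plot(x, lw=0.4)
    ax1.set_xlabel("iteration")
    ax1.set_ylabel(param)
    summ = posterior_summary(x)
    ax2.plot(summ.density_x, summ.density_y)
    ax2.set_xlabel(param)
    ax2.set_ylabel("density")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
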