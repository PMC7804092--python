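"""Rank-abundance distribution (RAD) models fitted by maximum likelihood.

Five classical models for the expected abundance a_r of the haplotype at
rank r (ranks 1..S, N total reads):

=================  ==================================  ==========
model              expected abundance a_r              parameters
=================  ==================================  ==========
broken stick       (N/S) * sum_{x=r..S} 1/x            none
preemption         N * alpha * (1-alpha)^(r-1)         alpha
lognormal          exp(mu_log + sigma_log * z_r)       mu_log, sigma_log
Zipf               N * p1 * r^gamma                    p1, gamma
Zipf-Mandelbrot    N * c * (r + beta)^gamma            c, beta, gamma
=================  ==================================  ==========

z_r is the standard-normal quantile at (S - r + 0.5)/S, the usual
plotting-position convention.  Counts are modelled as Poisson with mean
a_r, so the log-likelihood is sum_r [a_r observed] log-pmf terms; models
are compared by BIC = -2*loglik + k*ln(S) (ties broken by fewer
parameters).  The Zipf decay coefficient gamma is negative and p1 is the
fitted proportion of the most abundant haplotype.

Fitting uses deterministic multi-start optimisation: the one-dimensional
preemption profile is located on a coarse grid and polished by bounded
scalar search; lognormal and Zipf are Poisson GLMs (log link) and the
Zipf-Mandelbrot offset beta is profiled on top of the GLM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MODELS = ("brokenstick", "preemption", "lognormal", "zipf", "zipf_mandelbrot")
N_PARAMS = {"brokenstick": 0, "preemption": 1, "lognormal": 2,
            "zipf": 2, "zipf_mandelbrot": 3}

_LOGLIK_TOL = 1e-8


@dataclass(frozen=True)
class AbundanceVector:
    """Haplotype counts in descending rank order."""

    a: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.a, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("abundance vector must be a non-empty 1-D array")
        if (arr <= 0).any():
            raise ValueError("abundances must be positive counts")
        if (np.diff(arr) > 0).any():
            raise ValueError("abundances must be sorted in descending order")
        object.__setattr__(self, "a", arr)

    @property
    def N(self) -> int:
        return int(self.a.sum())

    @property
    def S(self) -> int:
        return int(self.a.size)


@dataclass
class RadFitResult:
    model: str
    params: dict[str, float]
    loglik: float
    k: int
    bic: float
    fitted: np.ndarray
    converged: bool = True
    message: str = ""
    delta_bic: float | None = None

    def __repr__(self) -> str:  # compact, for fit reports
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (f"RadFitResult({self.model}, {pars or 'no parameters'}, "
                f"loglik={self.loglik:.3f}, BIC={self.bic:.3f})")


def _lognormal_quantiles(S: int) -> np.ndarray:
    r = np.arange(1, S + 1)
    return stats.norm.ppf((S - r + 0.5) / S)


def expected_abundance(model: str, params: dict[str, float],
                       N: int, S: int) -> np.ndarray:
    """Expected abundances a_1..a_S for one model at given parameters."""
    r = np.arange(1, S + 1, dtype=float)
    if model == "brokenstick":
        return (N / S) * np.cumsum(1.0 / r[::-1])[::-1]
    if model == "preemption":
        alpha = params["alpha"]
        if not 0.0 < alpha < 1.0:
            raise ValueError("preemption alpha must be in (0, 1)")
        return N * alpha * (1.0 - alpha) ** (r - 1.0)
    if model == "lognormal":
        sigma = params["sigma_log"]
        if sigma <= 0:
            raise ValueError("lognormal sigma_log must be > 0")
        return np.exp(params["mu_log"] + sigma * _lognormal_quantiles(S))
    if model == "zipf":
        p1 = params["p1"]
        if not 0.0 < p1 <= 1.0:
            raise ValueError("zipf p1 must be in (0, 1]")
        return N * p1 * r ** params["gamma"]
    if model == "zipf_mandelbrot":
        beta = params["beta"]
        if beta <= -1.0:
            raise ValueError("zipf_mandelbrot beta must be > -1")
        return N * params["c"] * (r + beta) ** params["gamma"]
    raise ValueError(f"unknown model {model!r}")


def poisson_loglik(a: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood of counts ``a`` at means ``mu``."""
    mu = np.asarray(mu, dtype=float)
    if (mu <= 0).any() or not np.isfinite(mu).all():
        return -np.inf
    return float(np.sum(a * np.log(mu) - mu - gammaln(a + 1.0)))


def _bic(loglik: float, k: int, S: int) -> float:
    return -2.0 * loglik + k * np.log(S)


# -- individual model fits ---------------------------------------------------


def _fit_brokenstick(vec: AbundanceVector) -> RadFitResult:
    fitted = expected_abundance("brokenstick", {}, vec.N, vec.S)
    ll = poisson_loglik(vec.a, fitted)
    return RadFitResult("brokenstick", {}, ll, 0, _bic(ll, 0, vec.S), fitted)


def _fit_preemption(vec: AbundanceVector) -> RadFitResult:
    r = np.arange(1, vec.S + 1, dtype=float)
    a, N = vec.a, vec.N

    def nll(alpha: float) -> float:
        return -poisson_loglik(a, N * alpha * (1 - alpha) ** (r - 1))

    # coarse deterministic grid, then bounded polish inside the best bracket
    grid = np.linspace(1e-9, 1 - 1e-9, 4097)
    values = np.array([nll(x) for x in grid])
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    alpha = float(res.x) if res.fun <= values[i] else float(grid[i])
    fitted = expected_abundance("preemption", {"alpha": alpha}, N, vec.S)
    ll = poisson_loglik(a, fitted)
    return RadFitResult("preemption", {"alpha": alpha}, ll, 1,
                        _bic(ll, 1, vec.S), fitted, converged=res.success)


def _poisson_glm(a: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Poisson GLM of counts on [1, x]; returns (coef, loglik, converged)."""
    exog = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(a, exog, family=sm.families.Poisson()).fit(
                maxiter=200, tol=_LOGLIK_TOL)
        except Exception as exc:  # perfect separation, singular design...
            logger.debug("GLM failed: %s", exc)
            return np.array([np.nan, np.nan]), -np.inf, False
    mu = res.mu
    return res.params, poisson_loglik(a, mu), bool(res.converged)


def _fit_lognormal(vec: AbundanceVector) -> RadFitResult:
    z = _lognormal_quantiles(vec.S)
    coef, ll, conv = _poisson_glm(vec.a, z)
    params = {"mu_log": float(coef[0]), "sigma_log": float(coef[1])}
    fitted = np.exp(coef[0] + coef[1] * z)
    ok = conv and params["sigma_log"] > 0
    return RadFitResult("lognormal", params, ll, 2, _bic(ll, 2, vec.S), fitted,
                        converged=ok,
                        message="" if ok else "sigma_log <= 0 or no convergence")


def _fit_zipf(vec: AbundanceVector) -> RadFitResult:
    r = np.arange(1, vec.S + 1, dtype=float)
    coef, ll, conv = _poisson_glm(vec.a, np.log(r))
    p1 = float(np.exp(coef[0]) / vec.N)
    gamma = float(coef[1])
    params = {"p1": p1, "gamma": gamma}
    fitted = np.exp(coef[0]) * r ** gamma
    ok = conv and gamma < 0 and 0 < p1 <= 1
    return RadFitResult("zipf", params, ll, 2, _bic(ll, 2, vec.S), fitted,
                        converged=ok,
                        message="" if ok else "parameters left the Zipf domain")


def _fit_zipf_mandelbrot(vec: AbundanceVector) -> RadFitResult:
    r = np.arange(1, vec.S + 1, dtype=float)
    a, N, S = vec.a, vec.N, vec.S

    def profile_nll(log1p_beta: float) -> float:
        beta = np.expm1(log1p_beta)
        _, ll, _ = _poisson_glm(a, np.log(r + beta))
        return -ll

    # deterministic multi-start over the beta profile (beta = 0 recovers
    # the plain Zipf solution, so the ZM likelihood never falls below it)
    starts = np.log1p(np.array([0.0, 0.1, 1.0, 5.0, 20.0, 100.0]))
    best_t, best_val = None, np.inf
    for t in starts:
        v = profile_nll(t)
        if v < best_val:
            best_t, best_val = t, v
    span = np.log1p(1000.0)
    res = optimize.minimize_scalar(
        profile_nll, bounds=(max(best_t - 2.0, np.log1p(-0.999)),
                             min(best_t + 2.0, span)),
        method="bounded", options={"xatol": 1e-10})
    t = float(res.x) if res.fun <= best_val else float(best_t)
    beta = float(np.expm1(t))
    coef, ll, conv = _poisson_glm(a, np.log(r + beta))
    # compute in log space: large beta drives the intercept to extremes
    with np.errstate(over="ignore"):
        params = {"c": float(np.exp(coef[0] - np.log(N))), "beta": beta,
                  "gamma": float(coef[1])}
    fitted = np.exp(coef[0] + params["gamma"] * np.log(r + beta))
    return RadFitResult("zipf_mandelbrot", params, ll, 3, _bic(ll, 3, S),
                        fitted, converged=conv)


_FITTERS = {
    "brokenstick": _fit_brokenstick,
    "preemption": _fit_preemption,
    "lognormal": _fit_lognormal,
    "zipf": _fit_zipf,
    "zipf_mandelbrot": _fit_zipf_mandelbrot,
}


def fit_model(model: str, a: AbundanceVector | np.ndarray) -> RadFitResult:
    """Maximum-likelihood fit of one RAD model to a descending count vector.

    Requires more ranks than free parameters (S >= k+1).  Failure to
    converge is flagged on the result, not raised.
    """
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    vec = a if isinstance(a, AbundanceVector) else AbundanceVector(np.asarray(a))
    k = N_PARAMS[model]
    if vec.S < k + 1:
        raise ValueError(f"{model} needs at least {k + 1} ranks, got {vec.S}")
    return _FITTERS[model](vec)


def select_model(a: AbundanceVector | np.ndarray,
                 models: tuple[str, ...] = MODELS) -> list[RadFitResult]:
    """Fit all RAD models and rank them by BIC (ascending).

    BIC ties are broken in favour of the model with fewer parameters.
    A model whose fit fails is kept in the ranking with loglik = -inf and
    ``converged=False`` rather than aborting the comparison.
    """
    vec = a if isinstance(a, AbundanceVector) else AbundanceVector(np.asarray(a))
    if vec.S < 4:
        raise ValueError("model comparison needs at least 4 ranks")
    results: list[RadFitResult] = []
    for model in models:
        try:
            results.append(fit_model(model, vec))
        except Exception as exc:
            logger.warning("fit of %s failed: %s", model, exc)
            results.append(RadFitResult(model, {}, -np.inf, N_PARAMS[model],
                                        np.inf, np.array([]), converged=False,
                                        message=str(exc)))
    results.sort(key=lambda res: (res.bic, res.k))
    best = results[0].bic
    for res in results:
        res.delta_bic = res.bic - best
    return results


def write_fit_report(results: list[RadFitResult], path) -> None:
    """Tabular fit report: model, parameters, loglik, k, BIC, delta BIC."""
    with open(path, "w") as fh:
        fh.write("model\tparams\tloglik\tk\tbic\tdelta_bic\tconverged\n")
        for res in results:
            pars = ";".join(f"{k}={v:.6g}" for k, v in res.params.items())
            fh.write(f"{res.model}\t{pars}\t{res.loglik:.6f}\t{res.k}\t"
                     f"{res.bic:.6f}\t{res.delta_bic:.6f}\t{res.converged}\n")


def write_fitted_values(results: list[RadFitResult], path) -> None:
    """Per-rank fitted abundances of every model, for log-ordinate plots."""
    ok = [res for res in results if res.fitted.size]
    S = max(res.fitted.size for res in ok)
    with open(path, "w") as fh:
        fh.write("rank\t" + "\t".join(res.model for res in ok) + "\n")
        for r in range(S):
            cells = [f"{res.fitted[r]:.6g}" if r < res.fitted.size else ""
                     for res in ok]
            fh.write(f"{r + 1}\t" + "\t".join(cells) + "\n")
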