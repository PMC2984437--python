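"""Confidence intervals for the rate lambda.

Three routes, all operating on the (possibly 1-lfdr-weighted) truncated-f1
log-likelihood of a :class:`~polyarch.lambda_fit.LambdaFit`:

* ``ci_info`` — normal approximation with the observed Fisher information,
  the negative second derivative of the log-likelihood at the MLE, computed
  by Richardson-refined central differences.  The lower bound may come out
  negative for very flat likelihoods and is reported as-is with a warning.
* ``ci_mlrt`` — inversion of the maximum likelihood ratio test: the interval
  collects every lambda whose likelihood drop from the MLE stays below the
  chi-square(1) critical value.
* ``ci_param_bootstrap`` — parametric bootstrap: z-values are redrawn from
  the truncated convolution density at the fitted lambda via inverse-CDF
  sampling and refitted; percentile interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm

from .effect_size import TraitDesign
from .errors import EstimationError
from .lambda_fit import LAMBDA_BRACKET, LambdaFit, _TruncF1Loglik, fit_f1

__all__ = ["ConfidenceInterval", "ci_info", "ci_mlrt", "ci_param_bootstrap"]


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = 0.95
    method: str = "info"
    weighted: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _observed_information(fit: LambdaFit, h_rel: float = 1e-3) -> float:
    """Observed Fisher information -d2 loglik / d lambda2 at the MLE, by
    central second difference with one Richardson refinement."""
    lam = fit.lambda_hat
    ll = fit.loglik_at

    def second_diff(h: float) -> float:
        return (ll(lam + h) - 2.0 * ll(lam) + ll(lam - h)) / h**2

    h = h_rel * lam
    d2_h = second_diff(h)
    d2_h2 = second_diff(h / 2.0)
    d2 = (4.0 * d2_h2 - d2_h) / 3.0
    return -d2


def ci_info(fit: LambdaFit, level: float = 0.95) -> ConfidenceInterval:
    """Normal-approximation CI from the observed Fisher information."""
    info = _observed_information(fit)
    if not np.isfinite(info) or info <= 0:
        raise EstimationError(
            f"non-positive curvature at lambda_hat={fit.lambda_hat:.4g}"
        )
    se = 1.0 / np.sqrt(info)
    q = norm.ppf(0.5 + level / 2.0)
    lower = fit.lambda_hat - q * se
    upper = fit.lambda_hat + q * se
    if lower < 0:
        warnings.warn(
            f"information CI lower bound is negative ({lower:.1f}); "
            "reported unclipped"
        )
    return ConfidenceInterval(lower, upper, level, "info", fit.weights_used)


def ci_mlrt(fit: LambdaFit, level: float = 0.95) -> ConfidenceInterval:
    """CI by inverting the maximum likelihood ratio test."""
    lam = fit.lambda_hat
    ll_max = fit.loglik_at(lam)
    target = chi2.ppf(level, df=1) / 2.0

    def drop(l: float) -> float:
        return ll_max - fit.loglik_at(l) - target

    # lower endpoint: walk down until the drop exceeds the critical value
    lo = lam
    step = 0.5
    lower_bracket = None
    for _ in range(60):
        cand = max(lam * step, LAMBDA_BRACKET[0] * 1e-3)
        if drop(cand) > 0:
            lower_bracket = (cand, lo)
            break
        lo = cand
        step *= 0.5
    if lower_bracket is None:
        raise EstimationError("could not bracket the lower MLRT endpoint")
    lower = float(optimize.brentq(drop, *lower_bracket, xtol=1e-6))

    hi = lam
    factor = 2.0
    upper_bracket = None
    for _ in range(60):
        cand = lam * factor
        if drop(cand) > 0:
            upper_bracket = (hi, cand)
            break
        hi = cand
        factor *= 2.0
    if upper_bracket is None:
        raise EstimationError("could not bracket the upper MLRT endpoint")
    upper = float(optimize.brentq(drop, *upper_bracket, xtol=1e-6))
    return ConfidenceInterval(lower, upper, level, "mlrt", fit.weights_used)


def ci_param_bootstrap(
    fit: LambdaFit,
    design: TraitDesign,
    n_obs: int,
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
    n_grid: int = 2048,
    grid_span: float = 15.0,
) -> ConfidenceInterval:
    """Percentile CI from a parametric bootstrap of the truncated f1 fit.

    z-values are sampled by inverting the tabulated CDF of the truncated
    convolution density at the fitted lambda (random signs), and lambda is
    refitted on each of the B replicates.
    """
    rng = np.random.default_rng(seed)
    zc = fit.z_crit
    grid = np.linspace(zc, zc + grid_span, n_grid)
    helper = _TruncF1Loglik(grid, np.ones_like(grid), design, zc, shape=fit.shape)
    # unnormalised truncated density on the |z| grid at lambda_hat
    from scipy.stats import gamma as gamma_dist

    pdf_vg = gamma_dist.pdf(helper.vg_d, fit.shape, scale=1.0 / fit.lambda_hat)
    pw = pdf_vg * helper.dvg_d * helper.trapz_w
    dens = helper.kernel @ pw
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    if cdf[-1] <= 0:
        raise EstimationError("degenerate truncated density in bootstrap")
    cdf /= cdf[-1]
    # strictly increasing for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    grid_k, cdf_k = grid[keep], cdf[keep]

    estimates = []
    failures = 0
    for _ in range(B):
        u = rng.uniform(size=n_obs)
        z_abs = np.interp(u, cdf_k, grid_k)
        z = z_abs * rng.choice([-1.0, 1.0], n_obs)
        try:
            refit = fit_f1(z, None, design, zc, shape=fit.shape)
            estimates.append(refit.lambda_hat)
        except EstimationError:
            failures += 1
    if failures > 0.1 * B:
        raise EstimationError(f"bootstrap unstable: {failures}/{B} refits failed")
    alpha = 1.0 - level
    lower, upper = np.quantile(estimates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ConfidenceInterval(
        float(lower), float(upper), level, "param_bootstrap", fit.weights_used
    )
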