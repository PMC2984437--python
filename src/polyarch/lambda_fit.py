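"""Estimating the rate of the effect-size distribution.

The package's model: the liability variance explained (Vg) of every
susceptibility variant in the genome follows an exponential distribution
with rate lambda (mean 1/lambda), or more generally a gamma distribution
with fixed shape k and rate lambda (mean k/lambda).  The total number of
susceptibility variants is then heritability / mean(Vg).

Only variants passing a significance threshold are observed, so the density
of a *detected* Vg is the population density multiplied by detection power
and renormalised:

    f_det(v) = pwr(v) * f_lambda(v) / int_0^vmax pwr(u) * f_lambda(u) du.

Two fitting routes are provided:

* **moment fitting** of observed (possibly winner's-curse-corrected,
  possibly 1-lfdr-weighted) Vg values: solve for the lambda whose
  theoretical mean under the power-weighted density equals the observed
  (weighted) mean.  For the exponential family this coincides exactly with
  maximum likelihood under f_det.
* **truncated-density fitting of z-values**: the non-null z is the true
  noncentrality delta (a deterministic transform of Vg) plus standard normal
  noise, so its density f1(z) is a convolution; significant z-values follow
  f1 truncated at +-z_crit and lambda is estimated by (weighted) maximum
  likelihood.  No winner's-curse correction is needed on this route because
  the likelihood already conditions on selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .effect_size import NcpMap, TraitDesign, get_ncp_map, zcrit_from_fwer
from .errors import ArgumentError, ConfigurationError, EmptySelectionError, EstimationError
from .local_fdr import LfdrModel, fit_lfdr, weights_from_lfdr, zcut_from_fdr
from .winners_curse import CORRECTIONS, SelectedStatistic

__all__ = [
    "EffectDistribution",
    "LambdaFit",
    "VMAX",
    "LAMBDA_BRACKET",
    "detected_vg_density",
    "fit_moment",
    "delta_density",
    "f1_density",
    "fit_f1",
    "fit_gamma_scale",
    "n_variants",
    "run_estimator",
    "ESTIMATOR_NAMES",
    "EstimationContext",
]

#: upper integration bound for Vg — far beyond any plausible single-locus Vg
VMAX = 0.5
#: search bracket for the rate lambda
LAMBDA_BRACKET = (1.0, 1e6)


@dataclass(frozen=True)
class EffectDistribution:
    """Distribution of per-variant Vg: exponential or gamma with rate
    ``rate`` (per unit Vg) and shape ``shape`` (1 for exponential)."""

    family: str = "exponential"
    rate: float = 1000.0
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "gamma"):
            raise ArgumentError(f"unknown family {self.family!r}")
        if self.rate <= 0 or self.shape <= 0:
            raise ArgumentError("rate and shape must be positive")
        if self.family == "exponential" and self.shape != 1.0:
            raise ArgumentError("exponential family requires shape = 1")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def pdf(self, v):
        return gamma_dist.pdf(np.asarray(v, dtype=float), self.shape, scale=1.0 / self.rate)


@dataclass
class LambdaFit:
    """Result of one lambda estimation."""

    lambda_hat: float
    loglik_at: Callable[[float], float] = field(repr=False)
    n_markers_used: int = 0
    estimator_name: str = ""
    z_crit: float = float("nan")
    weights_used: bool = False
    shape: float = 1.0
    design: TraitDesign | None = field(default=None, repr=False)

    @property
    def distribution(self) -> EffectDistribution:
        family = "exponential" if self.shape == 1.0 else "gamma"
        return EffectDistribution(family, self.lambda_hat, self.shape)


# ---------------------------------------------------------------------------
# quadrature over Vg

def _vg_nodes(vmax: float = VMAX, per_segment: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes over (0, vmax], geometrically refined
    toward 0 where the exponential density concentrates for large lambda."""
    edges = np.concatenate([[0.0], np.geomspace(1e-8, vmax, 24)])
    x, w = np.polynomial.legendre.leggauss(per_segment)
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        nodes.append(0.5 * (b - a) * x + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * w)
    return np.concatenate(nodes), np.concatenate(weights)


_VG_NODES, _VG_WEIGHTS = _vg_nodes()


def _power_at_nodes(ncp_map: NcpMap, z_crit: float) -> np.ndarray:
    return np.asarray(ncp_map.power(np.clip(_VG_NODES, 0.0, ncp_map.vg_max), z_crit))


def detected_vg_density(v, lam: float, design: TraitDesign, z_crit: float):
    """Density of the Vg of a *detected* variant: power times the
    exponential density, renormalised over (0, vmax]."""
    if lam <= 0:
        raise ArgumentError("lambda must be positive")
    ncp_map = get_ncp_map(design)
    v = np.asarray(v, dtype=float)
    pwr_nodes = _power_at_nodes(ncp_map, z_crit)
    norm_const = float(np.sum(_VG_WEIGHTS * pwr_nodes * lam * np.exp(-lam * _VG_NODES)))
    pwr_v = np.asarray(ncp_map.power(np.clip(v, 0.0, ncp_map.vg_max), z_crit))
    return pwr_v * lam * np.exp(-lam * v) / norm_const


def _power_weighted_mean(lam: float, pwr_nodes: np.ndarray, shape: float = 1.0) -> float:
    """Theoretical mean of Vg under the power-weighted gamma density."""
    dens = gamma_dist.pdf(_VG_NODES, shape, scale=1.0 / lam)
    num = float(np.sum(_VG_WEIGHTS * _VG_NODES * pwr_nodes * dens))
    den = float(np.sum(_VG_WEIGHTS * pwr_nodes * dens))
    return num / den


def fit_moment(
    vg_values: np.ndarray,
    weights: np.ndarray | None,
    design: TraitDesign,
    z_crit: float,
    estimator_name: str = "moment",
) -> LambdaFit:
    """Method-of-moments / ML fit of lambda to observed Vg values.

    Solves  E_lambda[Vg | detected] = weighted mean of the observed Vg
    by bracketing root search; for the exponential family the root is also
    the zero of the power-adjusted ML score.
    """
    vg_values = np.asarray(vg_values, dtype=float)
    w = np.ones_like(vg_values) if weights is None else np.asarray(weights, dtype=float)
    if vg_values.size == 0:
        raise EmptySelectionError("no Vg values to fit")
    if w.sum() <= 0:
        raise EstimationError("weights sum to zero")
    target = float(np.sum(w * vg_values) / np.sum(w))
    if target <= 0:
        raise EstimationError("weighted mean Vg is not positive")

    ncp_map = get_ncp_map(design)
    pwr_nodes = _power_at_nodes(ncp_map, z_crit)

    def gap(lam: float) -> float:
        return _power_weighted_mean(lam, pwr_nodes) - target

    lo, hi = LAMBDA_BRACKET
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise EstimationError(
            f"moment equation has no root in [{lo:g}, {hi:g}]: "
            f"gap({lo:g})={g_lo:.3g}, gap({hi:g})={g_hi:.3g}"
        )
    lam_hat = float(optimize.brentq(gap, lo, hi, xtol=1e-6, rtol=1e-12))

    def loglik(lam: float) -> float:
        # power-adjusted exponential log-likelihood, dropping the
        # lambda-free log pwr(v_i) terms
        dens = lam * np.exp(-lam * _VG_NODES)
        norm_const = float(np.sum(_VG_WEIGHTS * pwr_nodes * dens))
        return float(np.sum(w * (np.log(lam) - lam * vg_values - np.log(norm_const))))

    return LambdaFit(
        lambda_hat=lam_hat,
        loglik_at=loglik,
        n_markers_used=int(vg_values.size),
        estimator_name=estimator_name,
        z_crit=z_crit,
        weights_used=weights is not None,
        design=design,
    )


# ---------------------------------------------------------------------------
# the convolution density f1(z)

def delta_density(delta, lam: float, design: TraitDesign, shape: float = 1.0):
    """Density of the noncentrality delta when Vg ~ gamma(shape, rate=lam),
    symmetrised over the sign of delta."""
    if lam <= 0:
        raise ArgumentError("lambda must be positive")
    ncp_map = get_ncp_map(design)
    d = np.abs(np.asarray(delta, dtype=float))
    vg = np.asarray(ncp_map.vg(d))
    dvg = np.asarray(ncp_map.dvg_ddelta(np.maximum(d, 1e-12)))
    return 0.5 * gamma_dist.pdf(vg, shape, scale=1.0 / lam) * dvg


def f1_density(z, lam: float, design: TraitDesign, shape: float = 1.0):
    """Marginal density of a non-null observed z: the convolution of the
    noncentrality density with standard normal noise."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.empty_like(z)
    for i, zi in enumerate(z):
        hi = abs(zi) + 8.0
        grid = np.linspace(-hi, hi, 4001)
        fd = delta_density(grid, lam, design, shape)
        out[i] = np.trapezoid(fd * norm.pdf(zi - grid), grid)
    return out if out.size > 1 else float(out[0])


class _TruncF1Loglik:
    """Precomputed machinery for the truncated-f1 (weighted) log-likelihood.

    The integral over delta is shared by every likelihood evaluation, so the
    normal kernels phi(z_i -+ delta_j) and the tail probabilities
    P(|Z| > z_crit | delta_j) are tabulated once on a fixed delta grid;
    each evaluation then only reweights the grid by the Vg density at the
    candidate lambda.
    """

    def __init__(
        self,
        z_abs: np.ndarray,
        weights: np.ndarray,
        design: TraitDesign,
        z_crit: float,
        shape: float = 1.0,
        n_delta: int = 2000,
        delta_pad: float = 8.0,
    ):
        self.z_abs = np.asarray(z_abs, dtype=float)
        self.w = np.asarray(weights, dtype=float)
        self.shape = shape
        ncp_map = get_ncp_map(design)
        d_hi = min(float(self.z_abs.max(initial=z_crit)) + delta_pad, ncp_map.delta_max)
        d = np.linspace(0.0, d_hi, n_delta)
        self.d = d
        # evaluate Vg and its derivative a hair off delta = 0: for gamma
        # shapes < 1 the Vg density has an integrable singularity there and
        # the product pdf(vg) * dvg/ddelta would evaluate as inf * 0
        d_eval = np.maximum(d, 0.5 * d[1])
        self.vg_d = np.asarray(ncp_map.vg(d_eval))
        self.dvg_d = np.asarray(ncp_map.dvg_ddelta(d_eval))
        # kernel of the symmetrised convolution and the selection tail
        self.kernel = 0.5 * (
            norm.pdf(self.z_abs[:, None] - d[None, :])
            + norm.pdf(self.z_abs[:, None] + d[None, :])
        )
        self.tail = ndtr(d - z_crit) + ndtr(-d - z_crit)
        self.trapz_w = np.gradient(d)

    def __call__(self, lam: float) -> float:
        p = gamma_dist.pdf(self.vg_d, self.shape, scale=1.0 / lam) * self.dvg_d
        pw = p * self.trapz_w
        f1 = self.kernel @ pw  # f1(z_i), up to the common delta normalisation
        trunc_mass = float(self.tail @ pw)
        if trunc_mass <= 0 or np.any(f1 <= 0):
            return -np.inf
        return float(np.sum(self.w * (np.log(f1) - np.log(trunc_mass))))


def fit_f1(
    z_values: np.ndarray,
    weights: np.ndarray | None,
    design: TraitDesign,
    z_crit: float,
    shape: float = 1.0,
    estimator_name: str = "fitfZ.conv",
) -> LambdaFit:
    """Maximum (weighted) likelihood fit of lambda to significant z-values
    under the truncated convolution density."""
    z_values = np.asarray(z_values, dtype=float)
    if z_values.size == 0:
        raise EmptySelectionError("no z-values to fit")
    z_abs = np.abs(z_values)
    if np.any(z_abs < z_crit - 1e-9):
        raise ArgumentError("all |z| must be at or above the truncation point z_crit")
    w = np.ones_like(z_abs) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise EstimationError("weights sum to zero")

    loglik = _TruncF1Loglik(z_abs, w, design, z_crit, shape=shape)
    lo, hi = np.log(LAMBDA_BRACKET[0]), np.log(LAMBDA_BRACKET[1])
    res = optimize.minimize_scalar(
        lambda t: -loglik(float(np.exp(t))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success or not np.isfinite(res.fun):
        raise EstimationError("truncated-f1 likelihood maximisation failed")
    lam_hat = float(np.exp(res.x))

    return LambdaFit(
        lambda_hat=lam_hat,
        loglik_at=lambda lam: loglik(float(lam)),
        n_markers_used=int(z_abs.size),
        estimator_name=estimator_name,
        z_crit=z_crit,
        weights_used=weights is not None,
        shape=shape,
        design=design,
    )


def fit_gamma_scale(
    z_values: np.ndarray,
    weights: np.ndarray | None,
    shape: float,
    design: TraitDesign,
    z_crit: float,
) -> LambdaFit:
    """Fit the rate of a gamma Vg distribution with fixed shape by the same
    truncated-f1 machinery (shape=1 reduces exactly to the exponential)."""
    return fit_f1(
        z_values, weights, design, z_crit, shape=shape,
        estimator_name=f"gamma(shape={shape:g})",
    )


def n_variants(dist: EffectDistribution, heritability: float, rounded: bool = True):
    """Estimated number of susceptibility variants: heritability divided by
    the mean per-variant Vg (half-up rounding for reporting)."""
    if not 0 < heritability <= 1:
        raise ArgumentError("heritability must lie in (0, 1]")
    value = heritability / dist.mean
    return int(math.floor(value + 0.5)) if rounded else value


# ---------------------------------------------------------------------------
# the named estimators

#: estimator name -> (selection mode, correction, fitting route)
_ESTIMATOR_TABLE: dict[str, tuple[str, str, str]] = {
    "Bonf": ("bonf", "none", "moment"),
    "Bonf.corr": ("bonf", "average", "moment"),
    "Bonf.corr1": ("bonf", "mle", "moment"),
    "Bonf.corr2": ("bonf", "postmean", "moment"),
    "Bonf.corr.med": ("bonf", "median", "moment"),
    "Bonf.corr.MSEmedian": ("bonf", "msemedian", "moment"),
    "Bonf.fitfZ.conv": ("bonf", "none", "f1"),
    "truncfdr": ("fdr", "none", "moment"),
    "truncfdr.corr": ("fdr", "average", "moment"),
    "truncfdr.corr1": ("fdr", "mle", "moment"),
    "truncfdr.corr2": ("fdr", "postmean", "moment"),
    "truncfdr.corr.median": ("fdr", "median", "moment"),
    "truncfdr.corr.MSEmedian": ("fdr", "msemedian", "moment"),
    "truncfdr.fitfZ.conv": ("fdr", "none", "f1"),
}

ESTIMATOR_NAMES: tuple[str, ...] = tuple(_ESTIMATOR_TABLE)


@dataclass
class EstimationContext:
    """Shared per-dataset state (selection thresholds, lfdr model) so that
    several estimators can run on the same scan without refitting."""

    z: np.ndarray
    design: TraitDesign
    fdr_cutoff: float = 0.3
    lfdr_model: LfdrModel | None = None
    _fdr_state: tuple | None = None

    def bonferroni(self) -> tuple[np.ndarray, np.ndarray, float]:
        zc = zcrit_from_fwer(self.design.fwer_alpha, self.design.n_markers)
        sel = np.abs(self.z) >= zc
        if not np.any(sel):
            raise EmptySelectionError("no marker passes the Bonferroni threshold")
        return self.z[sel], np.ones(int(sel.sum())), zc

    def fdr(self) -> tuple[np.ndarray, np.ndarray, float]:
        if self._fdr_state is None:
            if self.lfdr_model is None:
                self.lfdr_model = fit_lfdr(self.z)
            zc = zcut_from_fdr(self.lfdr_model, self.fdr_cutoff)
            weights, sel = weights_from_lfdr(self.lfdr_model, self.z, self.fdr_cutoff)
            # guard against one-sided wiggles below the common cutoff
            sel &= np.abs(self.z) >= zc
            if not np.any(sel):
                raise EmptySelectionError("no marker passes the lfdr threshold")
            self._fdr_state = (self.z[sel], weights[sel], zc)
        return self._fdr_state


def run_estimator(
    name: str,
    z_values: np.ndarray | None = None,
    design: TraitDesign | None = None,
    fdr_cutoff: float = 0.3,
    context: EstimationContext | None = None,
) -> LambdaFit:
    """Run one of the named estimators on a full vector of z-statistics.

    Selection (Bonferroni or local-fdr threshold), optional winner's-curse
    correction of each selected z, and fitting (moment fit of Vg or
    truncated-f1 ML of z) are dispatched from the estimator name.
    """
    if name not in _ESTIMATOR_TABLE:
        raise ConfigurationError(
            f"unknown estimator {name!r}; valid names: {', '.join(ESTIMATOR_NAMES)}"
        )
    if context is None:
        if z_values is None or design is None:
            raise ConfigurationError("provide either a context or (z_values, design)")
        context = EstimationContext(np.asarray(z_values, float), design, fdr_cutoff)
    design = context.design

    mode, correction, route = _ESTIMATOR_TABLE[name]
    z_sel, weights, zc = context.bonferroni() if mode == "bonf" else context.fdr()

    if route == "f1":
        fit = fit_f1(
            z_sel,
            weights if mode == "fdr" else None,
            design,
            zc,
            estimator_name=name,
        )
        return fit

    # moment route: correct each selected z, convert to Vg, fit
    z_abs = np.abs(z_sel)
    if correction == "none":
        mu = z_abs
    else:
        fn = CORRECTIONS[correction]
        # the MSE-median weight se^2 / (se^2 + (beta - beta_med)^2) is
        # invariant to the coefficient scale (beta = z * se), so on the
        # z-scale any positive se gives the identical estimate
        se_i = 1.0 if correction == "msemedian" else None
        mu = np.empty_like(z_abs)
        for i, za in enumerate(z_abs):
            mu[i] = fn(SelectedStatistic(float(za), zc, se_i))
    ncp_map = get_ncp_map(design)
    vg = np.asarray(ncp_map.vg(np.abs(mu)))
    fit = fit_moment(
        vg,
        weights if mode == "fdr" else None,
        design,
        zc,
        estimator_name=name,
    )
    return fit
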