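"""Local false discovery rates from the full vector of GWAS z-statistics.

Implements Efron's empirical-Bayes recipe: the marginal density f(z) of all
z-statistics is estimated by fitting a Poisson GLM with a smooth spline
basis to binned counts; the local fdr is then

    lfdr(z) = Pr(H0 | z) = pi0 * f0(z) / f(z),

clipped to [0, 1], where f0 is the null density (theoretical N(0,1) by
default, or an empirical normal fitted by central matching) and pi0 the null
proportion.  1 - lfdr(z) is the posterior probability that the marker is
truly associated and serves as a fitting weight downstream.

A monotonicity repair (isotonic regression of lfdr against |z|, per side)
guarantees that thresholding the lfdr selects a single contiguous |z| region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

from .errors import EmptySelectionError, EstimationError

__all__ = ["LfdrModel", "fit_lfdr", "zcut_from_fdr", "weights_from_lfdr"]


@dataclass
class LfdrModel:
    """Fitted marginal density and local fdr curve on a z grid."""

    pi0: float
    null_mean: float
    null_sd: float
    grid: np.ndarray
    f_grid: np.ndarray  # marginal density estimate on the grid
    lfdr_grid: np.ndarray  # isotonic-repaired lfdr on the grid
    _interp: interp1d = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self._interp = interp1d(
            self.grid,
            self.lfdr_grid,
            bounds_error=False,
            fill_value=(self.lfdr_grid[0], self.lfdr_grid[-1]),
        )

    def lfdr(self, z):
        """Local fdr evaluated at arbitrary z (linear interpolation)."""
        return np.clip(self._interp(np.asarray(z, dtype=float)), 0.0, 1.0)

    def f0(self, z):
        return norm.pdf(np.asarray(z, dtype=float), self.null_mean, self.null_sd)


def _poly_basis(x: np.ndarray, lo: float, hi: float, df: int) -> np.ndarray:
    """Chebyshev polynomial design matrix (degree df, plus intercept) on
    [lo, hi].  A global polynomial basis keeps the Poisson IRLS fit
    well-conditioned even where tail bins are empty, which local spline
    bases do not."""
    t = np.clip(2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return np.polynomial.chebyshev.chebvander(t, df)


def _fit_poisson(X: np.ndarray, y: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Poisson log-linear fit (Lindsey's method) by direct maximisation of
    the convex likelihood; IRLS-free so empty tail bins cannot derail it."""
    beta0 = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]

    def nll(beta):
        eta = np.clip(X @ beta + offset, -300.0, 40.0)
        mu = np.exp(eta)
        grad = X.T @ (mu - y)
        return float(np.sum(mu) - float(y @ eta)), grad

    res = minimize(nll, beta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12})
    if not np.all(np.isfinite(res.x)):
        raise EstimationError("Poisson density fit diverged")
    return res.x


def fit_lfdr(
    z_values: np.ndarray,
    bins: int = 120,
    df: int = 7,
    null: str = "theoretical",
    pi0_window: float = 1.6,
    n_grid: int = 1024,
) -> LfdrModel:
    """Fit the marginal z density and the local fdr curve.

    Parameters
    ----------
    z_values : array
        All z-statistics of the scan (not only the significant ones); the
        method needs the full histogram to locate the null bulk.
    bins, df : int
        Histogram bins and spline degrees of freedom of the Poisson fit
        (the defaults mirror the classical locfdr settings).
    null : {"theoretical", "empirical"}
        Theoretical N(0,1) null, or an empirical normal null whose mean/sd
        are recovered by central matching (a quadratic fit to log f around 0).
    pi0_window : float
        Half-width of the central |z| window used for pi0 (and empirical
        null) estimation.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 1000:
        warnings.warn(f"only {z.size} z-values; lfdr estimates will be unstable")
    if z.size < 2 or np.ptp(z) < 1e-12:
        raise EstimationError("degenerate z-values: cannot estimate the marginal density")

    lo, hi = float(z.min()), float(z.max())
    counts, edges = np.histogram(z, bins=bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    X = _poly_basis(mids, lo, hi, df)
    offset = np.full(bins, np.log(z.size * width))
    params = _fit_poisson(X, counts.astype(float), offset)

    grid = np.linspace(lo, hi, n_grid)
    eta = np.clip(_poly_basis(grid, lo, hi, df) @ params, -300.0, 50.0)
    f_grid = np.exp(eta)

    central = np.abs(grid) <= pi0_window
    if not np.any(central):
        raise EstimationError("no central z-values: cannot estimate pi0")

    if null == "theoretical":
        mean0, sd0 = 0.0, 1.0
        # under sparse alternatives f(0) ~= pi0 * phi(0): match at the centre
        i0 = int(np.argmin(np.abs(grid)))
        pi0 = float(min(1.0, f_grid[i0] / norm.pdf(grid[i0])))
    elif null == "empirical":
        # central matching: log f(z) ~ quadratic around 0 recovers the
        # empirical null's mean, sd, and pi0
        zc, lf = grid[central], np.log(f_grid[central])
        a2, a1, a0 = np.polyfit(zc, lf, 2)
        if a2 >= 0:
            raise EstimationError("central log-density not concave; empirical null failed")
        sd0 = float(np.sqrt(-0.5 / a2))
        mean0 = float(a1 * sd0**2)
        log_pi0 = a0 + mean0**2 / (2 * sd0**2) + np.log(sd0 * np.sqrt(2 * np.pi))
        pi0 = float(min(1.0, np.exp(log_pi0)))
    else:
        raise EstimationError(f"unknown null type {null!r}")

    raw = np.clip(pi0 * norm.pdf(grid, mean0, sd0) / f_grid, 0.0, 1.0)

    # monotone repair: lfdr nonincreasing in |z| on each side of the mode
    centre = mean0
    lfdr_grid = raw.copy()
    right = grid >= centre
    iso = IsotonicRegression(increasing=False)
    lfdr_grid[right] = iso.fit_transform(grid[right], raw[right])
    left = grid <= centre
    iso = IsotonicRegression(increasing=True)
    lfdr_grid[left] = iso.fit_transform(grid[left], raw[left])
    lfdr_grid = np.clip(lfdr_grid, 0.0, 1.0)

    return LfdrModel(
        pi0=pi0,
        null_mean=mean0,
        null_sd=sd0,
        grid=grid,
        f_grid=f_grid,
        lfdr_grid=lfdr_grid,
    )


def zcut_from_fdr(model: LfdrModel, fdr_threshold: float) -> float:
    """Smallest |z| at which the (two-sided) lfdr falls to the threshold.

    This cutoff plays the role of the selection threshold z_crit when markers
    are included by local fdr instead of Bonferroni: power and conditional
    likelihoods downstream are evaluated at this |z| cutoff.
    """
    if fdr_threshold >= 1.0:
        return 0.0
    amax = float(max(abs(model.grid[0]), abs(model.grid[-1])))
    a_grid = np.linspace(0.0, amax, 2048)
    best = np.minimum(model.lfdr(a_grid), model.lfdr(-a_grid))
    ok = best <= fdr_threshold
    if not np.any(ok):
        raise EmptySelectionError(
            f"no |z| attains lfdr <= {fdr_threshold}; selection is empty"
        )
    return float(a_grid[np.argmax(ok)])


def weights_from_lfdr(
    model: LfdrModel, z_values: np.ndarray, fdr_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker weights 1 - lfdr(z) for markers with lfdr <= threshold.

    Returns ``(weights, selected)``; excluded markers get weight 0 and
    ``selected`` False.
    """
    lf = model.lfdr(z_values)
    selected = lf <= fdr_threshold
    weights = np.where(selected, 1.0 - lf, 0.0)
    return weights, selected
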