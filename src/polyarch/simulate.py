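"""Synthetic GWAS z-statistic generator and estimator-evaluation harnesses.

The generative model mirrors the study conditions used throughout the
package's validation: each scan consists of ``n_markers`` independent
z-statistics, a fraction ``frac_null`` of which are null N(0,1).  Each
non-null marker draws its liability variance explained from
Vg ~ Exponential(rate lambda_true), maps it to the noncentrality delta of
the design (risk allele frequency fixed at 0.5), picks a random sign, and
observes z ~ N(+-delta, 1).

Defaults: 100,000 markers, 99.5% null, prevalence 0.001, local-fdr cutoff
0.3, genome-wide FWER 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effect_size import TraitDesign, get_ncp_map
from .errors import EstimationError
from .lambda_fit import EstimationContext, fit_f1, run_estimator
from .uncertainty import ci_info, ci_mlrt

__all__ = [
    "SimulationScenario",
    "EvaluationResult",
    "simulate_z",
    "evaluate_estimators",
    "coverage_study",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One simulation condition."""

    lambda_true: float = 1000.0
    n_cases: int = 3500
    n_controls: int = 3500
    n_markers: int = 100_000
    frac_null: float = 0.995
    prevalence: float = 0.001
    fdr_cutoff: float = 0.3
    fwer_alpha: float = 0.05
    n_reps: int = 300
    seed: int = 0
    randomize_sign: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.frac_null < 1.0:
            raise ValueError("frac_null must lie in (0, 1)")

    @property
    def design(self) -> TraitDesign:
        return TraitDesign(
            "binary",
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            prevalence=self.prevalence,
            n_markers=self.n_markers,
            fwer_alpha=self.fwer_alpha,
        )


@dataclass
class EvaluationResult:
    """Aggregated simulation output: one tidy table plus failure counts."""

    table: pd.DataFrame
    n_reps: int
    failures: dict = field(default_factory=dict)


def simulate_z(scenario: SimulationScenario, rng: np.random.Generator | int) -> np.ndarray:
    """One replicate of the generative model; reproducible given the rng."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = scenario.n_markers
    n_alt = m - int(round(m * scenario.frac_null))
    z = rng.standard_normal(m)
    if n_alt > 0:
        vg = rng.exponential(1.0 / scenario.lambda_true, n_alt)
        ncp_map = get_ncp_map(scenario.design)
        delta = np.asarray(ncp_map.delta(np.clip(vg, 0.0, ncp_map.vg_max)))
        if scenario.randomize_sign:
            delta = delta * rng.choice([-1.0, 1.0], n_alt)
        z[:n_alt] += delta  # noise already drawn; non-nulls are N(delta, 1)
    return z


def _rep_rngs(scenario: SimulationScenario, n_reps: int) -> list[np.random.Generator]:
    """Independent, order-insensitive substreams: replicate i always sees
    the same stream for a given master seed."""
    ss = np.random.SeedSequence(scenario.seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_reps)]


def evaluate_estimators(
    scenarios: list[SimulationScenario],
    estimator_names: list[str],
    n_reps: int | None = None,
) -> EvaluationResult:
    """RMSE / bias / SD / mean of the named estimators over replicates.

    Failed replicates (estimation errors) are excluded per estimator and
    counted; a scenario is flagged invalid if more than 20% of an
    estimator's replicates fail.
    """
    rows, failures = [], {}
    reps_used = 0
    for scen in scenarios:
        reps = scen.n_reps if n_reps is None else n_reps
        reps_used = max(reps_used, reps)
        estimates: dict[str, list[float]] = {n: [] for n in estimator_names}
        fails = {n: 0 for n in estimator_names}
        for rng in _rep_rngs(scen, reps):
            z = simulate_z(scen, rng)
            ctx = EstimationContext(z, scen.design, scen.fdr_cutoff)
            for name in estimator_names:
                try:
                    estimates[name].append(run_estimator(name, context=ctx).lambda_hat)
                except EstimationError:
                    fails[name] += 1
        for name in estimator_names:
            est = np.asarray(estimates[name])
            if est.size == 0:
                raise EstimationError(f"all replicates failed for {name}")
            err = est - scen.lambda_true
            rows.append(
                {
                    "lambda_true": scen.lambda_true,
                    "n_cases": scen.n_cases,
                    "estimator": name,
                    "n_ok": est.size,
                    "n_failed": fails[name],
                    "mean": est.mean(),
                    "bias": err.mean(),
                    "sd": est.std(ddof=1) if est.size > 1 else np.nan,
                    "rmse": float(np.sqrt(np.mean(err**2))),
                    "valid": fails[name] <= 0.2 * reps,
                }
            )
        failures[(scen.lambda_true, scen.n_cases)] = fails
    return EvaluationResult(pd.DataFrame(rows), reps_used, failures)


_CI_METHODS = ("info", "info_weighted", "mlrt", "mlrt_weighted")


def coverage_study(
    scenario: SimulationScenario,
    ci_methods: tuple[str, ...] = _CI_METHODS,
    n_reps: int | None = None,
    level: float = 0.95,
) -> EvaluationResult:
    """Empirical coverage and width of the analytic CIs for lambda.

    Per replicate the truncated-f1 likelihood is maximised on the
    Bonferroni-selected markers (unweighted) and on the lfdr-selected
    markers with 1-lfdr weights (the lfdr model is refitted in every
    replicate); Fisher-information and MLRT intervals are recorded for each.
    """
    reps = scenario.n_reps if n_reps is None else n_reps
    records: dict[str, list[tuple[bool, float]]] = {m: [] for m in ci_methods}
    fails = {m: 0 for m in ci_methods}
    for rng in _rep_rngs(scenario, reps):
        z = simulate_z(scenario, rng)
        ctx = EstimationContext(z, scenario.design, scenario.fdr_cutoff)
        fits = {}
        try:
            z_sel, _, zc = ctx.bonferroni()
            fits[False] = fit_f1(z_sel, None, scenario.design, zc)
        except EstimationError:
            fits[False] = None
        try:
            z_sel, w, zc = ctx.fdr()
            fits[True] = fit_f1(z_sel, w, scenario.design, zc)
        except EstimationError:
            fits[True] = None
        for method in ci_methods:
            weighted = method.endswith("_weighted")
            fit = fits[weighted]
            if fit is None:
                fails[method] += 1
                continue
            try:
                ci_fn = ci_info if method.startswith("info") else ci_mlrt
                ci = ci_fn(fit, level=level)
            except EstimationError:
                fails[method] += 1
                continue
            covered = ci.lower <= scenario.lambda_true <= ci.upper
            records[method].append((covered, ci.upper - ci.lower))
    rows = []
    for method in ci_methods:
        rec = records[method]
        if not rec:
            raise EstimationError(f"all replicates failed for CI method {method}")
        covered = np.array([r[0] for r in rec], dtype=float)
        widths = np.array([r[1] for r in rec])
        rows.append(
            {
                "lambda_true": scenario.lambda_true,
                "method": method,
                "level": level,
                "n_ok": len(rec),
                "n_failed": fails[method],
                "coverage": covered.mean(),
                "mean_width": widths.mean(),
                "sd_width": widths.std(ddof=1) if widths.size > 1 else np.nan,
                "valid": fails[method] <= 0.2 * reps,
            }
        )
    return EvaluationResult(pd.DataFrame(rows), reps, {scenario.lambda_true: fails})
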