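"""From a genome scan to the number of susceptibility variants.

Simulates one full GWAS (100,000 z-statistics; 0.5% truly associated with
Vg ~ Exponential(rate 1000)), then estimates the rate lambda with the two
best-performing estimators and converts it to a variant count.
"""

import numpy as np

from polyarch import (
    EstimationContext,
    SimulationScenario,
    ci_info,
    ci_mlrt,
    n_variants,
    run_estimator,
    simulate_z,
)

scenario = SimulationScenario(lambda_true=1000.0, seed=1)
z = simulate_z(scenario, np.random.default_rng(1))
print(f"Simulated scan: {z.size} markers, true lambda = {scenario.lambda_true:g}")

ctx = EstimationContext(z, scenario.design, fdr_cutoff=0.3)
heritability = 0.55

for name in ("Bonf", "truncfdr.corr.median", "truncfdr.fitfZ.conv"):
    fit = run_estimator(name, context=ctx)
    line = (
        f"{name:22s} lambda = {fit.lambda_hat:7.1f}  "
        f"({fit.n_markers_used} markers, |z| > {fit.z_crit:.2f})"
    )
    if name.endswith("fitfZ.conv"):
        ci_i, ci_m = ci_info(fit), ci_mlrt(fit)
        line += f"  info CI [{ci_i.lower:.0f}, {ci_i.upper:.0f}]"
        line += f"  MLRT CI [{ci_m.lower:.0f}, {ci_m.upper:.0f}]"
    print(line)
    print(
        f"{'':22s} -> with h^2 = {heritability}: "
        f"~{n_variants(fit.distribution, heritability)} susceptibility variants"
    )

print()
print("The uncorrected Bonferroni fit underestimates lambda (winner's curse")
print("inflates the observed effect sizes); the fdr-weighted median-corrected")
print("and truncated-convolution fits land near the truth, so the implied")
print("variant count (h^2 x lambda for the exponential model) is reliable.")
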