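"""Reading GWAS summary statistics, distance pruning, and the estimation
pipeline behind the command-line interface."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .effect_size import TraitDesign, zcrit_from_fwer
from .errors import ConfigurationError, EmptySelectionError
from .lambda_fit import (
    ESTIMATOR_NAMES,
    EstimationContext,
    n_variants,
    run_estimator,
)
from .uncertainty import ci_info, ci_mlrt

logger = logging.getLogger("polyarch")

__all__ = [
    "read_summary_stats",
    "prune_by_distance",
    "estimate_command",
    "DEFAULT_COLUMNS",
]

#: default column-name mapping; override any entry via ``format_spec``
DEFAULT_COLUMNS = {
    "marker_id": "snp",
    "chrom": "chr",
    "pos_bp": "pos",
    "z": "z",
    "p": "p",
    "direction": "direction",
    "raf": "raf",
}


def read_summary_stats(
    path,
    format_spec: dict | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics table into canonical columns.

    Exactly one of a z column or a two-sided p column (with optional
    direction column) must be present.  p-values are converted to |z| via
    the two-sided inverse normal; the sign comes from the direction column
    (+/- or a signed number) or defaults to +.  Rows with missing or
    non-numeric statistics are dropped with a logged count.
    """
    cols = dict(DEFAULT_COLUMNS)
    if format_spec:
        cols.update(format_spec)
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip() for c in df.columns]

    have_z = cols["z"] in df.columns
    have_p = cols["p"] in df.columns
    if not have_z and not have_p:
        raise ConfigurationError(
            f"missing mandatory statistic column: need {cols['z']!r} or {cols['p']!r}"
        )

    out = pd.DataFrame()
    for key in ("marker_id", "chrom"):
        if cols[key] in df.columns:
            out[key] = df[cols[key]].astype(str)
    if cols["pos_bp"] in df.columns:
        out["pos_bp"] = pd.to_numeric(df[cols["pos_bp"]], errors="coerce")
    if cols["raf"] in df.columns:
        out["raf"] = pd.to_numeric(df[cols["raf"]], errors="coerce")

    n_in = len(df)
    if have_z:
        out["z"] = pd.to_numeric(df[cols["z"]], errors="coerce")
    else:
        p = pd.to_numeric(df[cols["p"]], errors="coerce")
        p = p.where((p > 0) | (p.isna()), np.nan)  # p == 0 is unusable
        z_abs = -ndtri(np.clip(p / 2.0, 1e-320, 0.5))
        sign = np.ones(len(df))
        if cols["direction"] in df.columns:
            direction = df[cols["direction"]]
            if direction.dtype == object:
                sign = np.where(direction.astype(str).str.strip() == "-", -1.0, 1.0)
            else:
                sign = np.sign(pd.to_numeric(direction, errors="coerce")).fillna(1.0)
                sign = np.where(sign == 0, 1.0, sign)
        out["z"] = z_abs * sign
        out.loc[p == 1.0, "z"] = 0.0

    bad = ~np.isfinite(out["z"])
    if bad.any():
        logger.warning("dropped %d of %d rows with invalid statistics", bad.sum(), n_in)
        out = out[~bad]
    return out.reset_index(drop=True)


def prune_by_distance(table: pd.DataFrame, min_separation_bp: int = 30_000) -> pd.DataFrame:
    """Greedy distance pruning within chromosomes.

    Repeatedly keep the marker with the largest |z| (ties: smallest
    position) and drop every other marker strictly closer than
    ``min_separation_bp``; markers exactly at the separation survive.
    """
    if "pos_bp" not in table.columns or "chrom" not in table.columns:
        raise ConfigurationError("pruning requires chrom and pos_bp columns")
    keep_idx = []
    for _, sub in table.groupby("chrom", sort=False):
        order = sub.assign(_abs=sub["z"].abs()).sort_values(
            ["_abs", "pos_bp"], ascending=[False, True], kind="mergesort"
        )
        kept_pos: list[float] = []
        for idx, row in order.iterrows():
            pos = row["pos_bp"]
            arr = np.asarray(kept_pos)
            if arr.size and np.any(np.abs(arr - pos) < min_separation_bp):
                continue
            kept_pos.append(pos)
            keep_idx.append(idx)
    return table.loc[sorted(keep_idx)].reset_index(drop=True)


def estimate_command(config: dict) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline from a configuration mapping.

    Steps: read -> optional prune -> fit lfdr / select -> run the requested
    estimators -> CIs for the truncated-f1 fits -> number of variants at the
    configured heritability.  Returns (report table, run manifest).
    """
    dcfg = config.get("design", {})
    design = TraitDesign(
        trait_kind=dcfg.get("trait_kind", "binary"),
        n_cases=int(dcfg.get("n_cases", 0)),
        n_controls=int(dcfg.get("n_controls", 0)),
        n_total=int(dcfg.get("n_total", 0)),
        prevalence=float(dcfg.get("prevalence", 0.01)),
        fixed_raf=float(dcfg.get("fixed_raf", 0.5)),
        n_markers=int(dcfg.get("n_markers", 100_000)),
        fwer_alpha=float(dcfg.get("fwer_alpha", 0.05)),
    )
    estimators = config.get("estimators", ["truncfdr.corr.median", "truncfdr.fitfZ.conv"])
    for name in estimators:
        if name not in ESTIMATOR_NAMES:
            raise ConfigurationError(f"unknown estimator {name!r} in config")

    table = read_summary_stats(
        config["input"], config.get("columns"), config.get("sep")
    )
    logger.info("read %d markers", len(table))
    prune_bp = config.get("prune_bp")
    if prune_bp:
        before = len(table)
        table = prune_by_distance(table, int(prune_bp))
        logger.info("pruned %d -> %d markers (>= %d bp apart)", before, len(table), prune_bp)

    z = table["z"].to_numpy()
    fdr_cutoff = float(config.get("fdr_cutoff", 0.3))
    ctx = EstimationContext(z, design, fdr_cutoff)
    heritability = config.get("heritability")
    ci_level = float(config.get("ci_level", 0.95))

    rows = []
    for name in estimators:
        fit = run_estimator(name, context=ctx)
        row = {
            "estimator": name,
            "lambda_hat": fit.lambda_hat,
            "n_markers_used": fit.n_markers_used,
            "z_crit": fit.z_crit,
            "weighted": fit.weights_used,
        }
        if name.endswith("fitfZ.conv"):
            for label, fn in (("info", ci_info), ("mlrt", ci_mlrt)):
                try:
                    ci = fn(fit, level=ci_level)
                    row[f"ci_{label}_lower"] = ci.lower
                    row[f"ci_{label}_upper"] = ci.upper
                except Exception as exc:
                    logger.warning("CI %s failed for %s: %s", label, name, exc)
        if heritability is not None:
            row["n_variants"] = n_variants(fit.distribution, float(heritability))
        rows.append(row)
        logger.info(
            "%s: lambda=%.1f on %d markers (z_crit=%.3f)",
            name, fit.lambda_hat, fit.n_markers_used, fit.z_crit,
        )
    report = pd.DataFrame(rows)
    manifest = {
        "config": {k: v for k, v in config.items() if k != "columns"},
        "design": asdict(design),
        "n_markers_input": int(len(table)),
        "bonferroni_z": zcrit_from_fwer(design.fwer_alpha, design.n_markers),
        "estimators": list(estimators),
    }
    return report, manifest


def write_report(report: pd.DataFrame, manifest: dict, out_prefix: str) -> None:
    report.to_csv(f"{out_prefix}.tsv", sep="\t", index=False)
    with open(f"{out_prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
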