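"""End-to-end orchestration: convert → describe → pool → screen → compare.

``run_pipeline`` takes a sample table and a site registry and produces, per
community: descriptive statistics on both δ¹⁸O scales and for δ¹³C, robust
spread measures, a normality result, the locality-window outlier screen
(only for communities passing the sample-size gate), drinking-water
estimates with reference-water verdicts, and the breastfeeding screen.
Sites sharing a ``pooling_group`` are tested for poolability and screened as
one population when the test accepts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import conversions as conv
from .data_model import (
    OutlierReport,
    SiteGroup,
    ToothSample,
    ValidationReport,
    attach_samples,
    round_report,
    validate_dataset,
)
from .locality import LocalityScreen
from .provenance import (
    BreastfeedingReport,
    WaterCompatibilityVerdict,
    breastfeeding_screen,
    compare_reference_water,
    estimate_drinking_water,
)
from .site_statistics import pool_sites, poolability_tests, shapiro_wilk, site_summary


@dataclass
class RunOptions:
    alpha: float = 0.05
    min_n: int = 9
    quantile_type: int = 7
    methods: tuple[str, ...] = ("two_sd", "mad", "tukey_iqr", "two_permil")
    mad_variant: str = "auto"
    pool: bool = True
    seed: Optional[int] = None  # provenance only; the pipeline itself is deterministic


@dataclass
class RunResult:
    options: RunOptions
    validation: ValidationReport
    sites: dict[str, SiteGroup]
    summaries: dict[str, dict]
    normality: dict[str, object]
    pooling: dict[str, object]
    pooled_groups: dict[str, SiteGroup]
    outliers: dict[str, OutlierReport]
    gate_skipped: list[str] = field(default_factory=list)
    water_verdicts: dict[str, WaterCompatibilityVerdict] = field(default_factory=dict)
    breastfeeding: dict[str, BreastfeedingReport] = field(default_factory=dict)


def _screen_unit(unit: SiteGroup, opts: RunOptions) -> Optional[OutlierReport]:
    values = [conv.vpdb_to_vsmow(v) for v in unit.d18O_vpdb()]
    if len(values) < opts.min_n:
        return None
    screen = LocalityScreen(
        methods=opts.methods,
        mad_variant=opts.mad_variant,
        alpha=opts.alpha,
        min_n=opts.min_n,
        quantile_type=opts.quantile_type,
    ).fit(values)
    return screen.report(values, [s.sample_id for s in unit.samples], site_code=unit.code)


def run_pipeline(
    samples: Sequence[ToothSample],
    registry: Mapping[str, SiteGroup],
    options: Optional[RunOptions] = None,
) -> RunResult:
    """Run the full analysis; deterministic given inputs and options."""
    opts = options or RunOptions()
    validation = validate_dataset(samples, registry)
    sites = attach_samples(samples, registry)

    summaries = {c: site_summary(s, opts.quantile_type) for c, s in sites.items() if s.n}
    normality = {}
    for code, site in sites.items():
        vals = site.d18O_vpdb()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            normality[code] = shapiro_wilk(vals)

    # poolability and pooling
    pooling: dict[str, object] = {}
    pooled_groups: dict[str, SiteGroup] = {}
    if opts.pool:
        tags = sorted({s.pooling_group for s in sites.values() if s.pooling_group})
        for tag in tags:
            members = {c: s for c, s in sites.items() if s.pooling_group == tag and s.n}
            if len(members) < 2:
                continue
            groups = {c: [conv.vpdb_to_vsmow(v) for v in s.d18O_vpdb()]
                      for c, s in members.items()}
            report = poolability_tests(groups, alpha=opts.alpha)
            pooling[tag] = report
            if report.pooled:
                pooled_groups[tag] = pool_sites(sites, tag, poolability=report)

    # locality screening: pooled units replace their member sites
    pooled_members = {c for g in pooled_groups.values() for c in (g.member_codes or [])}
    outliers: dict[str, OutlierReport] = {}
    gate_skipped: list[str] = []
    units = [s for c, s in sites.items() if s.n and c not in pooled_members]
    units.extend(pooled_groups.values())
    for unit in units:
        rep = _screen_unit(unit, opts)
        if rep is None:
            gate_skipped.append(unit.code)
        else:
            outliers[unit.code] = rep

    # drinking water + reference verdicts; breastfeeding screen
    water: dict[str, WaterCompatibilityVerdict] = {}
    bf: dict[str, BreastfeedingReport] = {}
    for code, site in {**{c: s for c, s in sites.items() if s.n}, **pooled_groups}.items():
        est = estimate_drinking_water(site)
        water[code] = compare_reference_water(est, site.reference_water_range)
        if any(s.tooth_generation == "permanent" for s in site.samples):
            bf[code] = breastfeeding_screen(site)

    return RunResult(
        options=opts,
        validation=validation,
        sites=sites,
        summaries=summaries,
        normality=normality,
        pooling=pooling,
        pooled_groups=pooled_groups,
        outliers=outliers,
        gate_skipped=gate_skipped,
        water_verdicts=water,
        breastfeeding=bf,
    )


# ---------------------------------------------------------------------------
# exports


def _stats_row(code: str, summary: dict) -> dict:
    row: dict = {"site": code, "n": summary["n"]}
    for scale, label in (("d18O_vpdb", "d18O_vpdb"), ("d18O_vsmow", "d18O_vsmow"),
                         ("d13C", "d13C")):
        st = summary.get(scale)
        for stat in ("min", "max", "mean", "sd", "median", "q1", "q3"):
            val = getattr(st, stat) if st else float("nan")
            row[f"{label}_{stat}"] = val
            row[f"{label}_{stat}_1dp"] = round_report(val)
    return row


def export_reports(result: RunResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the five machine-readable artifacts; returns name → path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    stats_cols = ["site", "n"] + [
        f"{label}_{stat}{suffix}"
        for label in ("d18O_vpdb", "d18O_vsmow", "d13C")
        for stat in ("min", "max", "mean", "sd", "median", "q1", "q3")
        for suffix in ("", "_1dp")
    ]
    stats_df = pd.DataFrame(
        [_stats_row(c, s) for c, s in sorted(result.summaries.items())], columns=stats_cols
    )
    paths["site_stats"] = out / "site_stats.tsv"
    stats_df.to_csv(paths["site_stats"], sep="\t", index=False)

    spread_rows = []
    units = dict(result.summaries)
    for tag, grp in result.pooled_groups.items():
        units[tag] = site_summary(grp, result.options.quantile_type)
    for code, summary in sorted(units.items()):
        sp = summary.get("spread_vsmow")
        if sp is None:
            continue
        spread_rows.append(
            {
                "site": code,
                "iqr": sp.iqr, "iqr_1dp": round_report(sp.iqr),
                "mad_raw": sp.mad_raw, "mad_raw_1dp": round_report(sp.mad_raw),
                "mad_norm": sp.mad_norm, "mad_norm_1dp": round_report(sp.mad_norm),
                "mad_q3": sp.mad_q3, "mad_q3_1dp": round_report(sp.mad_q3),
            }
        )
    paths["spread"] = out / "spread.tsv"
    spread_cols = ["site", "iqr", "iqr_1dp", "mad_raw", "mad_raw_1dp",
                   "mad_norm", "mad_norm_1dp", "mad_q3", "mad_q3_1dp"]
    pd.DataFrame(spread_rows, columns=spread_cols).to_csv(paths["spread"], sep="\t", index=False)

    outlier_doc = {}
    for code, rep in result.outliers.items():
        outlier_doc[code] = {
            "methods": rep.methods,
            "windows": {
                m: {"center": w.center, "lower": w.lower, "upper": w.upper}
                for m, w in rep.windows.items()
            },
            "samples": [
                {
                    "sample_id": r.sample_id,
                    "value": r.value,
                    "flags": dict(r.flags),
                    "boundary": dict(r.boundary),
                    "consensus_count": r.consensus_count,
                    "is_consensus_outlier": r.is_consensus_outlier,
                }
                for r in rep.rows
            ],
        }
    paths["outliers"] = out / "outliers.json"
    paths["outliers"].write_text(json.dumps(
        {"gate_skipped": result.gate_skipped, "sites": outlier_doc}, indent=2, sort_keys=True))

    verdict_rows = [
        {
            "site": code,
            "mean_dw": v.mean_dw, "mean_dw_1dp": round_report(v.mean_dw),
            "sd_dw": v.sd_dw, "sd_dw_1dp": round_report(v.sd_dw),
            "ref_lower": v.reference_range[0] if v.reference_range else "",
            "ref_upper": v.reference_range[1] if v.reference_range else "",
            "verdict": v.verdict,
        }
        for code, v in sorted(result.water_verdicts.items())
    ]
    paths["water_verdicts"] = out / "water_verdicts.tsv"
    verdict_cols = ["site", "mean_dw", "mean_dw_1dp", "sd_dw", "sd_dw_1dp",
                    "ref_lower", "ref_upper", "verdict"]
    pd.DataFrame(verdict_rows, columns=verdict_cols).to_csv(
        paths["water_verdicts"], sep="\t", index=False)

    log = {
        "constants": {
            "vpdb_to_vsmow_slope": conv.VPDB_TO_VSMOW_SLOPE,
            "vpdb_to_vsmow_intercept": conv.VPDB_TO_VSMOW_INTERCEPT,
            "dw_slope": conv.DW_SLOPE,
            "dw_intercept": conv.DW_INTERCEPT,
        },
        "options": {
            "alpha": result.options.alpha,
            "min_n": result.options.min_n,
            "quantile_type": result.options.quantile_type,
            "methods": list(result.options.methods),
            "mad_variant": result.options.mad_variant,
            "pool": result.options.pool,
            "seed": result.options.seed,
        },
        "validation": {
            "n_findings": len(result.validation),
            "n_errors": len(result.validation.errors),
        },
        "pooling": {
            tag: {"test": r.test, "statistic": r.statistic, "p": r.p,
                  "groups": r.groups, "pooled": r.pooled}
            for tag, r in result.pooling.items()
        },
        "normality": {
            code: {"W": r.W, "p": r.p, "n": r.n} for code, r in result.normality.items()
        },
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    return paths
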