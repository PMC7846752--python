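"""Provenance plausibility checks beyond the statistical outlier screen.

Three independent diagnostics:

* reference-water compatibility — does a community's estimated drinking-water
  δ¹⁸O (mean ± 1 sd) overlap the modern local water range?
* breastfeeding screen — do deciduous teeth show the systematic 0.5–2‰ ¹⁸O
  enrichment expected when enamel mineralised before weaning?
* diagenetic mixing — do carbonate values fall on a mixing line between the
  biogenic population and a secondary-carbonate endmember (e.g. a cave
  speleothem), suggesting post-mortem alteration of δ¹³C?

All three are diagnostic only: they flag and quantify, never exclude samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conversions import vpdb_to_vsmow, vsmow_to_drinking_water
from .data_model import DrinkingWaterEstimate, SiteGroup, ToothSample


@dataclass(frozen=True)
class MixingEndmember:
    """A secondary-carbonate composition, e.g. one speleothem."""

    label: str
    d13C: float  # ‰ V-PDB
    d18O: float  # ‰ V-SMOW

    def __post_init__(self):
        if not (np.isfinite(self.d13C) and np.isfinite(self.d18O)):
            raise ValueError("endmember coordinates must be finite")


@dataclass(frozen=True)
class WaterCompatibilityVerdict:
    site_code: str
    mean_dw: float
    sd_dw: float
    reference_range: Optional[tuple[float, float]]
    verdict: str  # consistent | above | below | no_reference


@dataclass
class BreastfeedingReport:
    site_code: str
    n_deciduous: int
    n_permanent: int
    deciduous_values: list[float]
    permanent_min: Optional[float]
    permanent_max: Optional[float]
    permanent_median: Optional[float]
    mean_offset: Optional[float]  # deciduous mean − permanent mean, ‰
    systematic_enrichment: bool


def estimate_drinking_water(site: SiteGroup) -> DrinkingWaterEstimate:
    """Per-sample and site-level drinking-water δ¹⁸O from carbonate V-PDB values."""
    per_sample = {
        s.sample_id: vsmow_to_drinking_water(vpdb_to_vsmow(s.d18O_ca_vpdb))
        for s in site.samples
    }
    vals = np.array(list(per_sample.values()))
    if vals.size == 0:
        raise ValueError(f"site {site.code} has no samples")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return DrinkingWaterEstimate(site_code=site.code, per_sample_dw=per_sample,
                                 mean_dw=float(vals.mean()), sd_dw=sd)


def compare_reference_water(
    est: DrinkingWaterEstimate, ref: Optional[tuple[float, float]]
) -> WaterCompatibilityVerdict:
    """Verdict on overlap of mean ± 1 sd with the local reference range.

    The interval comparison is closed: touching the range at a single point
    counts as consistent. Reversed reference bounds are normalized first.
    """
    if ref is None:
        return WaterCompatibilityVerdict(est.site_code, est.mean_dw, est.sd_dw,
                                         None, "no_reference")
    lo, hi = min(ref), max(ref)
    sd = est.sd_dw if np.isfinite(est.sd_dw) else 0.0
    band = (est.mean_dw - sd, est.mean_dw + sd)
    if band[1] >= lo and band[0] <= hi:
        verdict = "consistent"
    elif est.mean_dw < lo:
        verdict = "below"
    else:
        verdict = "above"
    return WaterCompatibilityVerdict(est.site_code, est.mean_dw, est.sd_dw,
                                     (lo, hi), verdict)


def breastfeeding_screen(site: SiteGroup) -> BreastfeedingReport:
    """Compare deciduous-teeth δ¹⁸O against the permanent-teeth range.

    Systematic pre-weaning enrichment is flagged only when the deciduous−
    permanent mean offset falls in the expected 0.5–2.0‰ window AND every
    deciduous value exceeds the permanent median; isolated high values do not
    qualify.
    """
    perm = [s.d18O_ca_vpdb for s in site.samples if s.tooth_generation == "permanent"]
    dec = [s.d18O_ca_vpdb for s in site.samples if s.tooth_generation == "deciduous"]
    if not perm:
        raise ValueError(f"site {site.code}: breastfeeding screen needs >= 1 permanent tooth")
    if not dec:
        return BreastfeedingReport(site.code, 0, len(perm), [], min(perm), max(perm),
                                   float(np.median(perm)), None, False)
    offset = float(np.mean(dec) - np.mean(perm))
    perm_median = float(np.median(perm))
    flag = 0.5 <= offset <= 2.0 and all(d > perm_median for d in dec)
    return BreastfeedingReport(
        site_code=site.code,
        n_deciduous=len(dec),
        n_permanent=len(perm),
        deciduous_values=list(dec),
        permanent_min=min(perm),
        permanent_max=max(perm),
        permanent_median=perm_median,
        mean_offset=offset,
        systematic_enrichment=flag,
    )


def mixing_check(
    samples: Sequence[ToothSample],
    end_a: MixingEndmember,
    end_b: MixingEndmember,
) -> pd.DataFrame:
    """Two-endmember mixing diagnostics per sample.

    The mixing fraction f is solved on the δ¹³C axis alone (the axis diagenesis
    perturbs most): f = (δ¹³C − δ¹³C_b) / (δ¹³C_a − δ¹³C_b), so f = 1 at
    endmember A and f = 0 at endmember B. The off-line distance is the
    perpendicular distance to the A–B segment in coordinates standardized by
    the segment's per-axis span, making it invariant to affine rescaling of
    the δ¹⁸O axis. Samples without δ¹³C are skipped.
    """
    if end_a.d13C == end_b.d13C:
        raise ValueError("endmembers coincide in δ¹³C; mixing fraction is unidentifiable")
    span_c = end_a.d13C - end_b.d13C
    span_o = end_a.d18O - end_b.d18O
    records = []
    for s in samples:
        if s.d13C_ca_vpdb is None:
            continue
        d18O_vsmow = vpdb_to_vsmow(s.d18O_ca_vpdb)
        u = (s.d13C_ca_vpdb - end_b.d13C) / span_c
        v = (d18O_vsmow - end_b.d18O) / span_o if span_o != 0 else 0.0
        # distance from (u, v) to the unit segment (0,0)–(1,1)
        t = np.clip((u + v) / 2.0, 0.0, 1.0)
        dist = float(np.hypot(u - t, v - t))
        records.append(
            {
                "sample_id": s.sample_id,
                "d13C": s.d13C_ca_vpdb,
                "d18O_vsmow": d18O_vsmow,
                "mixing_fraction": float(u),
                "distance": dist,
                "between_endmembers": bool(0.0 <= u <= 1.0),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["sample_id", "d13C", "d18O_vsmow", "mixing_fraction",
                 "distance", "between_endmembers"],
    )
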