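"""Publication-style figures: per-site violin plots and bivariate scatter.

Violin plots carry an embedded box whose top/bottom are the third/first
quartiles and whose middle line is the median; whiskers span the non-outlier
range (Tukey convention) and individual outliers are drawn as dots. Sites are
drawn left to right in registry order (decreasing latitude in the bundled
registry). The bivariate plot shows δ¹⁸O against δ¹³C, coloured by site, with
marker shape distinguishing period (dots for Copper Age, diamonds for
Neolithic), optional triangles for deciduous teeth and optional endmember
overlays for the diagenesis check.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .data_model import ToothSample
from .provenance import MixingEndmember
from .site_statistics import descriptive_stats, robust_spread


def violin_plot(
    groups: Mapping[str, Sequence[float]],
    out_path: str | Path,
    *,
    ylabel: str = "δ¹⁸Oca ‰ V-SMOW",
    quantile_type: int = 7,
) -> dict[str, dict]:
    """One violin per site with quartile box, median line, whiskers and outlier dots.

    Returns the per-site box statistics actually drawn (q1, median, q3,
    whisker ends, outliers) so callers can verify figure/statistics agreement.
    """
    if not groups:
        raise ValueError("need at least one group")
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(groups)), 5))
    positions = np.arange(1, len(groups) + 1)
    drawn: dict[str, dict] = {}
    values_list = [np.asarray(v, dtype=float) for v in groups.values()]
    parts = ax.violinplot(values_list, positions=positions, showextrema=False, widths=0.8)
    palette = sns.color_palette("deep", len(groups))
    for body, color in zip(parts["bodies"], palette):
        body.set_facecolor(color)
        body.set_alpha(0.6)

    for pos, (code, vals) in zip(positions, groups.items()):
        vals = np.asarray(vals, dtype=float)
        st = descriptive_stats(vals, quantile_type)
        if vals.size >= 2:
            iqr = robust_spread(vals, quantile_type).iqr
            lo_fence, hi_fence = st.q1 - 1.5 * iqr, st.q3 + 1.5 * iqr
        else:
            lo_fence, hi_fence = st.min, st.max
        inliers = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        whisk_lo = float(inliers.min()) if inliers.size else st.min
        whisk_hi = float(inliers.max()) if inliers.size else st.max
        outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
        ax.add_patch(
            plt.Rectangle((pos - 0.08, st.q1), 0.16, max(st.q3 - st.q1, 0),
                          facecolor="white", edgecolor="black", zorder=3)
        )
        ax.hlines(st.median, pos - 0.08, pos + 0.08, color="black", zorder=4)
        ax.vlines(pos, whisk_lo, st.q1, color="black", zorder=2)
        ax.vlines(pos, st.q3, whisk_hi, color="black", zorder=2)
        if outliers.size:
            ax.plot(np.full(outliers.size, pos), outliers, "o", color="black",
                    markersize=3, zorder=5)
        drawn[code] = {
            "q1": st.q1, "median": st.median, "q3": st.q3,
            "whisker_low": whisk_lo, "whisker_high": whisk_hi,
            "outliers": outliers.tolist(),
        }
    ax.set_xticks(positions)
    ax.set_xticklabels(list(groups))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return drawn


def bivariate_plot(
    samples: Sequence[ToothSample],
    out_path: str | Path,
    *,
    endmembers: Optional[Sequence[MixingEndmember]] = None,
    mark_deciduous: bool = False,
) -> int:
    """δ¹⁸O (V-SMOW, x) vs δ¹³C (y) scatter; returns the number of points drawn.

    Samples missing δ¹³C are excluded (the count excluded is the difference
    between ``len(samples)`` and the return value).
    """
    from .conversions import vpdb_to_vsmow

    complete = [s for s in samples if s.d13C_ca_vpdb is not None]
    if not complete:
        raise ValueError("no samples with both isotopes")
    sites = sorted({s.site_code for s in complete})
    palette = dict(zip(sites, sns.color_palette("deep", len(sites))))
    fig, ax = plt.subplots(figsize=(7, 5))
    seen = set()
    for s in complete:
        if mark_deciduous and s.tooth_generation == "deciduous":
            marker = "^"
        else:
            marker = "o" if s.period == "copper_age" else "D"
        label = s.site_code if s.site_code not in seen else None
        seen.add(s.site_code)
        ax.plot(vpdb_to_vsmow(s.d18O_ca_vpdb), s.d13C_ca_vpdb, marker,
                color=palette[s.site_code], label=label, markersize=5)
    if endmembers:
        for em in endmembers:
            ax.plot(em.d18O, em.d13C, "*", color="black", markersize=12)
            ax.annotate(em.label, (em.d18O, em.d13C), textcoords="offset points",
                        xytext=(5, 5))
    ax.set_xlabel("δ¹⁸Oca ‰ V-SMOW")
    ax.set_ylabel("δ¹³Cca ‰ V-PDB")
    ax.legend(title="site", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return len(complete)
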