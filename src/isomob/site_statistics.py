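"""Per-site descriptive and robust statistics, normality, and poolability.

Locality screening rests on per-community summary statistics: the classical
mean/sd pair, the median with its robust spread companions (MAD and IQR), and
a Shapiro–Wilk normality check that decides which MAD variant the screen will
use. Small neighbouring sites from the same period can be pooled into one
statistical population when a location test finds no evidence of a shift.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .data_model import (
    DescriptiveStats,
    NormalityResult,
    PoolingReport,
    SiteGroup,
    SpreadMeasures,
)

#: normal-consistency constant: sd ≈ 1.4826 × MAD for Gaussian data
MAD_NORMAL_CONSTANT = 1.4826

_QUANTILE_METHODS = {7: "linear", 2: "averaged_inverted_cdf"}


def quantile(values: Sequence[float], p: float, quantile_type: int = 7) -> float:
    """Sample quantile by R's type-7 (default) or type-2 definition."""
    if quantile_type not in _QUANTILE_METHODS:
        raise ValueError(f"quantile_type must be one of {sorted(_QUANTILE_METHODS)}")
    return float(np.quantile(np.asarray(values, dtype=float), p,
                             method=_QUANTILE_METHODS[quantile_type]))


def _check_values(values: Sequence[float], min_n: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return arr


def descriptive_stats(values: Sequence[float], quantile_type: int = 7) -> DescriptiveStats:
    """Min/max/mean/sd/median/quartiles of one site's values.

    sd uses the n−1 denominator and is NaN for n = 1.
    """
    arr = _check_values(values, 1)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return DescriptiveStats(
        n=int(arr.size),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        q1=quantile(arr, 0.25, quantile_type),
        q3=quantile(arr, 0.75, quantile_type),
    )


def robust_spread(values: Sequence[float], quantile_type: int = 7) -> SpreadMeasures:
    """MAD (raw, normal-scaled, Q3 variant) and IQR of one site's values."""
    arr = _check_values(values, 2)
    abs_dev = np.abs(arr - np.median(arr))
    mad_raw = float(np.median(abs_dev))
    return SpreadMeasures(
        mad_raw=mad_raw,
        mad_norm=MAD_NORMAL_CONSTANT * mad_raw,
        mad_q3=quantile(abs_dev, 0.75, quantile_type),
        iqr=quantile(arr, 0.75, quantile_type) - quantile(arr, 0.25, quantile_type),
    )


def shapiro_wilk(values: Sequence[float]) -> NormalityResult:
    """Shapiro–Wilk goodness-of-fit to the normal distribution."""
    arr = _check_values(values, 3)
    if arr.size > 5000:
        raise ValueError("Shapiro–Wilk is unreliable above n = 5000")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro–Wilk is undefined for constant input")
    W, p = sstats.shapiro(arr)
    return NormalityResult(W=float(W), p=float(p), n=int(arr.size))


def poolability_tests(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    welch: bool = False,
) -> PoolingReport:
    """Test whether candidate sites share a common location.

    Two groups: two-sided Student's t (pooled variance; Welch by flag).
    Three or more: Kruskal–Wallis. ``pooled`` is true when p > alpha.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for code, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {code!r} is empty")
        arrays[code] = arr
    codes = list(arrays)
    if len(arrays) == 2:
        a, b = arrays.values()
        stat, p = sstats.ttest_ind(a, b, equal_var=not welch)
        test = "t_test"
    else:
        stat, p = sstats.kruskal(*arrays.values())
        test = "kruskal_wallis"
    return PoolingReport(test=test, statistic=float(stat), p=float(p),
                         groups=codes, pooled=bool(p > alpha))


def pool_sites(
    registry: Mapping[str, SiteGroup],
    pooling_group: str,
    poolability: Optional[PoolingReport] = None,
    force: bool = False,
) -> SiteGroup:
    """Merge the sites tagged with ``pooling_group`` into one SiteGroup.

    Pooling is finalized only when the supplied poolability test accepted it
    (``pooled=True``) or ``force`` is set explicitly.
    """
    members = [s for s in registry.values() if s.pooling_group == pooling_group]
    if not members:
        raise ValueError(f"no sites carry pooling_group {pooling_group!r}")
    if len(members) < 2:
        raise ValueError(f"pooling_group {pooling_group!r} has a single member; nothing to pool")
    if poolability is not None and not poolability.pooled and not force:
        raise ValueError(
            f"poolability test rejected pooling ({poolability.test} p = {poolability.p:.3g} "
            f"<= alpha); pass force=True to override"
        )
    ranges = [m.reference_water_range for m in members if m.reference_water_range]
    merged_range = None
    if ranges:
        merged_range = (min(r[0] for r in ranges), max(r[1] for r in ranges))
    merged = SiteGroup(
        code=pooling_group,
        name=f"pooled: {', '.join(m.code for m in members)}",
        period=members[0].period,
        reference_water_range=merged_range,
        pooling_group=pooling_group,
        samples=[s for m in members for s in m.samples],
        member_codes=[m.code for m in members],
    )
    return merged


def site_summary(site: SiteGroup, quantile_type: int = 7) -> dict:
    """Descriptive + robust statistics for one site on both δ¹⁸O scales and δ¹³C."""
    from .conversions import vpdb_to_vsmow

    vpdb = site.d18O_vpdb()
    vsmow = [vpdb_to_vsmow(v) for v in vpdb]
    out = {
        "code": site.code,
        "name": site.name,
        "n": site.n,
        "d18O_vpdb": descriptive_stats(vpdb, quantile_type) if vpdb else None,
        "d18O_vsmow": descriptive_stats(vsmow, quantile_type) if vsmow else None,
        "d13C": None,
        "spread_vsmow": robust_spread(vsmow, quantile_type) if len(vsmow) >= 2 else None,
    }
    d13c = site.d13C()
    if d13c:
        out["d13C"] = descriptive_stats(d13c, quantile_type)
    return out
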