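"""Locality windows and consensus outlier screening.

A community's "locality window" is the δ¹⁸O interval compatible with local
origin, built from the community's own sample under four criteria:

* ``two_sd`` — mean ± 2σ;
* ``three_mad_norm`` / ``three_mad_q3`` — median ± 3·MAD, using the
  normal-scaled MAD when the site passes a Shapiro–Wilk normality check and
  the skew-tolerant Q3 variant otherwise;
* ``tukey_iqr`` — Tukey's fences, [q1 − 1.5·IQR, q3 + 1.5·IQR];
* ``two_permil`` — a fixed mean ± 2.0‰ band.

An individual strictly outside every applied window is a consensus outlier —
the operational definition of a probable newcomer. The screen is applied only
to communities with at least ``min_n`` individuals (default 9); windows are
built from the full sample including the candidates, in a single pass.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin

from .data_model import (
    DescriptiveStats,
    LocalityWindow,
    NormalityResult,
    OutlierReport,
    SampleFlags,
    SpreadMeasures,
)
from .site_statistics import descriptive_stats, robust_spread, shapiro_wilk

WINDOW_METHODS = ("two_sd", "three_mad_norm", "three_mad_q3", "tukey_iqr", "two_permil")

#: half-width of the reporting-rounding unit; values this close to a window
#: bound are annotated as boundary cases
BOUNDARY_TOL = 0.05


def sample_size_gate(n: int, min_n: int = 9) -> bool:
    """True when a community is large enough for the outlier screen."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n >= min_n


def select_mad_variant(normality: NormalityResult, alpha: float = 0.05) -> str:
    """Choose the MAD window variant from a normality test.

    Normal sites (p > alpha) use the normal-consistent MADnorm; non-normal
    sites (p <= alpha) use the skew-tolerant MADQ3.
    """
    return "three_mad_norm" if normality.p > alpha else "three_mad_q3"


def locality_window(
    stats: DescriptiveStats, spread: Optional[SpreadMeasures], method: str
) -> LocalityWindow:
    """Build one locality window from a site's statistics."""
    if method == "two_sd":
        if stats.n < 2 or not np.isfinite(stats.sd):
            raise ValueError("two_sd window needs n >= 2 for a defined sd")
        c, half = stats.mean, 2.0 * stats.sd
        return LocalityWindow(method, c, c - half, c + half)
    if method == "two_permil":
        c = stats.mean
        return LocalityWindow(method, c, c - 2.0, c + 2.0)
    if spread is None:
        raise ValueError(f"method {method!r} needs robust spread measures")
    if method == "three_mad_norm":
        c = stats.median
        return LocalityWindow(method, c, c - 3.0 * spread.mad_norm, c + 3.0 * spread.mad_norm)
    if method == "three_mad_q3":
        c = stats.median
        return LocalityWindow(method, c, c - 3.0 * spread.mad_q3, c + 3.0 * spread.mad_q3)
    if method == "tukey_iqr":
        return LocalityWindow(method, stats.median,
                              stats.q1 - 1.5 * spread.iqr, stats.q3 + 1.5 * spread.iqr)
    raise ValueError(f"unknown window method {method!r}; choose from {WINDOW_METHODS}")


def classify_outliers(
    samples: Sequence[tuple[str, float]],
    windows: Sequence[LocalityWindow],
    site_code: str = "",
    boundary_tol: float = BOUNDARY_TOL,
) -> OutlierReport:
    """Flag each sample against every window; consensus = flagged by all.

    Windows are closed intervals: a value exactly on a bound is local.
    Values within ``boundary_tol`` of a bound are annotated as boundary
    cases so they can be reported separately, as is conventional when a
    single individual "sits at the boundary".
    """
    if not windows:
        raise ValueError("need at least one locality window")
    methods = [w.method for w in windows]
    if len(set(methods)) != len(methods):
        raise ValueError("duplicate window methods")
    rows: list[SampleFlags] = []
    for sid, value in samples:
        flags = {}
        boundary = {}
        for w in windows:
            flags[w.method] = bool(not w.contains(value))
            boundary[w.method] = bool(
                abs(value - w.lower) <= boundary_tol or abs(value - w.upper) <= boundary_tol
            )
        count = sum(flags.values())
        rows.append(
            SampleFlags(
                sample_id=sid,
                value=float(value),
                flags=flags,
                boundary=boundary,
                consensus_count=count,
                is_consensus_outlier=count == len(windows),
            )
        )
    return OutlierReport(site_code=site_code, methods=methods,
                         windows={w.method: w for w in windows}, rows=rows)


def consensus_summary(report: OutlierReport) -> pd.DataFrame:
    """Flat per-sample summary ordered by consensus count, then extremity."""
    if not report.rows:
        return pd.DataFrame(
            columns=["sample_id", "value", *report.methods, "consensus_count",
                     "is_consensus_outlier", "distance_from_center"]
        )
    df = report.to_frame()
    centers = np.mean([w.center for w in report.windows.values()])
    df["distance_from_center"] = (df["value"] - centers).abs()
    df = df.sort_values(
        ["consensus_count", "distance_from_center"], ascending=[False, False]
    ).reset_index(drop=True)
    return df


class LocalityScreen(BaseEstimator, OutlierMixin):
    """Per-community locality-window outlier screen (sklearn-style).

    ``fit`` computes the community's windows from a 1-d array (or (n, 1)
    column) of δ¹⁸O values; ``predict`` returns +1 for locals and −1 for
    consensus outliers, following the sklearn outlier-detector convention.

    Parameters
    ----------
    methods : sequence of str
        Criteria to apply. The token ``"mad"`` selects between MADnorm and
        MADQ3 by Shapiro–Wilk normality (``mad_variant="auto"``), or can be
        forced with ``mad_variant`` in {"norm", "q3"}.
    mad_variant : {"auto", "norm", "q3"}
    alpha : float
        Significance level for the normality-based MAD selection.
    min_n : int
        Sample-size gate; ``fit`` refuses smaller communities.
    quantile_type : {7, 2}
        Quantile definition for quartiles and MADQ3.

    Attributes
    ----------
    stats_ : DescriptiveStats
    spread_ : SpreadMeasures
    normality_ : NormalityResult or None
    mad_variant_ : str or None — the variant actually applied
    windows_ : dict of method → LocalityWindow
    """

    def __init__(
        self,
        methods: Sequence[str] = ("two_sd", "mad", "tukey_iqr", "two_permil"),
        mad_variant: str = "auto",
        alpha: float = 0.05,
        min_n: int = 9,
        quantile_type: int = 7,
    ):
        self.methods = methods
        self.mad_variant = mad_variant
        self.alpha = alpha
        self.min_n = min_n
        self.quantile_type = quantile_type

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _as_1d(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("expected a 1-d array of isotope values or an (n, 1) column")
        if not np.all(np.isfinite(arr)):
            raise ValueError("isotope values must be finite")
        return arr

    def _resolve_methods(self, values: np.ndarray) -> list[str]:
        resolved: list[str] = []
        for m in self.methods:
            if m == "mad":
                if self.mad_variant == "norm":
                    resolved.append("three_mad_norm")
                elif self.mad_variant == "q3":
                    resolved.append("three_mad_q3")
                elif self.mad_variant == "auto":
                    self.normality_ = shapiro_wilk(values)
                    resolved.append(select_mad_variant(self.normality_, self.alpha))
                else:
                    raise ValueError(f"mad_variant must be auto/norm/q3, got {self.mad_variant!r}")
            elif m in WINDOW_METHODS:
                resolved.append(m)
            else:
                raise ValueError(f"unknown method {m!r}")
        return resolved

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y=None):
        values = self._as_1d(X)
        if not sample_size_gate(values.size, self.min_n):
            raise ValueError(
                f"community of n = {values.size} is below the screening gate "
                f"(min_n = {self.min_n}); descriptive statistics are still available"
            )
        self.normality_ = None
        applied = self._resolve_methods(values)
        self.stats_ = descriptive_stats(values, self.quantile_type)
        self.spread_ = robust_spread(values, self.quantile_type)
        self.windows_ = {
            m: locality_window(self.stats_, self.spread_, m) for m in applied
        }
        self.mad_variant_ = next((m for m in applied if m.startswith("three_mad")), None)
        self.n_features_in_ = 1
        return self

    def report(self, X, sample_ids: Optional[Sequence[str]] = None,
               site_code: str = "") -> OutlierReport:
        """Full per-sample, per-method flag report for new or training values."""
        values = self._as_1d(X)
        if sample_ids is None:
            sample_ids = [str(i) for i in range(values.size)]
        if len(sample_ids) != values.size:
            raise ValueError("sample_ids length does not match X")
        return classify_outliers(list(zip(sample_ids, values)),
                                 list(self.windows_.values()), site_code=site_code)

    def predict(self, X) -> np.ndarray:
        """+1 local, −1 consensus outlier (flagged by every applied criterion)."""
        rep = self.report(X)
        return np.where([r.is_consensus_outlier for r in rep.rows], -1, 1)

    def decision_function(self, X) -> np.ndarray:
        """Signed margin to the nearest applied window bound, minimised over
        methods: negative values are outside at least one window."""
        values = self._as_1d(X)
        margins = []
        for w in self.windows_.values():
            margins.append(np.minimum(values - w.lower, w.upper - values))
        return np.min(margins, axis=0)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)
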