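"""Locality windows, MAD-variant selection, consensus classification, and the
sklearn-style screen estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomob import (
    LocalityScreen,
    classify_outliers,
    consensus_summary,
    descriptive_stats,
    locality_window,
    robust_spread,
    sample_size_gate,
    select_mad_variant,
    vpdb_to_vsmow,
)
from isomob.data_model import DescriptiveStats, NormalityResult, SpreadMeasures


def _stats(**kw):
    base = dict(n=20, min=0.0, max=1.0, mean=0.5, sd=0.1, median=0.5, q1=0.25, q3=0.75)
    base.update(kw)
    return DescriptiveStats(**base)


def _spread(**kw):
    base = dict(mad_raw=0.1, mad_norm=0.14826, mad_q3=0.2, iqr=0.5)
    base.update(kw)
    return SpreadMeasures(**base)


@pytest.mark.parametrize("n, expected", [(9, True), (8, False), (50, True), (0, False)])
def test_sample_size_gate(n, expected):
    assert sample_size_gate(n) is expected


def test_mad_variant_selection():
    assert select_mad_variant(NormalityResult(0.95, 0.47, 18)) == "three_mad_norm"
    assert select_mad_variant(NormalityResult(0.95, 0.02, 50)) == "three_mad_q3"
    # boundary: p == alpha counts as non-normal
    assert select_mad_variant(NormalityResult(0.95, 0.05, 20)) == "three_mad_q3"


def test_window_marche_community():
    # median 24.4 with MADnorm 0.7 → 4.2‰ locality range from 22.3 to 26.5
    w = locality_window(_stats(median=24.4), _spread(mad_norm=0.7), "three_mad_norm")
    assert (w.lower, w.upper) == (pytest.approx(22.3), pytest.approx(26.5))
    assert w.width == pytest.approx(4.2)


def test_window_pooled_rome():
    # quartiles 26.0/26.4 (IQR 0.4) → Tukey fences 25.4–27.0, width 1.6‰
    w = locality_window(_stats(q1=26.0, q3=26.4), _spread(iqr=0.4), "tukey_iqr")
    assert (w.lower, w.upper) == (pytest.approx(25.4), pytest.approx(27.0))
    assert w.width == pytest.approx(1.6)


def test_window_fixed_band():
    w = locality_window(_stats(mean=26.0), None, "two_permil")
    assert (w.lower, w.upper) == (24.0, 28.0)
    assert w.width == 4.0


def test_window_errors():
    with pytest.raises(ValueError):
        locality_window(_stats(), None, "tukey_iqr")
    with pytest.raises(ValueError):
        locality_window(_stats(n=1, sd=float("nan")), _spread(), "two_sd")
    with pytest.raises(ValueError):
        locality_window(_stats(), _spread(), "nonsense")


@given(
    st.lists(st.floats(min_value=-10, max_value=10), min_size=9, max_size=40),
)
@settings(derandomize=True, max_examples=150)
def test_window_width_identities(xs):
    stats = descriptive_stats(xs)
    spread = robust_spread(xs)
    if np.isfinite(stats.sd):
        assert locality_window(stats, spread, "two_sd").width == pytest.approx(4 * stats.sd)
    assert locality_window(stats, spread, "three_mad_norm").width == pytest.approx(
        6 * spread.mad_norm)
    assert locality_window(stats, spread, "three_mad_q3").width == pytest.approx(
        6 * spread.mad_q3)
    assert locality_window(stats, spread, "tukey_iqr").width == pytest.approx(4 * spread.iqr)
    assert locality_window(stats, spread, "two_permil").width == pytest.approx(4.0)


def test_strict_outside_convention():
    stats = descriptive_stats([0.0, 1.0, 2.0, 3.0, 4.0])
    w = locality_window(stats, robust_spread([0.0, 1.0, 2.0, 3.0, 4.0]), "two_permil")
    rep = classify_outliers([("on_bound", w.lower), ("inside", w.center),
                             ("outside", w.lower - 0.01)], [w])
    flags = {r.sample_id: r.flags["two_permil"] for r in rep.rows}
    assert flags == {"on_bound": False, "inside": False, "outside": True}
    boundary = {r.sample_id: r.boundary["two_permil"] for r in rep.rows}
    assert boundary["on_bound"] and boundary["outside"] and not boundary["inside"]


def test_identical_values_no_flags():
    vals = [26.0] * 12
    screen = LocalityScreen(mad_variant="norm").fit(vals)
    assert (screen.predict(vals) == 1).all()
    rep = screen.report(vals)
    assert all(r.consensus_count == 0 for r in rep.rows)


def test_planted_extreme_outlier_flagged_by_all(study_like):
    """A value 2.1‰ below a tight coastal community's mean is caught by all four
    criteria, windows computed with the candidate included."""
    from isomob.synthetic import SyntheticSiteConfig, generate_site

    cfg = SyntheticSiteConfig(site_code="SS", n=50, mu=26.9, sigma=0.55, seed=3)
    samples, _ = generate_site(cfg)
    values = [vpdb_to_vsmow(s.d18O_ca_vpdb) for s in samples]
    values[0] = 24.7  # plant the newcomer
    screen = LocalityScreen().fit(values)
    rep = screen.report(values, [s.sample_id for s in samples])
    row = rep.rows[0]
    assert row.is_consensus_outlier
    assert all(row.flags.values())
    assert len(rep.methods) == 4


def test_consensus_summary_ordering():
    vals = [26.0 + 0.05 * i for i in range(12)] + [30.0, 28.9]
    screen = LocalityScreen(mad_variant="norm").fit(vals)
    rep = screen.report(vals)
    df = consensus_summary(rep)
    assert df.iloc[0]["value"] == 30.0  # most extreme consensus outlier first
    assert list(df.columns[:2]) == ["sample_id", "value"]
    empty = consensus_summary(screen.report([]))
    assert empty.empty


def test_flag_monotonicity_nested_windows():
    vals = np.linspace(20, 30, 21)
    stats = descriptive_stats(vals)
    spread = robust_spread(vals)
    inner = locality_window(stats, spread, "two_permil")
    outer = locality_window(stats, spread, "tukey_iqr")
    assert inner.lower >= outer.lower and inner.upper <= outer.upper
    rep = classify_outliers([(str(i), v) for i, v in enumerate(vals)], [inner, outer])
    for r in rep.rows:
        if r.flags["tukey_iqr"]:
            assert r.flags["two_permil"]


@given(st.lists(st.floats(min_value=-8, max_value=-2), min_size=12, max_size=40))
@settings(derandomize=True, max_examples=100, deadline=None)
def test_classification_scale_invariant(xs):
    """The same individuals are flagged whether windows are built on V-PDB or
    V-SMOW values, for the scale-equivariant criteria (2σ, 3MAD, Tukey); the
    fixed ±2‰ band is a per-mil rule and is tested separately."""
    xs = np.round(np.asarray(xs), 6)
    ys = np.array([vpdb_to_vsmow(x) for x in xs])
    methods = ("two_sd", "mad", "tukey_iqr")
    try:
        a = LocalityScreen(methods=methods, mad_variant="norm").fit(xs).predict(xs)
        b = LocalityScreen(methods=methods, mad_variant="norm").fit(ys).predict(ys)
    except ValueError:
        return  # degenerate (constant) input
    assert (a == b).all()


def test_gate_refuses_small_communities():
    with pytest.raises(ValueError, match="gate"):
        LocalityScreen().fit([26.0, 26.1, 26.2])


def test_sklearn_protocol():
    screen = LocalityScreen(alpha=0.01)
    assert screen.get_params()["alpha"] == 0.01
    screen.set_params(min_n=12)
    assert screen.min_n == 12
    vals = list(np.linspace(25, 27, 15))
    labels = screen.set_params(min_n=9).fit_predict(vals)
    assert set(labels) <= {-1, 1}
    assert screen.decision_function(vals).shape == (15,)
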