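"""Descriptive/robust statistics against an independent brute-force oracle,
normality testing, and site-pooling logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomob import (
    descriptive_stats,
    pool_sites,
    poolability_tests,
    robust_spread,
    shapiro_wilk,
    vpdb_to_vsmow,
)
from isomob.data_model import SiteGroup, ToothSample
from isomob.site_statistics import MAD_NORMAL_CONSTANT, quantile


# --- independent oracle: sort + direct textbook formulas -------------------

def oracle_quantile_type7(xs, p):
    xs = sorted(xs)
    h = (len(xs) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def oracle_median(xs):
    xs = sorted(xs)
    n = len(xs)
    return xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2


def oracle_sd(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def test_quantile_example():
    assert quantile([1, 2, 3, 4], 0.25) == pytest.approx(1.75)
    assert quantile([1, 2, 3, 4], 0.75) == pytest.approx(3.25)


def test_constant_input():
    st7 = descriptive_stats([5.0, 5.0, 5.0])
    assert st7.sd == 0 and st7.range == 0 and st7.q1 == st7.q3 == 5.0
    sp = robust_spread([5.0, 5.0, 5.0])
    assert sp.mad_raw == sp.mad_norm == sp.mad_q3 == sp.iqr == 0


def test_mad_hand_computation():
    # |x − median| = {0, 0, 1, 1, 2, 4, 7} for median 2
    sp = robust_spread([1, 1, 2, 2, 4, 6, 9])
    assert sp.mad_raw == pytest.approx(1.0)
    assert sp.mad_norm == pytest.approx(1.4826)


def test_mad_norm_reporting():
    from isomob import round_report

    assert round_report(0.5 * MAD_NORMAL_CONSTANT) == 0.7


def test_errors():
    with pytest.raises(ValueError):
        descriptive_stats([])
    with pytest.raises(ValueError):
        descriptive_stats([1.0, float("nan")])
    with pytest.raises(ValueError):
        robust_spread([1.0])
    with pytest.raises(ValueError):
        shapiro_wilk([3.0, 3.0, 3.0])
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])


def test_against_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(2, 12))
        xs = rng.normal(0, 3, size=n).tolist()
        st7 = descriptive_stats(xs)
        assert st7.mean == pytest.approx(sum(xs) / n, abs=1e-9)
        assert st7.sd == pytest.approx(oracle_sd(xs), abs=1e-9)
        assert st7.median == pytest.approx(oracle_median(xs), abs=1e-9)
        assert st7.q1 == pytest.approx(oracle_quantile_type7(xs, 0.25), abs=1e-9)
        assert st7.q3 == pytest.approx(oracle_quantile_type7(xs, 0.75), abs=1e-9)
        sp = robust_spread(xs)
        devs = [abs(x - oracle_median(xs)) for x in xs]
        assert sp.mad_raw == pytest.approx(oracle_median(devs), abs=1e-9)
        assert sp.mad_q3 == pytest.approx(oracle_quantile_type7(devs, 0.75), abs=1e-9)
        assert sp.iqr == pytest.approx(
            oracle_quantile_type7(xs, 0.75) - oracle_quantile_type7(xs, 0.25), abs=1e-9
        )


@given(st.lists(st.floats(min_value=-20, max_value=20), min_size=2, max_size=40))
@settings(derandomize=True, max_examples=200)
def test_mad_norm_ratio_exact(xs):
    sp = robust_spread(xs)
    assert sp.mad_norm == MAD_NORMAL_CONSTANT * sp.mad_raw


@given(st.lists(st.floats(min_value=-20, max_value=20), min_size=2, max_size=30))
@settings(derandomize=True, max_examples=200)
def test_affine_equivariance_of_statistics(xs):
    """Converting the scale maps every statistic through the same affine map."""
    slope = 1.03091
    ys = [vpdb_to_vsmow(x) for x in xs]
    a, b = descriptive_stats(xs), descriptive_stats(ys)
    assert b.mean == pytest.approx(vpdb_to_vsmow(a.mean), abs=1e-8)
    assert b.median == pytest.approx(vpdb_to_vsmow(a.median), abs=1e-8)
    assert b.sd == pytest.approx(slope * a.sd, abs=1e-8)
    sa, sb = robust_spread(xs), robust_spread(ys)
    assert sb.mad_raw == pytest.approx(slope * sa.mad_raw, abs=1e-8)
    assert sb.iqr == pytest.approx(slope * sa.iqr, abs=1e-8)


def test_shapiro_on_normal_quantiles():
    from scipy.stats import norm

    probs = (np.arange(30) + 0.5) / 30
    res = shapiro_wilk(norm.ppf(probs))
    assert res.W > 0.98
    assert res.n == 30


def test_shapiro_rejects_bimodal():
    rng = np.random.default_rng(0)
    vals = np.concatenate([np.zeros(10), np.full(10, 10.0)]) + rng.normal(0, 0.01, 20)
    assert shapiro_wilk(vals).p < 0.05


def test_poolability_identical_groups():
    rep = poolability_tests({"A": [1, 2, 3], "B": [1, 2, 3]})
    assert rep.test == "t_test"
    assert rep.statistic == pytest.approx(0.0, abs=1e-12)
    assert rep.pooled


def test_poolability_separated_groups():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 0.01, 4)
    b = 10 + rng.normal(0, 0.01, 4)
    rep = poolability_tests({"A": a, "B": b})
    assert not rep.pooled and rep.p < 1e-6
    rep3 = poolability_tests({"A": a, "B": b, "C": 20 + rng.normal(0, 0.01, 4)})
    assert rep3.test == "kruskal_wallis" and not rep3.pooled


def test_poolability_errors():
    with pytest.raises(ValueError):
        poolability_tests({"A": [1.0]})
    with pytest.raises(ValueError):
        poolability_tests({"A": [1.0], "B": []})


def _mini_site(code, vals, group=None):
    samples = [
        ToothSample(f"{code}{i}", code, "copper_age", "M2", "permanent", v, -12.0)
        for i, v in enumerate(vals)
    ]
    return SiteGroup(code, code, "copper_age", pooling_group=group, samples=samples)


def test_pool_sites_merges_members(study_like):
    _, _, registry = study_like
    from isomob.data_model import attach_samples

    samples, _, _ = study_like
    sites = attach_samples(samples, registry)
    merged = pool_sites(sites, "rome_copper_age")
    assert sorted(merged.member_codes) == ["CM", "OC", "PB", "TC"]
    assert merged.n == 16 + 7 + 4 + 3  # 30, the pooled community size


def test_pool_single_site_refused():
    reg = {"A": _mini_site("A", [1, 2], group="g")}
    with pytest.raises(ValueError, match="single member"):
        pool_sites(reg, "g")


def test_pool_refused_without_override():
    reg = {"A": _mini_site("A", [0.0, 0.1], group="g"),
           "B": _mini_site("B", [10.0, 10.1], group="g")}
    rep = poolability_tests({"A": [0.0, 0.1], "B": [10.0, 10.1]})
    with pytest.raises(ValueError, match="force=True"):
        pool_sites(reg, "g", poolability=rep)
    merged = pool_sites(reg, "g", poolability=rep, force=True)
    assert merged.n == 4
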