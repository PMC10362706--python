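"""ICC(2,1), pilot sample size, paired side summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facevol.stats import (RaterTable, StatsError, icc_2way_random_single,
                           pilot_sample_size, summarize_sides)
from facevol.synthetic import make_rater_table


# -- ICC --------------------------------------------------------------------

def test_perfect_agreement_gives_icc_one():
    vals = np.tile(np.arange(10, dtype=float)[:, None], (1, 3))
    res = icc_2way_random_single(RaterTable(vals))
    assert res.icc == pytest.approx(1.0, abs=1e-12)


def test_variance_components_recovered():
    """sigma_subj = 2, sigma_err = 1, n = 100: mean ICC over seeded tables
    recovers the variance ratio 4/5 within 0.05."""
    iccs = []
    for seed in range(10):
        table = make_rater_table(100, 3, var_subject=4.0, var_rater=0.0,
                                 var_error=1.0, seed=seed)
        res = icc_2way_random_single(table)
        assert res.ci_low < res.icc < res.ci_high
        iccs.append(res.icc)
    assert np.mean(iccs) == pytest.approx(0.8, abs=0.05)


def test_constant_rater_shift_lowers_icc():
    """Absolute agreement penalizes a systematic between-rater shift, and
    more so for larger shifts (closed-form mean-squares oracle)."""
    rng = np.random.default_rng(0)
    base = rng.normal(0, 2, size=(40, 1))
    def icc_with_shift(c):
        table = np.hstack([base, base + c])
        return icc_2way_random_single(RaterTable(table)).icc
    i0, i1, i2 = icc_with_shift(0.0), icc_with_shift(1.0), icc_with_shift(3.0)
    assert i0 == pytest.approx(1.0, abs=1e-9)
    assert i2 < i1 < i0

    # oracle: with identical columns + shift c, MSR = 2 var(s), MSE = 0,
    # MSC = n c^2 / 2 ... ICC = MSR' terms; verify against direct formula
    c = 3.0
    y = np.hstack([base, base + c])
    n, k = y.shape
    grand = y.mean()
    msr = k * np.sum((y.mean(1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((y.mean(0) - grand) ** 2) / (k - 1)
    mse = np.sum((y - y.mean(1, keepdims=True) - y.mean(0) + grand) ** 2) \
        / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    assert i2 == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin():
    """Dual-route check against an independent implementation."""
    import pingouin as pg
    table = make_rater_table(25, 3, var_subject=2.0, var_rater=0.3,
                             var_error=0.7, seed=7)
    res = icc_2way_random_single(table)
    n, k = table.values.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": table.values.ravel(),
    })
    out = pg.intraclass_corr(df, targets="subject", raters="rater",
                             ratings="score")
    row = out[out["Type"] == "ICC(A,1)"].iloc[0]
    assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
    ci = row["CI95"] if "CI95" in out.columns else row["CI95%"]
    assert res.ci_low == pytest.approx(ci[0], abs=0.01)
    assert res.ci_high == pytest.approx(ci[1], abs=0.01)


def test_icc_invariant_to_common_constant():
    table = make_rater_table(30, 2, 3.0, 0.5, 1.0, seed=1)
    a = icc_2way_random_single(table).icc
    b = icc_2way_random_single(RaterTable(table.values + 100.0)).icc
    assert a == pytest.approx(b, abs=1e-9)


def test_zero_between_subject_variance_error():
    vals = np.tile([[1.0, 2.0]], (10, 1))
    with pytest.raises(StatsError, match="undefined"):
        icc_2way_random_single(RaterTable(vals))


def test_table_shape_validation():
    with pytest.raises(StatsError):
        RaterTable(np.zeros((1, 3)))
    with pytest.raises(StatsError):
        RaterTable(np.array([[1.0, np.nan], [2.0, 3.0]]))


# -- pilot sample size ------------------------------------------------------

def test_pilot_sample_size_reproduces_printed_value():
    res = pilot_sample_size(0.90, 0.10)
    assert res.n_rounded == 21.9


def test_pilot_sample_size_exact_case():
    assert pilot_sample_size(0.75, 0.50).n == pytest.approx(2.0, abs=1e-12)


@given(st.floats(0.05, 0.99), st.floats(0.02, 0.9))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_pilot_ceiling_is_least_sufficient_integer(conf, pi):
    """ceil(n) is the least m with 1 - (1-pi)^m >= confidence, by brute
    force integer search."""
    n = pilot_sample_size(conf, pi).n
    m = int(np.ceil(n - 1e-9))
    assert 1 - (1 - pi) ** m >= conf - 1e-9
    if m > 1:
        assert 1 - (1 - pi) ** (m - 1) < conf + 1e-9


def test_pilot_monotonicity():
    assert pilot_sample_size(0.95, 0.10).n > pilot_sample_size(0.90, 0.10).n
    assert pilot_sample_size(0.90, 0.20).n < pilot_sample_size(0.90, 0.10).n


def test_pilot_bounds_rejected():
    with pytest.raises(StatsError):
        pilot_sample_size(1.0, 0.1)
    with pytest.raises(StatsError):
        pilot_sample_size(0.9, 0.0)


# -- paired side summaries --------------------------------------------------

def _tidy(n, delta, sigma, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        base = rng.normal(0, 1)
        rows.append(("s%d" % s, "control", "T1-T0", "stvc", base))
        rows.append(("s%d" % s, "extraction", "T1-T0", "stvc",
                     base + delta + rng.normal(0, sigma)))
    return pd.DataFrame(rows, columns=["subject", "side", "period",
                                       "metric", "value"])


def test_identical_sides_all_zero():
    df = _tidy(10, 0.0, 0.0, seed=3)
    df.loc[df.side == "extraction", "value"] = \
        df.loc[df.side == "control", "value"].values
    out = summarize_sides(df)
    assert out.iloc[0]["mean_diff"] == pytest.approx(0.0)
    assert out.iloc[0]["test"] == "degenerate"


def test_known_side_effect_detected():
    """delta = 1 ml, sigma = 0.5, n = 30: analytic paired-t power ~ 1."""
    out = summarize_sides(_tidy(30, 1.0, 0.5, seed=11))
    row = out.iloc[0]
    assert row["mean_diff"] == pytest.approx(1.0, abs=0.3)
    assert row["p_value"] < 1e-6
    # closed-form power oracle: noncentrality delta / (sigma / sqrt(n))
    from scipy import stats as sps
    ncp = 1.0 / (0.5 / np.sqrt(30))
    power = 1 - sps.nct.cdf(sps.t.ppf(0.975, 29), 29, ncp)
    assert power > 0.999


def test_unpaired_record_error():
    df = _tidy(5, 1.0, 0.5, seed=2)
    df = df.drop(df[(df.subject == "s0") & (df.side == "control")].index)
    with pytest.raises(StatsError, match="unpaired"):
        summarize_sides(df)


def test_single_subject_error():
    with pytest.raises(StatsError, match=">= 2"):
        summarize_sides(_tidy(1, 1.0, 0.5, seed=2))
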