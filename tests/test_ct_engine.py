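"""Threshold grid, association fitting, best-fit selection and the
permutation empirical P-value."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyscore as ps
from polyscore.ct_engine import (
    CTError,
    _linear_scan,
    build_grid,
    empirical_p,
    fit_association,
    run_ct,
    run_multi_pheno,
)
from polyscore.scoring import ScoreConfig

from conftest import make_dataset, make_panel


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def test_fastscore_grid_sorts_and_dedups():
    np.testing.assert_allclose(
        build_grid("fastscore", bar_levels=[0.5, 0.001, 0.05, 0.5]),
        [0.001, 0.05, 0.5],
    )


def test_high_resolution_grid_matches_enumeration():
    """Oracle: enumerate the arithmetic sequence independently."""
    lower, upper, step = 5e-8, 1e-4, 5e-5
    got = build_grid("high_resolution", lower=lower, upper=upper, step=step)
    expected = []
    x = lower
    while x <= upper + 1e-18:
        expected.append(x)
        x += step
    if expected[-1] < upper:
        expected.append(upper)
    np.testing.assert_allclose(got, sorted(set(expected)))
    assert got[-1] == upper


def test_grid_configuration_errors():
    with pytest.raises(CTError):
        build_grid("high_resolution", lower=0.5, upper=0.1)
    with pytest.raises(CTError):
        build_grid("fastscore", bar_levels=[])


# ---------------------------------------------------------------------------
# association fitting
# ---------------------------------------------------------------------------

def test_perfect_fit_has_unit_incremental_r2():
    y = np.random.default_rng(0).normal(size=100)
    coef, se, p, r2 = fit_association(y, y, None, "quantitative")
    assert coef == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    assert p < 1e-100


def test_null_fit_is_near_zero():
    rng = np.random.default_rng(1)
    s = rng.normal(size=1000)
    y = rng.normal(size=1000)
    coef, se, p, r2 = fit_association(s, y, None, "quantitative")
    assert abs(coef) < 0.15
    assert r2 < 0.02


def test_ols_coefficient_matches_closed_form():
    """Closed-form oracle: slope = cov(s, y) / var(s)."""
    rng = np.random.default_rng(2)
    s = rng.normal(size=2000)
    y = 0.3 * s + rng.normal(size=2000)
    coef, *_ = fit_association(s, y, None, "quantitative")
    expected = np.cov(s, y, ddof=0)[0, 1] / s.var()
    assert coef == pytest.approx(expected, abs=1e-10)


def test_linear_scan_agrees_with_statsmodels_fit():
    """The vectorized scan must reproduce per-column OLS exactly."""
    rng = np.random.default_rng(3)
    n = 300
    S = rng.normal(size=(n, 4))
    cov = rng.normal(size=(n, 2))
    y = S[:, 1] * 0.4 + cov[:, 0] * 0.7 + rng.normal(size=n)
    c, se, p, r2 = _linear_scan(S, y, cov)
    for t in range(4):
        ec, ese, ep, er2 = fit_association(S[:, t], y, cov, "quantitative")
        assert c[t] == pytest.approx(ec, abs=1e-10)
        assert se[t] == pytest.approx(ese, abs=1e-10)
        assert p[t] == pytest.approx(ep, rel=1e-8)
        assert r2[t] == pytest.approx(er2, abs=1e-10)


def test_logistic_fit_reports_nagelkerke_increment():
    rng = np.random.default_rng(4)
    s = rng.normal(size=600)
    y = (rng.random(600) < 1 / (1 + np.exp(-1.5 * s))).astype(float)
    coef, se, p, r2 = fit_association(s, y, None, "binary")
    assert coef > 0.8
    assert 0 < r2 <= 1
    assert p < 1e-10


def test_zero_variance_score_rejected():
    with pytest.raises(CTError, match="variance"):
        fit_association(np.ones(100), np.random.default_rng(0).normal(size=100), None,
                        "quantitative")


# ---------------------------------------------------------------------------
# run_ct
# ---------------------------------------------------------------------------

def _toy_scan(seed=0, grid=(0.1, 0.5, 1.0), family="quantitative", n=200, m=50):
    rng = np.random.default_rng(seed)
    ds = make_dataset(rng.integers(0, 3, size=(n, m)))
    panel = make_panel(ds, betas=rng.normal(size=m), pvalues=rng.uniform(0, 1, m))
    sm = ps.compute_scores(ds, panel, np.asarray(grid), ScoreConfig())
    y = sm.scores[:, min(1, sm.scores.shape[1] - 1)] * 2 + rng.normal(size=n)
    if family == "binary":
        y = (y > np.median(y)).astype(float)
    return run_ct(ds, panel, np.asarray(grid), ScoreConfig(), y, family=family)


def test_single_threshold_grid_best_is_that_threshold():
    scan = _toy_scan(grid=(0.5,))
    assert scan.best["threshold"] == 0.5


def test_best_r2_is_the_maximum():
    scan = _toy_scan(seed=7, grid=(0.05, 0.2, 0.5, 1.0))
    r2 = scan.table["r2_incremental"].to_numpy()
    assert scan.best["r2_incremental"] == pytest.approx(np.nanmax(r2))


def test_run_ct_deterministic():
    a = _toy_scan(seed=5)
    b = _toy_scan(seed=5)
    pd.testing.assert_frame_equal(a.table, b.table)
    assert a.best_index == b.best_index


def test_binary_12_coding_autoshifted():
    scan = _toy_scan(seed=9, family="binary")
    rng = np.random.default_rng(9)
    ds = make_dataset(rng.integers(0, 3, size=(200, 50)))
    panel = make_panel(ds, betas=rng.normal(size=50), pvalues=rng.uniform(0, 1, 50))
    grid = np.array([0.1, 0.5, 1.0])
    sm = ps.compute_scores(ds, panel, grid, ScoreConfig())
    y = sm.scores[:, 1] * 2 + rng.normal(size=200)
    y = (y > np.median(y)).astype(float)
    scan2 = run_ct(ds, panel, grid, ScoreConfig(), y + 1, family="binary")
    pd.testing.assert_frame_equal(scan.table, scan2.table)


# ---------------------------------------------------------------------------
# empirical P (the permutation machinery)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "N,n_better,expected",
    [(100, 0, 1 / 101), (100, 100, 1.0), (10000, 5, 6 / 10001)],
)
def test_empirical_p_formula(N, n_better, expected):
    assert (n_better + 1) / (N + 1) == pytest.approx(expected)


def test_empirical_p_pseudocount_floor_and_reproducibility():
    scan = _toy_scan(seed=11)
    a = empirical_p(scan, n_permutations=100, seed=3)
    b = empirical_p(scan, n_permutations=100, seed=3)
    assert a == b
    assert 1 / 101 <= a.empirical_p <= 1.0
    assert a.empirical_p == pytest.approx((a.n_better + 1) / 101)


@settings(derandomize=True, max_examples=30)
@given(N=st.integers(1, 500), k=st.integers(0, 500))
def test_empirical_p_bounds(N, k):
    k = min(k, N)
    emp = (k + 1) / (N + 1)
    assert 1 / (N + 1) <= emp <= 1.0


def test_strong_signal_gives_floor_empirical_p():
    scan = _toy_scan(seed=13, n=500)
    res = empirical_p(scan, n_permutations=200, seed=1)
    assert res.empirical_p == pytest.approx(1 / 201)


def test_exact_logistic_permutation_agrees_directionally():
    """binary_fast and exact logistic refits should rank a real signal the same."""
    scan = _toy_scan(seed=15, family="binary", n=150, m=30)
    fast = empirical_p(scan, n_permutations=30, seed=2, binary_fast=True)
    slow = empirical_p(scan, n_permutations=30, seed=2, binary_fast=False)
    assert abs(fast.n_better - slow.n_better) <= 3


def test_permutation_requires_at_least_one():
    scan = _toy_scan()
    with pytest.raises(CTError):
        empirical_p(scan, n_permutations=0)


# ---------------------------------------------------------------------------
# multi-phenotype loop
# ---------------------------------------------------------------------------

def test_multi_pheno_matches_independent_single_runs():
    rng = np.random.default_rng(21)
    ds = make_dataset(rng.integers(0, 3, size=(250, 60)))
    panel = make_panel(ds, betas=rng.normal(size=60), pvalues=rng.uniform(0, 1, 60))
    grid = np.array([0.1, 0.5, 1.0])
    sm = ps.compute_scores(ds, panel, grid, ScoreConfig())
    phenos = pd.DataFrame(
        {
            "q1": sm.scores[:, 2] + rng.normal(size=250) * 0.1,
            "q2": rng.normal(size=250),
            "b1": (sm.scores[:, 2] > np.median(sm.scores[:, 2])).astype(float),
        }
    )
    fams = {"q1": "quantitative", "q2": "quantitative", "b1": "binary"}
    multi = run_multi_pheno(ds, panel, grid, ScoreConfig(), phenos, fams,
                            n_permutations=50, seed=7)
    assert [name for name, *_ in multi] == ["q1", "q2", "b1"]
    for name, scan, perm in multi:
        solo = run_ct(ds, panel, grid, ScoreConfig(), phenos[name].to_numpy(),
                      family=fams[name])
        pd.testing.assert_frame_equal(scan.table, solo.table)
        solo_perm = empirical_p(solo, 50, seed=7)
        assert perm == solo_perm


def test_identical_phenotype_columns_identical_scans():
    rng = np.random.default_rng(23)
    ds = make_dataset(rng.integers(0, 3, size=(100, 30)))
    panel = make_panel(ds, betas=rng.normal(size=30), pvalues=rng.uniform(0, 1, 30))
    y = rng.normal(size=100)
    phenos = pd.DataFrame({"a": y, "b": y})
    out = run_multi_pheno(ds, panel, np.array([0.5, 1.0]), ScoreConfig(), phenos,
                          {"a": "quantitative", "b": "quantitative"})
    pd.testing.assert_frame_equal(out[0][1].table, out[1][1].table)
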