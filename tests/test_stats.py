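"""Correlation screen, elastic-net regression and paired Wilcoxon tests
against independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from octmark.errors import ValidationError
from octmark.stats import (
    L1_RATIO_GRID,
    RegressionResult,
    build_report,
    compare_models,
    evaluate_on,
    fit_regression_cv,
    pearson_screen,
)


def _frame(cols: dict, ids=None) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    df = pd.DataFrame(cols)
    df.insert(0, "scan_id", ids or [f"s{i}" for i in range(n)])
    return df


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Direct-formula Pearson r and two-sided p via the t transform."""
    from scipy.stats import t as tdist

    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x * x).sum(), (y * y).sum()
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, p


# ---------------------------------------------------------------------------
# correlation screen

def test_perfect_linear_correlation():
    f = _frame({"feat": [1.0, 2.0, 3.0, 4.0]})
    m = _frame({"BCVA": [2.0, 4.0, 6.0, 8.0]})
    tab = pearson_screen(f, m)
    assert tab.r.loc["feat", "BCVA"] == pytest.approx(1.0)
    assert tab.significant.loc["feat", "BCVA"]


def test_screen_matches_formula_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        tab = pearson_screen(_frame({"f": x}), _frame({"m": y}))
        r_o, p_o = pearson_oracle(x, y)
        assert tab.r.loc["f", "m"] == pytest.approx(r_o, rel=1e-10)
        assert tab.p.loc["f", "m"] == pytest.approx(p_o, rel=1e-10)


def test_constant_column_flagged_not_zero():
    f = _frame({"f": [1.0, 1.0, 1.0, 1.0]})
    m = _frame({"m": [1.0, 2.0, 3.0, 4.0]})
    tab = pearson_screen(f, m)
    assert tab.undefined.loc["f", "m"]
    assert np.isnan(tab.r.loc["f", "m"])
    assert not tab.significant.loc["f", "m"]


def test_scale_and_sign_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=12)
    y = rng.normal(size=12) + 0.3 * x
    r0 = pearson_screen(_frame({"f": x}), _frame({"m": y})).r.iloc[0, 0]
    r_scaled = pearson_screen(_frame({"f": 3.0 * x + 5.0}), _frame({"m": y})).r.iloc[0, 0]
    r_flipped = pearson_screen(_frame({"f": -2.0 * x}), _frame({"m": y})).r.iloc[0, 0]
    assert r_scaled == pytest.approx(r0, rel=1e-12)
    assert r_flipped == pytest.approx(-r0, rel=1e-12)


def test_pairwise_complete_observations():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [1.0, 2.1, 3.0, 3.9, np.nan]
    tab = pearson_screen(_frame({"f": x}), _frame({"m": y}))
    assert tab.n.loc["f", "m"] == 3


# ---------------------------------------------------------------------------
# regression

def _regression_data(n=80, p=6, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = x @ beta + noise * rng.normal(size=n)
    ids = [f"s{i}" for i in range(n)]
    features = _frame({f"f{j}": x[:, j] for j in range(p)}, ids=ids)
    target = pd.Series(y, index=ids, name="y")
    return features, target, ids


def test_noiseless_linear_target_recovered():
    features, target, ids = _regression_data(noise=0.0)
    res = fit_regression_cv(features, target, (ids[:60], ids[60:]), seed=0)
    assert res.r2 >= 0.99


def test_r2_and_mae_match_manual_computation():
    features, target, ids = _regression_data(noise=0.5, seed=3)
    res = fit_regression_cv(features, target, (ids[:60], ids[60:]), seed=0)
    y_test = target.loc[ids[60:]].to_numpy()
    pred = res.predictions
    sse = np.sum((y_test - pred) ** 2)
    sst = np.sum((y_test - y_test.mean()) ** 2)
    assert res.r2 == pytest.approx(1 - sse / sst, rel=1e-12)
    assert res.mae_mean == pytest.approx(np.abs(y_test - pred).mean(), rel=1e-12)
    assert len(res.abs_errors) == 20
    # coefficients are on the original scale: predictions reproducible
    np.testing.assert_allclose(
        features.set_index("scan_id").loc[ids[60:]].to_numpy() @ res.coef + res.intercept,
        pred, rtol=1e-8,
    )


def test_shuffled_target_gives_no_skill():
    """A target independent of the features has near-zero R^2 in expectation."""
    r2s = []
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        features, target, ids = _regression_data(n=300, noise=0.0, seed=seed)
        target = pd.Series(rng.permutation(target.to_numpy()), index=target.index, name="y")
        res = fit_regression_cv(features, target, (ids[:270], ids[270:]), seed=seed)
        r2s.append(res.r2)
    assert np.mean(r2s) <= 0.05


def test_constant_mean_prediction_gives_zero_r2():
    features, target, ids = _regression_data(noise=0.5, seed=5)
    res = fit_regression_cv(features, target, (ids[:60], ids[60:]), seed=0)
    y_test = target.loc[res.test_scan_ids]
    const = RegressionResult(
        target="y", feature_set="const", l1_ratio=1.0, penalty=0.0, r2=0.0,
        mae_mean=0.0, mae_sd=0.0, abs_errors=np.zeros(1), predictions=np.zeros(1),
        test_scan_ids=[], coef=np.zeros(features.shape[1] - 1),
        intercept=float(y_test.mean()), n_train=0, n_test=0,
    )
    out = evaluate_on(const, features.set_index("scan_id").loc[res.test_scan_ids],
                      y_test, feature_set="const")
    assert out.r2 == pytest.approx(0.0, abs=1e-12)


def test_missing_targets_dropped_and_counted():
    features, target, ids = _regression_data(seed=7)
    target = target.copy()
    target.iloc[[0, 65]] = np.nan
    res = fit_regression_cv(features, target, (ids[:60], ids[60:]), seed=0)
    assert res.n_dropped == 2
    assert res.n_test == 19


def test_overlapping_split_rejected():
    features, target, ids = _regression_data()
    with pytest.raises(ValidationError):
        fit_regression_cv(features, target, (ids[:60], ids[55:]), seed=0)


def test_too_few_rows_for_folds_rejected():
    features, target, ids = _regression_data(n=8)
    with pytest.raises(ValidationError):
        fit_regression_cv(features, target, (ids[:4], ids[4:]), seed=0, folds=5)


def test_train_r2_non_increasing_with_ridge_penalty():
    """Sanity at the grid extremes: in the ridge limit, training R^2 falls
    monotonically as the penalty grows."""
    from sklearn.linear_model import ElasticNet

    rng = np.random.default_rng(11)
    x = rng.normal(size=(60, 5))
    y = x @ rng.normal(size=5) + 0.3 * rng.normal(size=60)
    scores = []
    for alpha in (1e-4, 1e-2, 1e-1, 1.0, 10.0):
        m = ElasticNet(alpha=alpha, l1_ratio=min(L1_RATIO_GRID), max_iter=50000)
        m.fit(x, y)
        scores.append(m.score(x, y))
    assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison

def _result_from_errors(err, ids=None, name="m"):
    err = np.asarray(err, float)
    ids = ids or [f"s{i}" for i in range(len(err))]
    return RegressionResult(
        target="y", feature_set=name, l1_ratio=0.5, penalty=0.1, r2=0.0,
        mae_mean=float(err.mean()), mae_sd=float(err.std()), abs_errors=err,
        predictions=err, test_scan_ids=ids, coef=np.zeros(1), intercept=0.0,
        n_train=0, n_test=len(err),
    )


def wilcoxon_exact_oracle(diff: np.ndarray) -> tuple[float, float]:
    """Exhaustive enumeration of the signed-rank null over all 2^n sign
    assignments (no ties, no zeros)."""
    n = len(diff)
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_plus = ranks[diff > 0].sum()
    dist = np.array([
        np.sum(ranks[list(signs)]) if signs else 0.0
        for k in range(n + 1)
        for signs in itertools.combinations(range(n), k)
    ])
    p_low = np.mean(dist <= w_plus)
    p_high = np.mean(dist >= w_plus)
    return w_plus, min(1.0, 2 * min(p_low, p_high))


def test_identical_errors_degenerate():
    a = _result_from_errors([1.0, 2.0, 3.0])
    b = _result_from_errors([1.0, 2.0, 3.0])
    cmpres = compare_models(a, b)
    assert cmpres.degenerate
    assert cmpres.p_value is None
    assert cmpres.verdict == "not significant, degenerate"


def test_exact_p_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        diff = rng.normal(0.3, 1.0, size=8)
        diff[diff == 0] = 0.1
        a = _result_from_errors(np.abs(diff) * (diff > 0) + 1.0)
        b = _result_from_errors(1.0 + np.abs(diff) * (diff < 0), ids=a.test_scan_ids)
        # a.err - b.err == diff by construction
        cmpres = compare_models(a, b)
        w_o, p_o = wilcoxon_exact_oracle(diff)
        assert cmpres.p_value == pytest.approx(p_o, rel=1e-10)


def test_constant_shift_detected():
    rng = np.random.default_rng(1)
    base = rng.random(12) + 1.0
    a = _result_from_errors(base)
    b = _result_from_errors(base + 5.0, ids=a.test_scan_ids)
    cmpres = compare_models(a, b)
    assert cmpres.p_value < 0.05
    assert cmpres.significant


def test_mismatched_lengths_rejected():
    a = _result_from_errors([1.0, 2.0])
    b = _result_from_errors([1.0, 2.0, 3.0])
    with pytest.raises(ValidationError):
        compare_models(a, b)


def test_zero_differences_dropped():
    a = _result_from_errors([1.0, 2.0, 3.0, 4.0, 7.0])
    b = _result_from_errors([1.0, 2.0, 5.0, 2.0, 3.0], ids=a.test_scan_ids)
    cmpres = compare_models(a, b)
    assert cmpres.n_zero_dropped == 2
    assert cmpres.n_pairs == 3


# ---------------------------------------------------------------------------
# report bundle

def test_report_correlation_only(tmp_path):
    f = _frame({"f": [1.0, 2.0, 3.0, 4.0]})
    m = _frame({"m": [1.1, 1.9, 3.2, 3.8]})
    report = build_report(pearson_screen(f, m), [], [], tmp_path)
    assert (tmp_path / "report.html").exists()
    assert (tmp_path / "correlation_r.csv").exists()
    assert not (tmp_path / "regression_summary.csv").exists()


def test_report_grey_cells_match_significance(tmp_path):
    rng = np.random.default_rng(2)
    n = 30
    x1 = rng.normal(size=n)
    f = _frame({"strong": x1, "noise": rng.normal(size=n)})
    m = _frame({"m": x1 + 0.2 * rng.normal(size=n)})
    tab = pearson_screen(f, m)
    report = build_report(tab, [], [], tmp_path)
    sig = pd.read_csv(tmp_path / "correlation_significant.csv", index_col=0)
    p = pd.read_csv(tmp_path / "correlation_p.csv", index_col=0)
    # greyed (non-significant) cells are exactly those with p >= 0.05
    np.testing.assert_array_equal(sig.to_numpy(bool), p.to_numpy() < 0.05)
    assert report.paths["heatmap"].exists()


def test_report_full_bundle(tmp_path):
    features, target, ids = _regression_data(noise=0.5, seed=9)
    res_a = fit_regression_cv(features, target, (ids[:60], ids[60:]), seed=0,
                              feature_set="A")
    res_b = fit_regression_cv(features.drop(columns=["f0"]), target,
                              (ids[:60], ids[60:]), seed=0, feature_set="B")
    comp = compare_models(res_a, res_b)
    f = _frame({"f": features["f1"]}, ids=ids)
    m = _frame({"y": target.to_numpy()}, ids=ids)
    report = build_report(pearson_screen(f, m), [res_a, res_b], [comp], tmp_path)
    reg = pd.read_csv(tmp_path / "regression_summary.csv")
    assert set(reg["feature_set"]) == {"A", "B"}
    assert {"R2", "MAE_mean", "MAE_sd"} <= set(reg.columns)
    assert (tmp_path / "comparisons.csv").exists()
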