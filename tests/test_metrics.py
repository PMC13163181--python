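"""Agreement-statistics oracles: every estimator against an independent
brute-force or textbook computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polypcam as pc
from polypcam.depth import DepthMap
from polypcam.metrics import (
    PairedMeasurements,
    agreement_report,
    bland_altman,
    depth_map_metrics,
    group_compare,
    icc_two_way_mixed_absolute,
    lin_ccc,
    misclassification,
    percentage_and_measurement_error,
    terminal_digit_rate,
    trend_r_squared,
)


def _pairs(pred, ref):
    return PairedMeasurements(np.asarray(pred, float), np.asarray(ref, float))


# ---------------------------------------------------------------- depth maps


def test_depth_metrics_identity():
    d = DepthMap(np.full((8, 8), 17.0))
    assert depth_map_metrics(d, d) == (0.0, 0.0, 0.0)


def test_depth_metrics_hand_example():
    gt = DepthMap(np.array([[10.0, 20.0]]))
    pred = DepthMap(np.array([[11.0, 18.0]]))
    are, rmse, log_err = depth_map_metrics(gt, pred)
    assert are == pytest.approx(0.10)
    assert rmse == pytest.approx(math.sqrt(2.5))
    assert log_err == pytest.approx((abs(math.log10(1.1)) + abs(math.log10(0.9))) / 2)


def test_depth_metrics_match_pixel_loop(rng):
    gt_vals = rng.uniform(5, 60, size=(23, 17))
    pred_vals = gt_vals * rng.uniform(0.8, 1.2, size=gt_vals.shape)
    valid = rng.random(gt_vals.shape) > 0.1
    gt = DepthMap(gt_vals, valid)
    pred = DepthMap(pred_vals, np.ones_like(valid))
    are, rmse, log_err = depth_map_metrics(gt, pred)

    # naive per-pixel loop
    tot_are = tot_sq = tot_log = n = 0.0
    for i in range(gt_vals.shape[0]):
        for j in range(gt_vals.shape[1]):
            if valid[i, j]:
                g, p = gt_vals[i, j], pred_vals[i, j]
                tot_are += abs(g - p) / g
                tot_sq += (g - p) ** 2
                tot_log += abs(math.log10(g) - math.log10(p))
                n += 1
    assert are == pytest.approx(tot_are / n, abs=1e-9)
    assert rmse == pytest.approx(math.sqrt(tot_sq / n), abs=1e-9)
    assert log_err == pytest.approx(tot_log / n, abs=1e-9)


def test_depth_metrics_require_overlap():
    a = DepthMap(np.ones((4, 4)), np.zeros((4, 4), bool))
    with pytest.raises(ValueError):
        depth_map_metrics(a, a)


# ------------------------------------------------------------------- PE / ME


def test_pe_me_exact_cases():
    out = percentage_and_measurement_error(_pairs([8.0, 10.0], [10.0, 10.0]))
    assert out["pe"][0] == pytest.approx(20.0)
    assert out["me"][0] == pytest.approx(-2.0)
    assert out["pe"][1] == 0.0 and out["me"][1] == 0.0


def test_pe_me_match_elementwise_loop(rng):
    pred = rng.uniform(2, 16, 40)
    ref = rng.uniform(2, 16, 40)
    out = percentage_and_measurement_error(_pairs(pred, ref))
    for i in range(40):
        assert out["pe"][i] == pytest.approx(abs(pred[i] - ref[i]) / ref[i] * 100, abs=1e-9)
        assert out["me"][i] == pytest.approx(pred[i] - ref[i], abs=1e-12)
    q1, q3 = out["pe_iqr"]
    assert q1 == pytest.approx(np.quantile(out["pe"], 0.25))
    assert q3 == pytest.approx(np.quantile(out["pe"], 0.75))


# ----------------------------------------------------------------------- CCC


def test_ccc_perfect_and_reversed():
    x = np.array([4.0, 6.0, 8.0, 11.0])
    assert lin_ccc(_pairs(x, x))[0] == pytest.approx(1.0)
    # perfect reversal around a common mean: CCC = -1 needs equal means
    y = 2 * x.mean() - x
    assert lin_ccc(_pairs(y, x))[0] == pytest.approx(-1.0)


def test_ccc_matches_textbook_formula():
    # six paired size readings (mm)
    x = np.array([4.2, 5.1, 6.9, 8.4, 10.2, 12.5])
    y = np.array([4.0, 5.5, 6.5, 9.0, 9.8, 12.9])
    ccc, lo, hi = lin_ccc(_pairs(x, y))
    # textbook computation with explicit sums, 1/n moments
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((xi - mx) ** 2 for xi in x) / n
    sy2 = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    expected = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    assert ccc == pytest.approx(expected, abs=1e-9)
    assert lo < ccc < hi


def test_ccc_bounded_by_pearson(rng):
    for _ in range(20):
        x = rng.uniform(2, 16, 15)
        y = x * rng.uniform(0.8, 1.2) + rng.normal(0, 1, 15) + rng.uniform(0, 2)
        y = np.clip(y, 0.5, None)
        ccc = lin_ccc(_pairs(y, x))[0]
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-12


# ----------------------------------------------------------------------- ICC


def _icc_anova_oracle(y):
    """Explicit sums-of-squares decomposition for ICC(A,1)."""
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_identical_sessions_is_one():
    s = np.array([4.1, 5.2, 7.9, 9.3, 11.0])
    icc, lo, hi = icc_two_way_mixed_absolute(s, s)
    assert icc == pytest.approx(1.0)


def test_icc_matches_anova_oracle(rng):
    s1 = rng.uniform(4, 11, 5)
    s2 = s1 + rng.normal(0, 0.6, 5)
    icc, _, _ = icc_two_way_mixed_absolute(s1, s2)
    oracle = _icc_anova_oracle(np.column_stack([s1, s2]))
    assert icc == pytest.approx(max(oracle, 0.0), abs=1e-9)


def test_icc_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    s1 = rng.uniform(4, 11, 8)
    s2 = s1 * rng.uniform(0.9, 1.1, 8)
    icc, lo, hi = icc_two_way_mixed_absolute(s1, s2)
    df = pd.DataFrame(
        {
            "targets": list(range(8)) * 2,
            "raters": ["a"] * 8 + ["b"] * 8,
            "score": np.concatenate([s1, s2]),
        }
    )
    ref = pingouin.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
    row = ref[ref.Type == "ICC(A,1)"].iloc[0]
    assert icc == pytest.approx(row.ICC, abs=1e-6)
    ci = np.asarray(row.CI95, dtype=float)
    assert lo == pytest.approx(ci[0], abs=0.02)
    assert hi == pytest.approx(ci[1], abs=0.02)


def test_icc_near_zero_for_independent_sessions():
    # expectation over seeds: independent sessions carry no target signal
    # (clamping negative ANOVA estimates to 0 leaves a small positive mean)
    rng = np.random.default_rng(5)
    vals = [icc_two_way_mixed_absolute(rng.uniform(4, 11, 10), rng.uniform(4, 11, 10))[0] for _ in range(200)]
    assert abs(np.mean(vals)) < 0.15


def test_icc_ccc_agree_without_session_effect():
    rng = np.random.default_rng(11)
    true = rng.uniform(4, 11, 60)
    s1 = true + rng.normal(0, 0.3, 60)
    s2 = true + rng.normal(0, 0.3, 60)
    icc = icc_two_way_mixed_absolute(s1, s2)[0]
    ccc = lin_ccc(_pairs(s1, s2))[0]
    assert icc == pytest.approx(ccc, abs=0.02)


# -------------------------------------------------------------- Bland-Altman


def test_bland_altman_cases(rng):
    x = np.array([4.0, 7.0, 9.0])
    assert bland_altman(_pairs(x, x)) == (0.0, 0.0, 0.0)
    m, lo, hi = bland_altman(_pairs(x + 1.0, x))
    assert (m, lo, hi) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))
    pred = rng.uniform(2, 16, 30)
    ref = rng.uniform(2, 16, 30)
    m, lo, hi = bland_altman(_pairs(pred, ref))
    d = pred - ref
    assert m == pytest.approx(d.mean(), abs=1e-12)
    assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
    assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)


# ----------------------------------------------------- misclassification etc.


def test_misclassification_counts():
    out = misclassification(_pairs([5.2, 4.8, 9.9], [4.0, 6.0, 12.0]))
    assert out[5.0]["underestimated"] == 1 and out[5.0]["overestimated"] == 1
    assert out[10.0]["underestimated"] == 1 and out[10.0]["overestimated"] == 0
    same = misclassification(_pairs([4.0, 6.0, 12.0], [4.0, 6.0, 12.0]))
    assert all(v["underestimated"] == 0 and v["overestimated"] == 0 for v in same.values())


def test_misclassification_matches_loop(rng):
    pred = rng.uniform(2, 16, 100)
    ref = rng.uniform(2, 16, 100)
    out = misclassification(_pairs(pred, ref))
    for c in (5.0, 10.0):
        under = sum(1 for p, r in zip(pred, ref) if r >= c and p < c)
        over = sum(1 for p, r in zip(pred, ref) if r < c and p >= c)
        assert out[c]["underestimated"] == under
        assert out[c]["overestimated"] == over


def test_terminal_digit_rounding_rule():
    count, rate = terminal_digit_rate(np.array([5.2, 7.1, 10.4]))
    assert count == 2
    assert terminal_digit_rate(np.array([5.2]), digits_mm=())[0] == 0


def test_terminal_digit_uniform_rate():
    # uniform sizes on (2, 16): the rounding rule hits {5,10,15} on
    # (4.5,5.5) u (9.5,10.5) u (14.5,15.5), measure 3 of 14
    rng = np.random.default_rng(3)
    p = rng.uniform(2, 16, 200_000)
    _, rate = terminal_digit_rate(p)
    assert rate == pytest.approx(3 / 14, abs=0.01)


def test_trend_r_squared():
    x = np.array([4.0, 6.0, 9.0, 12.0])
    assert trend_r_squared(_pairs(x, x)) == pytest.approx(1.0)
    assert trend_r_squared(_pairs(np.full(4, 7.0), x)) == 0.0
    rng = np.random.default_rng(8)
    ref = rng.uniform(2, 16, 25)
    pred = 1.1 * ref + rng.normal(0, 1, 25) + 5
    # closed-form normal equations
    r = np.corrcoef(ref, pred)[0, 1]
    assert trend_r_squared(_pairs(np.clip(pred, 0.1, None), ref)) == pytest.approx(r**2, abs=1e-9)


# ------------------------------------------------------------ group compare


def test_group_compare_identical():
    a = np.array([3.0, 5.0, 8.0, 2.0, 7.0])
    assert group_compare(a, a, paired=True) == pytest.approx(1.0)


def test_group_compare_disjoint_support():
    a = np.linspace(1, 2, 10)
    b = np.linspace(10, 20, 10)
    assert group_compare(a, b, paired=False) < 0.01
    assert group_compare(a, b, paired=True) < 0.01


def test_group_compare_symmetry(rng):
    a = rng.uniform(0, 10, 12)
    b = rng.uniform(0, 10, 12)
    assert group_compare(a, b) == pytest.approx(group_compare(b, a), abs=1e-12)


# ------------------------------------------------------------ invariants


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(1.0, 50.0), min_size=3, max_size=30), st.integers(0, 2**31 - 1))
def test_rmse_dominates_mae(vals, seed):
    gt = np.asarray(vals)
    pred = gt * np.random.default_rng(seed).uniform(0.7, 1.3, len(gt))
    _, rmse, _ = depth_map_metrics(DepthMap(gt[None, :]), DepthMap(pred[None, :]))
    mae = np.mean(np.abs(gt - pred))
    assert rmse >= mae - 1e-12


def test_summaries_invariant_to_paired_permutation(rng):
    pred = rng.uniform(2, 16, 30)
    ref = rng.uniform(2, 16, 30)
    perm = rng.permutation(30)
    a = agreement_report(_pairs(pred, ref))
    b = agreement_report(_pairs(pred[perm], ref[perm]))
    assert a.pe_mean == pytest.approx(b.pe_mean, abs=1e-9)
    assert a.ccc == pytest.approx(b.ccc, abs=1e-12)
    assert a.bland_altman_loa_mm == pytest.approx(b.bland_altman_loa_mm, abs=1e-9)
    assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)


def test_agreement_report_roundtrip(rng):
    pred = rng.uniform(4, 11, 20)
    ref = rng.uniform(4, 11, 20)
    rep = agreement_report(_pairs(pred, ref), session2=_pairs(pred * 1.01, ref))
    d = rep.to_dict()
    assert d["n"] == 40
    assert rep.icc is not None
    row = rep.to_csv_row()
    assert row.shape[0] == 1 and "ccc" in row.columns
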