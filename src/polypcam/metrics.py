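"""Method-agreement and error statistics for paired measurements.

Covers the complete evaluation suite of a measurement-system study:

* depth-map metrics — average relative error (ARE), RMSE and mean
  absolute log10 error between predicted and ground-truth depth maps;
* per-item percentage error PE = |pred − ref|/ref·100 and signed
  measurement error ME = pred − ref, with mean and IQR summaries;
* Lin's concordance correlation coefficient (CCC) with a Fisher-z CI;
* single-measure two-way absolute-agreement intraclass correlation
  ICC(A,1) with its F-distribution CI;
* Bland–Altman limits of agreement;
* clinically motivated size-misclassification counts at 5/10 mm
  cut-offs, terminal-digit preference, OLS trend R², and two-sided
  Wilcoxon / Mann–Whitney group comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "depth_map_metrics",
    "percentage_and_measurement_error",
    "lin_ccc",
    "icc_two_way_mixed_absolute",
    "bland_altman",
    "misclassification",
    "terminal_digit_rate",
    "trend_r_squared",
    "group_compare",
    "agreement_report",
]


@dataclass
class PairedMeasurements:
    """Predicted vs reference values (mm) with optional item labels."""

    predicted: np.ndarray
    reference: np.ndarray
    labels: Optional[Sequence] = None
    session: int = 1

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.predicted.shape != self.reference.shape or self.predicted.ndim != 1:
            raise ValueError("predicted and reference must be equal-length 1-D vectors")
        if len(self.predicted) < 2:
            raise ValueError("need at least 2 paired measurements")
        if np.any(self.reference <= 0) or np.any(self.predicted <= 0):
            raise ValueError("paired measurements must be positive")

    def __len__(self) -> int:
        return len(self.predicted)


def depth_map_metrics(d_gt, d_pred) -> tuple[float, float, float]:
    """(ARE, RMSE, mean |log10| error) over the valid-pixel intersection.

    ARE = mean(|gt − pred| / gt) — a fraction, not percent;
    RMSE = sqrt(mean((gt − pred)²)) in mm;
    the log10 error is mean(|log10 gt − log10 pred|).
    """
    if d_gt.shape != d_pred.shape:
        raise ValueError("depth maps must share a shape")
    both = d_gt.valid & d_pred.valid
    if not both.any():
        raise ValueError("no common valid pixels between the depth maps")
    g = d_gt.values_mm[both]
    p = d_pred.values_mm[both]
    are = float(np.mean(np.abs(g - p) / g))
    rmse = float(np.sqrt(np.mean((g - p) ** 2)))
    log_err = float(np.mean(np.abs(np.log10(g) - np.log10(p))))
    return are, rmse, log_err


def _iqr(x: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear-interpolation quantiles
    return float(q1), float(q3)


def percentage_and_measurement_error(pairs: PairedMeasurements) -> dict:
    """Per-item PE (%) and ME (mm) plus mean/IQR summaries."""
    if np.any(pairs.reference == 0):
        raise ValueError("percentage error undefined for zero reference")
    pe = np.abs(pairs.predicted - pairs.reference) / pairs.reference * 100.0
    me = pairs.predicted - pairs.reference
    return {
        "pe": pe,
        "me": me,
        "pe_mean": float(pe.mean()),
        "pe_iqr": _iqr(pe),
        "me_mean": float(me.mean()),
        "me_iqr": _iqr(me),
    }


def lin_ccc(pairs: PairedMeasurements, alpha: float = 0.05) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    CCC = 2·cov(x, y) / (var x + var y + (mean x − mean y)²), with
    population (1/n) moments; the CI uses the asymptotic variance of the
    z-transformed estimate (Lin 1989, with the 1992 erratum).
    """
    x, y = pairs.predicted, pairs.reference
    n = len(x)
    if n < 3:
        raise ValueError("CCC needs n >= 3")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("degenerate inputs: zero variance and equal means")
    ccc = 2 * sxy / denom
    if sx2 == 0 or sy2 == 0:
        return float(ccc), float("nan"), float("nan")  # flagged undefined CI
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(r) < 1e-12 or abs(ccc) >= 1 - 1e-15:
        return float(ccc), float("nan"), float("nan")
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c_b = ccc / r
    z = np.arctanh(ccc)
    se_z2 = (
        (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
        - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)
    ) / (n - 2)
    se_z = float(np.sqrt(max(se_z2, 0.0)))
    zc = stats.norm.ppf(1 - alpha / 2)
    return float(ccc), float(np.tanh(z - zc * se_z)), float(np.tanh(z + zc * se_z))


def icc_two_way_mixed_absolute(
    session1: np.ndarray, session2: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Single-measure absolute-agreement ICC(A,1) across two sessions.

    From the two-way ANOVA mean squares (rows = targets, columns =
    sessions): ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),
    k = 2.  Negative ANOVA estimates are clamped to 0.  The CI is the
    McGraw & Wong F-based construction.
    """
    y = np.column_stack([np.asarray(session1, float), np.asarray(session2, float)])
    n, k = y.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 targets")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 0.0, 0.0, 0.0
    icc = (msr - mse) / denom
    clamped = max(icc, 0.0)

    # McGraw & Wong (1996) CI for ICC(A,1)
    if mse <= 0:
        return float(min(clamped, 1.0)), float("nan"), float("nan")
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    fj = msc / mse
    nu = (a * fj + b) ** 2 / (a**2 * fj**2 / (k - 1) + b**2 / ((n - 1) * (k - 1)))
    f_obs = msr / mse
    fl = stats.f.ppf(1 - alpha / 2, n - 1, nu)
    fu = stats.f.ppf(1 - alpha / 2, nu, n - 1)
    lower = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    return float(min(clamped, 1.0)), float(lower), float(upper)


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """(mean difference, lower LoA, upper LoA): mean ± 1.96·SD of pred − ref."""
    diff = pairs.predicted - pairs.reference
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def misclassification(
    pairs: PairedMeasurements, cutoffs_mm: Sequence[float] = (5.0, 10.0)
) -> dict:
    """Size-category misclassification counts at clinical cut-offs.

    For each cut-off c: items with reference ≥ c predicted < c are
    *underestimated*; items with reference < c predicted ≥ c are
    *overestimated*.  Rates use the ≥c and <c subsets as denominators.
    """
    out = {}
    p, r = pairs.predicted, pairs.reference
    for c in cutoffs_mm:
        ge = r >= c
        under = int(np.sum(ge & (p < c)))
        over = int(np.sum(~ge & (p >= c)))
        n_ge, n_lt = int(ge.sum()), int((~ge).sum())
        out[float(c)] = {
            "underestimated": under,
            "n_at_or_above": n_ge,
            "under_rate": under / n_ge if n_ge else float("nan"),
            "overestimated": over,
            "n_below": n_lt,
            "over_rate": over / n_lt if n_lt else float("nan"),
        }
    return out


def terminal_digit_rate(
    predictions_mm: np.ndarray, digits_mm: Sequence[float] = (5.0, 10.0, 15.0)
) -> tuple[int, float]:
    """Count/rate of predictions landing on preferred round sizes.

    A continuous estimator never returns exactly 5/10/15 mm, so
    membership is judged after rounding to the nearest integer
    millimetre (half away from zero, the clinical reporting rule).
    """
    p = np.asarray(predictions_mm, dtype=float)
    if len(p) == 0:
        return 0, float("nan")
    rounded = np.floor(p + 0.5)  # round half away from zero for positive sizes
    count = int(np.isin(rounded, np.asarray(digits_mm, dtype=float)).sum())
    return count, count / len(p)


def trend_r_squared(pairs: PairedMeasurements) -> float:
    """R² of the OLS regression of predicted on reference."""
    x, y = pairs.reference, pairs.predicted
    sy2 = np.sum((y - y.mean()) ** 2)
    sx2 = np.sum((x - x.mean()) ** 2)
    if sy2 == 0 or sx2 == 0:
        return 0.0  # a constant vector carries no explainable variation
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    return float(sxy**2 / (sx2 * sy2))


def group_compare(
    group_a: np.ndarray, group_b: np.ndarray, paired: bool = False
) -> float:
    """Two-sided p-value comparing two PE groups.

    Paired groups use the Wilcoxon signed-rank test, unpaired the
    Mann–Whitney U test; exact enumeration for small samples without
    ties, normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal lengths")
        d = a - b
        if np.all(d == 0):
            return 1.0
        method = "exact" if len(d) <= 25 and not _has_ties(np.abs(d[d != 0])) else "approx"
        return float(stats.wilcoxon(a, b, alternative="two-sided", method=method).pvalue)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not _has_ties(np.concatenate([a, b]))) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _has_ties(x: np.ndarray) -> bool:
    return len(np.unique(x)) < len(x)


@dataclass
class AgreementReport:
    """Bundle of paired-measurement statistics for one stratum."""

    n: int
    pe_mean: float
    pe_iqr: tuple[float, float]
    me_mean_mm: float
    me_iqr_mm: tuple[float, float]
    ccc: float
    ccc_ci: tuple[float, float]
    bland_altman_mean_mm: float
    bland_altman_loa_mm: tuple[float, float]
    r_squared: float
    misclassification: dict
    terminal_digit_count: int
    terminal_digit_rate: float
    icc: Optional[float] = None
    icc_ci: Optional[tuple[float, float]] = None
    icc_clamped: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["misclassification"] = {
            str(k): v for k, v in self.misclassification.items()
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv_row(self) -> pd.DataFrame:
        flat = {
            "n": self.n,
            "pe_mean": self.pe_mean,
            "pe_q1": self.pe_iqr[0],
            "pe_q3": self.pe_iqr[1],
            "me_mean_mm": self.me_mean_mm,
            "me_q1_mm": self.me_iqr_mm[0],
            "me_q3_mm": self.me_iqr_mm[1],
            "ccc": self.ccc,
            "ccc_lo": self.ccc_ci[0],
            "ccc_hi": self.ccc_ci[1],
            "ba_mean_mm": self.bland_altman_mean_mm,
            "ba_loa_lo_mm": self.bland_altman_loa_mm[0],
            "ba_loa_hi_mm": self.bland_altman_loa_mm[1],
            "r_squared": self.r_squared,
            "terminal_digit_count": self.terminal_digit_count,
            "terminal_digit_rate": self.terminal_digit_rate,
            "icc": self.icc,
            "icc_lo": None if self.icc_ci is None else self.icc_ci[0],
            "icc_hi": None if self.icc_ci is None else self.icc_ci[1],
        }
        for c, m in self.misclassification.items():
            flat[f"under_{c:g}mm"] = m["underestimated"]
            flat[f"over_{c:g}mm"] = m["overestimated"]
        return pd.DataFrame([flat])


def agreement_report(
    pairs: PairedMeasurements,
    session2: Optional[PairedMeasurements] = None,
    cutoffs_mm: Sequence[float] = (5.0, 10.0),
) -> AgreementReport:
    """Compute the full agreement panel for one set of paired measurements.

    When a second session is given (same targets, same order), the
    paired-measurement statistics pool both sessions and the ICC is
    computed between the two sessions' predictions.
    """
    pooled = pairs
    icc = icc_ci = None
    clamped = False
    if session2 is not None:
        if len(session2) != len(pairs):
            raise ValueError("sessions must measure the same targets")
        pooled = PairedMeasurements(
            np.concatenate([pairs.predicted, session2.predicted]),
            np.concatenate([pairs.reference, session2.reference]),
        )
        if len(pairs) >= 3:
            icc, lo, hi = icc_two_way_mixed_absolute(pairs.predicted, session2.predicted)
            icc_ci = (lo, hi)
            clamped = icc == 0.0 and lo < 0

    err = percentage_and_measurement_error(pooled)
    ccc, lo, hi = lin_ccc(pooled)
    ba_mean, ba_lo, ba_hi = bland_altman(pooled)
    td_count, td_rate = terminal_digit_rate(pooled.predicted)
    return AgreementReport(
        n=len(pooled),
        pe_mean=err["pe_mean"],
        pe_iqr=err["pe_iqr"],
        me_mean_mm=err["me_mean"],
        me_iqr_mm=err["me_iqr"],
        ccc=ccc,
        ccc_ci=(lo, hi),
        bland_altman_mean_mm=ba_mean,
        bland_altman_loa_mm=(ba_lo, ba_hi),
        r_squared=trend_r_squared(pooled),
        misclassification=misclassification(pooled, cutoffs_mm),
        terminal_digit_count=td_count,
        terminal_digit_rate=td_rate,
        icc=icc,
        icc_ci=icc_ci,
        icc_clamped=clamped,
    )
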