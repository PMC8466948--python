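"""Method-agreement statistics: ANOVA, OLS regression, Bland–Altman, ICC.

The cross-modality comparison layer: a one-way ANOVA with imaging modality
as the factor (significance at p < 0.01), ordinary least-squares regression
with R², Bland–Altman bias and 95% limits of agreement (reference = the
first, micro-CT-role series), and a two-way mixed-effects absolute-agreement
single-measure ICC — ICC(A,1) — with the qualitative classes low (< 0.5),
good (0.5–0.75) and excellent (> 0.75).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = ["AgreementReport", "one_way_anova", "linear_regression",
           "bland_altman", "icc", "agreement_report", "P_SIGNIFICANT"]

#: Significance level for the modality-effect ANOVA.
P_SIGNIFICANT = 0.01


@dataclasses.dataclass(frozen=True)
class AgreementReport:
    anova_p: float
    anova_significant: bool
    slope: float
    intercept: float
    R2: float
    bias: float
    loa_low: float
    loa_high: float
    bias_pct: float
    icc_value: float
    icc_class: str


def one_way_anova(groups) -> tuple[float, bool]:
    """Classic one-way F-test across groups; returns (p, significant).

    Degenerate case: zero within-group variance with unequal means gives
    p = 0 (infinite F) rather than an exception; identical groups give
    F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    means = [g.mean() for g in groups]
    if within == 0:
        p = 1.0 if np.ptp(means) == 0 else 0.0
    else:
        _, p = stats.f_oneway(*groups)
        p = float(p)
    return p, p < P_SIGNIFICANT


def linear_regression(x, y) -> dict:
    """Ordinary least squares of y on x; R² is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "R2": float(res.rvalue**2)}


def bland_altman(x, y) -> dict:
    """Bias and 95% limits of agreement of y against the reference x.

    ``d = y − x``; bias = mean(d); LoA = bias ± 1.96·SD(d) (sample SD);
    percent bias is relative to the reference mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired series with n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    ref_mean = float(x.mean())
    return {"bias": bias, "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd,
            "bias_pct": 100.0 * bias / ref_mean if ref_mean != 0 else float("nan")}


def _icc_mean_squares(data: np.ndarray):
    """Two-way ANOVA mean squares for an n-subjects × k-raters table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(x, y, form: str = "A,1") -> dict:
    """Intraclass correlation between two paired measurement series.

    ``form`` selects the estimator: ``"A,1"`` (default; two-way
    absolute-agreement single-measure), ``"C,1"`` (consistency) or
    ``"A,k"`` (average-measure absolute agreement).  Classes: low (< 0.5),
    good (0.5–0.75), excellent (> 0.75); values exactly on a boundary are
    assigned upward.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired series with n >= 3")
    data = np.column_stack([x, y])
    if np.allclose(data, data.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    n, k = data.shape
    msr, msc, mse = _icc_mean_squares(data)
    if form == "A,1":
        value = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    elif form == "C,1":
        value = (msr - mse) / (msr + (k - 1) * mse)
    elif form == "A,k":
        value = (msr - mse) / (msr + (msc - mse) / n)
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    value = float(value)
    return {"value": value, "class": classify_icc(value)}


def classify_icc(value: float) -> str:
    """Qualitative agreement class; boundary values are assigned upward."""
    if value >= 0.75:
        return "excellent"
    if value >= 0.5:
        return "good"
    return "low"


def agreement_report(reference, other) -> AgreementReport:
    """Full agreement panel of one parameter between two modalities."""
    p, sig = one_way_anova([reference, other])
    reg = linear_regression(reference, other)
    ba = bland_altman(reference, other)
    ic = icc(reference, other)
    return AgreementReport(anova_p=p, anova_significant=sig,
                           slope=reg["slope"], intercept=reg["intercept"],
                           R2=reg["R2"], bias=ba["bias"],
                           loa_low=ba["loa_low"], loa_high=ba["loa_high"],
                           bias_pct=ba["bias_pct"], icc_value=ic["value"],
                           icc_class=ic["class"])
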