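"""Method-agreement and group-comparison statistics for validation.

The battery applied to held-out per-jump records: Pearson correlation
and a paired t-test between measured and predicted GRF, Lin's
concordance correlation coefficient (precision times a location/scale
accuracy penalty), Bland-Altman bias and limits of agreement with the
fraction of points outside them, a relative bias percentage, and a
one-way repeated-measures ANOVA (with Bonferroni post-hocs) for
wear-position and intensity comparisons.

Lin's CCC uses the biased, divide-by-n moment estimators of the
original concordance estimator — the n-1 variants differ noticeably at
small n, so the choice is fixed and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "pearson_r",
    "paired_t",
    "lins_ccc",
    "bland_altman",
    "bias_percent",
    "rm_anova_oneway",
    "post_hoc_pairwise",
    "agreement_report",
]


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x, y = _pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation is undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test on ``d = x - y``; returns ``(t, df, p)``.

    Zero-variance differences with nonzero mean give an infinite t with
    p = 0; identical inputs give t = 0, p = 1.
    """
    x, y = _pair(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    n = d.size
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, n - 1, 1.0
        return float(np.sign(mean)) * np.inf, n - 1, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``2*s_xy / (s_x^2 + s_y^2 + (mean(x) - mean(y))^2)`` with biased
    (divide-by-n) variance and covariance estimators.
    """
    x, y = _pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    mx, my = np.mean(x), np.mean(y)
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("concordance is undefined when both inputs are the same constant")
    return float(2.0 * sxy / denom)


def bland_altman(
    measured, predicted, k: float = 1.96
) -> tuple[float, float, float, float, int, float]:
    """Bland-Altman agreement on ``d = measured - predicted``.

    Returns ``(bias, sd_diff, loa_low, loa_high, n_outside, pct_outside)``
    where the limits of agreement are ``bias +/- k * sd`` (sample SD,
    n-1 denominator) and points strictly outside them are counted.
    """
    x, y = _pair(measured, predicted)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if k <= 0:
        raise ValueError("k must be positive")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - k * sd, bias + k * sd
    n_out = int(np.sum((d < lo) | (d > hi)))
    return bias, sd, lo, hi, n_out, 100.0 * n_out / d.size


def bias_percent(measured, predicted) -> float:
    """Mean difference relative to the mean measured value, in percent."""
    x, y = _pair(measured, predicted)
    mx = float(np.mean(x))
    if mx == 0.0:
        raise ValueError("bias percentage is undefined when the measured mean is zero")
    return float(np.mean(x - y) / mx * 100.0)


def rm_anova_oneway(data) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on a subjects-by-conditions matrix.

    The total sum of squares is decomposed into subject, condition and
    error components; ``F = MS_conditions / MS_error`` with
    ``df1 = k - 1`` and ``df2 = (k - 1)(n - 1)``.  No sphericity
    correction is applied.  Missing cells are an error.
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    n, k = a.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(a).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    grand = a.mean()
    ss_subjects = k * np.sum((a.mean(axis=1) - grand) ** 2)
    ss_conditions = n * np.sum((a.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((a - grand) ** 2)
    ss_error = ss_total - ss_subjects - ss_conditions
    # snap float-cancellation residue so e.g. identical conditions give F = 0
    tol = 1e-12 * max(ss_total, 1.0)
    ss_conditions = 0.0 if ss_conditions < tol else ss_conditions
    ss_error = 0.0 if ss_error < tol else ss_error
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_error = ss_error / df2
    if ms_error <= 0:
        # all residual variance explained; conditions identical gives F = 0
        f = 0.0 if ss_conditions == 0 else np.inf
        return float(f), df1, df2, 1.0 if ss_conditions == 0 else 0.0
    f = float((ss_conditions / df1) / ms_error)
    p = float(stats.f.sf(f, df1, df2))
    return f, df1, df2, p


def post_hoc_pairwise(data, method: str = "bonferroni") -> list[dict]:
    """Paired t-tests between all condition pairs with multiplicity adjustment.

    Returns one record per pair with raw and adjusted p-values
    (``p_adj = min(1, m * p_raw)`` for Bonferroni over ``m`` pairs).
    """
    if method != "bonferroni":
        raise ValueError(f"unsupported adjustment method: {method!r}")
    a = np.asarray(data, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    k = a.shape[1]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    out = []
    for i, j in pairs:
        t, df, p = paired_t(a[:, i], a[:, j])
        out.append({"pair": (i, j), "t": t, "df": df, "p_raw": p, "p_adj": min(1.0, m * p)})
    return out


@dataclass
class AgreementReport:
    """Validation summary for predicted vs. measured GRF."""

    n: int
    paired_t: tuple[float, int, float]
    pearson_r: float
    ccc: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outside: int
    pct_outside: float
    bias_percent: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paired_t"] = {"t": self.paired_t[0], "df": self.paired_t[1], "p": self.paired_t[2]}
        return d


def agreement_report(measured, predicted, k: float = 1.96) -> AgreementReport:
    """Run the full agreement battery on paired measured/predicted values."""
    x, y = _pair(measured, predicted)
    bias, sd, lo, hi, n_out, pct = bland_altman(x, y, k=k)
    return AgreementReport(
        n=x.size,
        paired_t=paired_t(x, y),
        pearson_r=pearson_r(x, y),
        ccc=lins_ccc(x, y),
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        n_outside=n_out,
        pct_outside=pct,
        bias_percent=bias_percent(x, y),
    )
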