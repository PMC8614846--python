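"""Agreement statistics between two measurement series.

Used to compare automated joint-space-width estimates against reference
(radiologist) measurements, or two human observers against each other.
The report combines:

* Pearson correlation r (with two-sided p) and R² = r² from the simple
  linear regression of one series on the other;
* Bland–Altman bias (mean of differences, first argument minus second) and
  95% limits of agreement, bias ± 1.96·SD of the differences (SD with
  denominator n−1);
* ICC(2,1): two-way random-effects, absolute-agreement, single-measurement
  intraclass correlation, computed from the two-way ANOVA mean squares;
* the interobserver error summary as mean and SD of the *absolute*
  differences (signed summaries are the bias and SD of differences above).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementReport", "agreement", "icc_agreement",
           "bland_altman_points", "plot_bland_altman"]


@dataclass
class AgreementReport:
    """Agreement summary for paired series (difference = a - b)."""

    n: int
    pearson_r: float
    pearson_p: float
    r_squared: float
    bias_d: float                # mean difference, mm
    loa_half_width: float        # 1.96 * SD(differences), mm
    icc: float
    mean_abs_error: float        # mean |difference|, mm
    sd_error: float              # SD of |difference|, mm
    sd_d: float                  # SD of signed differences, mm


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"series lengths differ: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series contain non-finite values")
    return a, b


def agreement(a, b) -> AgreementReport:
    """Full agreement report between series ``a`` and ``b``.

    When either series has zero variance the Pearson correlation is
    undefined; r, p and R² are reported as NaN with a warning while the
    Bland–Altman and ICC statistics are still computed.
    """
    a, b = _check_pair(a, b)
    d = a - b
    bias = float(d.mean())
    sd_d = float(d.std(ddof=1))
    abs_d = np.abs(d)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a series; Pearson correlation undefined",
                      stacklevel=2)
        r = p = np.nan
    else:
        res = stats.pearsonr(a, b)
        r, p = float(res.statistic), float(res.pvalue)
    return AgreementReport(
        n=a.size,
        pearson_r=r,
        pearson_p=p,
        r_squared=r * r if np.isfinite(r) else np.nan,
        bias_d=bias,
        loa_half_width=1.96 * sd_d,
        icc=icc_agreement(a, b),
        mean_abs_error=float(abs_d.mean()),
        sd_error=float(abs_d.std(ddof=1)),
        sd_d=sd_d,
    )


def icc_agreement(a, b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    With n subjects (rows) and k=2 raters (columns), from the two-way ANOVA
    mean squares MSR (rows), MSC (columns) and MSE (residual):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1)·MSE + (k/n)·(MSC - MSE))
    """
    a, b = _check_pair(a, b)
    table = np.column_stack([a, b])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((table - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


def bland_altman_points(a, b) -> pd.DataFrame:
    """Per-pair (mean, difference) table for a Bland–Altman plot.

    The returned frame carries the bias and the two limits of agreement in
    its ``attrs`` (keys ``bias``, ``loa_low``, ``loa_high``).
    """
    a, b = _check_pair(a, b)
    d = a - b
    out = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    out.attrs["bias"] = bias
    out.attrs["loa_low"] = bias - half
    out.attrs["loa_high"] = bias + half
    return out


def plot_bland_altman(a, b, path=None, ax=None):
    """Render the Bland–Altman plot; writes to ``path`` if given."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pts = bland_altman_points(a, b)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pts["mean"], pts["difference"], s=12, alpha=0.6)
    ax.axhline(pts.attrs["bias"], color="red", label=f"bias {pts.attrs['bias']:.2f} mm")
    for key in ("loa_low", "loa_high"):
        ax.axhline(pts.attrs[key], color="tab:blue", linestyle="--")
    ax.set_xlabel("mean of pair (mm)")
    ax.set_ylabel("difference a - b (mm)")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
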