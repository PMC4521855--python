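"""Per-period trend regressions on deseasonalized carcass rates.

For each market period, carcass rate is regressed on the serially
numbered month (a single 1..n numbering over the whole study, not
restarted per period).  A quadratic is fitted to permit curvature, and
retained only when a partial F-test says the linear model is
significantly less predictive.  The reported "slope" is the average
change in carcass rate per month: the linear coefficient, or — when the
quadratic is retained — the tangent slope at the period midpoint

    slope(t_m) = b1 + 2 b2 t_m,
    Var       = Var(b1) + 4 t_m^2 Var(b2) + 4 t_m Cov(b1, b2),

with a t-based 95% CI from linear-model theory.  Slopes of taxa with very
different abundances are made comparable by normalization: dividing by
the taxon/total SD ratio, or by the taxon's fraction of the total rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrendFit:
    period: str
    model: str  # "linear" or "quadratic"
    coefficients: np.ndarray  # b0, b1 (, b2)
    covariance: np.ndarray
    midpoint: float
    slope: float  # carcasses per market day per month
    slope_se: float
    ci95_halfwidth: float
    normalized_slope: float | None
    n: int
    f_pvalue: float  # partial F-test of quadratic vs linear


def fit_period_trend(y, months, alpha: float = 0.05, period: str = "") -> TrendFit:
    """Quadratic-vs-linear trend fit for one period.

    ``months`` are the global serial month numbers of the period; the
    midpoint slope is evaluated at their midrange.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(months, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError(f"period needs >= 6 months, got {n}")
    t_m = 0.5 * (t.min() + t.max())

    Xl = np.column_stack([np.ones(n), t])
    Xq = np.column_stack([np.ones(n), t, t**2])
    bl, rss_l, cov_l = _ols(Xl, y)
    bq, rss_q, cov_q = _ols(Xq, y)

    df_q = n - 3
    if df_q <= 0:
        raise ValueError("too few points for a quadratic fit")
    f = max(rss_l - rss_q, 0.0) / (rss_q / df_q) if rss_q > 0 else np.inf
    f_p = float(stats.f.sf(f, 1, df_q))

    if f_p < alpha:
        slope = bq[1] + 2.0 * bq[2] * t_m
        var = cov_q[1, 1] + 4 * t_m**2 * cov_q[2, 2] + 4 * t_m * cov_q[1, 2]
        df = df_q
        model, b, cov = "quadratic", bq, cov_q
    else:
        slope = bl[1]
        var = cov_l[1, 1]
        df = n - 2
        model, b, cov = "linear", bl, cov_l
    se = float(np.sqrt(max(var, 0.0)))
    half = float(stats.t.ppf(0.975, df) * se)
    return TrendFit(
        period=period, model=model, coefficients=b, covariance=cov,
        midpoint=t_m, slope=float(slope), slope_se=se,
        ci95_halfwidth=half, normalized_slope=None, n=n, f_pvalue=f_p,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ X.T @ y
    resid = y - X @ b
    rss = float(resid @ resid)
    df = len(y) - X.shape[1]
    sigma2 = rss / df if df > 0 else np.nan
    return b, rss, sigma2 * XtX_inv


def normalize_slope(slope: float, taxon_series, total_series, method: str = "sd_ratio") -> float:
    """Rescale a taxon's slope for cross-taxon comparison.

    ``sd_ratio`` divides by SD(taxon)/SD(total) over the full series (the
    slightly more conservative choice for uncommon taxa); ``fraction``
    divides by mean(taxon)/mean(total), the taxon's share of the market.
    """
    x = np.asarray(taxon_series, dtype=float)
    tot = np.asarray(total_series, dtype=float)
    if method == "sd_ratio":
        sx, st = np.std(x, ddof=1), np.std(tot, ddof=1)
        if sx == 0 or st == 0:
            raise ValueError("zero standard deviation in normalization series")
        return float(slope / (sx / st))
    if method == "fraction":
        mx, mt = np.mean(x), np.mean(tot)
        if mx == 0 or mt == 0:
            raise ValueError("zero mean in normalization series")
        return float(slope / (mx / mt))
    raise ValueError(f"unknown normalization method {method!r}")


def compare_slopes(fits: dict[str, TrendFit] | list[TrendFit]) -> pd.DataFrame:
    """Pairwise period comparison of slopes.

    Reports a Welch-type z-test on the slope difference (the operational
    definition of "significantly different") alongside the cruder
    95%-CI-overlap check.
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.period, f) for f in fits]
    if len(items) < 2:
        raise ValueError("need at least two period fits to compare")
    rows = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (la, fa), (lb, fb) = items[i], items[j]
            se = np.hypot(fa.slope_se, fb.slope_se)
            z = (fa.slope - fb.slope) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            no_overlap = (
                fa.slope - fa.ci95_halfwidth > fb.slope + fb.ci95_halfwidth
                or fb.slope - fb.ci95_halfwidth > fa.slope + fa.ci95_halfwidth
            )
            rows.append(
                {
                    "period_a": la, "period_b": lb,
                    "slope_a": fa.slope, "slope_b": fb.slope,
                    "z": float(z), "p_value": float(p),
                    "significant": bool(p < 0.05),
                    "ci_nonoverlap": bool(no_overlap),
                }
            )
    return pd.DataFrame(rows)
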