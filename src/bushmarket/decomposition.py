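"""Loess smoothing and the additive trend/seasonal/error split.

The monthly carcass rate is partitioned as

    Y_t = T_t + S_t + E_t

where T_t is the long-term trend, S_t the seasonal component and E_t the
monthly error.  The trend is a first-order loess over the 24 nearest
monthly points; the residual Y - T is smoothed with a second-order loess
over 6 points to give S, and E is defined by subtraction, so additivity
is exact by construction.  Loess here means local polynomial regression
with tricube weights over a fixed number of nearest neighbors and no
robustness iterations.

``deseasonalize`` (T + E) feeds the trend regressions; ``denoise``
(T + S) feeds the income-proxy regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bushmarket.census_io import MonthlySeries


@dataclass
class DecompositionResult:
    months: pd.PeriodIndex
    Y: np.ndarray
    T: np.ndarray
    S: np.ndarray
    E: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.months.astype(str), "Y": self.Y, "T": self.T, "S": self.S, "E": self.E}
        )


def loess_smooth(y, q: int, degree: int = 1) -> np.ndarray:
    """Loess-smooth a regularly spaced series.

    At each point the ``q`` nearest neighbors (by index distance) get
    tricube weights ``(1 - (d / d_max)^3)^3`` and a degree-``degree``
    weighted least-squares polynomial is evaluated at the point.  Boundary
    windows shrink asymmetrically, as in standard local regression.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if q < degree + 2:
        raise ValueError(f"q={q} too small for degree {degree} (need >= {degree + 2})")
    if q > n:
        raise ValueError(f"q={q} exceeds series length {n}")
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        idx = np.argsort(dist, kind="stable")[:q]
        d = dist[idx]
        dmax = d.max()
        if dmax == 0:
            out[i] = y[i]
            continue
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        # the farthest point gets weight 0; centre local coordinates on x_i
        u = x[idx] - x[i]
        cols = [np.ones_like(u), u] + ([u**2] if degree == 2 else [])
        X = np.column_stack(cols)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]  # polynomial evaluated at u = 0
    return out


def decompose(
    series: MonthlySeries | pd.Series | np.ndarray,
    q_trend: int = 24,
    q_seasonal: int = 6,
) -> DecompositionResult:
    """Two-stage loess decomposition Y = T + S + E.

    T is a degree-1 loess over ``q_trend`` points; S is a degree-2 loess of
    the detrended series over ``q_seasonal`` points; E = Y - T - S.
    """
    if isinstance(series, MonthlySeries):
        months, y = series.months, series.values
    elif isinstance(series, pd.Series):
        months = pd.PeriodIndex(series.index, freq="M")
        y = series.to_numpy(dtype=float)
    else:
        y = np.asarray(series, dtype=float)
        months = pd.period_range("2000-01", periods=len(y), freq="M")
    if len(y) < q_trend:
        raise ValueError(f"series length {len(y)} shorter than trend span {q_trend}")
    T = loess_smooth(y, q=q_trend, degree=1)
    S = loess_smooth(y - T, q=q_seasonal, degree=2)
    E = y - T - S
    return DecompositionResult(months=months, Y=y, T=T, S=S, E=E)


def deseasonalize(result: DecompositionResult) -> pd.Series:
    """Trend plus error (T + E): seasonal variation removed."""
    return pd.Series(result.T + result.E, index=result.months, name="deseasonalized")


def denoise(result: DecompositionResult) -> pd.Series:
    """Trend plus seasonal (T + S): monthly error variation removed."""
    return pd.Series(result.T + result.S, index=result.months, name="denoised")
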