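"""Seasonal-ARIMA intervention (transfer-function) modelling.

The market series is analysed on the square-root scale as

    z_t = mu + sum_j m_t^(j) + N_t

where ``N_t`` is a zero-mean Gaussian SARIMA process — here an
ARIMA(p,0,0)x(P,0,0)_s — and each external event ``j`` (a coup attempt, a
hunting law, a trade ban) contributes a transfer response ``m_t`` built
from three primitives:

* a **step** ``w_S * S_t`` — a permanent shift in the mean from the event
  month on;
* a **pulse** ``w_P * P_t`` — a momentary deviation in the event month;
* a **time lag** ``1/(1 - delta B)`` applied to the pulse, which turns the
  spike into a geometric decay ``w_P * delta**(t - T)`` — the number of
  steps the perturbed mean needs to return to its (possibly shifted)
  baseline.

Estimation is exact Gaussian maximum likelihood via the state-space
(prediction-error) machinery of :mod:`statsmodels`; the nonlinear lag
parameter is handled by profiling the likelihood over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tsa.statespace.sarimax import SARIMAX


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SarimaSpec:
    """Shape and (optionally) coefficients of a SARIMA noise model.

    Orders follow the usual (p, d, q)x(P, D, Q)_s notation.  ``ar`` and
    ``seasonal_ar`` hold the autoregressive coefficients when the spec
    describes a concrete process (for simulation or as a fit result);
    ``mean`` is the process mean on the modelling (sqrt) scale and
    ``sigma`` the innovation standard deviation.
    """

    p: int = 2
    d: int = 0
    q: int = 0
    P: int = 1
    D: int = 0
    Q: int = 0
    s: int = 12
    ar: tuple[float, ...] = ()
    seasonal_ar: tuple[float, ...] = ()
    ma: tuple[float, ...] = ()
    seasonal_ma: tuple[float, ...] = ()
    mean: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("season length s must be >= 1")
        for name, coeffs, order in [
            ("ar", self.ar, self.p),
            ("seasonal_ar", self.seasonal_ar, self.P),
        ]:
            if coeffs and len(coeffs) != order:
                raise ValueError(f"{name} has {len(coeffs)} coefficients, order is {order}")

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal_order(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, self.s)

    def check_stationary(self) -> None:
        """Raise ``ValueError`` (reporting the offending roots) unless all
        AR polynomials have roots outside the unit circle."""
        for name, coeffs in [("ar", self.ar), ("seasonal_ar", self.seasonal_ar)]:
            if not coeffs:
                continue
            roots = _ar_poly_roots(coeffs)
            bad = roots[np.abs(roots) <= 1.0 + 1e-10]
            if bad.size:
                raise ValueError(
                    f"non-stationary {name} polynomial {coeffs}: "
                    f"roots inside/on unit circle: {bad}"
                )


def _ar_poly_roots(coeffs: Sequence[float]) -> np.ndarray:
    # polynomial 1 - c1 B - c2 B^2 - ...; np.roots wants highest degree first
    poly = np.r_[[-c for c in coeffs[::-1]], 1.0]
    return np.roots(poly)


def expand_ar_polynomial(ar: Sequence[float], seasonal_ar: Sequence[float], s: int) -> np.ndarray:
    """Coefficients a_k of the product AR polynomial, so that
    ``u_t = sum_k a_k u_{t-k} + eps_t``."""
    base = np.r_[1.0, [-c for c in ar]]
    seas = np.zeros(len(seasonal_ar) * s + 1)
    seas[0] = 1.0
    for j, c in enumerate(seasonal_ar, start=1):
        seas[j * s] = -c
    prod = np.convolve(base, seas)
    return -prod[1:]


@dataclass
class InterventionSpec:
    """One external event and its transfer-function components.

    A component is present when its weight is not None.  ``lag_delta``
    attaches the geometric-decay operator 1/(1 - delta B) to the pulse;
    ``lag_on_step=True`` attaches it to the step instead.  ``target_groups``
    is used by the synthetic census generator to decide which taxa the
    event perturbs (None means all).
    """

    event_month: str | pd.Period
    step_weight: float | None = None
    pulse_weight: float | None = None
    lag_delta: float | None = None
    lag_on_step: bool = False
    step_se: float | None = None
    pulse_se: float | None = None
    lag_se: float | None = None
    target_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.event_month = pd.Period(self.event_month, freq="M")
        if self.step_weight is None and self.pulse_weight is None:
            raise ValueError(f"intervention {self.event_month}: no component present")
        if self.lag_delta is not None:
            if abs(self.lag_delta) >= 1:
                raise ValueError(f"|lag_delta| must be < 1, got {self.lag_delta}")
            acted_on = self.step_weight if self.lag_on_step else self.pulse_weight
            if acted_on is None:
                raise ValueError("lag_delta requires the component it acts on to be present")

    @property
    def has_lag(self) -> bool:
        return self.lag_delta is not None

    def component_labels(self) -> list[str]:
        out = []
        tag = self.event_month.strftime("%Y-%m")
        if self.step_weight is not None:
            out.append(f"step_{tag}")
        if self.pulse_weight is not None:
            out.append(f"pulse_{tag}")
        return out


def fit_shapes(interventions: Sequence[InterventionSpec]) -> list[InterventionSpec]:
    """Fitting shapes matching a list of concrete interventions: the same
    components with zero starting weights (lag start 0.5)."""
    return [
        InterventionSpec(
            event_month=s.event_month,
            step_weight=0.0 if s.step_weight is not None else None,
            pulse_weight=0.0 if s.pulse_weight is not None else None,
            lag_delta=0.5 if s.has_lag else None,
            lag_on_step=s.lag_on_step,
            target_groups=s.target_groups,
        )
        for s in interventions
    ]


def transfer_response(spec: InterventionSpec, months: pd.PeriodIndex) -> np.ndarray:
    """Response series m_t of one intervention over ``months``.

    The pulse part follows the exact recursion
    ``m_t = delta * m_{t-1} + w_P * P_t`` (delta = 0 without a lag), the
    step part is ``w_S`` from the event month on, filtered by the same
    recursion when the lag acts on the step.
    """
    months = pd.PeriodIndex(months, freq="M")
    event = pd.Period(spec.event_month, freq="M")
    if event > months[-1]:
        raise ValueError(f"event {event} is after the series end {months[-1]}")
    k = months.asi8 - event.ordinal  # months since event; negative before
    delta = spec.lag_delta if spec.lag_delta is not None else 0.0
    resp = np.zeros(len(months))
    if spec.pulse_weight is not None:
        d = delta if not spec.lag_on_step else 0.0
        on = k >= 0
        resp[on] += spec.pulse_weight * np.power(d, k[on], dtype=float)
    if spec.step_weight is not None:
        on = k >= 0
        if spec.lag_on_step and delta != 0.0:
            # (1 - delta B)^-1 applied to the step: partial geometric sums
            resp[on] += spec.step_weight * (1 - np.power(delta, k[on] + 1)) / (1 - delta)
        else:
            resp[on] += spec.step_weight
    return resp


# ---------------------------------------------------------------------------
# noise-model fitting
# ---------------------------------------------------------------------------


@dataclass
class SarimaFit:
    """Estimated SARIMA noise model with standard errors and diagnostics."""

    spec: SarimaSpec
    ses: dict[str, float]
    params: dict[str, float]
    llf: float
    aic: float
    nobs: int
    result: object = field(repr=False, default=None)

    @property
    def ar_se(self) -> tuple[float, ...]:
        return tuple(self.ses[f"ar.L{i}"] for i in range(1, self.spec.p + 1))

    @property
    def seasonal_ar_se(self) -> tuple[float, ...]:
        return tuple(
            self.ses[f"ar.S.L{(i) * self.spec.s}"] for i in range(1, self.spec.P + 1)
        )


def _as_series(z) -> pd.Series:
    if isinstance(z, pd.Series):
        return z
    return pd.Series(np.asarray(z, dtype=float))


def _n_sarima_params(orders: SarimaSpec) -> int:
    return orders.p + orders.q + orders.P + orders.Q + 2  # + mean + sigma2


def sarima_fit(
    z,
    orders: SarimaSpec | None = None,
    method: str = "mle",
    include_mean: bool = True,
) -> SarimaFit:
    """Fit the SARIMA noise model to a (sqrt-scale) monthly series.

    ``method='mle'`` uses exact Gaussian maximum likelihood through the
    Kalman-filter prediction-error decomposition; ``method='css'``
    minimizes the conditional sum of squares (pure-AR models only), which
    also serves as an independent cross-check.
    """
    orders = orders or SarimaSpec()
    z = _as_series(z)
    if z.isna().any():
        raise ValueError("series contains missing values")
    n_par = _n_sarima_params(orders)
    if len(z) <= 5 * n_par:
        raise ValueError(f"series length {len(z)} too short for {n_par} parameters")
    if method == "css":
        return _css_fit(z, orders, include_mean)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")

    exog = pd.DataFrame({"intercept": np.ones(len(z))}) if include_mean else None
    model = SARIMAX(
        pd.Series(z.to_numpy()),
        exog=exog,
        order=orders.order,
        seasonal_order=orders.seasonal_order,
        trend="n",
        enforce_stationarity=True,
        enforce_invertibility=True,
    )
    res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        # one retry from perturbed starting values before giving up
        start = res.params * 0.9
        res2 = model.fit(start_params=start, disp=0, maxiter=500)
        if res2.mle_retvals.get("converged", True) or res2.llf > res.llf:
            res = res2
        else:
            gnorm = np.max(np.abs(res.mle_retvals.get("gopt", [np.nan])))
            raise RuntimeError(f"SARIMA optimizer did not converge (|grad| = {gnorm:.3g})")
    return _wrap_sarima_result(res, orders)


def _wrap_sarima_result(res, orders: SarimaSpec) -> SarimaFit:
    params = dict(zip(res.model.param_names, np.asarray(res.params, dtype=float)))
    ses = dict(zip(res.model.param_names, np.asarray(res.bse, dtype=float)))
    ar = tuple(params.get(f"ar.L{i}", 0.0) for i in range(1, orders.p + 1))
    sar = tuple(params.get(f"ar.S.L{i * orders.s}", 0.0) for i in range(1, orders.P + 1))
    spec = replace(
        orders,
        ar=ar,
        seasonal_ar=sar,
        mean=params.get("intercept", 0.0),
        sigma=float(np.sqrt(params["sigma2"])),
    )
    return SarimaFit(
        spec=spec,
        ses=ses,
        params=params,
        llf=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
        result=res,
    )


def _css_fit(z: pd.Series, orders: SarimaSpec, include_mean: bool) -> SarimaFit:
    if orders.d or orders.D or orders.q or orders.Q:
        raise ValueError("css method supports pure AR models only")
    y = z.to_numpy(dtype=float)
    maxlag = orders.p + orders.P * orders.s

    def resid(theta: np.ndarray) -> np.ndarray:
        mu = theta[0] if include_mean else 0.0
        off = 1 if include_mean else 0
        ar = theta[off : off + orders.p]
        sar = theta[off + orders.p : off + orders.p + orders.P]
        a = expand_ar_polynomial(ar, sar, orders.s)
        u = y - mu
        e = u[maxlag:].copy()
        for k, ak in enumerate(a, start=1):
            e -= ak * u[maxlag - k : len(y) - k]
        return e

    x0 = np.r_[[np.mean(y)] if include_mean else [], np.zeros(orders.p + orders.P)]
    sol = optimize.least_squares(resid, x0, method="lm")
    if not sol.success:
        raise RuntimeError(f"CSS optimizer failed: {sol.message}")
    e = resid(sol.x)
    n_eff = len(e)
    sigma2 = float(np.sum(e**2) / n_eff)
    # Gauss-Newton covariance of the CSS estimates
    J = sol.jac
    cov = sigma2 * np.linalg.inv(J.T @ J)
    se = np.sqrt(np.diag(cov))
    off = 1 if include_mean else 0
    names = (["intercept"] if include_mean else []) + [
        f"ar.L{i}" for i in range(1, orders.p + 1)
    ] + [f"ar.S.L{i * orders.s}" for i in range(1, orders.P + 1)]
    params = dict(zip(names, sol.x))
    ses = dict(zip(names, se))
    params["sigma2"] = sigma2
    llf = -0.5 * n_eff * (np.log(2 * np.pi * sigma2) + 1)
    spec = replace(
        orders,
        ar=tuple(sol.x[off : off + orders.p]),
        seasonal_ar=tuple(sol.x[off + orders.p :]),
        mean=params.get("intercept", 0.0),
        sigma=float(np.sqrt(sigma2)),
    )
    k = len(sol.x) + 1
    return SarimaFit(
        spec=spec, ses=ses, params=params, llf=llf, aic=2 * k - 2 * llf,
        nobs=len(y), result=None,
    )


# ---------------------------------------------------------------------------
# joint intervention fitting
# ---------------------------------------------------------------------------


@dataclass
class LjungBoxResult:
    statistic: float
    df: int
    pvalue: float


@dataclass
class InterventionFit:
    """Joint fit of the SARIMA noise model and intervention weights."""

    noise: SarimaFit
    interventions: list[InterventionSpec]
    rmse: float
    aic: float
    llf: float
    ljung_box: LjungBoxResult
    fitted: pd.Series
    months: pd.PeriodIndex
    cov_weights: pd.DataFrame  # intercept + intervention weights
    _z: pd.Series = field(repr=False, default=None)
    _orders: SarimaSpec = field(repr=False, default=None)

    def mean_path(self, params_override: dict | None = None) -> pd.Series:
        """Deterministic model mean mu + sum_j m_t over the fitted months."""
        mu = self.noise.spec.mean
        specs = self.interventions
        if params_override:
            mu = params_override.get("intercept", mu)
            specs = params_override.get("interventions", specs)
        total = np.full(len(self.months), mu, dtype=float)
        for spec in specs:
            total += transfer_response(spec, self.months)
        return pd.Series(total, index=self.months)

    def parameter_table(self) -> pd.DataFrame:
        """Per-event estimate (SE) table: one column per event, rows
        step / pulse / time lag."""
        cols = {}
        for spec in self.interventions:
            tag = spec.event_month.strftime("%m/%Y")
            cols[tag] = {
                "step": _fmt(spec.step_weight, spec.step_se),
                "pulse": _fmt(spec.pulse_weight, spec.pulse_se),
                "time_lag": _fmt(spec.lag_delta, spec.lag_se) if spec.has_lag else "---",
            }
        return pd.DataFrame(cols)


def _fmt(est: float | None, se: float | None) -> str:
    if est is None:
        return "---"
    return f"{est:.3f} ({se:.3f})" if se is not None else f"{est:.3f}"


def _require_period_index(z) -> pd.Series:
    z = _as_series(z)
    if not isinstance(z.index, pd.PeriodIndex):
        z = pd.Series(z.to_numpy(), index=pd.period_range("2000-01", periods=len(z), freq="M"))
    return z


def _build_exog(
    interventions: list[InterventionSpec], months: pd.PeriodIndex, deltas: np.ndarray
) -> pd.DataFrame:
    """Unit-weight response columns; ``deltas`` supplies lag values for the
    events that carry one (in order)."""
    cols = {}
    di = 0
    for spec in interventions:
        delta = None
        if spec.has_lag:
            delta = float(deltas[di])
            di += 1
        tag = spec.event_month.strftime("%Y-%m")
        if spec.step_weight is not None:
            unit = InterventionSpec(
                spec.event_month, step_weight=1.0,
                lag_delta=delta if spec.lag_on_step else None, lag_on_step=spec.lag_on_step,
            )
            cols[f"step_{tag}"] = transfer_response(unit, months)
        if spec.pulse_weight is not None:
            unit = InterventionSpec(
                spec.event_month, pulse_weight=1.0,
                lag_delta=delta if not spec.lag_on_step else None,
            )
            cols[f"pulse_{tag}"] = transfer_response(unit, months)
    return pd.DataFrame(cols, index=months)


def _start_params(model, y: np.ndarray, X: np.ndarray, orders: SarimaSpec) -> np.ndarray:
    """OLS starting values for the regression weights; mild positive AR
    starts; residual variance for sigma2."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    start = {}
    for name, b in zip(model.exog_names, beta):
        start[name] = float(b)
    for i in range(1, orders.p + 1):
        start[f"ar.L{i}"] = 0.3 / i
    for i in range(1, orders.q + 1):
        start[f"ma.L{i}"] = 0.0
    for i in range(1, orders.P + 1):
        start[f"ar.S.L{i * orders.s}"] = 0.2
    for i in range(1, orders.Q + 1):
        start[f"ma.S.L{i * orders.s}"] = 0.0
    start["sigma2"] = float(np.var(resid)) * 0.8 + 1e-8
    return np.array([start.get(n, 0.0) for n in model.param_names])


def arimax_fit(
    z,
    orders: SarimaSpec | None = None,
    interventions: Sequence[InterventionSpec] = (),
    lb_lags: int = 12,
) -> InterventionFit:
    """Joint ML fit of ``z_t = mu + sum_j m_t^(j) + N_t``.

    Intervention components enter as regression terms with SARIMA errors;
    a geometric lag parameter, being nonlinear, is profiled: for each
    candidate delta the remaining parameters are maximized exactly, and
    the profile likelihood is optimized over delta.  Its standard error
    comes from the curvature of the profile log-likelihood.
    """
    orders = orders or SarimaSpec()
    z = _require_period_index(z)
    if z.isna().any():
        raise ValueError("series contains missing values")
    interventions = [replace(s) for s in interventions]
    months = pd.PeriodIndex(z.index, freq="M")
    labels = [lab for s in interventions for lab in s.component_labels()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"collinear interventions: duplicated components {labels}")
    for s in interventions:
        if pd.Period(s.event_month, "M") < months[0] or pd.Period(s.event_month, "M") > months[-1]:
            raise ValueError(f"event {s.event_month} outside series range")
    if not interventions:
        base = sarima_fit(z, orders)
        resid = np.asarray(base.result.resid, dtype=float)
        lb = ljung_box(resid, lags=lb_lags, n_fitted_params=orders.p + orders.P)
        cov = _weights_cov(base.result, ["intercept"])
        return InterventionFit(
            noise=base, interventions=[], rmse=float(np.sqrt(np.mean(resid**2))),
            aic=base.aic, llf=base.llf, ljung_box=lb,
            fitted=pd.Series(np.asarray(base.result.fittedvalues), index=months),
            months=months, cov_weights=cov, _z=z, _orders=orders,
        )

    lagged = [s for s in interventions if s.has_lag]
    state: dict = {True: None, False: None}

    def fit_given_deltas(
        deltas: np.ndarray, maxiter: int = 200, concentrated: bool = False, final: bool = False
    ):
        exog = _build_exog(interventions, months, deltas)
        exog.insert(0, "intercept", 1.0)
        model = SARIMAX(
            pd.Series(z.to_numpy()), exog=exog.reset_index(drop=True),
            order=orders.order, seasonal_order=orders.seasonal_order,
            trend="n", enforce_stationarity=True, enforce_invertibility=True,
            concentrate_scale=concentrated,
        )
        start = state[concentrated]
        if start is None and not concentrated and state[True] is not None:
            # reuse the concentrated solution, appending its scale as sigma2
            start = np.r_[state[True][0], state[True][1]]
        if start is None or len(start) != model.k_params:
            start = _start_params(model, z.to_numpy(), exog.to_numpy(), orders)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(start_params=start, disp=0, maxiter=maxiter)
            if final and not res.mle_retvals.get("converged", True):
                res2 = model.fit(disp=0, maxiter=500)
                if res2.llf > res.llf:
                    res = res2
        if concentrated:
            state[True] = (np.asarray(res.params), float(res.scale))
        else:
            state[False] = np.asarray(res.params)
        return res, exog

    if lagged:
        d0 = np.array([s.lag_delta for s in lagged], dtype=float)

        def neg_profile(dvec: np.ndarray, maxiter: int = 200) -> float:
            # concentrated-scale fits: same profile likelihood, cheaper
            res, _ = fit_given_deltas(np.atleast_1d(dvec), maxiter=maxiter, concentrated=True)
            return -float(res.llf)

        if len(lagged) == 1:
            # the profile in delta can be multimodal (a decaying pulse can
            # be traded off against the AR terms), so scan a coarse grid
            # with iteration-capped fits before the local refine
            grid = np.unique(np.r_[np.linspace(-0.9, 0.9, 7), 0.95, 0.975, d0])
            vals = [neg_profile(np.array([d]), maxiter=50) for d in grid]
            i_best = int(np.argmin(vals))
            lo = grid[i_best - 1] if i_best > 0 else -0.995
            hi = grid[i_best + 1] if i_best < len(grid) - 1 else 0.995
            sol = optimize.minimize_scalar(
                lambda d: neg_profile(np.array([d])),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 2e-3},
            )
            dhat = np.array([sol.x])
        else:
            sol = optimize.minimize(
                neg_profile, d0, method="L-BFGS-B",
                bounds=[(-0.995, 0.995)] * len(lagged),
            )
            dhat = np.asarray(sol.x)
        lag_ses = _profile_ses(neg_profile, dhat)
    else:
        dhat = np.array([])
        lag_ses = []

    res, exog = fit_given_deltas(dhat, final=True)
    params = dict(zip(res.model.param_names, np.asarray(res.params, dtype=float)))
    ses = dict(zip(res.model.param_names, np.asarray(res.bse, dtype=float)))

    di = 0
    fitted_specs: list[InterventionSpec] = []
    for spec in interventions:
        tag = spec.event_month.strftime("%Y-%m")
        new = replace(spec)
        if spec.step_weight is not None:
            new.step_weight = params[f"step_{tag}"]
            new.step_se = ses[f"step_{tag}"]
        if spec.pulse_weight is not None:
            new.pulse_weight = params[f"pulse_{tag}"]
            new.pulse_se = ses[f"pulse_{tag}"]
        if spec.has_lag:
            new.lag_delta = float(dhat[di])
            new.lag_se = float(lag_ses[di])
            di += 1
        fitted_specs.append(new)

    noise = _wrap_sarima_result_named(res, orders, params, ses)
    resid = np.asarray(res.resid, dtype=float)
    n_fitted = orders.p + orders.P + orders.q + orders.Q
    lb = ljung_box(resid, lags=lb_lags, n_fitted_params=n_fitted)
    weight_names = list(exog.columns)  # intercept first
    cov = _weights_cov(res, weight_names)
    # the profiled lag parameters count toward AIC
    k_extra = len(dhat)
    return InterventionFit(
        noise=noise, interventions=fitted_specs,
        rmse=float(np.sqrt(np.mean(resid**2))),
        aic=float(res.aic) + 2 * k_extra, llf=float(res.llf), ljung_box=lb,
        fitted=pd.Series(np.asarray(res.fittedvalues), index=months),
        months=months, cov_weights=cov, _z=z, _orders=orders,
    )


def _wrap_sarima_result_named(res, orders, params, ses) -> SarimaFit:
    ar = tuple(params.get(f"ar.L{i}", 0.0) for i in range(1, orders.p + 1))
    sar = tuple(params.get(f"ar.S.L{i * orders.s}", 0.0) for i in range(1, orders.P + 1))
    spec = replace(
        orders, ar=ar, seasonal_ar=sar,
        mean=params.get("intercept", 0.0),
        sigma=float(np.sqrt(params["sigma2"])),
    )
    return SarimaFit(
        spec=spec, ses=ses, params=params, llf=float(res.llf),
        aic=float(res.aic), nobs=int(res.nobs), result=res,
    )


def _weights_cov(res, names: list[str], name_map: dict | None = None) -> pd.DataFrame:
    cov = res.cov_params()
    if not isinstance(cov, pd.DataFrame):
        cov = pd.DataFrame(cov, index=res.model.param_names, columns=res.model.param_names)
    if name_map:
        cov = cov.rename(index=name_map, columns=name_map)
    present = [n for n in names if n in cov.index]
    return cov.loc[present, present]


def _profile_ses(neg_profile, dhat: np.ndarray, h: float = 5e-3) -> list[float]:
    """SEs of profiled lag parameters from the profile-likelihood curvature."""
    ses = []
    for i in range(len(dhat)):
        def f(x):
            d = dhat.copy()
            d[i] = x
            return neg_profile(d)
        x0 = float(dhat[i])
        hi = min(h, 0.995 - abs(x0))  # keep the stencil inside the bounds
        f0, fp, fm = f(x0), f(x0 + hi), f(x0 - hi)
        curv = (fp - 2 * f0 + fm) / hi**2
        ses.append(float(np.sqrt(1.0 / curv)) if curv > 0 else np.nan)
    return ses


def prune_nonsignificant(fit: InterventionFit, z_crit: float = 1.96) -> InterventionFit:
    """Iteratively drop intervention components with |estimate|/SE below
    ``z_crit`` (least significant first, one at a time) and refit."""
    current = fit
    while True:
        candidates: list[tuple[float, int, str]] = []
        for j, spec in enumerate(current.interventions):
            if spec.step_weight is not None and spec.step_se:
                candidates.append((abs(spec.step_weight) / spec.step_se, j, "step"))
            if spec.pulse_weight is not None and spec.pulse_se:
                candidates.append((abs(spec.pulse_weight) / spec.pulse_se, j, "pulse"))
        weak = [c for c in candidates if c[0] < z_crit]
        if not weak:
            return current
        _, j, comp = min(weak)
        new_specs = []
        for i, spec in enumerate(current.interventions):
            spec = replace(spec)
            if i == j:
                if comp == "step":
                    spec.step_weight = None
                    spec.step_se = None
                    if spec.lag_on_step:
                        spec.lag_delta = None
                else:
                    spec.pulse_weight = None
                    spec.pulse_se = None
                    if spec.has_lag and not spec.lag_on_step:
                        spec.lag_delta = None
                if spec.step_weight is None and spec.pulse_weight is None:
                    continue
                # reset the lag start value for the refit
                if spec.has_lag:
                    spec.lag_delta = 0.5
            elif spec.has_lag:
                spec.lag_delta = 0.5
            new_specs.append(spec)
        current = arimax_fit(current._z, current._orders, new_specs)


# ---------------------------------------------------------------------------
# diagnostics and effect sizes
# ---------------------------------------------------------------------------


def ljung_box(residuals, lags: int = 12, n_fitted_params: int = 0) -> LjungBoxResult:
    """Ljung-Box portmanteau statistic
    ``Q = n (n + 2) sum_{k<=L} rho_k^2 / (n - k)``.

    Degrees of freedom are ``L - n_fitted_params`` (floored at 1), the
    usual correction when the residuals come from a fitted ARMA model.
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if lags >= n / 2:
        raise ValueError(f"lags={lags} too large for series of length {n}")
    e = e - e.mean()
    denom = float(np.sum(e**2))
    if denom == 0:
        raise ValueError("constant residuals: autocorrelation undefined")
    q = 0.0
    for k in range(1, lags + 1):
        rho = float(np.sum(e[k:] * e[:-k])) / denom
        q += rho**2 / (n - k)
    q *= n * (n + 2)
    df = max(lags - n_fitted_params, 1)
    return LjungBoxResult(statistic=float(q), df=df, pvalue=float(stats.chi2.sf(q, df)))


def percent_change(
    fit: InterventionFit,
    from_month,
    to_month,
    method: str = "delta",
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Percent change in the back-transformed (squared) model mean between
    two months, with a 95% CI.

    Returns ``100 * (y_from - y_to) / y_from`` where ``y = (model mean)^2``
    on the original carcass-rate scale.  The CI propagates uncertainty in
    the intercept and intervention weights — by the delta method
    (``method='delta'``) or by a parametric bootstrap resampling the
    weights from their estimated Gaussian (``method='bootstrap'``).  The
    profiled lag parameter is held at its estimate; its uncertainty is
    small in the fitted models (SE ~ 0.01) and is not propagated.
    """
    from_p = pd.Period(from_month, freq="M")
    to_p = pd.Period(to_month, freq="M")
    for p in (from_p, to_p):
        if p not in fit.months:
            raise ValueError(f"month {p} not in fitted range")

    weight_names = list(fit.cov_weights.index)
    theta_hat = _pack_weights(fit, weight_names)

    def pct(theta: np.ndarray) -> float:
        path = _mean_path_from_theta(fit, weight_names, theta)
        y_from = float(path[from_p]) ** 2
        y_to = float(path[to_p]) ** 2
        if y_from == 0:
            raise ValueError("model mean is zero at the reference month")
        return 100.0 * (y_from - y_to) / y_from

    est = pct(theta_hat)
    cov = fit.cov_weights.to_numpy()
    if method == "delta":
        g = np.zeros(len(theta_hat))
        h = 1e-6 * np.maximum(np.abs(theta_hat), 1.0)
        for i in range(len(theta_hat)):
            up, dn = theta_hat.copy(), theta_hat.copy()
            up[i] += h[i]
            dn[i] -= h[i]
            g[i] = (pct(up) - pct(dn)) / (2 * h[i])
        var = float(g @ cov @ g)
        half = 1.96 * np.sqrt(max(var, 0.0))
        return est, (est - half, est + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(theta_hat, cov, size=n_boot)
        vals = np.array([pct(d) for d in draws])
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return est, (float(lo), float(hi))
    raise ValueError(f"unknown method {method!r}")


def _pack_weights(fit: InterventionFit, names: list[str]) -> np.ndarray:
    vals = []
    for name in names:
        if name == "intercept":
            vals.append(fit.noise.spec.mean)
        else:
            comp, tag = name.split("_", 1)
            spec = next(
                s for s in fit.interventions if s.event_month.strftime("%Y-%m") == tag
            )
            vals.append(spec.step_weight if comp == "step" else spec.pulse_weight)
    return np.array(vals, dtype=float)


def _mean_path_from_theta(
    fit: InterventionFit, names: list[str], theta: np.ndarray
) -> pd.Series:
    mu = fit.noise.spec.mean
    specs = [replace(s) for s in fit.interventions]
    by_tag = {s.event_month.strftime("%Y-%m"): s for s in specs}
    for name, val in zip(names, theta):
        if name == "intercept":
            mu = float(val)
        else:
            comp, tag = name.split("_", 1)
            if comp == "step":
                by_tag[tag].step_weight = float(val)
            else:
                by_tag[tag].pulse_weight = float(val)
    total = np.full(len(fit.months), mu)
    for s in specs:
        total += transfer_response(s, fit.months)
    return pd.Series(total, index=fit.months)
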