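"""Synthetic bushmeat-market census generator.

Emulates the statistical structure the downstream analysis assumes: daily
species-level carcass counts with period-specific linear trends, 12-month
multiplicative seasonality, a capture-method mix shifting from trap to
shotgun across periods, an island/import origin mix, and sqrt-scale
SARIMA noise perturbed by pulse/step/lagged-step intervention responses.
The generator and the estimator are conjugate on the sqrt scale —
intervention effects multiply the expected rate through its square root —
so parameter-recovery tests exercise exactly the fitted model.

Counts are Poisson by default (the field data only record totals, so any
count law is an assumption; a negative-binomial option adds
overdispersion).  All randomness flows from one integer seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from bushmarket._seeding import substream
from bushmarket.intervention_ts import (
    InterventionSpec,
    SarimaSpec,
    expand_ar_polynomial,
    transfer_response,
)

VALID_GROUPS = ("avian", "primate", "reptile", "rodent", "ungulate", "other")

#: arrival condition mix: mostly fresh, some smoked, few alive
DEFAULT_CONDITION_PROBS = {"fresh": 0.82, "smoked": 0.13, "alive": 0.05}


@dataclass
class SpeciesProfile:
    """Generative profile of one species.

    ``trend_per_month_by_period`` and ``shotgun_probability_by_period``
    hold one value per market period (the study design has three).  The
    expected per-market-day rate in global month t is

        lambda_t = max(0, r_t * (1 + amplitude * cos(2*pi*(t - phase)/12)))

    where r_t accumulates the period-specific monthly trend on top of
    ``baseline_rate``.
    """

    name: str
    group: str
    mass_kg: float = 1.0
    island_proportion: float = 1.0
    shotgun_probability_by_period: tuple[float, ...] = (0.5,)
    baseline_rate: float = 1.0
    trend_per_month_by_period: tuple[float, ...] = (0.0,)
    seasonal_amplitude: float = 0.0
    seasonal_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {VALID_GROUPS}")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if not 0 <= self.island_proportion <= 1:
            raise ValueError("island_proportion must be in [0, 1]")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        self.shotgun_probability_by_period = tuple(self.shotgun_probability_by_period)
        self.trend_per_month_by_period = tuple(self.trend_per_month_by_period)


@dataclass
class MarketDaysSpec:
    """Market days per month: ``base`` minus a binomial dropout.

    The default reflects a six-day market week (26 working days) with
    occasional closures.
    """

    base: int = 26
    max_dropout: int = 4
    dropout_prob: float = 0.25


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic market scenario."""

    start_month: str = "1997-10"
    n_months: int = 156
    species_profiles: list[SpeciesProfile] = field(default_factory=list)
    interventions: list[InterventionSpec] = field(default_factory=list)
    noise: SarimaSpec = field(default_factory=lambda: SarimaSpec(ar=(0.343, 0.301), seasonal_ar=(0.208,), sigma=0.323))
    market_days: MarketDaysSpec = field(default_factory=MarketDaysSpec)
    period_starts: tuple[str, ...] = ("2003-04", "2007-11")
    condition_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONDITION_PROBS))
    price_per_kg_fcfa: float = 2500.0
    price_lognorm_sd: float = 0.25
    count_model: str = "poisson"
    negbin_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 24:
            raise ValueError("n_months must be >= 24")
        if self.count_model not in ("poisson", "negbin"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        n_periods = len(self.period_starts) + 1
        for sp in self.species_profiles:
            for attr in ("shotgun_probability_by_period", "trend_per_month_by_period"):
                vals = getattr(sp, attr)
                if len(vals) == 1:
                    setattr(sp, attr, vals * n_periods)
                elif len(vals) != n_periods:
                    raise ValueError(
                        f"{sp.name}.{attr}: {len(vals)} values for {n_periods} periods"
                    )

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=self.n_months, freq="M")

    def period_index(self) -> np.ndarray:
        """0-based period number of every month."""
        months = self.months
        idx = np.zeros(self.n_months, dtype=int)
        for b in self.period_starts:
            idx += (months >= pd.Period(b, freq="M")).astype(int)
        return idx


# ---------------------------------------------------------------------------
# expected rates
# ---------------------------------------------------------------------------


def expected_rates(config: ScenarioConfig, profile: SpeciesProfile) -> np.ndarray:
    """Expected carcasses per market day for one species in every month,
    including seasonal modulation and sqrt-scale intervention effects."""
    t = np.arange(1, config.n_months + 1, dtype=float)
    periods = config.period_index()
    incr = np.array([profile.trend_per_month_by_period[p] for p in periods])
    r = profile.baseline_rate + np.cumsum(incr)
    seasonal = 1.0 + profile.seasonal_amplitude * np.cos(
        2 * np.pi * (t - profile.seasonal_phase) / 12.0
    )
    lam = np.maximum(0.0, r * seasonal)
    m = _intervention_response(config, profile.group)
    if m is not None:
        lam = np.maximum(0.0, np.sqrt(lam) + m) ** 2
    return lam


def _intervention_response(config: ScenarioConfig, group: str) -> np.ndarray | None:
    relevant = [
        s for s in config.interventions
        if s.target_groups is None or group in s.target_groups
    ]
    if not relevant:
        return None
    months = config.months
    return np.sum([transfer_response(s, months) for s in relevant], axis=0)


# ---------------------------------------------------------------------------
# census generation
# ---------------------------------------------------------------------------


def generate_market_calendar(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    spec = config.market_days
    dropout = rng.binomial(spec.max_dropout, spec.dropout_prob, size=config.n_months)
    days = spec.base - dropout
    months = config.months
    return pd.DataFrame(
        {"year": months.year, "month": months.month, "market_days": days}
    )


def generate_census(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the daily carcass-record table and the market-day calendar.

    Returns ``(records, calendar)``.  Records have one row per carcass with
    columns date (ISO-8601), species, group, method, origin, condition,
    price_fcfa.  Identical configs (including seed) give identical tables.
    """
    if not config.species_profiles:
        raise ValueError("scenario has no species profiles")
    rng = substream(config.seed, "census")
    calendar = generate_market_calendar(config, rng)
    months = config.months
    periods = config.period_index()
    cond_names = list(config.condition_probs)
    cond_p = np.array([config.condition_probs[c] for c in cond_names], dtype=float)
    cond_p = cond_p / cond_p.sum()

    rows: list[pd.DataFrame] = []
    for profile in config.species_profiles:
        lam = expected_rates(config, profile)
        for i, month in enumerate(months):
            n_days = int(calendar["market_days"].iloc[i])
            if n_days == 0 or lam[i] == 0:
                continue
            day_counts = _draw_counts(rng, lam[i], n_days, config)
            total = int(day_counts.sum())
            if total == 0:
                continue
            day_of_month = np.repeat(np.arange(1, n_days + 1), day_counts)
            dates = pd.Timestamp(month.start_time) + pd.to_timedelta(day_of_month - 1, unit="D")
            p_shot = profile.shotgun_probability_by_period[periods[i]]
            method = np.where(rng.random(total) < p_shot, "shotgun", "trap")
            origin = np.where(rng.random(total) < profile.island_proportion, "island", "import")
            condition = rng.choice(cond_names, size=total, p=cond_p)
            price = np.round(
                profile.mass_kg
                * config.price_per_kg_fcfa
                * rng.lognormal(0.0, config.price_lognorm_sd, size=total),
                -1,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "date": dates.strftime("%Y-%m-%d"),
                        "species": profile.name,
                        "group": profile.group,
                        "method": method,
                        "origin": origin,
                        "condition": condition,
                        "price_fcfa": price,
                    }
                )
            )
    if rows:
        records = pd.concat(rows, ignore_index=True)
        records = records.sort_values(
            ["date", "species"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        records = pd.DataFrame(
            columns=["date", "species", "group", "method", "origin", "condition", "price_fcfa"]
        )
    return records, calendar


def _draw_counts(
    rng: np.random.Generator, lam: float, n_days: int, config: ScenarioConfig
) -> np.ndarray:
    if config.count_model == "poisson":
        return rng.poisson(lam, size=n_days)
    # negative binomial with mean lam and variance lam * (1 + lam / k)
    k = config.negbin_dispersion
    p = k / (k + lam)
    return rng.negative_binomial(k, p, size=n_days)


# ---------------------------------------------------------------------------
# sqrt-scale series generation
# ---------------------------------------------------------------------------

BURN_IN_MONTHS = 120  # ten seasonal cycles


def simulate_sarima(
    noise: SarimaSpec, n: int, rng: np.random.Generator, burn_in: int = BURN_IN_MONTHS
) -> np.ndarray:
    """Zero-mean Gaussian SARIMA realization of length ``n`` (d = D = 0)."""
    if noise.d or noise.D or noise.q or noise.Q:
        raise ValueError("simulator supports pure (seasonal) AR models")
    if noise.sigma < 0:
        raise ValueError("innovation SD must be non-negative")
    noise.check_stationary()
    a = expand_ar_polynomial(noise.ar, noise.seasonal_ar, noise.s)
    maxlag = len(a)
    total = n + max(burn_in, 2 * maxlag)
    eps = rng.normal(0.0, noise.sigma, size=total)
    u = np.zeros(total)
    for t in range(total):
        acc = eps[t]
        for k in range(1, min(maxlag, t) + 1):
            acc += a[k - 1] * u[t - k]
        u[t] = acc
    return u[-n:]


def generate_sqrt_series(
    noise: SarimaSpec,
    interventions: Sequence[InterventionSpec],
    n_months: int,
    seed: int,
    start_month: str = "1997-10",
) -> pd.Series:
    """Monthly sqrt-scale series ``z_t = mu + m_t + N_t``.

    ``m_t`` is the summed transfer response of the interventions and
    ``N_t`` a Gaussian SARIMA realization (burn-in of ten seasonal cycles
    discarded).  Used as the exact generating process in
    parameter-recovery experiments.
    """
    if n_months <= 0:
        raise ValueError("n_months must be positive")
    rng = substream(seed, "sqrt_series")
    months = pd.period_range(start_month, periods=n_months, freq="M")
    z = noise.mean + simulate_sarima(noise, n_months, rng)
    for spec in interventions:
        z = z + transfer_response(spec, months)
    return pd.Series(z, index=months)


# ---------------------------------------------------------------------------
# scenario serialization
# ---------------------------------------------------------------------------


def scenario_to_yaml(config: ScenarioConfig) -> str:
    def _intervention(s: InterventionSpec) -> dict:
        d = {"event_month": str(s.event_month)}
        for k in ("step_weight", "pulse_weight", "lag_delta"):
            v = getattr(s, k)
            if v is not None:
                d[k] = float(v)
        if s.lag_on_step:
            d["lag_on_step"] = True
        if s.target_groups is not None:
            d["target_groups"] = list(s.target_groups)
        return d

    doc = {
        "start_month": config.start_month,
        "n_months": config.n_months,
        "seed": config.seed,
        "period_starts": list(config.period_starts),
        "count_model": config.count_model,
        "market_days": {
            "base": config.market_days.base,
            "max_dropout": config.market_days.max_dropout,
            "dropout_prob": config.market_days.dropout_prob,
        },
        "noise": {
            "order": list(config.noise.order),
            "seasonal_order": list(config.noise.seasonal_order),
            "ar": list(config.noise.ar),
            "seasonal_ar": list(config.noise.seasonal_ar),
            "mean": config.noise.mean,
            "sigma": config.noise.sigma,
        },
        "interventions": [_intervention(s) for s in config.interventions],
        "species": [
            {
                "name": sp.name,
                "group": sp.group,
                "mass_kg": sp.mass_kg,
                "island_proportion": sp.island_proportion,
                "baseline_rate": sp.baseline_rate,
                "trend_per_month_by_period": list(sp.trend_per_month_by_period),
                "shotgun_probability_by_period": list(sp.shotgun_probability_by_period),
                "seasonal_amplitude": sp.seasonal_amplitude,
                "seasonal_phase": sp.seasonal_phase,
            }
            for sp in config.species_profiles
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scenario_from_yaml(text_or_path) -> ScenarioConfig:
    if hasattr(text_or_path, "read"):
        doc = yaml.safe_load(text_or_path)
    elif "\n" in str(text_or_path):
        doc = yaml.safe_load(io.StringIO(str(text_or_path)))
    else:
        with open(text_or_path) as fh:
            doc = yaml.safe_load(fh)
    noise_doc = doc.get("noise", {})
    order = noise_doc.get("order", [2, 0, 0])
    sorder = noise_doc.get("seasonal_order", [1, 0, 0, 12])
    noise = SarimaSpec(
        p=order[0], d=order[1], q=order[2],
        P=sorder[0], D=sorder[1], Q=sorder[2], s=sorder[3],
        ar=tuple(noise_doc.get("ar", ())),
        seasonal_ar=tuple(noise_doc.get("seasonal_ar", ())),
        mean=float(noise_doc.get("mean", 0.0)),
        sigma=float(noise_doc.get("sigma", 1.0)),
    )
    interventions = [
        InterventionSpec(
            event_month=d["event_month"],
            step_weight=d.get("step_weight"),
            pulse_weight=d.get("pulse_weight"),
            lag_delta=d.get("lag_delta"),
            lag_on_step=d.get("lag_on_step", False),
            target_groups=tuple(d["target_groups"]) if d.get("target_groups") else None,
        )
        for d in doc.get("interventions", [])
    ]
    species = [
        SpeciesProfile(
            name=d["name"],
            group=d["group"],
            mass_kg=d.get("mass_kg", 1.0),
            island_proportion=d.get("island_proportion", 1.0),
            baseline_rate=d.get("baseline_rate", 1.0),
            trend_per_month_by_period=tuple(d.get("trend_per_month_by_period", (0.0,))),
            shotgun_probability_by_period=tuple(d.get("shotgun_probability_by_period", (0.5,))),
            seasonal_amplitude=d.get("seasonal_amplitude", 0.0),
            seasonal_phase=d.get("seasonal_phase", 0.0),
        )
        for d in doc.get("species", [])
    ]
    md = doc.get("market_days", {})
    return ScenarioConfig(
        start_month=str(doc.get("start_month", "1997-10")),
        n_months=int(doc.get("n_months", 156)),
        species_profiles=species,
        interventions=interventions,
        noise=noise,
        market_days=MarketDaysSpec(
            base=int(md.get("base", 26)),
            max_dropout=int(md.get("max_dropout", 4)),
            dropout_prob=float(md.get("dropout_prob", 0.25)),
        ),
        period_starts=tuple(doc.get("period_starts", ("2003-04", "2007-11"))),
        count_model=str(doc.get("count_model", "poisson")),
        seed=int(doc.get("seed", 0)),
    )
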