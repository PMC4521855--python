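"""Config-driven orchestration of the full market analysis.

Stages: generate or ingest the census -> prepare monthly rate series ->
intervention model on the sqrt primate series -> loess decomposition ->
per-period trend regressions -> association statistics.  Every
intermediate is written as CSV into the output directory together with a
structured JSON run report; identical config + seed give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import bushmarket
from bushmarket import (
    association_stats,
    census_io,
    decomposition,
    intervention_ts,
    synthetic_market,
    trend_regression,
)
from bushmarket._seeding import substream

log = logging.getLogger("bushmarket.pipeline")

DEFAULT_EVENTS = [
    {"event_month": "1998-02", "components": ["pulse"]},
    {"event_month": "2000-05", "components": ["pulse"]},
    {"event_month": "2002-03", "components": ["step", "pulse"]},
    {"event_month": "2003-11", "components": ["step", "pulse"]},
    {"event_month": "2007-11", "components": ["step", "pulse", "lag"]},
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Exactly one of ``scenario`` (a synthetic-scenario YAML path or text)
    and ``census_csv``+``calendar_csv`` must be given.
    """

    scenario: str | None = None
    census_csv: str | None = None
    calendar_csv: str | None = None
    species_reference_csv: str | None = None
    oil_price_csv: str | None = None
    period_breakpoints: tuple[str, str] = ("2003-04", "2007-11")
    events: list[dict] = field(default_factory=lambda: [dict(e) for e in DEFAULT_EVENTS])
    prune_events: bool = True
    impute_months: list[str] = field(default_factory=list)
    q_trend: int = 24
    q_seasonal: int = 6
    alpha: float = 0.05
    n_boot: int = 10_000
    rarity_threshold: int = census_io.RARITY_THRESHOLD
    intervention_stratum: str = "primate"
    seed: int = 0
    out_dir: str = "bushmarket_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "period_breakpoints" in doc:
            doc["period_breakpoints"] = tuple(doc["period_breakpoints"])
        return cls(**doc)


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    has_scenario = config.scenario is not None
    has_census = config.census_csv is not None
    if has_scenario == has_census:
        problems.append("exactly one of scenario / census_csv must be set")
    if has_census and config.calendar_csv is None:
        problems.append("census_csv requires calendar_csv")
    try:
        b0, b1 = (pd.Period(b, freq="M") for b in config.period_breakpoints)
        if not b0 < b1:
            problems.append("period_breakpoints: must be strictly increasing")
    except Exception as exc:  # malformed month strings
        problems.append(f"period_breakpoints: {exc}")
    if config.n_boot <= 0:
        problems.append("n_boot: must be positive")
    if not 0 < config.alpha < 1:
        problems.append("alpha: must be in (0, 1)")
    if config.q_trend < 3 or config.q_seasonal < 4:
        problems.append("smoothing spans too small")
    if config.rarity_threshold < 0:
        problems.append("rarity_threshold: must be non-negative")
    for ev in config.events:
        comps = ev.get("components", [])
        if not any(c in comps for c in ("step", "pulse")):
            problems.append(f"event {ev.get('event_month')}: needs a step or pulse component")
        if "lag" in comps and "pulse" not in comps and "step" not in comps:
            problems.append(f"event {ev.get('event_month')}: lag needs a component to act on")
    return problems


def _event_shapes(events: list[dict]) -> list[intervention_ts.InterventionSpec]:
    shapes = []
    for ev in events:
        comps = ev.get("components", [])
        shapes.append(
            intervention_ts.InterventionSpec(
                event_month=ev["event_month"],
                step_weight=0.0 if "step" in comps else None,
                pulse_weight=0.0 if "pulse" in comps else None,
                lag_delta=0.5 if "lag" in comps else None,
                lag_on_step=bool(ev.get("lag_on_step", False)),
            )
        )
    return shapes


def _synthetic_oil_price(months: pd.PeriodIndex, seed: int) -> pd.Series:
    """Synthetic stand-in for a monthly income-proxy series (oil price,
    USD/barrel): an upward drift with AR(1) wander, for demo runs that
    have no user-supplied covariate."""
    rng = substream(seed, "oil_price")
    n = len(months)
    e = rng.normal(0, 2.0, size=n)
    u = np.zeros(n)
    for t in range(1, n):
        u[t] = 0.8 * u[t - 1] + e[t]
    price = 18.0 + 0.55 * np.arange(n) + u
    return pd.Series(np.maximum(price, 5.0), index=months, name="usd_per_barrel")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "versions": {
            "bushmarket": bushmarket.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }

    def stage(name: str, **info):
        log.info("stage %-12s %s", name, info)
        report["stages"].append({"stage": name, **info})

    try:
        # -- ingest / simulate ------------------------------------------------
        if config.scenario is not None:
            scen = synthetic_market.scenario_from_yaml(config.scenario)
            scen.seed = config.seed
            records, calendar = synthetic_market.generate_census(scen)
            records.to_csv(out / "census.csv", index=False)
            calendar.to_csv(out / "calendar.csv", index=False)
            stage("simulate", n_records=len(records), n_months=scen.n_months)
        else:
            records = census_io.read_census(config.census_csv)
            calendar = census_io.read_calendar(config.calendar_csv)
            stage("ingest", n_records=len(records), n_months=len(calendar))

        reference = census_io.load_species_reference(config.species_reference_csv)

        # -- prepare ----------------------------------------------------------
        records = census_io.filter_rare(records, config.rarity_threshold)
        domestic = records[records["origin"] == "island"].reset_index(drop=True)
        strata = {
            "total": census_io.monthly_rates(domestic, calendar),
            config.intervention_stratum: census_io.monthly_rates(
                domestic, calendar, group=config.intervention_stratum
            ),
            "shotgun": census_io.monthly_rates(domestic, calendar, method="shotgun"),
            "trap": census_io.monthly_rates(domestic, calendar, method="trap"),
        }
        for month in config.impute_months:
            strata = {k: census_io.impute_gap(s, month) for k, s in strata.items()}
        partition = census_io.PeriodPartition(breakpoints=config.period_breakpoints)
        months = strata["total"].months
        periods = census_io.assign_periods(months, partition)
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "month": s.months.astype(str),
                        "stratum": name,
                        "rate": s.values,
                        "market_days": s.market_days,
                    }
                )
                for name, s in strata.items()
            ],
            ignore_index=True,
        )
        long.to_csv(out / "monthly_rates.csv", index=False)
        try:
            summary = census_io.market_summary(records, reference)
            summary.to_csv(out / "market_summary.csv", index=False)
        except ValueError:
            # synthetic species are not in the field reference table
            summary = census_io.market_summary(
                records,
                pd.DataFrame(
                    {
                        "species": sorted(records["species"].unique()),
                        "group": records.groupby("species")["group"].first().sort_index().to_numpy(),
                        "mass_kg": 1.0,
                    }
                ),
            )
            summary.to_csv(out / "market_summary.csv", index=False)
        stage("prepare", n_domestic=len(domestic), n_months=len(months))

        # -- intervention model ----------------------------------------------
        z = np.sqrt(strata[config.intervention_stratum].rate)
        shapes = _event_shapes(config.events)
        fit = intervention_ts.arimax_fit(z, intervention_ts.SarimaSpec(), shapes)
        if config.prune_events:
            fit = intervention_ts.prune_nonsignificant(fit)
        fit.parameter_table().to_csv(out / "intervention_parameters.csv")
        pd.DataFrame(
            {
                "month": fit.months.astype(str),
                "observed_sqrt": z.to_numpy(),
                "fitted_sqrt": fit.fitted.to_numpy(),
                "residual": z.to_numpy() - fit.fitted.to_numpy(),
            }
        ).to_csv(out / "intervention_fitted.csv", index=False)
        diag = {
            "rmse": fit.rmse,
            "aic": fit.aic,
            "ljung_box_stat": fit.ljung_box.statistic,
            "ljung_box_df": fit.ljung_box.df,
            "ljung_box_p": fit.ljung_box.pvalue,
            "n_events_kept": len(fit.interventions),
        }
        pd.DataFrame([diag]).to_csv(out / "intervention_diagnostics.csv", index=False)
        stage("intervene", **{k: round(v, 4) if isinstance(v, float) else v for k, v in diag.items()})

        # -- decomposition ----------------------------------------------------
        decomps = {}
        for name, s in strata.items():
            d = decomposition.decompose(s, q_trend=config.q_trend, q_seasonal=config.q_seasonal)
            decomps[name] = d
            d.to_frame().to_csv(out / f"decomposition_{name}.csv", index=False)
        stage("decompose", strata=list(decomps))

        # -- trends ------------------------------------------------------------
        serial = np.arange(1, len(months) + 1)
        trend_rows = []
        fits_by_stratum: dict[str, dict[str, trend_regression.TrendFit]] = {}
        for name, d in decomps.items():
            deseas = decomposition.deseasonalize(d).to_numpy()
            fits = {}
            for label in partition.labels:
                mask = (periods == label).to_numpy()
                tf = trend_regression.fit_period_trend(
                    deseas[mask], serial[mask], alpha=config.alpha, period=label
                )
                tf.normalized_slope = trend_regression.normalize_slope(
                    tf.slope, strata[name].values, strata["total"].values, "sd_ratio"
                )
                fits[label] = tf
                trend_rows.append(
                    {
                        "stratum": name,
                        "period": label,
                        "model": tf.model,
                        "slope": tf.slope,
                        "ci95_halfwidth": tf.ci95_halfwidth,
                        "normalized_slope": tf.normalized_slope,
                        "n": tf.n,
                    }
                )
            fits_by_stratum[name] = fits
        pd.DataFrame(trend_rows).to_csv(out / "trend_slopes.csv", index=False)
        comps = pd.concat(
            [
                trend_regression.compare_slopes(fits).assign(stratum=name)
                for name, fits in fits_by_stratum.items()
            ],
            ignore_index=True,
        )
        comps.to_csv(out / "slope_comparisons.csv", index=False)
        stage("trends", n_fits=len(trend_rows))

        # -- associations ------------------------------------------------------
        anova_df = pd.concat(
            [
                pd.DataFrame(
                    {
                        "rate": strata[m].values,
                        "method": m,
                        "period": periods.to_numpy(),
                    }
                )
                for m in ("shotgun", "trap")
            ],
            ignore_index=True,
        )
        anova = association_stats.gls_anova(anova_df)
        anova.table.to_csv(out / "anova.csv", index=False)

        corr = association_stats.bootstrap_correlation(
            strata["trap"].values,
            strata["shotgun"].values,
            n_boot=config.n_boot,
            seed=int(substream(config.seed, "bootstrap").integers(2**31)),
        )
        pd.DataFrame(
            [{"r": corr.r, "ci_lo": corr.ci95[0], "ci_hi": corr.ci95[1], "n_boot": corr.n_boot}]
        ).to_csv(out / "trap_shotgun_correlation.csv", index=False)

        if config.oil_price_csv is not None:
            oil = pd.read_csv(config.oil_price_csv)
            covariate = pd.Series(
                oil["usd_per_barrel"].to_numpy(),
                index=pd.PeriodIndex(oil["month"], freq="M"),
            )
        else:
            covariate = _synthetic_oil_price(months, config.seed)
            covariate.rename_axis("month").reset_index().assign(
                month=lambda d: d["month"].astype(str)
            ).to_csv(out / "oil_price_synthetic.csv", index=False)
        denoised = {
            name.capitalize(): decomposition.denoise(d)
            for name, d in decomps.items()
            if name in ("total", "shotgun", "trap")
        }
        proxy = association_stats.proxy_regression(denoised, covariate, periods)
        proxy.to_csv(out / "income_proxy_regression.csv", index=False)
        stage(
            "associate",
            interaction_F=round(anova.f_for("method:period")[0], 3),
            trap_shotgun_r=round(corr.r, 4),
        )
    except Exception as exc:
        failed = len(report["stages"])
        names = ["simulate/ingest", "prepare", "intervene", "decompose", "trends", "associate"]
        stage_name = names[min(failed, len(names) - 1)]
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc

    report_text = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(report_text)
    report["checksum"] = hashlib.sha256(report_text.encode()).hexdigest()
    (out / "run.log").write_text(
        "\n".join(f"{s['stage']}: " + ", ".join(f"{k}={v}" for k, v in s.items() if k != "stage")
                  for s in report["stages"]) + "\n"
    )
    return report
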