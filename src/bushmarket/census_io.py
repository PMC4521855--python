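"""Reading, validating, filtering and aggregating carcass records.

Carcass records arrive as one row per market entry (date, species, taxon
group, capture method, origin, condition, price).  This module turns them
into the analysis quantities: the monthly *carcass rate* (carcasses per
market day, the pipeline's central response variable), the market-period
labels, and the species/group market summary (counts, biomass, shares).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["date", "species", "group", "method", "origin", "condition", "price_fcfa"]

#: species counted fewer than this many times over the whole study are
#: dropped as rare (and at risk of misidentification)
RARITY_THRESHOLD = 75


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MonthlySeries:
    """A gap-free monthly carcass-rate series with its market-day counts."""

    months: pd.PeriodIndex
    values: np.ndarray
    market_days: np.ndarray

    def __post_init__(self) -> None:
        self.months = pd.PeriodIndex(self.months, freq="M")
        self.values = np.asarray(self.values, dtype=float)
        self.market_days = np.asarray(self.market_days)
        if not (len(self.months) == len(self.values) == len(self.market_days)):
            raise ValueError("months, values and market_days must be equally long")
        diffs = np.diff(self.months.asi8)
        if len(diffs) and not np.all(diffs == 1):
            raise ValueError("months must be consecutive calendar months")

    def __len__(self) -> int:
        return len(self.months)

    @property
    def rate(self) -> pd.Series:
        return pd.Series(self.values, index=self.months, name="rate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.months.astype(str), "rate": self.values, "market_days": self.market_days}
        )


@dataclass
class PeriodPartition:
    """Two breakpoints splitting the study window into three market periods.

    Each breakpoint *opens* its period: a month equal to a breakpoint is
    labeled with the later period.
    """

    breakpoints: tuple[str, str] = ("2003-04", "2007-11")
    labels: tuple[str, str, str] = ("Early", "Pre-ban", "Post-ban")

    def __post_init__(self) -> None:
        self.breakpoints = tuple(pd.Period(b, freq="M") for b in self.breakpoints)
        if not self.breakpoints[0] < self.breakpoints[1]:
            raise ValueError("breakpoints must be strictly ordered")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need one more label than breakpoints")

    def label_of(self, month) -> str:
        m = pd.Period(month, freq="M")
        idx = sum(m >= b for b in self.breakpoints)
        return self.labels[idx]


# ---------------------------------------------------------------------------
# species reference
# ---------------------------------------------------------------------------


def load_species_reference(path=None) -> pd.DataFrame:
    """Packaged species reference: species, group, body mass (kg), island
    proportion and study-total counts transcribed from the published
    market summary.

    Note: the published table's per-row biomass is kept in
    ``biomass_printed``; for two species (African rock python,
    African brush-tailed porcupine) it implies an unrounded mass, so
    ``n_total * mass_kg`` differs slightly from the printed value there.
    """
    if path is None:
        src = resources.files("bushmarket").joinpath("data/species_reference.csv")
        with resources.as_file(src) as p:
            ref = pd.read_csv(p)
    else:
        ref = pd.read_csv(path)
    if (ref["mass_kg"] <= 0).any():
        raise ValueError("species reference contains non-positive masses")
    if ref["species"].duplicated().any():
        dupes = ref.loc[ref["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in reference: {dupes}")
    return ref


def _normalize_name(s: pd.Series) -> pd.Series:
    return s.str.strip().str.replace(r"\s+", " ", regex=True).str.casefold()


# ---------------------------------------------------------------------------
# record-level operations
# ---------------------------------------------------------------------------


def read_census(path) -> pd.DataFrame:
    records = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in records.columns and c != "price_fcfa"]
    if missing:
        raise ValueError(f"census file missing columns: {missing}")
    return records


def read_calendar(path) -> pd.DataFrame:
    cal = pd.read_csv(path)
    missing = [c for c in ("year", "month", "market_days") if c not in cal.columns]
    if missing:
        raise ValueError(f"calendar file missing columns: {missing}")
    return cal


def filter_rare(records: pd.DataFrame, threshold: int = RARITY_THRESHOLD) -> pd.DataFrame:
    """Drop all records of species seen fewer than ``threshold`` times over
    the whole study (species with exactly ``threshold`` are kept)."""
    if records.empty:
        return records.copy()
    counts = records["species"].value_counts()
    keep = counts.index[counts >= threshold]
    return records[records["species"].isin(keep)].reset_index(drop=True)


def _calendar_periods(calendar: pd.DataFrame) -> pd.PeriodIndex:
    return pd.PeriodIndex(
        [pd.Period(f"{y}-{m:02d}", freq="M") for y, m in zip(calendar["year"], calendar["month"])],
        freq="M",
    )


def monthly_rates(
    records: pd.DataFrame,
    calendar: pd.DataFrame,
    species: str | None = None,
    group: str | None = None,
    method: str | None = None,
    origin: str | None = None,
) -> MonthlySeries:
    """Carcasses per market day, by month, for the selected stratum.

    The calendar defines the month axis; months with no selected records
    get rate 0.  A month that has records but zero surveyed days is an
    error (a rate cannot be formed there).
    """
    sel = records
    for col, val in [("species", species), ("group", group), ("method", method), ("origin", origin)]:
        if val is not None:
            sel = sel[sel[col] == val]
    cal_months = _calendar_periods(calendar)
    order = np.argsort(cal_months.asi8)
    cal_months = cal_months[order]
    days = calendar["market_days"].to_numpy()[order]

    rec_months = pd.PeriodIndex(pd.to_datetime(sel["date"]), freq="M")
    outside = ~np.isin(rec_months.asi8, cal_months.asi8)
    if outside.any():
        bad = sorted(set(rec_months[outside].astype(str)))
        raise ValueError(f"records in months not covered by the calendar: {bad}")
    counts = pd.Series(1, index=rec_months).groupby(level=0).sum()
    counts = counts.reindex(cal_months, fill_value=0).to_numpy()
    zero_day = (days == 0) & (counts > 0)
    if zero_day.any():
        bad = cal_months[zero_day].astype(str).tolist()
        raise ValueError(f"months with records but zero surveyed days: {bad}")
    values = np.divide(
        counts, days, out=np.zeros(len(days), dtype=float), where=days > 0
    )
    return MonthlySeries(months=cal_months, values=values, market_days=days)


def impute_gap(series: MonthlySeries, month) -> MonthlySeries:
    """Replace the value at ``month`` by the mean of its two neighbors.

    Intended for an isolated single-month observation gap (e.g. a market
    closure); both neighbors must carry observed values — chained
    imputation is refused.
    """
    m = pd.Period(month, freq="M")
    if m not in series.months:
        raise ValueError(f"month {m} not in series")
    i = int(series.months.get_loc(m))
    if i == 0 or i == len(series) - 1:
        raise ValueError(f"month {m} has no neighbor on both sides")
    left, right = series.values[i - 1], series.values[i + 1]
    if np.isnan(left) or np.isnan(right):
        raise ValueError(f"neighbor of {m} is missing; refusing chained imputation")
    values = series.values.copy()
    values[i] = 0.5 * (left + right)
    return MonthlySeries(series.months, values, series.market_days.copy())


def assign_periods(months, partition: PeriodPartition | None = None) -> pd.Series:
    """Label every month Early / Pre-ban / Post-ban (each breakpoint opens
    its period)."""
    partition = partition or PeriodPartition()
    if isinstance(months, MonthlySeries):
        months = months.months
    months = pd.PeriodIndex(months, freq="M")
    for b in partition.breakpoints:
        if b < months[0] or b > months[-1]:
            raise ValueError(f"breakpoint {b} outside series range {months[0]}..{months[-1]}")
    labels = [partition.label_of(m) for m in months]
    return pd.Series(pd.Categorical(labels, categories=list(partition.labels), ordered=True), index=months)


# ---------------------------------------------------------------------------
# market summary (counts, biomass, shares)
# ---------------------------------------------------------------------------


def market_summary(records: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Species / group / overall counts, biomass and percentage shares.

    Biomass per species is ``n * mass_kg``; shares are subtotal/total x 100
    reported to 2 decimals.  ``records`` may alternatively carry a
    precomputed ``n`` column (one row per species) for summarising
    published count tables.
    """
    if "n" in records.columns and "date" not in records.columns:
        counts = records.set_index("species")["n"]
    else:
        counts = records["species"].value_counts()
    ref = reference.copy()
    ref["_key"] = _normalize_name(ref["species"])
    key = _normalize_name(pd.Series(counts.index, index=counts.index))
    unknown = sorted(set(key) - set(ref["_key"]))
    if unknown:
        raise ValueError(f"species not in reference table: {unknown}")
    merged = (
        pd.DataFrame({"_key": key, "n": counts.to_numpy()})
        .merge(ref, on="_key", how="left")
    )
    merged["biomass_kg"] = merged["n"] * merged["mass_kg"]

    total_n = int(merged["n"].sum())
    total_b = float(merged["biomass_kg"].sum())

    species_rows = merged[["species", "group", "n", "biomass_kg"]].copy()
    species_rows["level"] = "species"
    species_rows["label"] = species_rows["species"]

    grp = merged.groupby("group", as_index=False)[["n", "biomass_kg"]].sum()
    grp["level"] = "group"
    grp["label"] = grp["group"]

    overall = pd.DataFrame(
        {"label": ["Total"], "level": ["total"], "group": [""], "n": [total_n], "biomass_kg": [total_b]}
    )
    out = pd.concat(
        [species_rows[["level", "label", "group", "n", "biomass_kg"]],
         grp[["level", "label", "group", "n", "biomass_kg"]],
         overall[["level", "label", "group", "n", "biomass_kg"]]],
        ignore_index=True,
    )
    out["count_share_pct"] = np.round(100.0 * out["n"] / total_n, 2)
    out["biomass_share_pct"] = np.round(100.0 * out["biomass_kg"] / total_b, 2)
    out["biomass_kg"] = np.round(out["biomass_kg"], 2)
    return out


def reference_summary(reference: pd.DataFrame) -> pd.DataFrame:
    """Market summary computed from the study-total counts packaged in the
    species reference itself (the published count table)."""
    pseudo = reference[["species", "n_total"]].rename(columns={"n_total": "n"})
    return market_summary(pseudo, reference)


def summary_value(summary: pd.DataFrame, label: str, column: str) -> float:
    """Convenience lookup of one cell of a market summary table."""
    row = summary[summary["label"] == label]
    if row.empty:
        raise KeyError(f"no summary row labeled {label!r}")
    return float(row.iloc[0][column])
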