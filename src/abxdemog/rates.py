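"""Prescription rates per 100,000 population and female:male contrasts.

Rates divide item totals by ONS-style mid-year population counts. The
mid-year estimate of a calendar year serves every month of that year;
when a stratification carries no time dimension and the records span
several years, the denominator is person-years (the sum of the yearly
populations), which keeps rates additive under stratum collapsing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_ingest import ValidationError, period_year

PER = 100_000

#: Dimensions a stratification may use.
DIMENSIONS = ("drug", "family", "age_band", "sex", "region", "period", "year")
#: Dimensions that exist in the population table (others are collapsed).
_POP_DIMS = ("age_band", "sex", "region")


def _with_year(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["year"] = period_year(out["period"])
    return out


def compute_rates(
    records: pd.DataFrame,
    population: pd.DataFrame,
    strata: list[str],
    per: float = PER,
) -> pd.DataFrame:
    """Sum items within each stratum and attach the matching population
    denominator.

    Parameters
    ----------
    records
        De-redacted canonical record table (no missing ``items``).
    population
        Population cells (age_band, sex, region, year, count) covering
        every demographic cell and year present in the records.
    strata
        Subset of drug / family / age_band / sex / region / period /
        year to keep; all other dimensions are collapsed.
    per
        Rate scale; 100,000 by default, 1.0 gives per-person rates.

    Returns
    -------
    DataFrame with the stratum columns plus ``items``, ``population``
    and ``rate``; rows where the denominator is zero carry
    ``rate = NaN`` and ``zero_population = True``.
    """
    bad = [s for s in strata if s not in DIMENSIONS]
    if bad:
        raise ValidationError(f"unknown stratum dimension(s): {bad}")
    if records["items"].isna().any():
        raise ValidationError("records still contain redacted items; impute first")

    rec = _with_year(records)
    years_present = sorted(rec["year"].unique())

    pop_missing = _check_denominators(rec, population)
    if pop_missing:
        raise ValidationError(f"missing population cells for keys: {pop_missing[:10]}")

    items = rec.groupby(strata, as_index=False, observed=True)["items"].sum() if strata else (
        pd.DataFrame({"items": [int(rec["items"].sum())]})
    )

    pop = _aggregate_population(population, strata, years_present)
    if strata:
        join_keys = [s for s in strata if s in _POP_DIMS or s == "year"]
        if "period" in strata and "year" not in strata:
            items["year"] = period_year(items["period"])
            join_keys = join_keys + ["year"]
        if join_keys:
            out = items.merge(pop, on=join_keys, how="left")
        else:
            out = items.copy()
            out["population"] = int(pop["population"].iloc[0])
        if "period" in strata and "year" not in strata:
            out = out.drop(columns="year")
    else:
        out = items.copy()
        out["population"] = int(pop["population"].iloc[0])

    out["population"] = out["population"].fillna(0).astype(np.int64)
    out["zero_population"] = out["population"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rate"] = np.where(
            out["population"] > 0, out["items"] / out["population"] * per, np.nan
        )
    return out


def _check_denominators(rec: pd.DataFrame, population: pd.DataFrame) -> list[tuple]:
    need = rec[["age_band", "sex", "region", "year"]].drop_duplicates()
    have = population[["age_band", "sex", "region", "year"]].drop_duplicates()
    merged = need.merge(have, how="left", indicator=True,
                        on=["age_band", "sex", "region", "year"])
    missing = merged.loc[merged["_merge"] == "left_only"]
    return list(missing[["age_band", "sex", "region", "year"]].itertuples(index=False, name=None))


def _aggregate_population(
    population: pd.DataFrame, strata: list[str], years_present: list[int]
) -> pd.DataFrame:
    keep = [s for s in strata if s in _POP_DIMS]
    time_resolved = ("year" in strata) or ("period" in strata)
    pop = population.loc[population["year"].isin(years_present)]
    group = keep + (["year"] if time_resolved else [])
    if group:
        agg = pop.groupby(group, as_index=False, observed=True)["count"].sum()
    else:
        agg = pd.DataFrame({"count": [int(pop["count"].sum())]})
    return agg.rename(columns={"count": "population"})


def sex_contrast(rates: pd.DataFrame) -> pd.DataFrame:
    """Female:male rate contrasts per remaining stratum.

    Input must be a rate table stratified by at least drug, age_band
    and sex. Output has one row per stratum with ``log_ratio``
    (natural log of female over male rate; ``±inf`` when exactly one
    rate is zero), ``female_majority`` (female rate strictly greater)
    and ``both_zero`` (excluded from majority summaries downstream).
    """
    for col in ("drug", "age_band", "sex", "rate"):
        if col not in rates.columns:
            raise ValidationError(f"rate table lacks column {col!r}")
    keys = [c for c in rates.columns if c not in
            ("sex", "items", "population", "rate", "zero_population")]
    wide = rates.pivot_table(index=keys, columns="sex", values="rate",
                             aggfunc="first", observed=True)
    for s in ("Female", "Male"):
        if s not in wide.columns:
            wide[s] = np.nan
    wide = wide.rename(columns={"Female": "rate_f", "Male": "rate_m"}).reset_index()
    f = wide["rate_f"].fillna(0.0)
    m = wide["rate_m"].fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log(f.to_numpy() / m.to_numpy())
    lr = np.where((f == 0) & (m == 0), np.nan, lr)
    wide["log_ratio"] = lr
    wide["female_majority"] = (f > m).to_numpy()
    wide["both_zero"] = ((f == 0) & (m == 0)).to_numpy()
    return wide
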