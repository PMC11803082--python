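"""Per-drug summary tables and the headline counts computed from them.

summarize_drugs produces the study's per-drug summary (totals over
complete calendar years, rounded mean annual items, percentage of
items to females, the peak calendar month, and per-sex top age bands
by rate); headline_counts condenses a summary table into the counts
quoted in prose: how many of the top drugs declined between the first
and last complete year, how many are female-majority, the peak-month
distribution, and how many cut prescribing by at least 10% from 2019
to 2023.

mean_annual uses round-half-to-even, which reproduces the reference
summary table's printed values (half-away-from-zero does not: e.g. a
total of 9,181,476 over 8 years prints as 1,147,684).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core_ingest import FEMALE, StudyCalendar, ValidationError, period_month, period_year
from .rates import compute_rates

PCT_RULE = "pct_ge_50"  # printed-percentage rule: >= 50% counts as female-majority
RAW_RULE = "raw_gt_half"  # raw-count rule: strictly more than half of items


def round_half_even(x: float) -> int:
    """Banker's rounding to an integer (matches R's round())."""
    return int(np.rint(x))


def summarize_drugs(
    records: pd.DataFrame,
    calendar: StudyCalendar | None = None,
    top_n: int = 20,
    population: pd.DataFrame | None = None,
    band_year: int = 2023,
) -> pd.DataFrame:
    """Summarise the ``top_n`` most-prescribed drugs.

    Ranking and totals cover the calendar's complete years; the top
    month is taken over the whole dataset (ties break to the earliest
    month).  When a population table is supplied, the three top age
    bands per sex by ``band_year`` rate are included (descending
    rate).  Output columns: drug, total_items, mean_annual,
    pct_female, top_month, one ``total_<year>`` column per complete
    year, and optionally top_bands_female / top_bands_male.
    """
    calendar = calendar or StudyCalendar()
    if records["items"].isna().any():
        raise ValidationError("records still contain redacted items; impute first")
    rec = records.copy()
    rec["year"] = period_year(rec["period"])
    complete = rec.loc[rec["year"].isin(calendar.complete_years)]

    totals = complete.groupby("drug", observed=True)["items"].sum().sort_values(
        ascending=False, kind="stable"
    )
    if top_n > len(totals):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(totals)} drugs available; summarising all"
        )
        top_n = len(totals)
    top = list(totals.index[:top_n])
    n_years = len(calendar.complete_years)

    yearly = complete.groupby(["drug", "year"], observed=True)["items"].sum()
    fem = complete.loc[complete["sex"] == FEMALE].groupby("drug", observed=True)["items"].sum()

    month_items = rec.groupby(["drug", rec["period"].pipe(period_month)], observed=True)[
        "items"
    ].sum()

    band_tops: dict[str, dict[str, str]] = {}
    if population is not None:
        year_rec = rec.loc[rec["year"] == band_year]
        if not year_rec.empty:
            rts = compute_rates(
                year_rec.drop(columns="year"), population,
                ["drug", "age_band", "sex"],
            )
            for (drug, sex), sub in rts.groupby(["drug", "sex"], observed=True):
                ranked = sub.sort_values(["rate", "age_band"], ascending=[False, True])
                bands = ",".join(ranked["age_band"].head(3))
                band_tops.setdefault(drug, {})[sex] = bands

    rows = []
    for drug in top:
        total = int(totals[drug])
        months = month_items.loc[drug]
        top_month = int(months.index[months.to_numpy() == months.max()].min())
        row = {
            "drug": drug,
            "total_items": total,
            "mean_annual": round_half_even(total / n_years),
            "pct_female": float(fem.get(drug, 0)) / total * 100 if total else np.nan,
            "top_month": top_month,
        }
        for year in calendar.complete_years:
            row[f"total_{year}"] = int(yearly.get((drug, year), 0))
        if population is not None:
            row["top_bands_female"] = band_tops.get(drug, {}).get("Female", "")
            row["top_bands_male"] = band_tops.get(drug, {}).get("Male", "")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class HeadlineCounts:
    n_top: int
    n_decreasing_2016_2023: int
    n_female_majority: int
    month_distribution: dict[int, int] = field(default_factory=dict)
    n_reduction_ge_10pct_2019_2023: int = 0


def headline_counts(
    summaries: pd.DataFrame,
    first_year: int = 2016,
    mid_year: int = 2019,
    last_year: int = 2023,
    female_majority_rule: str = PCT_RULE,
) -> HeadlineCounts:
    """Condense a drug-summary table into the headline counts.

    Requires ``total_<first_year>``, ``total_<mid_year>`` and
    ``total_<last_year>`` columns plus ``pct_female`` and
    ``top_month``.  The female-majority rule is the printed-percentage
    >= 50 by default; "raw_gt_half" demands strictly more than half.
    """
    needed = [f"total_{first_year}", f"total_{mid_year}", f"total_{last_year}",
              "pct_female", "top_month"]
    for col in needed:
        if col not in summaries.columns:
            raise ValidationError(f"summary table lacks column {col!r}")
        bad = summaries.loc[summaries[col].isna(), "drug"]
        if len(bad):
            raise ValidationError(f"missing {col!r} for drug(s): {list(bad)}")

    first = summaries[f"total_{first_year}"].astype(float)
    mid = summaries[f"total_{mid_year}"].astype(float)
    last = summaries[f"total_{last_year}"].astype(float)

    if female_majority_rule == PCT_RULE:
        fm = summaries["pct_female"] >= 50
    elif female_majority_rule == RAW_RULE:
        fm = summaries["pct_female"] > 50
    else:
        raise ValidationError(f"unknown female-majority rule: {female_majority_rule!r}")

    months = summaries["top_month"].astype(int)
    dist = months.value_counts().sort_index().to_dict()

    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = (mid - last) / mid
    return HeadlineCounts(
        n_top=len(summaries),
        n_decreasing_2016_2023=int((last < first).sum()),
        n_female_majority=int(fm.sum()),
        month_distribution={int(k): int(v) for k, v in dist.items()},
        n_reduction_ge_10pct_2019_2023=int((reduction >= 0.10).sum()),
    )


def load_table1() -> pd.DataFrame:
    """The packaged top-20 reference summary fixture (printed totals,
    yearly columns, female percentages and top months), used by tests
    and the demo."""
    data = resources.files("abxdemog.data")
    with resources.as_file(data / "table1_top20.csv") as f:
        df = pd.read_csv(f)
    int_cols = [c for c in df.columns if c.startswith("total_")] + [
        "mean_annual_printed", "pct_female", "top_month"
    ]
    for c in int_cols:
        df[c] = df[c].astype(int)
    return df
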