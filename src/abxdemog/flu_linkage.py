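"""RTI-antibiotic prescribing around influenza-vaccination rollouts.

RTI (respiratory tract infection) prescribing is proxied by the BNF
families "Penicillins" and "Cephalosporins and other beta-lactams",
excluding amoxicillin by default (its volume and breadth of
indications would swamp any vaccination signal).  Influenza seasons
run 1 October – 30 March; with monthly data every October–March month
belongs to the season starting that October (so March is included
whole; the one-day boundary only bites at daily resolution).  Rates
per age group are compared relative to the 15–50 reference group, and
season-over-season proportional changes are reported alongside the
schedule of vaccination introductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core_ingest import AGE_BANDS, ValidationError, period_month, period_year

RTI_FAMILIES = ("Penicillins", "Cephalosporins and other beta-lactams")
AMOXICILLIN = "Amoxicillin"

#: Analysis age groups built from the canonical bands.  The "5–10"
#: group is the canonical band "6–10" (the vaccination groups' edges do
#: not align exactly with the 23-band scheme).
ANALYSIS_GROUPS: dict[str, tuple[str, ...]] = {
    "0–1": ("0–1",),
    "2–5": ("2–5",),
    "5–10": ("6–10",),
    "11–15": ("11–15",),
    "15–50": tuple(b.label for b in AGE_BANDS if 16 <= b.lower <= 46),
    "50–65": ("51–55", "56–60", "61–65"),
    "65+": tuple(b.label for b in AGE_BANDS if b.lower >= 66),
}
REFERENCE_GROUP = "15–50"


@dataclass(frozen=True)
class VaccinationSchedule:
    """Season-start year → analysis age groups newly eligible."""

    entries: dict[int, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, source) -> "VaccinationSchedule":
        df = pd.read_csv(source, dtype=str)
        for col in ("season_start_year", "age_group"):
            if col not in df.columns:
                raise ValidationError(f"schedule lacks column {col!r}")
        entries: dict[int, tuple[str, ...]] = {}
        for year, grp in zip(df["season_start_year"].astype(int), df["age_group"]):
            entries[year] = entries.get(year, ()) + (grp.strip(),)
        return cls(entries=entries)

    def introduced(self, season: int, group: str) -> bool:
        return group in self.entries.get(season, ())


def load_default_schedule() -> VaccinationSchedule:
    """The packaged UKHSA-style childhood/older-adult rollout schedule."""
    data = resources.files("abxdemog.data")
    with resources.as_file(data / "flu_schedule.csv") as f:
        return VaccinationSchedule.from_csv(f)


def select_rti_records(
    records: pd.DataFrame, include_amoxicillin: bool = False
) -> pd.DataFrame:
    """Keep only the two RTI proxy families; drop amoxicillin unless
    asked to keep it."""
    fam = records["family"].str.strip().str.lower()
    keep = fam.isin({f.lower() for f in RTI_FAMILIES})
    if not include_amoxicillin:
        keep &= records["drug"].str.strip().str.lower() != AMOXICILLIN.lower()
    return records.loc[keep].reset_index(drop=True)


def assign_season(periods: pd.Series) -> pd.Series:
    """Season start year for each period, NA outside October–March."""
    years = period_year(periods)
    months = period_month(periods)
    season = pd.Series(pd.NA, index=periods.index, dtype="Int64")
    season[months >= 10] = years[months >= 10]
    season[months <= 3] = years[months <= 3] - 1
    return season


def season_relative_rates(
    records: pd.DataFrame,
    population: pd.DataFrame,
    schedule: VaccinationSchedule | None = None,
    reference_group: str = REFERENCE_GROUP,
    groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-season, per-age-group RTI prescribing relative to the
    reference group.

    Returns one row per (age_group, season) with the season's items,
    population (of the year containing October), per-capita ``rate``,
    ``relative_rate`` versus the reference group, ``prop_change``
    versus the group's previous season (NaN for the first season), and
    a ``vaccination_introduced`` flag from the schedule.
    """
    groups = groups or ANALYSIS_GROUPS
    if reference_group not in groups:
        raise ValidationError(f"reference group {reference_group!r} not in groups")
    if records["items"].isna().any():
        raise ValidationError("records still contain redacted items; impute first")

    rec = records.copy()
    rec["season"] = assign_season(rec["period"])
    rec = rec.loc[rec["season"].notna()]

    band_to_group: dict[str, str] = {}
    for g, bands in groups.items():
        for b in bands:
            band_to_group[b] = g
    rec["age_group"] = rec["age_band"].map(band_to_group)
    rec = rec.loc[rec["age_group"].notna()]

    items = rec.groupby(["age_group", "season"], observed=True)["items"].sum()

    pop = population.copy()
    pop["age_group"] = pop["age_band"].map(band_to_group)
    pop = pop.loc[pop["age_group"].notna()]
    pop_by_year = pop.groupby(["age_group", "year"], observed=True)["count"].sum()

    rows = []
    ref_rates: dict[int, float] = {}
    # Seasons whose October-year population is unavailable (e.g. a season
    # straddling the start of the data) are dropped, not errors.
    seasons = []
    for season in sorted({int(s) for s in rec["season"].unique()}):
        ref_pop = pop_by_year.get((reference_group, season))
        if ref_pop is None or ref_pop == 0:
            continue
        seasons.append(season)
        ref_rates[season] = float(items.get((reference_group, season), 0)) / float(ref_pop)

    for group in groups:
        prev_rate = None
        for season in seasons:
            n = int(items.get((group, season), 0))
            p = pop_by_year.get((group, season))
            if p is None or p == 0:
                continue
            rate = n / float(p)
            rel = rate / ref_rates[season] if ref_rates[season] > 0 else np.nan
            prop = rate / prev_rate - 1 if prev_rate not in (None, 0) else np.nan
            rows.append(
                {
                    "age_group": group,
                    "season": season,
                    "items": n,
                    "population": int(p),
                    "rate": rate,
                    "relative_rate": rel,
                    "prop_change": prop,
                    "vaccination_introduced": (
                        schedule.introduced(season, group) if schedule else False
                    ),
                }
            )
            prev_rate = rate
    return pd.DataFrame(
        rows,
        columns=["age_group", "season", "items", "population", "rate",
                 "relative_rate", "prop_change", "vaccination_introduced"],
    )
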