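"""Parsing, validation, filtering and de-redaction of disaggregated
prescription data and population denominators.

The canonical in-memory containers are pandas DataFrames:

* **record table** — one row per disaggregated cell, columns
  ``period`` ("YYYY-MM"), ``drug``, ``family``, ``age_band``, ``sex``,
  ``region``, ``items`` (nullable ``Int64``; ``pd.NA`` marks a redacted
  cell whose true count is 1–4).
* **population table** — columns ``age_band``, ``sex``, ``region``,
  ``year``, ``count`` (mid-year person counts).

Age follows a closed 23-band scheme: "0–1", "2–5", then 5-year bands up
to "105+".  Sex is one of Female / Male / Indeterminate / Unknown; only
Female and Male survive exclusion filtering.  Counts below the
suppressor's threshold (5) arrive as a redaction marker ("*") and are
substituted during imputation, 1 by default.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["period", "drug", "family", "age_band", "sex", "region", "items"]
POPULATION_COLUMNS = ["age_band", "sex", "region", "year", "count"]

FEMALE = "Female"
MALE = "Male"
INDETERMINATE = "Indeterminate"
UNKNOWN = "Unknown"

NATIONAL_REGION = "ENGLAND"

_DASHES = {"–": "-", "—": "-", "−": "-"}  # en/em dash, minus


class ValidationError(ValueError):
    """Raised on invalid labels, configuration or parameter values."""


@dataclass(frozen=True)
class AgeBand:
    """One band of the closed 23-band age scheme.

    ``upper is None`` marks the open-ended terminal band ("105+").
    """

    label: str
    lower: int
    upper: int | None

    def contains(self, age: int) -> bool:
        if self.upper is None:
            return age >= self.lower
        return self.lower <= age <= self.upper


def _build_scheme() -> tuple[AgeBand, ...]:
    bands = [AgeBand("0–1", 0, 1), AgeBand("2–5", 2, 5)]
    lo = 6
    while lo <= 101:
        hi = lo + 4
        bands.append(AgeBand(f"{lo}–{hi}", lo, hi))
        lo = hi + 1
    bands.append(AgeBand("105+", 105, None))
    return tuple(bands)


#: The canonical 23 bands, in ascending age order.
AGE_BANDS: tuple[AgeBand, ...] = _build_scheme()
AGE_BAND_LABELS: tuple[str, ...] = tuple(b.label for b in AGE_BANDS)
_BAND_BY_KEY = {b.label.replace("–", "-"): b for b in AGE_BANDS}

SEXES = (FEMALE, MALE, INDETERMINATE, UNKNOWN)
MAIN_SEXES = (FEMALE, MALE)


def parse_age_band(label: str) -> AgeBand:
    """Return the canonical band for ``label``.

    Hyphen/en-dash/em-dash variants and surrounding whitespace are
    normalised; any other deviation is a hard error.
    """
    if not isinstance(label, str) or not label.strip():
        raise ValidationError("empty age band label")
    key = label.strip()
    for dash, repl in _DASHES.items():
        key = key.replace(dash, repl)
    key = key.replace(" ", "")
    band = _BAND_BY_KEY.get(key)
    if band is None:
        raise ValidationError(f"unknown age band label: {label!r}")
    return band


def band_for_age(age: int) -> AgeBand:
    """Map an integer age to its band.

    The published labels share the endpoint 105 ("101–105" and
    "105+"); the lower band wins there, so the terminal band holds
    ages 106 and up in practice.
    """
    if age < 0:
        raise ValidationError(f"negative age: {age}")
    for band in AGE_BANDS:
        if band.contains(age):
            return band
    raise AssertionError("unreachable: bands cover [0, inf)")


def child_band_labels(age_limit: int = 20) -> tuple[str, ...]:
    """Bands whose upper bound is <= ``age_limit`` (default: the
    under-20 "children" scope, i.e. "0–1" through "16–20")."""
    return tuple(
        b.label for b in AGE_BANDS if b.upper is not None and b.upper <= age_limit
    )


@dataclass(frozen=True)
class StudyCalendar:
    """Study time windows: COVID-19 disruption period, complete calendar
    years, and the influenza season boundaries."""

    covid_start: str = "2020-03"
    covid_end: str = "2022-06"
    complete_years: tuple[int, ...] = tuple(range(2016, 2024))
    flu_season_start: str = "10-01"
    flu_season_end: str = "03-30"

    def __post_init__(self) -> None:
        if self.covid_start > self.covid_end:
            raise ValidationError("covid_start after covid_end")

    def in_covid_window(self, periods: pd.Series | Sequence[str]) -> pd.Series:
        s = pd.Series(periods)
        return (s >= self.covid_start) & (s <= self.covid_end)


@dataclass
class ExclusionReport:
    """What apply_exclusions removed, and why."""

    n_input: int = 0
    n_unknown_demographics: int = 0
    pct_unknown: float = 0.0
    n_indeterminate: int = 0
    drugs_dropped_rare: list[str] = field(default_factory=list)
    threshold_rare: float = 10.0
    n_rare_records: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def period_year(periods: pd.Series) -> pd.Series:
    """Calendar year of "YYYY-MM" period strings, as int."""
    return periods.str.slice(0, 4).astype(int)


def period_month(periods: pd.Series) -> pd.Series:
    """Calendar month (1–12) of "YYYY-MM" period strings."""
    return periods.str.slice(5, 7).astype(int)


def _normalise_period(raw: str) -> str | None:
    try:
        p = pd.Period(raw, freq="M")
    except Exception:
        return None
    return f"{p.year:04d}-{p.month:02d}"


DEFAULT_COLUMN_MAP = {
    "period": "period",
    "drug": "drug",
    "family": "family",
    "age_band": "age_band",
    "sex": "sex",
    "region": "region",
    "items": "items",
}

_SEX_ALIASES = {
    "female": FEMALE,
    "f": FEMALE,
    "male": MALE,
    "m": MALE,
    "indeterminate": INDETERMINATE,
    "i": INDETERMINATE,
    "unknown": UNKNOWN,
    "": UNKNOWN,
}


def read_prescriptions(
    source,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    redaction_marker: str = "*",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited prescription extract into the canonical record
    table.

    Parameters
    ----------
    source
        Path or file-like object with a header row. Comma or tab
        delimited (sniffed when ``delimiter`` is None).
    column_map
        Mapping from canonical column name (period, drug, family,
        age_band, sex, region, items) to the header name in the file.
    redaction_marker
        The string marking small-number-suppressed counts (default "*").

    Returns
    -------
    (records, rejects)
        ``records`` is the canonical table (row order preserved,
        redacted items as ``pd.NA``); ``rejects`` collects malformed
        rows with a ``reject_reason`` column rather than dropping them
        silently.  Unknown sex or age-band labels are *not* rejects:
        they parse to the Unknown category and are handled by
        :func:`apply_exclusions`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(source, dtype=str, sep=delimiter, engine="python").fillna("")
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {missing}")

    df = pd.DataFrame({canon: raw[src].astype(str).str.strip() for canon, src in cmap.items()})

    reasons = pd.Series("", index=df.index, dtype=object)

    periods = df["period"].map(_normalise_period)
    reasons[periods.isna() & (reasons == "")] = "unparseable period"
    df["period"] = periods

    def _band(label: str) -> str:
        try:
            return parse_age_band(label).label
        except ValidationError:
            return UNKNOWN

    df["age_band"] = df["age_band"].map(_band)
    df["sex"] = df["sex"].str.lower().map(lambda s: _SEX_ALIASES.get(s, UNKNOWN))
    df.loc[df["region"] == "", "region"] = NATIONAL_REGION

    items_raw = df["items"]
    is_redacted = items_raw == redaction_marker
    numeric = pd.to_numeric(items_raw.where(~is_redacted), errors="coerce")
    bad_items = ~is_redacted & (numeric.isna() | (numeric != numeric.round()) | (numeric < 1))
    reasons[bad_items & (reasons == "")] = "items not a positive integer or redaction marker"

    items = pd.array(
        [pd.NA if r else int(v) for r, v in zip(is_redacted, numeric.fillna(0))],
        dtype="Int64",
    )
    df["items"] = items

    ok = reasons == ""
    rejects = df.loc[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    return df.loc[ok, RECORD_COLUMNS].reset_index(drop=True), rejects.reset_index(drop=True)


def read_population(source, delimiter: str | None = None) -> pd.DataFrame:
    """Read an ONS-style mid-year population table (age_band, sex,
    region, year, count)."""
    df = pd.read_csv(source, dtype=str, sep=delimiter, engine="python")
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing population column(s): {missing}")
    out = df[POPULATION_COLUMNS].copy()
    out["age_band"] = out["age_band"].map(lambda s: parse_age_band(s).label)
    out["year"] = out["year"].astype(int)
    out["count"] = out["count"].astype(int)
    if (out["count"] < 0).any():
        raise ValidationError("negative population count")
    dup = out.duplicated(subset=["age_band", "sex", "region", "year"])
    if dup.any():
        raise ValidationError("duplicate population cells")
    return out


def apply_exclusions(
    records: pd.DataFrame,
    rare_threshold: float = 10.0,
    calendar: StudyCalendar | None = None,
    imputation_value: int = 1,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the study's exclusion rules.

    Removes, in order: records with Unknown age band or Unknown sex;
    records of Indeterminate sex; then every record of any drug whose
    mean items per complete calendar year (redacted cells counted at
    ``imputation_value``) falls below ``rare_threshold``.

    The returned :class:`ExclusionReport` carries the counts and the
    unknown-demographics fraction of the input.
    """
    calendar = calendar or StudyCalendar()
    report = ExclusionReport(n_input=len(records), threshold_rare=float(rare_threshold))
    if records.empty:
        return records.copy(), report

    unknown = (records["age_band"] == UNKNOWN) | (records["sex"] == UNKNOWN)
    report.n_unknown_demographics = int(unknown.sum())
    report.pct_unknown = report.n_unknown_demographics / len(records)
    kept = records.loc[~unknown]

    indet = kept["sex"] == INDETERMINATE
    report.n_indeterminate = int(indet.sum())
    kept = kept.loc[~indet]

    if not kept.empty and rare_threshold > 0:
        years = period_year(kept["period"])
        in_complete = years.isin(calendar.complete_years)
        counted = kept.loc[in_complete]
        items = counted["items"].fillna(imputation_value).astype(float)
        totals = items.groupby(counted["drug"]).sum()
        mean_annual = totals / len(calendar.complete_years)
        rare = sorted(mean_annual.index[mean_annual < rare_threshold])
        # A drug absent from the complete years entirely has mean 0.
        never_seen = sorted(set(kept["drug"]) - set(mean_annual.index))
        rare = sorted(set(rare) | set(never_seen))
        report.drugs_dropped_rare = rare
        drop = kept["drug"].isin(rare)
        report.n_rare_records = int(drop.sum())
        kept = kept.loc[~drop]

    return kept.reset_index(drop=True), report


SCOPE_ALL = "all"
SCOPE_MALES = "males_only"
SCOPE_CHILDREN = "children_only"
SCOPES = (SCOPE_ALL, SCOPE_MALES, SCOPE_CHILDREN)


def impute_redacted(
    records: pd.DataFrame,
    value: int = 1,
    scope: str = SCOPE_ALL,
    default: int = 1,
) -> pd.DataFrame:
    """Substitute redacted counts.

    Redacted cells inside ``scope`` take ``value``; redacted cells
    outside it take ``default`` (the study's baseline of 1). The
    children scope covers age bands wholly below 20 years ("0–1"
    through "16–20").
    """
    if value not in (1, 2, 3, 4):
        raise ValidationError(f"imputation value must be in 1..4, got {value}")
    if scope not in SCOPES:
        raise ValidationError(f"unknown scope: {scope!r}")
    out = records.copy()
    red = out["items"].isna()
    if scope == SCOPE_ALL:
        in_scope = pd.Series(True, index=out.index)
    elif scope == SCOPE_MALES:
        in_scope = out["sex"] == MALE
    else:
        in_scope = out["age_band"].isin(child_band_labels())
    out.loc[red & in_scope, "items"] = value
    out.loc[red & ~in_scope, "items"] = default
    out["items"] = out["items"].astype("Int64")
    return out


def filter_regions(records: pd.DataFrame, keep: Iterable[str]) -> pd.DataFrame:
    """Keep-list region filter (e.g. England-only analysis)."""
    keep = set(keep)
    return records.loc[records["region"].isin(keep)].reset_index(drop=True)


def collapse_bands_86plus(records: pd.DataFrame) -> pd.DataFrame:
    """Optionally collapse bands >= 86 into a single "86+" reporting
    band (presentation choice; the analysis scheme keeps all 23)."""
    out = records.copy()
    high = {b.label for b in AGE_BANDS if b.lower >= 86}
    out.loc[out["age_band"].isin(high), "age_band"] = "86+"
    return out


def write_records(records: pd.DataFrame, path_or_buf) -> None:
    """Serialise a canonical record table to CSV (redacted cells back
    to "*"); lossless round trip with :func:`read_prescriptions`."""
    out = records[RECORD_COLUMNS].copy()
    out["items"] = out["items"].astype(object).where(out["items"].notna(), "*")
    out.to_csv(path_or_buf, index=False)


def records_to_csv_bytes(records: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_records(records, buf)
    return buf.getvalue().encode()
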