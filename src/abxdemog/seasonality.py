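"""Rule-based seasonality classification of monthly prescribing series.

A drug is "seasonal" when, in its pre-COVID monthly profile (mean
national items per calendar month, averaged over years), at least
``min_months`` (default 2) calendar months sit at or above
``threshold_factor`` (default 1.2, i.e. 20% higher) times the overall
mean.  The overall mean is the mean of the 12 month-means, so the rule
is insensitive to incomplete years contributing different month counts;
a switch selects the raw all-months mean instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_ingest import StudyCalendar, ValidationError, period_month, period_year

MONTHS = tuple(range(1, 13))


@dataclass(frozen=True)
class MonthlyProfile:
    drug: str
    month_means: tuple[float, ...]  # index 0 = January
    overall_mean: float
    years_used: tuple[int, ...]


@dataclass(frozen=True)
class SeasonalityVerdict:
    drug: str
    seasonal: bool
    peak_months: tuple[int, ...]  # 1 = January
    threshold_factor: float = 1.2
    min_months: int = 2
    overall_mean: float = 0.0


def monthly_profile(
    records: pd.DataFrame,
    drug: str,
    calendar: StudyCalendar | None = None,
    mean_of_month_means: bool = True,
) -> MonthlyProfile:
    """Pre-COVID monthly profile of national item totals for ``drug``.

    Months on or after ``calendar.covid_start`` are excluded (the
    default window keeps April 2015 – February 2020). Requires all 12
    calendar months to be observed at least once.
    """
    calendar = calendar or StudyCalendar()
    sub = records.loc[records["drug"] == drug]
    if sub.empty:
        raise ValidationError(f"drug not present in records: {drug!r}")
    if sub["items"].isna().any():
        raise ValidationError("records still contain redacted items; impute first")
    sub = sub.loc[sub["period"] < calendar.covid_start]
    totals = sub.groupby("period", observed=True)["items"].sum()
    months = period_month(totals.index.to_series())
    by_month = totals.groupby(months.to_numpy()).mean()
    if len(by_month) < 12:
        raise ValidationError(
            f"profile undefined for {drug!r}: only {len(by_month)} of 12 "
            "calendar months observed pre-COVID"
        )
    month_means = tuple(float(by_month[m]) for m in MONTHS)
    overall = (
        sum(month_means) / 12.0 if mean_of_month_means else float(totals.mean())
    )
    years = tuple(sorted(period_year(totals.index.to_series()).unique()))
    return MonthlyProfile(drug=drug, month_means=month_means,
                          overall_mean=overall, years_used=years)


def classify_seasonal(
    profile: MonthlyProfile,
    threshold_factor: float = 1.2,
    min_months: int = 2,
) -> SeasonalityVerdict:
    """Apply the peak-month threshold rule to a profile.

    Peak months satisfy ``month_mean >= threshold_factor *
    overall_mean`` (inclusive); seasonal iff at least ``min_months``
    peaks.
    """
    if threshold_factor <= 1:
        raise ValidationError("threshold_factor must exceed 1")
    if min_months < 1:
        raise ValidationError("min_months must be >= 1")
    cut = threshold_factor * profile.overall_mean
    peaks = tuple(m for m in MONTHS if profile.month_means[m - 1] >= cut)
    return SeasonalityVerdict(
        drug=profile.drug,
        seasonal=len(peaks) >= min_months,
        peak_months=peaks,
        threshold_factor=threshold_factor,
        min_months=min_months,
        overall_mean=profile.overall_mean,
    )


def classify_all(
    records: pd.DataFrame,
    calendar: StudyCalendar | None = None,
    threshold_factor: float = 1.2,
    min_months: int = 2,
) -> pd.DataFrame:
    """Verdict table for every drug in the records."""
    rows = []
    for drug in sorted(records["drug"].unique()):
        prof = monthly_profile(records, drug, calendar)
        v = classify_seasonal(prof, threshold_factor, min_months)
        rows.append(
            {
                "drug": drug,
                "seasonal": v.seasonal,
                "peak_months": ",".join(str(m) for m in v.peak_months),
                "overall_mean": v.overall_mean,
            }
        )
    return pd.DataFrame(rows, columns=["drug", "seasonal", "peak_months", "overall_mean"])
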