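"""Synthetic prescription-data generator with retained ground truth.

Emulates the structure of an NHSBSA-style monthly extract: item counts
per (drug, 23-band age, sex, region, month) with hockey-stick age
profiles, a female excess, drug-specific winter seasonality, a
COVID-era dip and small-number suppression of counts below 5.  Every
stochastic draw is keyed to the config seed, and the expected mean and
the drawn (pre-suppression) count of every stratum are retained so
that each analysis stage can be tested for recovery of the truth.

The generator is a test instrument: it reproduces the statistical
*structure* the analysis assumes, not the marginals of the real
English data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_ingest import (
    AGE_BAND_LABELS,
    FEMALE,
    MALE,
    RECORD_COLUMNS,
    StudyCalendar,
    ValidationError,
)

# England-shaped per-sex base population by band (persons, per sex).
_BASE_POP = {
    "0–1": 550_000, "2–5": 1_250_000, "6–10": 1_600_000, "11–15": 1_650_000,
    "16–20": 1_550_000, "21–25": 1_700_000, "26–30": 1_850_000,
    "31–35": 1_900_000, "36–40": 1_850_000, "41–45": 1_700_000,
    "46–50": 1_750_000, "51–55": 1_850_000, "56–60": 1_800_000,
    "61–65": 1_550_000, "66–70": 1_350_000, "71–75": 1_250_000,
    "76–80": 1_000_000, "81–85": 700_000, "86–90": 400_000,
    "91–95": 180_000, "96–100": 50_000, "101–105": 8_000, "105+": 1_000,
}
# Female survival advantage at older ages.
_FEMALE_POP_FACTOR = {
    "76–80": 1.15, "81–85": 1.3, "86–90": 1.5, "91–95": 1.8,
    "96–100": 2.2, "101–105": 2.6, "105+": 3.0,
}

#: Hockey-stick age multipliers: high in infancy, dip in school age,
#: exponential-ish rise into old age.
HOCKEY_STICK_PROFILE = {
    "0–1": 3.0, "2–5": 2.0, "6–10": 1.0, "11–15": 0.6, "16–20": 0.7,
    "21–25": 0.8, "26–30": 0.8, "31–35": 0.8, "36–40": 0.8, "41–45": 0.9,
    "46–50": 1.0, "51–55": 1.1, "56–60": 1.2, "61–65": 1.4, "66–70": 1.6,
    "71–75": 1.9, "76–80": 2.3, "81–85": 2.8, "86–90": 3.4, "91–95": 3.8,
    "96–100": 4.0, "101–105": 4.0, "105+": 4.0,
}


@dataclass(frozen=True)
class DrugSpec:
    """Generating parameters for one drug."""

    name: str
    family: str
    aware_category: str
    base_monthly_rate: float  # items per 100,000 persons per month, sexes pooled
    seasonal_amplitude: float = 0.0  # peak-month multiplier is 1 + amplitude
    peak_months: tuple[int, ...] = ()
    fm_ratio: float = 1.0  # female rate over male rate
    age_profile: Mapping[str, float] | None = None  # None -> hockey stick

    def __post_init__(self) -> None:
        if self.base_monthly_rate <= 0:
            raise ValidationError(f"{self.name}: base rate must be positive")
        if self.seasonal_amplitude < 0:
            raise ValidationError(f"{self.name}: negative amplitude")
        if self.fm_ratio <= 0:
            raise ValidationError(f"{self.name}: fm_ratio must be positive")


@dataclass(frozen=True)
class RegionSpec:
    code: str
    size_multiplier: float = 1.0
    prescribing_multiplier: float = 1.0


@dataclass(frozen=True)
class RateShift:
    """Multiplier applied to given age bands from a period onward
    (e.g. a vaccination-linked drop in one age group)."""

    age_bands: tuple[str, ...]
    start_period: str
    multiplier: float


def default_drugs() -> tuple[DrugSpec, ...]:
    """Twenty drugs shaped like the most-prescribed English antibiotics:
    winter-seasonal respiratory penicillins/macrolides, strongly
    female-skewed urinary drugs, a male-skewed quinolone, and a mix of
    AWaRe categories."""
    return (
        DrugSpec("Amoxicillin", "Penicillins", "Access", 1000, 0.5, (12, 1), 1.4),
        DrugSpec("Nitrofurantoin", "Urinary-tract infections", "Access", 520, 0.0, (), 4.5),
        DrugSpec("Flucloxacillin sodium", "Penicillins", "Access", 500, 0.15, (7,), 1.2),
        DrugSpec("Doxycycline hyclate", "Tetracyclines", "Access", 430, 0.4, (12, 1), 1.5),
        DrugSpec("Penicillin V", "Penicillins", "Access", 290, 0.6, (12, 1), 1.45),
        DrugSpec("Trimethoprim", "Sulphonamides and trimethoprim", "Access", 270, 0.0, (), 3.0),
        DrugSpec("Clarithromycin", "Macrolides", "Watch", 270, 0.5, (12, 1), 1.7),
        DrugSpec("Co-amoxiclav", "Penicillins", "Access", 170, 0.3, (12, 1), 1.5),
        DrugSpec("Lymecycline", "Tetracyclines", "Watch", 150, 0.0, (), 1.4,
                 {**HOCKEY_STICK_PROFILE, "11–15": 6.0, "16–20": 8.0, "21–25": 4.0}),
        DrugSpec("Cefalexin", "Cephalosporins and other beta-lactams", "Access", 110, 0.2, (12,), 4.0),
        DrugSpec("Azithromycin", "Macrolides", "Watch", 110, 0.3, (12, 1), 1.3),
        DrugSpec("Metronidazole", "Metronidazole, tinidazole and ornidazole", "Access", 78, 0.0, (), 3.5),
        DrugSpec("Ciprofloxacin", "Quinolones", "Watch", 66, 0.0, (), 0.92),
        DrugSpec("Erythromycin", "Macrolides", "Watch", 63, 0.35, (12, 1), 1.9),
        DrugSpec("Oxytetracycline", "Tetracyclines", "Access", 45, 0.0, (), 1.05),
        DrugSpec("Pivmecillinam hydrochloride", "Penicillins", "Access", 33, 0.0, (), 3.8),
        DrugSpec("Erythromycin ethylsuccinate", "Macrolides", "Watch", 29, 0.4, (12, 1), 1.0),
        DrugSpec("Co-trimoxazole", "Sulphonamides and trimethoprim", "Access", 26, 0.0, (), 0.8),
        DrugSpec("Methenamine hippurate", "Urinary-tract infections", "Unclassified", 20, 0.0, (), 4.0),
        DrugSpec("Colistimethate sodium", "Some other antibacterials", "Reserve", 11, 0.0, (), 0.95),
    )


def default_regions(n: int = 42) -> tuple[RegionSpec, ...]:
    """ICB-like regions Q01..Qnn, equal sizes, mild prescribing spread."""
    mults = 0.85 + 0.3 * (np.arange(n) % 7) / 6.0
    return tuple(
        RegionSpec(code=f"Q{i + 1:02d}", size_multiplier=1.0,
                   prescribing_multiplier=float(round(mults[i], 3)))
        for i in range(n)
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic study dataset."""

    seed: int = 0
    start_period: str = "2022-01"
    end_period: str = "2023-12"
    drugs: tuple[DrugSpec, ...] = field(default_factory=default_drugs)
    regions: tuple[RegionSpec, ...] = field(default_factory=default_regions)
    covid_dip: float = 0.7
    suppression_threshold: int = 5
    distribution: str = "poisson"  # or "negbin"
    negbin_dispersion: float = 5.0  # negbin size parameter (larger = closer to Poisson)
    calendar: StudyCalendar = field(default_factory=StudyCalendar)
    rate_shifts: tuple[RateShift, ...] = ()

    def periods(self) -> list[str]:
        idx = pd.period_range(self.start_period, self.end_period, freq="M")
        return [f"{p.year:04d}-{p.month:02d}" for p in idx]

    def years(self) -> list[int]:
        return sorted({int(p[:4]) for p in self.periods()})


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests: the config, and the
    full stratum grid with expected means and drawn pre-suppression
    counts."""

    config: SyntheticConfig
    grid: pd.DataFrame  # period drug family age_band sex region mean items

    def true_total(self) -> int:
        return int(self.grid["items"].sum())

    def expected_items(self) -> pd.DataFrame:
        return self.grid[["period", "drug", "family", "age_band", "sex", "region", "mean"]]

    def summary_json(self) -> str:
        per_drug = self.grid.groupby("drug", observed=True)["mean"].sum()
        payload = {
            "seed": self.config.seed,
            "start_period": self.config.start_period,
            "end_period": self.config.end_period,
            "n_drugs": len(self.config.drugs),
            "n_regions": len(self.config.regions),
            "true_total_items": self.true_total(),
            "expected_items_by_drug": {k: float(v) for k, v in per_drug.items()},
        }
        return json.dumps(payload, indent=2)


def _population_array(config: SyntheticConfig) -> np.ndarray:
    """Deterministic cell counts, shape (region, band, sex); constant
    across years.  Sex axis order is (Female, Male)."""
    total_size = sum(r.size_multiplier for r in config.regions)
    shares = np.array([r.size_multiplier / total_size for r in config.regions])
    base = np.array([_BASE_POP[b] for b in AGE_BAND_LABELS], dtype=float)
    female = base * np.array([_FEMALE_POP_FACTOR.get(b, 1.0) for b in AGE_BAND_LABELS])
    per_sex = np.stack([female, base], axis=-1)  # (band, sex)
    return np.round(shares[:, None, None] * per_sex[None, :, :])


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic population table: per region, band, sex and year;
    region totals proportional to ``size_multiplier``."""
    arr = _population_array(config)  # (region, band, sex)
    years = config.years()
    n_r, n_b, n_s = arr.shape
    n_y = len(years)
    return pd.DataFrame(
        {
            "age_band": np.tile(np.repeat(list(AGE_BAND_LABELS), n_s * n_y), n_r),
            "sex": np.tile(np.repeat([FEMALE, MALE], n_y), n_r * n_b),
            "region": np.repeat([r.code for r in config.regions], n_b * n_s * n_y),
            "year": np.tile(years, n_r * n_b * n_s),
            "count": np.repeat(arr.reshape(-1), n_y).astype(np.int64),
        }
    )


def _sex_factors(fm_ratio: float) -> dict[str, float]:
    # Pooled rate stays at base_monthly_rate when F and M populations match.
    return {FEMALE: 2 * fm_ratio / (1 + fm_ratio), MALE: 2 / (1 + fm_ratio)}


def generate_prescriptions(
    config: SyntheticConfig, population: pd.DataFrame
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw monthly item counts for every stratum.

    The mean of each (drug, band, sex, region, month) count is the
    product of the drug's base rate, its age and sex factors, the
    seasonal multiplier (1 + amplitude in peak months), the region's
    prescribing multiplier, the COVID dip inside the study calendar's
    window, any configured rate shifts, and the stratum population per
    100,000.  Counts are Poisson (or negative-binomial) draws; strata
    that draw zero are absent from the record table, never redacted.
    """
    rng = np.random.default_rng(config.seed)
    periods = np.array(config.periods())
    months = np.array([int(p[5:]) for p in periods])
    covid = config.calendar.in_covid_window(pd.Series(periods)).to_numpy()
    covid_mult = np.where(covid, config.covid_dip, 1.0)

    bands = list(AGE_BAND_LABELS)
    sexes = [FEMALE, MALE]
    n_d, n_r, n_b, n_s, n_p = (
        len(config.drugs), len(config.regions), len(bands), len(sexes), len(periods),
    )

    # factor arrays: mean has shape (drug, region, band, sex, period)
    base_rate = np.array([d.base_monthly_rate for d in config.drugs]) / 1e5
    profile = np.array(
        [[(d.age_profile or HOCKEY_STICK_PROFILE).get(b, 1.0) for b in bands]
         for d in config.drugs]
    )  # (drug, band)
    sexf = np.array(
        [[_sex_factors(d.fm_ratio)[s] for s in sexes] for d in config.drugs]
    )  # (drug, sex)
    seasonal = np.array(
        [np.where(np.isin(months, d.peak_months), 1.0 + d.seasonal_amplitude, 1.0)
         for d in config.drugs]
    )  # (drug, period)
    regmult = np.array([r.prescribing_multiplier for r in config.regions])
    pop_arr = _population_array(config)  # (region, band, sex)

    mean = (
        base_rate[:, None, None, None, None]
        * regmult[None, :, None, None, None]
        * profile[:, None, :, None, None]
        * sexf[:, None, None, :, None]
        * seasonal[:, None, None, None, :]
        * covid_mult[None, None, None, None, :]
        * pop_arr[None, :, :, :, None]
    )
    band_index = {b: i for i, b in enumerate(bands)}
    for shift in config.rate_shifts:
        b_idx = [band_index[b] for b in shift.age_bands]
        p_mask = periods >= shift.start_period
        sub = mean[:, :, b_idx, :, :]
        sub[..., p_mask] *= shift.multiplier
        mean[:, :, b_idx, :, :] = sub

    drug_names = [d.name for d in config.drugs]
    families = [d.family for d in config.drugs]
    reps_drug = n_r * n_b * n_s * n_p
    grid = pd.DataFrame(
        {
            "period": np.tile(periods, n_d * n_r * n_b * n_s),
            "drug": np.repeat(drug_names, reps_drug),
            "family": np.repeat(families, reps_drug),
            "age_band": np.tile(np.repeat(bands, n_s * n_p), n_d * n_r),
            "sex": np.tile(np.repeat(sexes, n_p), n_d * n_r * n_b),
            "region": np.tile(
                np.repeat([r.code for r in config.regions], n_b * n_s * n_p), n_d
            ),
            "mean": mean.reshape(-1),
        }
    )
    mu = grid["mean"].to_numpy()
    if config.distribution == "poisson":
        counts = rng.poisson(mu)
    elif config.distribution == "negbin":
        size = config.negbin_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, np.clip(p, 1e-12, 1.0))
    else:
        raise ValidationError(f"unknown distribution: {config.distribution!r}")
    grid["items"] = counts

    records = grid.loc[grid["items"] > 0,
                       ["period", "drug", "family", "age_band", "sex", "region", "items"]]
    records = records.reset_index(drop=True)
    records["items"] = records["items"].astype("Int64")
    return records, SyntheticTruth(config=config, grid=grid)


def apply_suppression(records: pd.DataFrame, threshold: int = 5) -> pd.DataFrame:
    """Small-number suppression: counts below ``threshold`` become the
    redaction marker (missing ``items``); others pass through."""
    out = records.copy()
    out["items"] = out["items"].astype("Int64")
    out.loc[out["items"] < threshold, "items"] = pd.NA
    return out


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Convenience wrapper: (population, suppressed records, truth)."""
    population = generate_population(config)
    records, truth = generate_prescriptions(config, population)
    suppressed = apply_suppression(records, config.suppression_threshold)
    return population, suppressed, truth
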