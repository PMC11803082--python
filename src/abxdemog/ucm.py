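"""Updated Comparison Metric (UCM): age/sex prescribing-unit weights
and region comparison.

The UCM generalises the STAR-PU idea to the 23-band age scheme: each
(age band, sex) cell's weight is its per-capita prescribing rate in a
reference year relative to the baseline cell, females aged 66–70.
Weights are computed nationally (all regions pooled), optionally per
BNF drug family ("UCM-family"), clamped to [0.01, 100]; child bands
with no prescriptions take a 0.01 substitute.  A region's weighted
population is the weight-weighted sum of its population cells, and its
metric is items per weighted person; regions are ranked descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_ingest import (
    AGE_BANDS,
    FEMALE,
    ValidationError,
    period_year,
)

DEFAULT_BASELINE = ("66–70", FEMALE)
OVERALL = "overall"

#: Bands eligible for the zero-items child substitute: the paper's
#: "children aged up to 16" does not align with band edges, so the
#: default covers bands whose lower bound is below 16.
CHILD_SUBSTITUTE_BANDS: tuple[str, ...] = tuple(
    b.label for b in AGE_BANDS if b.lower < 16
)


@dataclass(frozen=True)
class UCMWeightTable:
    """Weights per (age band, sex) with their construction parameters."""

    weights: Mapping[tuple[str, str], float]
    baseline: tuple[str, str] = DEFAULT_BASELINE
    family: str = OVERALL
    floor: float = 0.01
    cap: float = 100.0
    child_substitute: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_band": b, "sex": s, "family": self.family, "weight": w}
            for (b, s), w in sorted(self.weights.items())
        ]
        return pd.DataFrame(rows, columns=["age_band", "sex", "family", "weight"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "UCMWeightTable":
        fam = df["family"].iloc[0] if "family" in df.columns and len(df) else OVERALL
        weights = {
            (r.age_band, r.sex): float(r.weight) for r in df.itertuples(index=False)
        }
        return cls(weights=weights, family=fam, **kwargs)


def compute_ucm_weights(
    records: pd.DataFrame,
    population: pd.DataFrame,
    baseline: tuple[str, str] = DEFAULT_BASELINE,
    family: str | None = None,
    year: int = 2023,
    floor: float = 0.01,
    cap: float = 100.0,
    child_substitute: float = 0.01,
    clamp_zero_adult: bool = False,
) -> UCMWeightTable:
    """Compute UCM weights from national data of one calendar year.

    weight(band, sex) = per-capita items(band, sex) / per-capita items
    at the baseline cell. ``family`` restricts the numerator to one BNF
    family (UCM-family); None uses all prescriptions.  Cells in the
    child bands with zero items take ``child_substitute``; a zero-item
    adult cell is an error unless ``clamp_zero_adult`` floors it.
    """
    if records["items"].isna().any():
        raise ValidationError("records still contain redacted items; impute first")
    rec = records.loc[period_year(records["period"]) == year]
    if family is not None:
        rec = rec.loc[rec["family"] == family]
    items = rec.groupby(["age_band", "sex"], observed=True)["items"].sum()

    pop = population.loc[population["year"] == year]
    popn = pop.groupby(["age_band", "sex"], observed=True)["count"].sum()
    cells = [(b, s) for (b, s) in popn.index if popn[(b, s)] > 0]
    if not cells:
        raise ValidationError(f"no population for year {year}")
    if baseline not in popn.index or popn[baseline] == 0:
        raise ValidationError(f"baseline cell {baseline} has no population in {year}")
    base_items = float(items.get(baseline, 0))
    if base_items == 0:
        raise ValidationError(f"baseline cell {baseline} has zero items in {year}")
    base_rate = base_items / float(popn[baseline])

    weights: dict[tuple[str, str], float] = {}
    for cell in cells:
        n_items = float(items.get(cell, 0))
        if n_items == 0:
            if cell[0] in CHILD_SUBSTITUTE_BANDS:
                weights[cell] = child_substitute
                continue
            if not clamp_zero_adult:
                raise ValidationError(
                    f"zero items in non-child cell {cell} for "
                    f"family={family or OVERALL!r}, year {year}"
                )
        rate = n_items / float(popn[cell])
        weights[cell] = min(max(rate / base_rate, floor), cap)
    # exact unity at the baseline regardless of float rounding
    weights[baseline] = 1.0
    return UCMWeightTable(
        weights=weights,
        baseline=baseline,
        family=family or OVERALL,
        floor=floor,
        cap=cap,
        child_substitute=child_substitute,
    )


def apply_ucm(
    weights: UCMWeightTable,
    population_by_region: pd.DataFrame,
    items_by_region: Mapping[str, int],
) -> pd.DataFrame:
    """Weighted populations and per-weighted-person metrics by region.

    ``population_by_region`` holds one year's population cells;
    ``items_by_region`` maps region code to that year's item total.
    """
    pop = population_by_region.groupby(
        ["region", "age_band", "sex"], as_index=False, observed=True
    )["count"].sum()
    missing = sorted(
        {(r.age_band, r.sex) for r in pop.itertuples(index=False)}
        - set(weights.weights)
    )
    if missing:
        raise ValidationError(f"weights missing for cells: {missing[:5]}")
    pop["w"] = [
        weights.weights[(b, s)] * c
        for b, s, c in zip(pop["age_band"], pop["sex"], pop["count"])
    ]
    wpop = pop.groupby("region", observed=True)["w"].sum()
    regions_no_pop = sorted(set(items_by_region) - set(wpop.index))
    if regions_no_pop:
        raise ValidationError(f"regions without population: {regions_no_pop}")
    rows = []
    for region in sorted(items_by_region):
        wp = float(wpop[region])
        n = int(items_by_region[region])
        rows.append(
            {
                "region": region,
                "weighted_population": wp,
                "items": n,
                "metric": n / wp if wp > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["region", "weighted_population", "items", "metric"])


def quartile_groups(n_regions: int) -> list[int]:
    """Rank cut-points for the 4 colour groups: 10/10/10/rest at the
    English ICB count of 42, proportional cuts otherwise."""
    if n_regions == 42:
        return [10, 20, 30]
    return [round(n_regions * k / 4.2) for k in (1, 2, 3)]


def rank_regions(metrics: pd.DataFrame) -> pd.DataFrame:
    """Rank regions descending by metric (1 = highest prescriber);
    ties break by ascending region code; attach quartile groups."""
    if metrics.empty:
        raise ValidationError("no regions to rank")
    out = metrics.sort_values(
        ["metric", "region"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    cuts = quartile_groups(len(out))
    out["quartile_group"] = np.searchsorted(cuts, out["rank"], side="left") + 1
    return out
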