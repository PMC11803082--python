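"""AWaRe (Access / Watch / Reserve) classification and Access-share
targets.

Drugs are mapped to WHO AWaRe categories via a packaged reference
table plus a manual-override file that resolves prescription-data name
variants (salt suffixes, UK spellings) to reference names.  Drugs that
resolve to no category are explicitly ``Unclassified`` and stay in the
denominator: the targets are fractions of *total* consumption, so
dropping unmatched drugs would inflate the Access share.

Targets evaluated per stratum: the older WHO 60% Access level, the UN
General Assembly 70% level, and the proposed 80% level for oral use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .core_ingest import ValidationError

ACCESS = "Access"
WATCH = "Watch"
RESERVE = "Reserve"
UNCLASSIFIED = "Unclassified"
CATEGORIES = (ACCESS, WATCH, RESERVE, UNCLASSIFIED)

TARGET_LEVELS = (60, 70, 80)


def _norm(name: str) -> str:
    return " ".join(str(name).split()).lower()


@dataclass
class AWaReMap:
    """Drug-name → category lookup with manual-match overrides."""

    entries: dict[str, str]  # normalised drug name -> category
    overrides: dict[str, str] = field(default_factory=dict)  # normalised source -> reference

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values()} - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown AWaRe categories: {sorted(bad)}")

    def category(self, drug: str) -> str:
        key = _norm(drug)
        if key in self.entries:
            return self.entries[key]
        ref = self.overrides.get(key)
        if ref is not None and _norm(ref) in self.entries:
            return self.entries[_norm(ref)]
        return UNCLASSIFIED

    @classmethod
    def from_files(cls, map_source, overrides_source=None) -> "AWaReMap":
        """Load from CSV: map (drug, category); overrides
        (source_name, reference_name)."""
        m = pd.read_csv(map_source, dtype=str)
        for col in ("drug", "category"):
            if col not in m.columns:
                raise ValidationError(f"AWaRe map lacks column {col!r}")
        entries = {_norm(d): c.strip() for d, c in zip(m["drug"], m["category"])}
        overrides: dict[str, str] = {}
        if overrides_source is not None:
            o = pd.read_csv(overrides_source, dtype=str)
            for col in ("source_name", "reference_name"):
                if col not in o.columns:
                    raise ValidationError(f"overrides file lacks column {col!r}")
            for s, r in zip(o["source_name"], o["reference_name"]):
                key = _norm(s)
                if key in overrides and _norm(overrides[key]) != _norm(r):
                    raise ValidationError(f"conflicting overrides for {s!r}")
                overrides[key] = r
        return cls(entries=entries, overrides=overrides)


def load_default_map() -> AWaReMap:
    """The packaged WHO AWaRe reference table and override list."""
    data = resources.files("abxdemog.data")
    with resources.as_file(data / "aware_who.csv") as m, resources.as_file(
        data / "aware_overrides.csv"
    ) as o:
        return AWaReMap.from_files(m, o)


def resolve_categories(drugs: Iterable[str], aware_map: AWaReMap) -> dict[str, str]:
    """Category per drug: exact (case/whitespace-insensitive) match,
    then override table, else Unclassified."""
    return {d: aware_map.category(d) for d in drugs}


def aware_breakdown(
    records: pd.DataFrame,
    aware_map: AWaReMap,
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """Item-weighted AWaRe category shares per stratum.

    Returns one row per stratum with ``share_access`` ..
    ``share_unclassified`` (fractions of the stratum's items, summing
    to 1), ``n_items``, and ``meets_60`` / ``meets_70`` / ``meets_80``
    flags on the Access share.
    """
    if records["items"].isna().any():
        raise ValidationError("records still contain redacted items; impute first")
    strata = strata or []
    rec = records.copy()
    cats = resolve_categories(rec["drug"].unique(), aware_map)
    rec["category"] = rec["drug"].map(cats)
    group = strata + ["category"]
    counts = rec.groupby(group, observed=True)["items"].sum().reset_index()
    if strata:
        wide = counts.pivot_table(
            index=strata, columns="category", values="items",
            aggfunc="sum", fill_value=0, observed=True,
        )
    else:
        wide = counts.set_index("category")["items"].to_frame().T
        wide.index = [0]
    for c in CATEGORIES:
        if c not in wide.columns:
            wide[c] = 0
    wide = wide[list(CATEGORIES)]
    total = wide.sum(axis=1)
    out = wide.reset_index()[strata] if strata else pd.DataFrame(index=wide.index)
    for c in CATEGORIES:
        out[f"share_{c.lower()}"] = (wide[c] / total.where(total > 0)).to_numpy()
    out["n_items"] = total.to_numpy().astype(int)
    out["undefined_shares"] = (total == 0).to_numpy()
    for level in TARGET_LEVELS:
        out[f"meets_{level}"] = (out["share_access"] >= level / 100).fillna(False)
    return out.reset_index(drop=True)
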