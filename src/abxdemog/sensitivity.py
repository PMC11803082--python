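"""Redaction-imputation sensitivity scan.

Counts below the suppression threshold arrive redacted; the analysis
substitutes a fixed value (1 by default, the minimum possible).  This
module quantifies how the headline female-majority pattern shifts when
the substitute is raised to its maximum (4), either for everyone, for
males only, or for children only — the three scopes that could bias
the sex contrast in opposite directions.

For each (value, scope) combination the scan imputes, computes
per-drug per-age-band sex majorities on per-capita rates, and reports
the fraction of drugs that are female-majority in at least 50%, 75%
and 90% of their age bands (bands where both sexes have zero items are
excluded from the band denominator).
"""

from __future__ import annotations

import pandas as pd

from .core_ingest import SCOPES, SCOPE_ALL, ValidationError, impute_redacted
from .rates import compute_rates, sex_contrast

THRESHOLDS = (0.50, 0.75, 0.90)


def female_majority_fractions(
    records: pd.DataFrame, population: pd.DataFrame
) -> dict[str, float]:
    """Fractions of drugs female-majority in >=50/75/90% of age bands.

    ``records`` must already be de-redacted.  Majority is strict
    (female per-capita rate > male rate); a band enters a drug's
    denominator only if at least one sex has items there.
    """
    rts = compute_rates(records, population, ["drug", "age_band", "sex"])
    ctr = sex_contrast(rts)
    usable = ctr.loc[~ctr["both_zero"]]
    if usable.empty:
        raise ValidationError("no drug/age-band cells with any items")
    per_drug = usable.groupby("drug", observed=True)["female_majority"].mean()
    n_drugs = len(per_drug)
    return {
        f"frac_female_majority_{int(t * 100)}": float((per_drug >= t).sum()) / n_drugs
        for t in THRESHOLDS
    }


def sensitivity_scan(
    records: pd.DataFrame,
    population: pd.DataFrame,
    values: tuple[int, ...] = (1, 4),
    scopes: tuple[str, ...] = SCOPES,
) -> pd.DataFrame:
    """Scan imputation values × scopes on a raw (still-redacted) table.

    Always includes the study baseline (value 1, scope "all") as the
    first row for comparison.
    """
    for v in values:
        if v not in (1, 2, 3, 4):
            raise ValidationError(f"imputation value must be in 1..4, got {v}")
    combos = [(1, SCOPE_ALL)]
    for v in values:
        for s in scopes:
            if s not in SCOPES:
                raise ValidationError(f"unknown scope: {s!r}")
            if (v, s) != (1, SCOPE_ALL):
                combos.append((v, s))
    rows = []
    for value, scope in combos:
        imputed = impute_redacted(records, value=value, scope=scope)
        fracs = female_majority_fractions(imputed, population)
        rows.append({"value": value, "scope": scope, **fracs})
    return pd.DataFrame(rows)
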