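import io

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abxdemog.core_ingest import (
    AGE_BANDS,
    UNKNOWN,
    ValidationError,
    apply_exclusions,
    band_for_age,
    child_band_labels,
    impute_redacted,
    parse_age_band,
    read_prescriptions,
    records_to_csv_bytes,
    write_records,
)
from conftest import make_records


@pytest.mark.parametrize(
    "label,lower,upper",
    [
        ("0–1", 0, 1),
        ("2–5", 2, 5),
        ("105+", 105, None),
        ("66-70", 66, 70),  # ASCII hyphen dialect
        ("66—70", 66, 70),  # em dash
        (" 11–15 ", 11, 15),
        ("101 - 105", 101, 105),
    ],
)
def test_parse_age_band_accepts_dialects(label, lower, upper):
    band = parse_age_band(label)
    assert (band.lower, band.upper) == (lower, upper)


@pytest.mark.parametrize("label", ["", "  ", "66–71", "5-9", "adult", "105"])
def test_parse_age_band_rejects_unknown_labels(label):
    with pytest.raises(ValidationError):
        parse_age_band(label)


def test_scheme_has_23_bands_partitioning_ages():
    assert len(AGE_BANDS) == 23
    for age in range(0, 130):
        matches = [b for b in AGE_BANDS if b.contains(age)]
        # the published labels share endpoint 105; membership is still unique
        assert len(matches) == (2 if age == 105 else 1)
        assert band_for_age(age) is matches[0]


def test_children_scope_covers_bands_up_to_16_20():
    assert child_band_labels() == ("0–1", "2–5", "6–10", "11–15", "16–20")


CSV_GOOD = """period,drug,family,age_band,sex,region,items
2023-01,Amoxicillin,Penicillins,2–5,Female,QRL,120
2023-01,Amoxicillin,Penicillins,6-10,male,QRL,*
2023-02,Trimethoprim,Sulphonamides and trimethoprim,66–70,Female,QRL,15
"""


def test_read_prescriptions_parses_counts_and_redactions():
    records, rejects = read_prescriptions(io.StringIO(CSV_GOOD))
    assert len(records) == 3 and rejects.empty
    assert records.loc[0, "items"] == 120
    assert pd.isna(records.loc[1, "items"])  # "*" -> redacted
    assert records.loc[1, "sex"] == "Male"  # case-normalised
    assert records.loc[1, "age_band"] == "6–10"  # dialect-normalised


@pytest.mark.parametrize("bad_items", ["0", "-3", "2.5", "twelve"])
def test_read_prescriptions_rejects_bad_counts(bad_items):
    csv = CSV_GOOD + f"2023-03,Amoxicillin,Penicillins,2–5,Female,QRL,{bad_items}\n"
    records, rejects = read_prescriptions(io.StringIO(csv))
    assert len(records) == 3
    assert len(rejects) == 1 and "items" in rejects.loc[0, "reject_reason"]


def test_read_prescriptions_missing_column_is_config_error():
    with pytest.raises(ValidationError, match="column"):
        read_prescriptions(io.StringIO("period,drug\n2023-01,Amoxicillin\n"))


def test_read_prescriptions_column_mapping_and_unknown_demographics():
    csv = "YM,Drug,Fam,Age,Gender,ICB,N\n2023-01,X,F1,weird,???,QA,7\n"
    records, rejects = read_prescriptions(
        io.StringIO(csv),
        column_map={"period": "YM", "drug": "Drug", "family": "Fam",
                    "age_band": "Age", "sex": "Gender", "region": "ICB",
                    "items": "N"},
    )
    assert rejects.empty
    assert records.loc[0, "age_band"] == UNKNOWN
    assert records.loc[0, "sex"] == UNKNOWN


def _bulk(n, sex="Female", band="21–25", drug="Amoxicillin", items=100):
    return [("2023-01", drug, "Penicillins", band, sex, "ENGLAND", items)] * n


def test_exclusions_count_unknowns_like_the_study():
    # 1000 records of which 33 have unknown sex -> 3.3% excluded
    records = make_records(_bulk(967) + _bulk(33, sex=UNKNOWN))
    kept, report = apply_exclusions(records)
    assert len(kept) == 967
    assert report.n_unknown_demographics == 33
    assert report.pct_unknown == pytest.approx(0.033)


def test_exclusions_drop_indeterminate_and_rare_drugs():
    rows = _bulk(10)
    # a drug with 5 items in each complete year: mean 5 < threshold 10
    rows += [(f"{y}-06", "RareDrug", "Penicillins", "21–25", "Male", "ENGLAND", 5)
             for y in range(2016, 2024)]
    rows += _bulk(3, sex="Indeterminate")
    kept, report = apply_exclusions(records := make_records(rows), rare_threshold=10)
    assert report.n_indeterminate == 3
    assert report.drugs_dropped_rare == ["RareDrug"]
    assert set(kept["drug"]) == {"Amoxicillin"}
    # idempotence
    again, report2 = apply_exclusions(kept)
    pd.testing.assert_frame_equal(again, kept)
    assert report2.n_unknown_demographics == 0


def test_exclusions_no_op_on_clean_data_and_empty_input():
    records = make_records(_bulk(5))
    kept, _ = apply_exclusions(records)
    pd.testing.assert_frame_equal(kept, records)
    empty, report = apply_exclusions(records.iloc[0:0])
    assert empty.empty and report.n_input == 0


def test_impute_scopes():
    rows = [
        ("2023-01", "X", "F", "21–25", "Female", "A", None),
        ("2023-01", "X", "F", "21–25", "Male", "A", None),
        ("2023-01", "X", "F", "6–10", "Female", "A", None),
        ("2023-01", "X", "F", "21–25", "Female", "A", 50),
    ]
    records = make_records(rows)
    all4 = impute_redacted(records, value=4, scope="all")
    assert list(all4["items"]) == [4, 4, 4, 50]
    males = impute_redacted(records, value=4, scope="males_only")
    assert list(males["items"]) == [1, 4, 1, 50]  # out-of-scope takes default 1
    children = impute_redacted(records, value=3, scope="children_only")
    assert list(children["items"]) == [1, 1, 3, 50]


@pytest.mark.parametrize("value", [0, 5, -1])
def test_impute_rejects_out_of_range_values(value):
    with pytest.raises(ValidationError):
        impute_redacted(make_records([]), value=value)


@given(
    n_redacted=st.integers(0, 30),
    n_known=st.integers(0, 30),
    data=st.data(),
)
@settings(max_examples=25, deadline=None)
def test_imputation_total_identity_and_monotonicity(n_redacted, n_known, data):
    """total(value=4) - total(value=1) = 3 * (number of redacted cells),
    and totals are non-decreasing in the imputation value."""
    rows = [("2023-01", "X", "F", "21–25", "Female", "A", None)] * n_redacted
    rows += [
        ("2023-01", "X", "F", "21–25", "Male", "A",
         data.draw(st.integers(5, 500)))
        for _ in range(n_known)
    ]
    records = make_records(rows)
    totals = [int(impute_redacted(records, value=v)["items"].sum())
              for v in (1, 2, 3, 4)]
    assert totals == sorted(totals)
    assert totals[3] - totals[0] == 3 * n_redacted


def test_csv_round_trip_is_lossless():
    records = make_records(
        [("2023-01", "Amoxicillin", "Penicillins", "2–5", "Female", "QRL", 120),
         ("2023-02", "Amoxicillin", "Penicillins", "105+", "Male", "QRL", None)]
    )
    buf = io.StringIO(records_to_csv_bytes(records).decode())
    back, rejects = read_prescriptions(buf)
    assert rejects.empty
    pd.testing.assert_frame_equal(back, records)
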