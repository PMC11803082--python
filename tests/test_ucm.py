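import numpy as np
import pandas as pd
import pytest

from abxdemog.core_ingest import ValidationError
from abxdemog.ucm import (
    UCMWeightTable,
    apply_ucm,
    compute_ucm_weights,
    quartile_groups,
    rank_regions,
)
from conftest import make_records


def _pop(cells, year=2023):
    return pd.DataFrame(
        [{"age_band": b, "sex": s, "region": r, "year": year, "count": c}
         for (b, s, r, c) in cells]
    )


def _items(cells, period="2023-06", drug="X", family="F"):
    return make_records(
        [(period, drug, family, b, s, r, n) for (b, s, r, n) in cells]
    )


def test_weights_baseline_unity_and_hand_ratio():
    # baseline rate 0.10 items/person; male 86-90 rate 0.20 -> weight 2
    records = _items([("66–70", "Female", "A", 1000),
                      ("86–90", "Male", "A", 400)])
    pop = _pop([("66–70", "Female", "A", 10_000), ("86–90", "Male", "A", 2_000)])
    table = compute_ucm_weights(records, pop)
    assert table.weights[("66–70", "Female")] == 1.0
    assert table.weights[("86–90", "Male")] == pytest.approx(2.0)


def test_zero_items_child_band_takes_substitute_and_adult_errors():
    records = _items([("66–70", "Female", "A", 1000)])
    pop = _pop([("66–70", "Female", "A", 10_000),
                ("2–5", "Male", "A", 5_000),
                ("41–45", "Male", "A", 5_000)])
    with pytest.raises(ValidationError, match="non-child"):
        compute_ucm_weights(records, pop)
    table = compute_ucm_weights(records, pop, clamp_zero_adult=True)
    assert table.weights[("2–5", "Male")] == 0.01
    assert table.weights[("41–45", "Male")] == 0.01  # floored when clamping enabled


def test_weights_clamped_to_limits():
    records = _items([("66–70", "Female", "A", 10),
                      ("86–90", "Male", "A", 500_000)])
    pop = _pop([("66–70", "Female", "A", 100_000), ("86–90", "Male", "A", 100)])
    table = compute_ucm_weights(records, pop)
    assert table.weights[("86–90", "Male")] == 100.0  # capped


def test_baseline_without_items_is_an_error():
    records = _items([("86–90", "Male", "A", 100)])
    pop = _pop([("66–70", "Female", "A", 10_000), ("86–90", "Male", "A", 100)])
    with pytest.raises(ValidationError, match="baseline"):
        compute_ucm_weights(records, pop)


def test_apply_ucm_hand_computed_weighted_population():
    weights = UCMWeightTable(weights={("66–70", "Female"): 1.0, ("86–90", "Male"): 2.0})
    pop = _pop([("66–70", "Female", "R1", 1000), ("86–90", "Male", "R1", 500)])
    out = apply_ucm(weights, pop, {"R1": 400})
    assert out.loc[0, "weighted_population"] == pytest.approx(2000.0)
    assert out.loc[0, "metric"] == pytest.approx(0.2)


def test_identity_weights_give_crude_per_capita():
    weights = UCMWeightTable(weights={("66–70", "Female"): 1.0, ("2–5", "Male"): 1.0})
    pop = _pop([("66–70", "Female", "R1", 800), ("2–5", "Male", "R1", 200)])
    out = apply_ucm(weights, pop, {"R1": 100})
    assert out.loc[0, "metric"] == pytest.approx(0.1)


def test_metric_scale_invariance_and_size_invariance():
    weights = UCMWeightTable(weights={("66–70", "Female"): 1.0, ("86–90", "Male"): 2.0})
    pop = _pop([("66–70", "Female", "R1", 1000), ("86–90", "Male", "R1", 500),
                ("66–70", "Female", "R2", 3000), ("86–90", "Male", "R2", 1500)])
    # R2 is a 3x-scaled copy of R1 with 3x the items -> equal metrics
    out = apply_ucm(weights, pop, {"R1": 400, "R2": 1200}).set_index("region")
    assert out.loc["R1", "metric"] == pytest.approx(out.loc["R2", "metric"])


def test_region_missing_population_is_an_error():
    weights = UCMWeightTable(weights={("66–70", "Female"): 1.0})
    pop = _pop([("66–70", "Female", "R1", 1000)])
    with pytest.raises(ValidationError, match="without population"):
        apply_ucm(weights, pop, {"R1": 10, "R9": 10})


def test_ranking_sort_ties_and_groups():
    metrics = pd.DataFrame(
        {"region": ["QX", "B", "QA", "C"],
         "weighted_population": [1.0] * 4,
         "items": [1] * 4,
         "metric": [0.1, 0.3, 0.1, 0.2]}
    )
    ranked = rank_regions(metrics).set_index("region")
    assert ranked.loc["B", "rank"] == 1
    assert ranked.loc["C", "rank"] == 2
    assert ranked.loc["QA", "rank"] == 3  # tie broken by code: QA before QX
    assert ranked.loc["QX", "rank"] == 4


def test_quartile_groups_for_42_regions_are_10_10_10_12():
    assert quartile_groups(42) == [10, 20, 30]
    ranks = np.arange(1, 43)
    groups = np.searchsorted([10, 20, 30], ranks, side="left") + 1
    sizes = pd.Series(groups).value_counts().sort_index().tolist()
    assert sizes == [10, 10, 10, 12]


def test_weight_recovery_from_synthetic_rate_structure():
    """Weights recover the generating age/sex relative rates within 2%
    at >= 1e5 expected items per cell."""
    from abxdemog.synthetic_data import (
        DrugSpec, RegionSpec, SyntheticConfig, generate_population,
        generate_prescriptions, HOCKEY_STICK_PROFILE, _sex_factors,
    )

    config = SyntheticConfig(
        seed=11, start_period="2023-01", end_period="2023-12",
        drugs=(DrugSpec("D", "F", "Access", 9000.0, fm_ratio=1.6),),
        regions=(RegionSpec("R"),),
        covid_dip=1.0,
    )
    population = generate_population(config)
    records, truth = generate_prescriptions(config, population)
    # restrict the check to cells with >= 1e5 expected annual items
    expected = truth.grid.groupby(["age_band", "sex"], observed=True)["mean"].sum()
    table = compute_ucm_weights(records, population, year=2023)
    sexf = _sex_factors(1.6)
    base_rate = HOCKEY_STICK_PROFILE["66–70"] * sexf["Female"]
    checked = 0
    for (band, sex), w in table.weights.items():
        if expected[(band, sex)] < 1e5:
            continue
        true_w = HOCKEY_STICK_PROFILE[band] * sexf[sex] / base_rate
        assert w == pytest.approx(true_w, rel=0.02)
        checked += 1
    assert checked >= 20


def test_higher_prescribing_region_ranks_above_identical_twin():
    """+20% uniform prescribing multiplier on an otherwise identical
    region wins the ranking."""
    from abxdemog.synthetic_data import (
        DrugSpec, RegionSpec, SyntheticConfig, generate_population,
        generate_prescriptions,
    )
    from abxdemog.core_ingest import period_year

    config = SyntheticConfig(
        seed=13, start_period="2023-01", end_period="2023-12",
        drugs=(DrugSpec("D", "F", "Access", 500.0, fm_ratio=1.4),),
        regions=(RegionSpec("TWIN_LO", 1.0, 1.0), RegionSpec("TWIN_HI", 1.0, 1.2)),
        covid_dip=1.0,
    )
    population = generate_population(config)
    records, _ = generate_prescriptions(config, population)
    weights = compute_ucm_weights(records, population, year=2023)
    items = records.groupby("region", observed=True)["items"].sum().to_dict()
    ranked = rank_regions(
        apply_ucm(weights, population, items)
    ).set_index("region")
    assert ranked.loc["TWIN_HI", "rank"] == 1
    assert ranked.loc["TWIN_LO", "rank"] == 2


def test_weight_table_csv_round_trip(tmp_path):
    records = _items([("66–70", "Female", "A", 1000), ("86–90", "Male", "A", 400)])
    pop = _pop([("66–70", "Female", "A", 10_000), ("86–90", "Male", "A", 2_000)])
    table = compute_ucm_weights(records, pop)
    path = tmp_path / "w.csv"
    table.to_frame().to_csv(path, index=False)
    back = UCMWeightTable.from_frame(pd.read_csv(path))
    assert back.weights == table.weights
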