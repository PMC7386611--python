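"""Label-effect scenarios, product classification and intake deltas."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import labelsim as ls
from labelsim.scenarios import (
    ILLUSTRATIVE_THRESHOLDS,
    NutrientThresholds,
    effective_fractions,
)

from conftest import weighted_mean


def test_builtin_scenarios_carry_published_fractions():
    scenarios = {s.name: s for s in ls.builtin_scenarios()}
    assert len(scenarios) >= 5
    main = scenarios["main_canada"]
    assert main.beverage_kcal_frac == -0.105
    assert main.snack_kcal_frac == -0.030
    assert main.beverage_sodium_frac == -0.076
    assert main.snack_sodium_frac == -0.083
    chile = scenarios["chile_aggregate"]
    assert chile.beverage_kcal_frac == -0.075
    assert chile.snack_kcal_frac == -0.030  # snacks held at the main value
    strat = scenarios["chile_stratified_chile_limits"]
    assert (strat.highin_frac, strat.not_highin_frac) == (-0.275, 0.108)
    assert strat.thresholds.jurisdiction == "chile_stage1"
    strat_mx = scenarios["chile_stratified_mexico_limits"]
    assert (strat_mx.highin_frac, strat_mx.not_highin_frac) == (-0.275, 0.108)
    assert strat_mx.thresholds.jurisdiction == "mexico"
    uru = scenarios["uruguay_snacks"]
    assert uru.snack_kcal_frac == -0.1168
    assert uru.snack_sodium_frac == -0.5017


def test_invalid_scenarios_rejected():
    with pytest.raises(ValueError, match="outside"):
        ls.Scenario(name="bad", beverage_kcal_frac=-1.0)
    with pytest.raises(ValueError, match="stratified"):
        ls.Scenario(name="bad", mode="stratified", highin_frac=-0.2)
    with pytest.raises(ValueError, match="thresholds"):
        ls.Scenario(name="bad", mode="stratified", highin_frac=-0.2, not_highin_frac=0.1)
    with pytest.raises(KeyError, match="unknown scenario"):
        ls.get_scenario("no_such")


def test_delta_reproduces_reported_intake_changes(reference_adult):
    """Survey-mean intakes under the main scenario give the printed deltas."""
    record = reference_adult.iloc[0]
    d = ls.scenario_delta(record, ls.get_scenario("main_canada"))
    assert round(d.d_beverage_kcal, 1) == -23.2
    assert round(d.d_snack_kcal, 1) == -13.6
    assert round(d.d_total_kcal, 1) == -36.8
    assert d.d_total_kcal == d.d_beverage_kcal + d.d_snack_kcal


def test_zero_intake_gives_zero_delta():
    record = {"person_id": 1, "beverage_kcal": 0.0, "snack_kcal": 0.0,
              "beverage_sodium_mg": 0.0, "snack_sodium_mg": 0.0}
    for sc in ls.builtin_scenarios():
        d = ls.scenario_delta(record, sc)
        assert d.d_total_kcal == 0.0 and d.d_sodium_mg == 0.0


def test_stratified_share_blend_hand_value():
    """100 kcal, share 0.5, fractions (-0.275, +0.108) -> -8.35 kcal/day."""
    sc = ls.Scenario(
        name="strat", mode="stratified", highin_frac=-0.275, not_highin_frac=0.108,
        thresholds=ILLUSTRATIVE_THRESHOLDS["chile_stage1"],
    )
    record = {"person_id": 0, "beverage_kcal": 100.0, "snack_kcal": 0.0}
    d = ls.scenario_delta(record, sc, highin_share=0.5)
    assert d.d_beverage_kcal == pytest.approx(-8.35)
    # share bounds enforced
    with pytest.raises(ValueError, match="highin_share"):
        effective_fractions(sc, highin_share=1.5)


@given(
    bev=st.floats(0, 3000),
    snack=st.floats(0, 3000),
    scale=st.floats(0.01, 100),
)
def test_deltas_homogeneous_of_degree_one(bev, snack, scale):
    sc = ls.get_scenario("main_canada")
    base = {"person_id": 0, "beverage_kcal": bev, "snack_kcal": snack,
            "beverage_sodium_mg": 0.2 * bev, "snack_sodium_mg": 1.5 * snack}
    scaled = {k: (v * scale if k != "person_id" else v) for k, v in base.items()}
    d1, d2 = ls.scenario_delta(base, sc), ls.scenario_delta(scaled, sc)
    assert d2.d_total_kcal == pytest.approx(scale * d1.d_total_kcal, rel=1e-9, abs=1e-9)
    assert d2.d_sodium_mg == pytest.approx(scale * d1.d_sodium_mg, rel=1e-9, abs=1e-9)
    # sign: all-negative fractions can only reduce intake
    assert d1.d_total_kcal <= 0 and d1.d_sodium_mg <= 0


def test_population_delta_identity(cohort_small):
    """Weighted mean of d_total equals the fraction-weighted intake means."""
    sc = ls.get_scenario("main_canada")
    d = ls.scenario_deltas(cohort_small, sc)
    lhs = weighted_mean(cohort_small, d["d_total_kcal"])
    rhs = sc.beverage_kcal_frac * weighted_mean(
        cohort_small, cohort_small["beverage_kcal"]
    ) + sc.snack_kcal_frac * weighted_mean(cohort_small, cohort_small["snack_kcal"])
    assert lhs == pytest.approx(rhs, rel=1e-9)
    np.testing.assert_array_equal(
        d["d_total_kcal"], d["d_beverage_kcal"] + d["d_snack_kcal"]
    )


# --- product classification ----------------------------------------------

_TH = NutrientThresholds(
    jurisdiction="test",
    per_100g={"energy_kcal": 275.0, "sugars_g": 10.0, "sodium_mg": 300.0},
    per_100ml={"energy_kcal": 70.0, "sugars_g": 5.0},
)


def test_profile_exactly_at_limits_carries_no_label():
    profile = {"energy_kcal": 275.0, "sugars_g": 10.0, "sodium_mg": 300.0}
    flags = ls.classify_product(profile, _TH, basis="solid")
    assert not flags["any_label"]


def test_single_exceedance_sets_nutrient_and_overall_flags():
    flags = ls.classify_product({"sodium_mg": 301.0, "sugars_g": 1.0}, _TH, basis="solid")
    assert flags["sodium_mg"] and flags["any_label"] and not flags["sugars_g"]
    # nutrient with no limit on this basis is never flagged
    flags = ls.classify_product({"sodium_mg": 9999.0}, _TH, basis="liquid")
    assert not flags["any_label"]


def test_basis_mismatch_raises():
    th = NutrientThresholds(jurisdiction="solids_only", per_100g={"sugars_g": 10.0})
    with pytest.raises(ValueError, match="unit-basis mismatch"):
        ls.classify_product({"sugars_g": 1.0}, th, basis="liquid")
    with pytest.raises(ValueError, match="negative amount"):
        ls.classify_product({"sugars_g": -1.0}, th, basis="solid")


@given(
    amounts=st.dictionaries(
        st.sampled_from(["energy_kcal", "sugars_g", "sodium_mg", "trans_fat_g"]),
        st.floats(0, 500),
        min_size=1,
    ),
    basis=st.sampled_from(["solid", "liquid"]),
)
def test_classification_matches_brute_force(amounts, basis):
    """Flags equal an exhaustive per-nutrient strict comparison."""
    flags = ls.classify_product(amounts, _TH, basis=basis)
    limits = _TH.per_100g if basis == "solid" else _TH.per_100ml
    expected = {n: (n in limits and a > limits[n]) for n, a in amounts.items()}
    assert {k: v for k, v in flags.items() if k != "any_label"} == expected
    assert flags["any_label"] == any(expected.values())


def test_thresholds_csv_round_trip(tmp_path):
    path = tmp_path / "limits.csv"
    path.write_text(
        "nutrient,basis,limit,unit\n"
        "sodium_mg,solid,300,mg/100g\n"
        "sugars_g,liquid,5,g/100mL\n"
    )
    th = ls.scenarios.load_thresholds_csv(path, jurisdiction="custom")
    assert th.per_100g == {"sodium_mg": 300.0}
    assert th.per_100ml == {"sugars_g": 5.0}
    with pytest.raises(ValueError, match="missing column"):
        bad = tmp_path / "bad.csv"
        bad.write_text("nutrient,limit\nsodium_mg,300\n")
        ls.scenarios.load_thresholds_csv(bad, jurisdiction="x")
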