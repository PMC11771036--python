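"""Footprint engine: conservation, linearity and normalization conventions."""
import numpy as np
import pandas as pd
import pytest

from dietprint import (
    DailyIntake,
    PersonFootprint,
    ValidationError,
    aggregate_groups,
    annualize,
    cohort_reference_kcal,
    percent_contributions,
    per_kcal_normalize,
    person_footprint,
)
from dietprint.engine import (
    FOOTPRINT_COLUMNS,
    category_totals,
    cohort_totals,
    contributions_table,
    person_footprints,
)
from dietprint._util import round_half_up


def naive_cohort_totals(intake_df, catalogue, coefficients):
    """Independent per-record loop oracle for cohort footprint sums."""
    totals = {"energy_kcal": 0.0, "water_l": 0.0, "ghge_kg": 0.0, "nitrogen_g": 0.0}
    for row in intake_df.itertuples(index=False):
        item = catalogue.get(row.item_id)
        coef = coefficients.get(row.item_id)
        totals["energy_kcal"] += row.grams_per_day / 100.0 * item.energy_kcal_per_100g
        totals["water_l"] += row.grams_per_day / 1000.0 * coef.water_l_per_kg
        totals["ghge_kg"] += row.grams_per_day / 1000.0 * coef.ghge_kgco2eq_per_kg
        totals["nitrogen_g"] += (
            row.grams_per_day / 100.0 * item.protein_g_per_100g / item.nitrogen_factor
        )
    return totals


def test_unit_intake_gives_unit_footprint(micro_catalogue):
    from dietprint import CoefficientTable, EfpCoefficients

    catalogue, _ = micro_catalogue
    coefs = CoefficientTable([EfpCoefficients("wheat", 1.0, 1.0)])
    pf = person_footprint([DailyIntake("p", "wheat", 1000.0)], catalogue, coefs)
    assert pf.water_l_per_day == pytest.approx(1.0)
    assert pf.ghge_kgco2eq_per_day == pytest.approx(1.0)


def test_empty_intake_is_zero_footprint(micro_catalogue):
    catalogue, coefs = micro_catalogue
    pf = person_footprint([], catalogue, coefs, participant_id="p")
    assert pf.water_l_per_day == pf.ghge_kgco2eq_per_day == pf.nitrogen_g_per_day == 0.0
    with pytest.raises(ValidationError):
        per_kcal_normalize(pf, 1000.0)


def test_missing_coefficient_error_names_item(micro_catalogue):
    from dietprint import CoefficientTable

    catalogue, _ = micro_catalogue
    with pytest.raises(KeyError, match="wheat"):
        person_footprint([DailyIntake("p", "wheat", 10.0)], catalogue, CoefficientTable([]))


def test_vectorized_engine_matches_loop_oracle(micro_catalogue):
    catalogue, coefs = micro_catalogue
    rng = np.random.default_rng(7)
    for _ in range(10):
        n_people = rng.integers(1, 21)
        rows = []
        for p in range(n_people):
            for item in ("wheat", "beefx", "oil"):
                if rng.random() < 0.8:
                    rows.append((f"p{p}", item, float(rng.gamma(2.0, 50.0))))
        intake = pd.DataFrame(rows, columns=["participant_id", "item_id", "grams_per_day"])
        contrib = contributions_table(intake, catalogue, coefs)
        pf = person_footprints(contrib)
        oracle = naive_cohort_totals(intake, catalogue, coefs)
        for col in ("energy_kcal", *FOOTPRINT_COLUMNS):
            assert pf[col].sum() == pytest.approx(oracle[col], rel=1e-9)


def test_linearity_under_intake_doubling(micro_catalogue):
    catalogue, coefs = micro_catalogue
    intake = pd.DataFrame(
        {"participant_id": ["p"] * 3, "item_id": ["wheat", "beefx", "oil"],
         "grams_per_day": [120.0, 45.0, 11.0]}
    )
    one = person_footprints(contributions_table(intake, catalogue, coefs)).iloc[0]
    doubled = intake.assign(grams_per_day=intake["grams_per_day"] * 2)
    two = person_footprints(contributions_table(doubled, catalogue, coefs)).iloc[0]
    for col in FOOTPRINT_COLUMNS:
        assert two[col] == pytest.approx(2 * one[col], rel=1e-12)
        assert two[f"{col}_per_1000kcal"] == pytest.approx(
            one[f"{col}_per_1000kcal"], rel=1e-12
        )


def test_group_category_total_conservation(packaged):
    from dietprint import GeneratorConfig, generate_cohort

    cohort = generate_cohort(GeneratorConfig(n=25, seed=3))
    catalogue, coefs = packaged
    contrib = contributions_table(cohort.daily_intake, catalogue, coefs)
    groups = aggregate_groups(contrib)
    cats = category_totals(groups)
    totals = cohort_totals(groups)
    pf = person_footprints(contrib)
    n = len(pf)
    for col in FOOTPRINT_COLUMNS:
        assert groups[col].sum() == pytest.approx(cats[col].sum(), rel=1e-12)
        assert totals[col] == pytest.approx(pf[col].sum() / n, rel=1e-9)


def test_per_kcal_normalization():
    pf = PersonFootprint("p", energy_kcal_per_day=2000.0, intake_g_per_day=0.0,
                         water_l_per_day=100.0, ghge_kgco2eq_per_day=4.0,
                         nitrogen_g_per_day=8.0)
    water, ghge, nitrogen = per_kcal_normalize(pf, 1000.0)
    assert ghge == pytest.approx(2.0)
    assert water == pytest.approx(50.0)
    with pytest.raises(ValidationError):
        per_kcal_normalize(pf, 0.0)


def test_cohort_per_kcal_is_mean_of_ratios(micro_catalogue):
    """Per-kcal cohort statistics average per-person ratios, and that differs
    from dividing the cohort-mean footprint by the cohort-mean energy."""
    catalogue, coefs = micro_catalogue
    intake = pd.DataFrame(
        {"participant_id": ["p1", "p2"], "item_id": ["wheat", "beefx"],
         "grams_per_day": [100.0, 400.0]}
    )
    pf = person_footprints(contributions_table(intake, catalogue, coefs))
    mean_ratio = pf["water_l_per_1000kcal"].mean()
    ratio_of_means = 1000.0 * pf["water_l"].mean() / pf["energy_kcal"].mean()
    assert mean_ratio != pytest.approx(ratio_of_means, rel=1e-3)
    scaled = cohort_reference_kcal({"water_l": mean_ratio}, 2500.0)
    assert scaled["water_l"] == pytest.approx(2.5 * mean_ratio, rel=1e-12)


def test_percent_contributions_sum_to_100_and_symmetry():
    groups = pd.DataFrame(
        {"group": ["a", "b", "c"], "efp_category": ["x", "y", "z"],
         "water_l": [5.0, 5.0, 5.0], "ghge_kg": [1.0, 1.0, 1.0],
         "nitrogen_g": [2.0, 2.0, 2.0]}
    )
    pct = percent_contributions(groups)
    for col in FOOTPRINT_COLUMNS:
        assert pct[f"{col}_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert (pct[f"{col}_pct_display"] == 33.33).all()


def test_single_group_contributes_everything():
    groups = pd.DataFrame(
        {"group": ["only"], "efp_category": ["x"], "water_l": [3.0],
         "ghge_kg": [1.0], "nitrogen_g": [0.5]}
    )
    pct = percent_contributions(groups)
    assert (pct[[f"{c}_pct" for c in FOOTPRINT_COLUMNS]].iloc[0] == 100.0).all()


def test_annualize():
    assert annualize(0.0) == 0.0
    assert annualize(10.0) == pytest.approx(3.65)
    with pytest.raises(ValidationError):
        annualize(-1.0)


def test_display_rounding_is_half_up():
    assert round_half_up(15.975, 2) == 15.98
    assert round_half_up(2.265, 2) == 2.27
    assert round_half_up(44.015, 2) == 44.02
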