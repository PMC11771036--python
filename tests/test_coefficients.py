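"""Recipe decomposition and nitrogen conversion."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietprint import (
    CoefficientTable,
    EfpCoefficients,
    FoodCatalogue,
    FoodItem,
    Recipe,
    ValidationError,
    nitrogen_content,
    resolve_catalogue,
    resolve_recipe,
)


def _catalogue(ids, protein=5.0, factor=6.25):
    items = [
        FoodItem(i, i, "g", "other", energy_kcal_per_100g=100.0,
                 protein_g_per_100g=protein, nitrogen_factor=factor)
        for i in ids
    ]
    items.append(
        FoodItem("dish", "dish", "g", "other", energy_kcal_per_100g=0.0,
                 protein_g_per_100g=0.0, is_composite=True)
    )
    return FoodCatalogue(items)


def test_equal_weight_recipe_is_mean():
    cat = _catalogue(["a", "b"])
    table = CoefficientTable([EfpCoefficients("a", 100.0, 1.0), EfpCoefficients("b", 300.0, 3.0)])
    recipe = Recipe("dish", (("a", 0.5), ("b", 0.5)))
    coef, _ = resolve_recipe(recipe, table, cat)
    assert coef.water_l_per_kg == pytest.approx(200.0)
    assert coef.source == "recipe-derived"


def test_single_ingredient_recipe_is_identity():
    cat = _catalogue(["a"])
    table = CoefficientTable([EfpCoefficients("a", 123.4, 5.6)])
    coef, item = resolve_recipe(Recipe("dish", (("a", 1.0),)), table, cat)
    assert coef.water_l_per_kg == pytest.approx(123.4)
    assert coef.ghge_kgco2eq_per_kg == pytest.approx(5.6)
    assert item.protein_g_per_100g == pytest.approx(5.0)


def test_three_ingredient_weighted_sum():
    cat = _catalogue(["a", "b", "c"])
    table = CoefficientTable(
        [EfpCoefficients("a", 0.0, 1.0), EfpCoefficients("b", 0.0, 2.0),
         EfpCoefficients("c", 0.0, 4.0)]
    )
    recipe = Recipe("dish", (("a", 0.5), ("b", 0.3), ("c", 0.2)))
    coef, _ = resolve_recipe(recipe, table, cat)
    assert coef.ghge_kgco2eq_per_kg == pytest.approx(1.9)


def test_recipe_invariant_under_ingredient_permutation():
    cat = _catalogue(["a", "b", "c"])
    table = CoefficientTable(
        [EfpCoefficients("a", 10.0, 1.0), EfpCoefficients("b", 20.0, 2.0),
         EfpCoefficients("c", 40.0, 4.0)]
    )
    fwd = Recipe("dish", (("a", 0.5), ("b", 0.3), ("c", 0.2)))
    rev = Recipe("dish", (("c", 0.2), ("a", 0.5), ("b", 0.3)))
    c1, i1 = resolve_recipe(fwd, table, cat)
    c2, i2 = resolve_recipe(rev, table, cat)
    assert c1.water_l_per_kg == pytest.approx(c2.water_l_per_kg)
    assert i1.nitrogen_factor == pytest.approx(i2.nitrogen_factor)


def test_recipe_validation_errors():
    with pytest.raises(ValidationError):
        Recipe("dish", (("a", 0.5), ("b", 0.4)))  # fractions sum to 0.9
    with pytest.raises(ValidationError):
        Recipe("dish", (("a", 1.5),))
    cat = _catalogue(["a"])
    table = CoefficientTable([])
    with pytest.raises(ValidationError, match="'a'"):
        resolve_recipe(Recipe("dish", (("a", 1.0),)), table, cat)


def test_cyclic_recipe_rejected():
    items = [
        FoodItem("d1", "d1", "g", "other", 0.0, 0.0, is_composite=True),
        FoodItem("d2", "d2", "g", "other", 0.0, 0.0, is_composite=True),
    ]
    cat = FoodCatalogue(items)
    recipes = {
        "d1": Recipe("d1", (("d2", 1.0),)),
        "d2": Recipe("d2", (("d1", 1.0),)),
    }
    with pytest.raises(ValidationError, match="cycl"):
        resolve_catalogue(cat, CoefficientTable([]), recipes)


def test_composite_nitrogen_is_additive_across_ingredients():
    """Composite N = sum of fraction_i * protein_i / factor_i exactly."""
    items = [
        FoodItem("a", "a", "g", "other", 100.0, 10.0, nitrogen_factor=5.0),
        FoodItem("b", "b", "g", "other", 100.0, 20.0, nitrogen_factor=7.0),
        FoodItem("dish", "dish", "g", "other", 0.0, 0.0, is_composite=True),
    ]
    cat = FoodCatalogue(items)
    table = CoefficientTable([EfpCoefficients("a", 1.0, 1.0), EfpCoefficients("b", 1.0, 1.0)])
    _, item = resolve_recipe(Recipe("dish", (("a", 0.4), ("b", 0.6))), table, cat)
    expected_n = 0.4 * 10.0 / 5.0 + 0.6 * 20.0 / 7.0
    assert item.protein_g_per_100g / item.nitrogen_factor == pytest.approx(expected_n, rel=1e-12)


def test_resolution_idempotent_on_resolved_items(packaged):
    catalogue, coefficients = packaged
    again_cat, again_coef = resolve_catalogue(catalogue, coefficients, {})
    assert again_coef.get("tabbouleh") == coefficients.get("tabbouleh")
    assert again_cat.get("tabbouleh") == catalogue.get("tabbouleh")


@pytest.mark.parametrize(
    "protein,factor,expected",
    [(6.25, 6.25, 1.0), (0.0, 6.25, 0.0), (23.55, 5.83, 4.0394511149228135)],
)
def test_nitrogen_content(protein, factor, expected):
    assert nitrogen_content(protein, factor) == pytest.approx(expected, rel=1e-9)


def test_nitrogen_content_rejects_bad_factor():
    with pytest.raises(ValidationError):
        nitrogen_content(10.0, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    protein=st.floats(min_value=0, max_value=1e3, allow_nan=False),
    k=st.floats(min_value=0, max_value=100, allow_nan=False),
    factor=st.floats(min_value=5.0, max_value=7.0),
)
def test_nitrogen_content_homogeneous(protein, k, factor):
    assert nitrogen_content(k * protein, factor) == pytest.approx(
        k * nitrogen_content(protein, factor), rel=1e-9, abs=1e-12
    )
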