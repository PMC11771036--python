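"""Environmental-intensity coefficients, nitrogen conversion and recipes.

Each food item carries a water intensity (L per kg fresh weight) and a
greenhouse-gas intensity (kg CO2-eq per kg).  Composite dishes have no
direct coefficients; they are resolved from a standardized recipe as the
mass-fraction-weighted sum of their ingredients' intensities.  The same
weighting applies to energy and protein; the composite's nitrogen factor is
chosen so that nitrogen stays exactly additive across ingredients
(protein_i / factor_i summed, never pooled protein over a pooled factor).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .data_model import (
    DEFAULT_NITROGEN_FACTOR,
    FoodCatalogue,
    FoodItem,
    ValidationError,
)

__all__ = [
    "EfpCoefficients",
    "CoefficientTable",
    "Recipe",
    "MAX_RECIPE_DEPTH",
    "FRACTION_TOL",
    "nitrogen_content",
    "resolve_recipe",
    "resolve_catalogue",
]

#: recipes may nest (a composite ingredient inside another composite) to this depth
MAX_RECIPE_DEPTH = 3

FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class EfpCoefficients:
    item_id: str
    water_l_per_kg: float
    ghge_kgco2eq_per_kg: float
    source: str = ""

    def __post_init__(self) -> None:
        for name in ("water_l_per_kg", "ghge_kgco2eq_per_kg"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValidationError(f"{self.item_id}: {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class Recipe:
    composite_item_id: str
    ingredients: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValidationError(f"{self.composite_item_id}: empty recipe")
        total = 0.0
        for ing, frac in self.ingredients:
            if not (0.0 < frac <= 1.0):
                raise ValidationError(
                    f"{self.composite_item_id}: mass fraction {frac} for {ing!r} outside (0, 1]"
                )
            total += frac
        if abs(total - 1.0) > FRACTION_TOL:
            raise ValidationError(
                f"{self.composite_item_id}: ingredient fractions sum to {total}, not 1"
            )


class CoefficientTable:
    """Per-item coefficient lookup."""

    def __init__(self, coefficients: Iterable[EfpCoefficients]):
        self._coef: dict[str, EfpCoefficients] = {}
        for c in coefficients:
            if c.item_id in self._coef:
                raise ValidationError(f"duplicate coefficient row for {c.item_id!r}")
            self._coef[c.item_id] = c

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._coef

    def __iter__(self):
        return iter(self._coef.values())

    def __len__(self) -> int:
        return len(self._coef)

    def get(self, item_id: str) -> EfpCoefficients:
        try:
            return self._coef[item_id]
        except KeyError:
            raise KeyError(f"no environmental coefficients for item {item_id!r}") from None

    def add(self, coef: EfpCoefficients) -> None:
        self._coef[coef.item_id] = coef

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self])

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        df = pd.read_csv(path, dtype={"item_id": str, "source": str})
        return cls(
            EfpCoefficients(
                item_id=r.item_id,
                water_l_per_kg=float(r.water_l_per_kg),
                ghge_kgco2eq_per_kg=float(r.ghge_kgco2eq_per_kg),
                source=r.source,
            )
            for r in df.itertuples(index=False)
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_recipes(path: str | Path) -> dict[str, Recipe]:
    """Read a long-format recipe CSV (composite_id, ingredient_id, mass_fraction)."""
    df = pd.read_csv(path, dtype={"composite_id": str, "ingredient_id": str})
    recipes = {}
    for cid, sub in df.groupby("composite_id", sort=True):
        recipes[cid] = Recipe(
            composite_item_id=cid,
            ingredients=tuple(
                (r.ingredient_id, float(r.mass_fraction)) for r in sub.itertuples(index=False)
            ),
        )
    return recipes


def nitrogen_content(protein_g: float, nitrogen_factor: float = DEFAULT_NITROGEN_FACTOR) -> float:
    """Nitrogen mass (g) of a protein mass, via the food's conversion factor.

    Protein is roughly a fixed multiple of its nitrogen content, so dividing
    protein by the (Jones) factor recovers nitrogen; 6.25 is the generic
    convention used when no food-specific factor is available.
    """
    if nitrogen_factor <= 0:
        raise ValidationError(f"nitrogen factor must be > 0, got {nitrogen_factor}")
    if protein_g < 0:
        raise ValidationError(f"protein mass must be >= 0, got {protein_g}")
    return protein_g / nitrogen_factor


def resolve_recipe(
    recipe: Recipe,
    table: CoefficientTable,
    catalogue: FoodCatalogue,
    recipes: dict[str, Recipe] | None = None,
    _depth: int = 0,
    _stack: tuple[str, ...] = (),
) -> tuple[EfpCoefficients, FoodItem]:
    """Resolve one composite dish to coefficients plus composition.

    Returns the recipe-derived coefficients and a copy of the catalogue item
    with energy, protein and nitrogen factor filled in from the weighted
    ingredients.  Nested composites resolve recursively up to
    ``MAX_RECIPE_DEPTH``; cycles are rejected.
    """
    cid = recipe.composite_item_id
    if cid in _stack:
        raise ValidationError(f"cyclic recipe involving {cid!r}")
    if _depth > MAX_RECIPE_DEPTH:
        raise ValidationError(f"recipe nesting deeper than {MAX_RECIPE_DEPTH} at {cid!r}")

    water = ghge = energy = protein = nitrogen_per_100g = 0.0
    for ing_id, frac in recipe.ingredients:
        try:
            ing_item = catalogue.get(ing_id)
        except KeyError:
            raise ValidationError(f"{cid}: ingredient {ing_id!r} not in catalogue") from None
        if ing_item.is_composite and ing_id not in table:
            if not recipes or ing_id not in recipes:
                raise ValidationError(f"{cid}: no recipe or coefficients for composite {ing_id!r}")
            ing_coef, ing_item = resolve_recipe(
                recipes[ing_id], table, catalogue, recipes, _depth + 1, _stack + (cid,)
            )
        else:
            try:
                ing_coef = table.get(ing_id)
            except KeyError:
                raise ValidationError(
                    f"{cid}: missing environmental coefficients for ingredient {ing_id!r}"
                ) from None
        water += frac * ing_coef.water_l_per_kg
        ghge += frac * ing_coef.ghge_kgco2eq_per_kg
        energy += frac * ing_item.energy_kcal_per_100g
        protein += frac * ing_item.protein_g_per_100g
        nitrogen_per_100g += frac * ing_item.protein_g_per_100g / ing_item.nitrogen_factor

    composite = catalogue.get(cid)
    factor = protein / nitrogen_per_100g if nitrogen_per_100g > 0 else DEFAULT_NITROGEN_FACTOR
    resolved_item = FoodItem(
        item_id=composite.item_id,
        name=composite.name,
        group=composite.group,
        efp_category=composite.efp_category,
        pyramid_group=composite.pyramid_group,
        intake_group=composite.intake_group,
        energy_kcal_per_100g=energy,
        protein_g_per_100g=protein,
        nitrogen_factor=factor,
        is_beverage=composite.is_beverage,
        is_composite=True,
        density_g_per_ml=composite.density_g_per_ml,
    )
    coef = EfpCoefficients(cid, water, ghge, source="recipe-derived")
    return coef, resolved_item


def resolve_catalogue(
    catalogue: FoodCatalogue,
    table: CoefficientTable,
    recipes: dict[str, Recipe],
) -> tuple[FoodCatalogue, CoefficientTable]:
    """Resolve every composite in the catalogue; idempotent on resolved items.

    After resolution every item has exactly one coefficient row.
    """
    new_table = CoefficientTable(list(table))
    new_cat = catalogue
    for item in catalogue:
        if not item.is_composite or item.item_id in new_table:
            continue
        if item.item_id not in recipes:
            raise ValidationError(
                f"composite item {item.item_id!r} has neither coefficients nor a recipe"
            )
        coef, resolved = resolve_recipe(recipes[item.item_id], table, catalogue, recipes)
        new_table.add(coef)
        new_cat = new_cat.replace_item(resolved)
    missing = [it.item_id for it in new_cat if it.item_id not in new_table]
    if missing:
        raise ValidationError(f"items without environmental coefficients: {missing}")
    return new_cat, new_table
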