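"""Core footprint computation.

Per item and day, footprints follow from intake mass and per-kg intensity:

    water  (L/d)        = mass (kg/d) * water intensity (L/kg)
    GHGE   (kg CO2-eq/d)= mass (kg/d) * GHG intensity (kg CO2-eq/kg)
    nitrogen (g/d)      = protein consumed (g/d) / nitrogen factor
    energy (kcal/d)     = mass (g/d) / 100 * energy density (kcal/100 g)

Everything else is bookkeeping: per-person sums, energy normalization,
food-group aggregation and percent contributions.  Cohort per-1000-kcal
statistics are means of per-person ratios, not ratios of cohort means --
the two differ whenever energy varies between people, and the published
convention is the former.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._util import round_half_up
from .coefficients import CoefficientTable, nitrogen_content
from .data_model import DailyIntake, FoodCatalogue, ValidationError

__all__ = [
    "PersonFootprint",
    "GroupFootprint",
    "FOOTPRINT_COLUMNS",
    "contributions_table",
    "person_footprint",
    "person_footprints",
    "per_kcal_normalize",
    "cohort_reference_kcal",
    "aggregate_groups",
    "category_totals",
    "cohort_totals",
    "percent_contributions",
    "annualize",
]

FOOTPRINT_COLUMNS = ["water_l", "ghge_kg", "nitrogen_g"]
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class PersonFootprint:
    """One participant's daily energy, intake mass and footprints."""

    participant_id: str
    energy_kcal_per_day: float
    intake_g_per_day: float
    water_l_per_day: float
    ghge_kgco2eq_per_day: float
    nitrogen_g_per_day: float

    def per_1000_kcal(self) -> tuple[float, float, float]:
        return per_kcal_normalize(self, 1000.0)


@dataclass(frozen=True)
class GroupFootprint:
    """Cohort-mean per-capita footprints of one food group."""

    group: str
    efp_category: str
    water_l: float
    ghge_kg: float
    nitrogen_g: float


def contributions_table(
    intake: pd.DataFrame, catalogue: FoodCatalogue, coefficients: CoefficientTable
) -> pd.DataFrame:
    """Item-level footprint contributions, one row per intake row.

    ``intake`` is the canonical daily-intake ledger (participant_id,
    item_id, grams_per_day).  Raises if any item lacks composition or
    coefficients.
    """
    if intake.empty:
        return pd.DataFrame(
            columns=[
                "participant_id", "item_id", "group", "efp_category",
                "grams_per_day", "energy_kcal", "water_l", "ghge_kg", "nitrogen_g",
            ]
        )
    if (intake["grams_per_day"] < 0).any():
        bad = intake.loc[intake["grams_per_day"] < 0].iloc[0]
        raise ValidationError(
            f"negative intake for participant {bad['participant_id']!r} item {bad['item_id']!r}"
        )
    cat = catalogue.to_frame()
    coef = coefficients.to_frame()
    missing = set(intake["item_id"]) - set(cat["item_id"])
    if missing:
        raise ValidationError(f"intake references unknown items: {sorted(missing)}")
    missing = set(intake["item_id"]) - set(coef["item_id"])
    if missing:
        raise ValidationError(f"no environmental coefficients for items: {sorted(missing)}")

    df = intake.merge(
        cat[["item_id", "group", "efp_category", "energy_kcal_per_100g",
             "protein_g_per_100g", "nitrogen_factor"]],
        on="item_id",
    ).merge(coef[["item_id", "water_l_per_kg", "ghge_kgco2eq_per_kg"]], on="item_id")

    kg = df["grams_per_day"] / 1000.0
    df["energy_kcal"] = df["grams_per_day"] / 100.0 * df["energy_kcal_per_100g"]
    df["water_l"] = kg * df["water_l_per_kg"]
    df["ghge_kg"] = kg * df["ghge_kgco2eq_per_kg"]
    protein = df["grams_per_day"] / 100.0 * df["protein_g_per_100g"]
    df["nitrogen_g"] = protein / df["nitrogen_factor"]
    return df[
        ["participant_id", "item_id", "group", "efp_category",
         "grams_per_day", "energy_kcal", "water_l", "ghge_kg", "nitrogen_g"]
    ]


def person_footprint(
    intakes: Iterable[DailyIntake],
    catalogue: FoodCatalogue,
    coefficients: CoefficientTable,
    participant_id: str | None = None,
) -> PersonFootprint:
    """Sum one participant's item contributions (scalar reference path)."""
    energy = mass = water = ghge = nitrogen = 0.0
    pid = participant_id
    for intake in intakes:
        if pid is None:
            pid = intake.participant_id
        item = catalogue.get(intake.item_id)
        coef = coefficients.get(intake.item_id)
        if intake.grams_per_day < 0:
            raise ValidationError(f"negative intake of {intake.item_id!r}")
        kg = intake.grams_per_day / 1000.0
        mass += intake.grams_per_day
        energy += intake.grams_per_day / 100.0 * item.energy_kcal_per_100g
        water += kg * coef.water_l_per_kg
        ghge += kg * coef.ghge_kgco2eq_per_kg
        nitrogen += nitrogen_content(
            intake.grams_per_day / 100.0 * item.protein_g_per_100g, item.nitrogen_factor
        )
    return PersonFootprint(pid or "", energy, mass, water, ghge, nitrogen)


def person_footprints(contributions: pd.DataFrame) -> pd.DataFrame:
    """Per-participant ledger with absolute and per-1000-kcal footprints.

    Per-kcal columns are NaN for participants with zero recorded energy;
    such participants stay in the absolute summaries.
    """
    agg = contributions.groupby("participant_id", sort=True).agg(
        energy_kcal=("energy_kcal", "sum"),
        intake_g=("grams_per_day", "sum"),
        water_l=("water_l", "sum"),
        ghge_kg=("ghge_kg", "sum"),
        nitrogen_g=("nitrogen_g", "sum"),
    )
    scale = 1000.0 / agg["energy_kcal"].where(agg["energy_kcal"] > 0)
    for col in FOOTPRINT_COLUMNS:
        agg[f"{col}_per_1000kcal"] = agg[col] * scale
    return agg.reset_index()


def per_kcal_normalize(pf: PersonFootprint, reference_kcal: float) -> tuple[float, float, float]:
    """Scale one participant's footprints to a reference energy intake."""
    if reference_kcal <= 0:
        raise ValidationError(f"reference energy must be > 0, got {reference_kcal}")
    if pf.energy_kcal_per_day <= 0:
        raise ValidationError(
            f"participant {pf.participant_id!r} has zero recorded energy; "
            "per-kcal footprints are undefined"
        )
    s = reference_kcal / pf.energy_kcal_per_day
    return (pf.water_l_per_day * s, pf.ghge_kgco2eq_per_day * s, pf.nitrogen_g_per_day * s)


def cohort_reference_kcal(
    per_1000kcal_means: Mapping[str, float], reference_kcal: float
) -> dict[str, float]:
    """Cohort footprints at a reference energy from per-1000-kcal means.

    The cohort statistic at, say, 2500 kcal is defined as the cohort mean of
    the per-person per-1000-kcal ratios scaled by 2.5.
    """
    if reference_kcal <= 0:
        raise ValidationError(f"reference energy must be > 0, got {reference_kcal}")
    s = reference_kcal / 1000.0
    return {k: v * s for k, v in per_1000kcal_means.items()}


def aggregate_groups(contributions: pd.DataFrame, n_participants: int | None = None) -> pd.DataFrame:
    """Cohort-mean per-capita footprints by food group.

    The denominator is the cohort size: a participant consuming nothing from
    a group contributes zero to that group's mean.
    """
    if n_participants is None:
        n_participants = contributions["participant_id"].nunique()
    if n_participants <= 0:
        raise ValidationError("cannot aggregate an empty cohort")
    unmapped = contributions["group"].isna() | (contributions["group"] == "")
    if unmapped.any():
        bad = contributions.loc[unmapped, "item_id"].unique()
        raise ValidationError(f"items without a food group: {sorted(bad)}")
    g = (
        contributions.groupby(["group", "efp_category"], sort=True)[FOOTPRINT_COLUMNS]
        .sum()
        .div(n_participants)
        .reset_index()
    )
    return g


def category_totals(group_footprints: pd.DataFrame) -> pd.DataFrame:
    """Sum group means into the animal / vegetable / other category rows."""
    return (
        group_footprints.groupby("efp_category", sort=True)[FOOTPRINT_COLUMNS].sum().reset_index()
    )


def cohort_totals(group_footprints: pd.DataFrame) -> dict[str, float]:
    return {c: float(group_footprints[c].sum()) for c in FOOTPRINT_COLUMNS}


def percent_contributions(
    group_footprints: pd.DataFrame, by: str = "group"
) -> pd.DataFrame:
    """Percent contribution of each group (or category) to each footprint.

    Unrounded percentages are kept; ``*_pct_display`` columns carry the
    half-up 2-decimal values used in reports.  Columns sum to 100 exactly
    before display rounding.
    """
    totals = cohort_totals(group_footprints)
    rows = group_footprints if by == "group" else category_totals(group_footprints)
    cols = [by] + (["efp_category"] if by != "efp_category" else [])
    out = rows[[c for c in cols if c in rows.columns]].copy()
    for col in FOOTPRINT_COLUMNS:
        total = totals[col]
        if total <= 0:
            if (rows[col] > 0).any():
                raise AssertionError(f"zero total with nonzero group for {col}")
            out[f"{col}_pct"] = 0.0
        else:
            out[f"{col}_pct"] = rows[col] / total * 100.0
        out[f"{col}_pct_display"] = out[f"{col}_pct"].map(lambda x: round_half_up(x, 2))
    return out


def annualize(daily_g: float) -> float:
    """Convert a daily flow in g/d to kg/year (365-day year)."""
    if daily_g < 0:
        raise ValidationError(f"daily value must be >= 0, got {daily_g}")
    return daily_g * DAYS_PER_YEAR / 1000.0
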