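"""Model/results interface over the footprint engine.

``DietaryFootprintModel`` is built from a daily-intake ledger plus the item
catalogue and coefficient table (composites are resolved on construction);
``fit()`` evaluates the footprint accounting for the whole cohort and
returns a ``DietaryFootprintResults`` carrying the per-person ledger, group
aggregates, percent contributions, and benchmark methods, with a
``summary()`` table in the style of the survey's footprint tables.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from . import engine, presets
from ._util import round_half_up
from .benchmarks import (
    EnvironmentalLimit,
    PyramidSpec,
    boundary_ratios,
    pyramid_deviation,
)
from .coefficients import CoefficientTable, Recipe, resolve_catalogue
from .data_model import FoodCatalogue, Participant, ValidationError, normalize_records

__all__ = ["DietaryFootprintModel", "DietaryFootprintResults"]


class DietaryFootprintModel:
    """Dietary environmental-footprint accounting for a cohort.

    Parameters
    ----------
    daily_intake
        Canonical intake ledger with columns participant_id, item_id,
        grams_per_day.
    catalogue, coefficients
        Item composition and environmental intensities.
    recipes
        Composite-dish recipes, resolved at construction so that every item
        has exactly one coefficient row.
    participants
        Optional demographics used by downstream cohort summaries.
    """

    def __init__(
        self,
        daily_intake: pd.DataFrame,
        catalogue: FoodCatalogue,
        coefficients: CoefficientTable,
        recipes: Mapping[str, Recipe] | None = None,
        participants: Iterable[Participant] | None = None,
    ):
        self.catalogue, self.coefficients = resolve_catalogue(
            catalogue, coefficients, dict(recipes or {})
        )
        required = {"participant_id", "item_id", "grams_per_day"}
        missing = required - set(daily_intake.columns)
        if missing:
            raise ValidationError(f"daily intake table missing columns: {sorted(missing)}")
        self.daily_intake = daily_intake.reset_index(drop=True)
        self.participants = list(participants) if participants is not None else None

    @classmethod
    def from_consumption(
        cls,
        records,
        catalogue: FoodCatalogue,
        coefficients: CoefficientTable,
        recipes: Mapping[str, Recipe] | None = None,
        participants: Iterable[Participant] | None = None,
    ) -> "DietaryFootprintModel":
        """Build from raw consumption records, normalizing frequencies first."""
        intake = normalize_records(records, catalogue)
        return cls(intake, catalogue, coefficients, recipes, participants)

    def fit(self) -> "DietaryFootprintResults":
        contrib = engine.contributions_table(
            self.daily_intake, self.catalogue, self.coefficients
        )
        return DietaryFootprintResults(self, contrib)


class DietaryFootprintResults:
    """Fitted cohort footprints with summaries and benchmark comparisons."""

    def __init__(self, model: DietaryFootprintModel, contributions: pd.DataFrame):
        self.model = model
        self.contributions = contributions
        self.person_footprints = engine.person_footprints(contributions)
        self.n = len(self.person_footprints)
        self.group_footprints = engine.aggregate_groups(contributions, self.n)
        self.category_footprints = engine.category_totals(self.group_footprints)
        self.totals = engine.cohort_totals(self.group_footprints)
        self.percent_by_group = engine.percent_contributions(self.group_footprints, by="group")
        self.percent_by_category = engine.percent_contributions(
            self.group_footprints, by="efp_category"
        )

    # -- cohort statistics -------------------------------------------------
    def footprint_means(self) -> pd.DataFrame:
        """Mean +/- sample SD of the absolute and per-1000-kcal footprints."""
        pf = self.person_footprints
        rows = []
        for col in ["energy_kcal", "water_l", "ghge_kg", "nitrogen_g",
                    "water_l_per_1000kcal", "ghge_kg_per_1000kcal",
                    "nitrogen_g_per_1000kcal"]:
            s = pf[col].dropna()
            rows.append({"quantity": col, "n": int(s.size), "mean": float(s.mean()),
                         "sd": float(s.std(ddof=1)) if s.size > 1 else 0.0})
        return pd.DataFrame(rows)

    def per_reference_kcal(self, reference_kcal: float) -> dict[str, float]:
        """Cohort footprints at a reference energy (mean of per-person ratios)."""
        pf = self.person_footprints
        per1000 = {
            col: float(pf[f"{col}_per_1000kcal"].dropna().mean())
            for col in engine.FOOTPRINT_COLUMNS
        }
        return engine.cohort_reference_kcal(per1000, reference_kcal)

    # -- benchmarks --------------------------------------------------------
    def boundary_ratios(
        self, limits: Mapping[str, EnvironmentalLimit] | None = None
    ) -> pd.DataFrame:
        return boundary_ratios(self.totals, limits or presets.default_limits())

    def pyramid_mean_intakes(self) -> pd.Series:
        """Cohort-mean intake (g/d) per Double-Pyramid group."""
        cat = self.model.catalogue.to_frame()
        df = self.model.daily_intake.merge(cat[["item_id", "pyramid_group"]], on="item_id")
        df = df[df["pyramid_group"] != ""]
        return df.groupby("pyramid_group")["grams_per_day"].sum() / self.n

    def pyramid_deviation(self, spec: PyramidSpec | None = None) -> pd.DataFrame:
        return pyramid_deviation(
            self.pyramid_mean_intakes().to_dict(), spec or presets.default_pyramid()
        )

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of cohort footprints and group contributions."""
        lines = [
            "Dietary environmental footprints",
            "=" * 64,
            f"participants: {self.n}",
            "",
            f"{'quantity':<28}{'mean':>12}{'sd':>12}",
            "-" * 52,
        ]
        for row in self.footprint_means().itertuples(index=False):
            lines.append(f"{row.quantity:<28}{row.mean:>12.2f}{row.sd:>12.2f}")
        lines += ["", f"{'category':<16}{'GHGE kg':>10}{'N g':>10}{'water L':>12}",
                  "-" * 48]
        for row in self.category_footprints.itertuples(index=False):
            lines.append(
                f"{row.efp_category:<16}{round_half_up(row.ghge_kg, 2):>10}"
                f"{round_half_up(row.nitrogen_g, 2):>10}"
                f"{round_half_up(row.water_l, 2):>12}"
            )
        totals = self.totals
        lines.append(
            f"{'total':<16}{round_half_up(totals['ghge_kg'], 2):>10}"
            f"{round_half_up(totals['nitrogen_g'], 2):>10}"
            f"{round_half_up(totals['water_l'], 2):>12}"
        )
        return "\n".join(lines)
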