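"""Packaged default datasets.

The package ships a self-contained fixture bundle: a ~45-item food
catalogue spanning every footprint group (including a composite dish, a
zero-protein oil and beverages reported in ml), the matching environmental
coefficients, the recipe table, per-capita environmental limits, the
Double-Pyramid tier spec, and the cohort calibration tables (group intake
distributions, demographic level probabilities, anthropometrics) that drive
the synthetic cohort generator.

The water/GHGE intensities are *effective* per-group values back-derived so
that expected group footprints are internally consistent with the
configured intake means; they are order-of-magnitude realistic but are not
literal commodity life-cycle values.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .benchmarks import EnvironmentalLimit, PyramidSpec, load_limits, load_pyramid
from .coefficients import CoefficientTable, Recipe, read_recipes, resolve_catalogue
from .data_model import FoodCatalogue

__all__ = [
    "data_path",
    "default_catalogue",
    "default_coefficients",
    "default_recipes",
    "default_resolved",
    "default_limits",
    "default_pyramid",
    "intake_distributions",
    "demographics",
    "anthropometrics",
]


def data_path(name: str) -> Path:
    return Path(resources.files("dietprint").joinpath("data", name))


def default_catalogue() -> FoodCatalogue:
    return FoodCatalogue.from_csv(data_path("food_catalogue.csv"))


def default_coefficients() -> CoefficientTable:
    return CoefficientTable.from_csv(data_path("efp_coefficients.csv"))


def default_recipes() -> dict[str, Recipe]:
    return read_recipes(data_path("recipes.csv"))


def default_resolved() -> tuple[FoodCatalogue, CoefficientTable]:
    """Catalogue and coefficients with all composite dishes resolved."""
    return resolve_catalogue(default_catalogue(), default_coefficients(), default_recipes())


def default_limits() -> dict[str, EnvironmentalLimit]:
    return load_limits(data_path("limits.yaml"))


def default_pyramid() -> PyramidSpec:
    return load_pyramid(data_path("pyramid.yaml"))


def intake_distributions() -> pd.DataFrame:
    return pd.read_csv(data_path("intake_distributions.csv"))


def demographics() -> dict:
    return yaml.safe_load(data_path("demographics.yaml").read_text(encoding="utf-8"))


def anthropometrics() -> dict:
    return yaml.safe_load(data_path("anthropometrics.yaml").read_text(encoding="utf-8"))
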