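import pytest

from dietprint import (
    CoefficientTable,
    EfpCoefficients,
    FoodCatalogue,
    FoodItem,
)
from dietprint import presets


@pytest.fixture(scope="session")
def packaged():
    """Packaged fixture catalogue and coefficients with composites resolved."""
    catalogue, coefficients = presets.default_resolved()
    return catalogue, coefficients


@pytest.fixture()
def micro_catalogue():
    """Three-item hand-built catalogue for scalar examples."""
    items = [
        FoodItem("wheat", "Wheat bread", "grains", "vegetable",
                 energy_kcal_per_100g=270.0, protein_g_per_100g=9.0,
                 nitrogen_factor=5.83),
        FoodItem("beefx", "Beef", "meat", "animal",
                 energy_kcal_per_100g=250.0, protein_g_per_100g=26.0),
        FoodItem("oil", "Olive oil", "oils", "vegetable",
                 energy_kcal_per_100g=884.0, protein_g_per_100g=0.0),
    ]
    coefs = CoefficientTable([
        EfpCoefficients("wheat", 1600.0, 1.4),
        EfpCoefficients("beefx", 15000.0, 27.0),
        EfpCoefficients("oil", 14400.0, 5.4),
    ])
    return FoodCatalogue(items), coefs
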