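"""Synthetic cohort generator.

Emulates the survey's statistical structure so the whole pipeline runs with
no external data: per-food-group daily intakes are drawn from log-normal
marginals moment-matched to the configured group means and SDs (intakes are
non-negative and right-skewed, and several configured SDs are near or above
their means, which rules out normal marginals), then split across the
group's catalogue items with symmetric Dirichlet weights.  A configurable
fraction of records is re-expressed in weekly (x7) or monthly (x30) units
to exercise frequency normalization.  Demographics are sampled from
configured level probabilities and anthropometrics from per-gender normals.

Groups are independent by default (no covariance information is available
for the intake distributions); a correlation knob shares a person-level
Gaussian factor across groups, which couples total intake mass and energy.

Everything is driven by one integer seed: the same seed reproduces the
generated bundle byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .coefficients import CoefficientTable, Recipe
from .data_model import (
    ConsumptionRecord,
    FoodCatalogue,
    FREQUENCY_DIVISORS,
    Participant,
    ValidationError,
    normalize_frequency,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "lognormal_params",
    "generate_cohort",
    "write_bundle",
    "parameter_recovery_check",
]


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) whose arithmetic mean and SD match exactly.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2.
    """
    if mean < 0 or sd < 0:
        raise ValidationError("mean and sd must be >= 0")
    if mean == 0:
        if sd > 0:
            raise ValidationError("cannot match sd > 0 with zero mean")
        return -math.inf, 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the survey's published calibration: 444 adults,
    group intake means/SDs, demographic level probabilities and per-gender
    anthropometrics, over the packaged fixture catalogue.
    """

    n: int = 444
    seed: int = 0
    intake: pd.DataFrame = field(default_factory=presets.intake_distributions)
    demographics: dict = field(default_factory=presets.demographics)
    anthropometrics: dict = field(default_factory=presets.anthropometrics)
    #: probability that a record is reported in each frequency unit
    frequency_mix: dict = field(
        default_factory=lambda: {"daily": 0.5, "weekly": 0.3, "monthly": 0.2}
    )
    dirichlet_alpha: float = 2.0
    #: shared person-level factor coupling the group intakes (0 = independent)
    intake_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        if not (0.0 <= self.intake_correlation < 1.0):
            raise ValidationError("intake correlation must be in [0, 1)")
        if abs(sum(self.frequency_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("frequency mix probabilities must sum to 1")
        unknown = set(self.frequency_mix) - set(FREQUENCY_DIVISORS)
        if unknown:
            raise ValidationError(f"unknown frequency units in mix: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    participants: list[Participant]
    consumption: pd.DataFrame          # participant_id, item_id, amount, frequency_unit
    daily_intake: pd.DataFrame         # ground-truth g/d (equals normalized consumption)
    catalogue: FoodCatalogue
    coefficients: CoefficientTable
    recipes: dict[str, Recipe]
    config: GeneratorConfig


def _sample_categorical(rng: np.random.Generator, levels: dict, size: int) -> np.ndarray:
    names = list(levels)
    p = np.asarray([levels[k] for k in names], dtype=float)
    p = p / p.sum()
    return rng.choice(names, size=size, p=p)


def _sample_participants(config: GeneratorConfig, rng: np.random.Generator) -> list[Participant]:
    demo, anthro = config.demographics, config.anthropometrics
    n = config.n
    gender = _sample_categorical(rng, demo["gender"], n)
    bands = demo["age_bands"]
    band_idx = rng.choice(len(bands), size=n, p=np.asarray([b["p"] for b in bands]))
    age = np.array(
        [rng.integers(bands[i]["low"], bands[i]["high"] + 1) for i in band_idx]
    )
    governorate = _sample_categorical(rng, demo["governorate"], n)
    marital = _sample_categorical(rng, demo["marital_status"], n)
    education = _sample_categorical(rng, demo["education"], n)
    employment = _sample_categorical(rng, demo["employment"], n)
    income = _sample_categorical(rng, demo["income_band"], n)
    household = _sample_categorical(rng, demo["household_size"], n).astype(int)
    rooms = _sample_categorical(rng, demo["n_rooms"], n).astype(int)

    out = []
    for i in range(n):
        a = anthro[gender[i]]
        weight = max(35.0, rng.normal(a["weight_kg"]["mean"], a["weight_kg"]["sd"]))
        height = max(130.0, rng.normal(a["height_cm"]["mean"], a["height_cm"]["sd"]))
        out.append(
            Participant(
                participant_id=f"P{i + 1:04d}",
                gender=str(gender[i]),
                age_years=int(age[i]),
                governorate=str(governorate[i]),
                weight_kg=round(float(weight), 1),
                height_cm=round(float(height), 1),
                household_size=int(household[i]),
                n_rooms=int(rooms[i]),
                employment=str(employment[i]),
                marital_status=str(marital[i]),
                income_band=str(income[i]),
                education=str(education[i]),
            )
        )
    return out


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate participants, consumption records and the fixture tables."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    catalogue = presets.default_catalogue()
    coefficients = presets.default_coefficients()
    recipes = presets.default_recipes()

    items_by_group: dict[str, list] = {}
    for item in catalogue:
        items_by_group.setdefault(item.intake_group, []).append(item)

    participants = _sample_participants(config, rng)

    units = list(config.frequency_mix)
    unit_p = np.asarray([config.frequency_mix[u] for u in units])
    rho = config.intake_correlation
    n = config.n

    groups = list(config.intake.itertuples(index=False))
    z_shared = rng.standard_normal(n)

    rows = []
    for g in groups:
        if g.intake_group not in items_by_group:
            raise ValidationError(f"no catalogue items for intake group {g.intake_group!r}")
        items = items_by_group[g.intake_group]
        k = len(items)
        mu, sigma = lognormal_params(float(g.mean_per_day), float(g.sd_per_day))
        if sigma == 0.0:
            totals = np.full(n, float(g.mean_per_day))
        else:
            z = math.sqrt(rho) * z_shared + math.sqrt(1.0 - rho) * rng.standard_normal(n)
            totals = np.exp(mu + sigma * z)
        weights = (
            rng.dirichlet(np.full(k, config.dirichlet_alpha), size=n)
            if k > 1
            else np.ones((n, 1))
        )
        unit_draws = rng.choice(units, size=(n, k), p=unit_p)
        for j, item in enumerate(items):
            grams = totals * weights[:, j]
            # beverages are reported in ml: convert mass back through density
            reported = grams / item.density_g_per_ml if item.is_beverage else grams
            for i in range(n):
                unit = str(unit_draws[i, j])
                amount = reported[i] * FREQUENCY_DIVISORS[unit]
                rows.append((participants[i].participant_id, item.item_id, amount, unit))

    consumption = pd.DataFrame(
        rows, columns=["participant_id", "item_id", "amount", "frequency_unit"]
    ).sort_values(["participant_id", "item_id"], kind="stable", ignore_index=True)

    # ground truth is defined as the normalized consumption, so frequency
    # re-expression round-trips exactly by construction
    daily_rows = [
        normalize_frequency(
            ConsumptionRecord(r.participant_id, r.item_id, r.amount, r.frequency_unit),
            catalogue.get(r.item_id),
        )
        for r in consumption.itertuples(index=False)
    ]
    daily_intake = pd.DataFrame(
        [(d.participant_id, d.item_id, d.grams_per_day) for d in daily_rows],
        columns=["participant_id", "item_id", "grams_per_day"],
    )
    return SyntheticCohort(
        participants, consumption, daily_intake, catalogue, coefficients, recipes, config
    )


def write_bundle(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write the four CSVs plus a manifest with config echo and checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "consumption": outdir / "consumption.csv",
        "participants": outdir / "participants.csv",
        "food_catalogue": outdir / "food_catalogue.csv",
        "efp_coefficients": outdir / "efp_coefficients.csv",
        "recipes": outdir / "recipes.csv",
    }
    cohort.consumption.to_csv(paths["consumption"], index=False)
    pd.DataFrame([vars(p) for p in cohort.participants]).to_csv(
        paths["participants"], index=False
    )
    cohort.catalogue.to_csv(paths["food_catalogue"])
    cohort.coefficients.to_csv(paths["efp_coefficients"])
    pd.DataFrame(
        [
            (r.composite_item_id, ing, frac)
            for r in cohort.recipes.values()
            for ing, frac in r.ingredients
        ],
        columns=["composite_id", "ingredient_id", "mass_fraction"],
    ).to_csv(paths["recipes"], index=False)

    manifest = {
        "seed": cohort.config.seed,
        "n": cohort.config.n,
        "frequency_mix": cohort.config.frequency_mix,
        "dirichlet_alpha": cohort.config.dirichlet_alpha,
        "intake_correlation": cohort.config.intake_correlation,
        "files": {
            k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def parameter_recovery_check(
    config: GeneratorConfig,
    daily_intake: pd.DataFrame,
    person_footprints: pd.DataFrame,
    catalogue: FoodCatalogue,
    coefficients: CoefficientTable,
    z_crit: float = 3.0,
) -> pd.DataFrame:
    """Compare pipeline outputs with the config-implied ground truth.

    Group intake means are checked against the configured means and cohort
    footprint totals against the coefficient-weighted expectation (expected
    item intake = group mean / number of items in the group, by symmetric
    Dirichlet splitting).  A deviation beyond ``z_crit`` standard errors of
    the sample mean is flagged; the report is always produced.
    """
    cat = catalogue.to_frame()
    intake = daily_intake.merge(cat[["item_id", "intake_group"]], on="item_id")
    n = intake["participant_id"].nunique()
    per_person = (
        intake.groupby(["participant_id", "intake_group"])["grams_per_day"]
        .sum()
        .unstack(fill_value=0.0)
    )
    rows = []
    for g in config.intake.itertuples(index=False):
        obs = per_person[g.intake_group]
        se = float(obs.std(ddof=1)) / math.sqrt(n) if n > 1 else float("inf")
        diff = float(obs.mean()) - float(g.mean_per_day)
        rows.append(
            {
                "quantity": f"intake:{g.intake_group}",
                "expected": float(g.mean_per_day),
                "observed": float(obs.mean()),
                "se": se,
                "z": diff / se if se > 0 else 0.0,
            }
        )

    coef = coefficients.to_frame()
    items = cat.merge(coef[["item_id", "water_l_per_kg", "ghge_kgco2eq_per_kg"]], on="item_id")
    counts = items.groupby("intake_group")["item_id"].count()
    means = config.intake.set_index("intake_group")["mean_per_day"]
    expected = {"water_l": 0.0, "ghge_kg": 0.0, "nitrogen_g": 0.0}
    for item in items.itertuples():
        if item.intake_group not in means.index:
            continue
        e_kg = float(means[item.intake_group]) / counts[item.intake_group] / 1000.0
        expected["water_l"] += e_kg * item.water_l_per_kg
        expected["ghge_kg"] += e_kg * item.ghge_kgco2eq_per_kg
        expected["nitrogen_g"] += (
            e_kg * 1000.0 / 100.0 * item.protein_g_per_100g / item.nitrogen_factor
        )
    for col, exp in expected.items():
        obs = person_footprints[col]
        se = float(obs.std(ddof=1)) / math.sqrt(len(obs)) if len(obs) > 1 else float("inf")
        diff = float(obs.mean()) - exp
        rows.append(
            {"quantity": f"footprint:{col}", "expected": exp,
             "observed": float(obs.mean()), "se": se, "z": diff / se if se > 0 else 0.0}
        )

    report = pd.DataFrame(rows)
    report["flag"] = report["z"].abs() > z_crit
    return report
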