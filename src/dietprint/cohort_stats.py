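"""Descriptive cohort statistics, anthropometrics and design formulas.

Continuous variables are summarized as mean +/- sample SD (n-1 denominator)
and categorical variables as counts with percentages, overall and per
gender stratum.  Also provides BMI with the three-band WHO classification,
the household crowding index, Atwater macronutrient energy shares, and the
survey sample-size / design-effect formulas.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import pandas as pd

from .data_model import Participant, ValidationError

__all__ = [
    "bmi",
    "crowding_index",
    "macronutrient_energy_shares",
    "sample_size",
    "design_effect",
    "summarize_cohort",
]

log = logging.getLogger(__name__)

#: three-band BMI scheme: underweight < 18.5 <= normal < 25 <= overweight & obese
BMI_CUTPOINTS = (18.5, 25.0)
CROWDING_THRESHOLD = 1.0
ATWATER = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0}


def bmi(weight_kg: float, height_cm: float) -> tuple[float, str]:
    """Body mass index (kg/m^2) and its three-band class."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValidationError("weight and height must be > 0")
    value = weight_kg / (height_cm / 100.0) ** 2
    under, over = BMI_CUTPOINTS
    if value < under:
        cls = "Underweight"
    elif value < over:
        cls = "Normal"
    else:
        cls = "Overweight & Obese"
    return value, cls


def crowding_index(household_size: int, n_rooms: int) -> tuple[float, str]:
    """Persons per room; strictly more than one person per room is crowding."""
    if household_size < 1 or n_rooms < 1:
        raise ValidationError("household size and room count must be >= 1")
    index = household_size / n_rooms
    return index, ("crowding" if index > CROWDING_THRESHOLD else "no crowding")


def macronutrient_energy_shares(
    carb_g: float, protein_g: float, fat_g: float, energy_kcal: float
) -> tuple[float, float, float]:
    """Percent of energy from carbohydrate, protein and fat (Atwater 4/4/9).

    Shares are reported as computed; they need not total exactly 100 when
    the energy denominator includes alcohol or fibre.
    """
    if energy_kcal <= 0:
        raise ValidationError("energy must be > 0")
    if min(carb_g, protein_g, fat_g) < 0:
        raise ValidationError("macronutrient grams must be >= 0")
    return (
        ATWATER["carbohydrate"] * carb_g / energy_kcal * 100.0,
        ATWATER["protein"] * protein_g / energy_kcal * 100.0,
        ATWATER["fat"] * fat_g / energy_kcal * 100.0,
    )


def sample_size(p: float, z: float, e: float) -> tuple[float, int]:
    """Required survey sample size n = p(1-p) z^2 / e^2, raw and ceiling."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p must be in [0, 1], got {p}")
    if z <= 0 or e <= 0:
        raise ValidationError("z and e must be > 0")
    n = p * (1.0 - p) * z * z / (e * e)
    return n, math.ceil(n)


def design_effect(m: float, rho: float, n: float | None = None) -> tuple[float, float | None]:
    """Cluster-sampling design effect 1 + (m-1) rho and the effective n."""
    if m < 1:
        raise ValidationError(f"cluster size m must be >= 1, got {m}")
    if not (0.0 <= rho <= 1.0):
        raise ValidationError(f"intra-cluster correlation must be in [0, 1], got {rho}")
    deff = 1.0 + (m - 1.0) * rho
    return deff, (None if n is None else n / deff)


def _continuous_summary(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    rows = []
    for var in variables:
        s = df[var].dropna()
        rows.append(
            {"variable": var, "n": int(s.size), "mean": float(s.mean()),
             "sd": float(s.std(ddof=1)) if s.size > 1 else 0.0}
        )
    return pd.DataFrame(rows)


def _categorical_summary(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    rows = []
    for var in variables:
        counts = df[var].value_counts(sort=False)
        total = int(counts.sum())
        for level, n in counts.items():
            rows.append(
                {"variable": var, "level": level, "n": int(n),
                 "pct": float(n) / total * 100.0 if total else 0.0}
            )
    return pd.DataFrame(rows)


def summarize_cohort(
    participants: Iterable[Participant],
    person_footprints: pd.DataFrame | None = None,
    intake: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive summary tables, overall and per gender stratum.

    Returns a dict of tidy DataFrames: demographics (categorical counts and
    percentages), anthropometrics (continuous mean +/- SD, with BMI and
    crowding derived per participant), and -- when provided -- per-person
    footprint and intake summaries.
    """
    pdf = pd.DataFrame([vars(p) for p in participants])
    if pdf.empty:
        raise ValidationError("cannot summarize an empty cohort")
    pdf["bmi"] = [bmi(w, h)[0] for w, h in zip(pdf["weight_kg"], pdf["height_cm"])]
    pdf["bmi_class"] = [bmi(w, h)[1] for w, h in zip(pdf["weight_kg"], pdf["height_cm"])]
    pdf["crowding"] = [
        crowding_index(s, r)[1] for s, r in zip(pdf["household_size"], pdf["n_rooms"])
    ]

    cat_vars = ["gender", "governorate", "marital_status", "employment",
                "income_band", "education", "bmi_class", "crowding"]
    cat_vars = [v for v in cat_vars if pdf[v].astype(str).str.len().gt(0).any()]
    cont_vars = ["age_years", "weight_kg", "height_cm", "bmi"]

    out: dict[str, pd.DataFrame] = {}
    strata = {"overall": pdf}
    for gender, sub in pdf.groupby("gender", sort=True):
        if sub.empty:
            log.info("empty %s stratum omitted from summary", gender)
            continue
        strata[gender] = sub

    demo_parts, anthro_parts = [], []
    for name, sub in strata.items():
        demo = _categorical_summary(sub, cat_vars)
        demo.insert(0, "stratum", name)
        demo_parts.append(demo)
        anthro = _continuous_summary(sub, cont_vars)
        anthro.insert(0, "stratum", name)
        anthro_parts.append(anthro)
    out["demographics"] = pd.concat(demo_parts, ignore_index=True)
    out["anthropometrics"] = pd.concat(anthro_parts, ignore_index=True)

    if person_footprints is not None and not person_footprints.empty:
        fp = person_footprints.merge(
            pdf[["participant_id", "gender"]], on="participant_id", how="left"
        )
        cols = [c for c in fp.columns if c not in ("participant_id", "gender")]
        parts = [_continuous_summary(fp, cols).assign(stratum="overall")]
        for gender, sub in fp.groupby("gender", sort=True):
            parts.append(_continuous_summary(sub, cols).assign(stratum=gender))
        out["footprints"] = pd.concat(parts, ignore_index=True)

    if intake is not None and not intake.empty:
        n = pdf["participant_id"].nunique()
        per_group = (
            intake.groupby(["participant_id", "intake_group"])["grams_per_day"]
            .sum()
            .unstack(fill_value=0.0)
            .reindex(pdf["participant_id"], fill_value=0.0)
        )
        out["intake_groups"] = pd.DataFrame(
            {
                "intake_group": per_group.columns,
                "n": n,
                "mean": per_group.mean(axis=0).to_numpy(),
                "sd": per_group.std(axis=0, ddof=1).to_numpy(),
            }
        )
    return out
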