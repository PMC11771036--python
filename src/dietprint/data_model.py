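"""Domain types, tabular I/O and frequency normalization.

Consumption is reported per item at a daily, weekly or monthly cadence.
Everything downstream works in grams per day, so the first pipeline stage
divides weekly amounts by 7 and monthly amounts by 30 (a month is fixed at
30 days) and converts beverage millilitres to grams through the item's
density (1.0 g/ml unless overridden).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "FREQUENCY_DIVISORS",
    "PROTEIN_ENERGY_TOL_KCAL",
    "FoodItem",
    "FoodCatalogue",
    "ConsumptionRecord",
    "Participant",
    "DailyIntake",
    "ValidationError",
    "normalize_frequency",
    "normalize_records",
    "read_consumption_table",
    "read_participant_table",
    "write_daily_intake",
    "read_daily_intake",
]

FREQUENCY_DIVISORS = {"daily": 1.0, "weekly": 7.0, "monthly": 30.0}

#: slack allowed when checking that protein energy cannot exceed total energy
PROTEIN_ENERGY_TOL_KCAL = 1.0

NITROGEN_FACTOR_RANGE = (5.0, 7.0)
DEFAULT_NITROGEN_FACTOR = 6.25


class ValidationError(ValueError):
    """Raised when an input value violates a domain invariant."""


@dataclass(frozen=True)
class FoodItem:
    """One food of the intake questionnaire with its composition and labels.

    ``group`` is the footprint-aggregation food group; ``efp_category`` is
    its top-level category (animal / vegetable / other); ``pyramid_group``
    names the Double-Pyramid consumption tier the item belongs to (empty
    for items outside the pyramid, e.g. drinking water).
    """

    item_id: str
    name: str
    group: str
    efp_category: str
    energy_kcal_per_100g: float
    protein_g_per_100g: float
    nitrogen_factor: float = DEFAULT_NITROGEN_FACTOR
    pyramid_group: str = ""
    intake_group: str = ""
    is_beverage: bool = False
    is_composite: bool = False
    density_g_per_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.efp_category not in {"animal", "vegetable", "other"}:
            raise ValidationError(
                f"{self.item_id}: efp_category {self.efp_category!r} is not "
                "one of animal/vegetable/other"
            )
        if self.energy_kcal_per_100g < 0 or self.protein_g_per_100g < 0:
            raise ValidationError(f"{self.item_id}: negative composition value")
        if 4.0 * self.protein_g_per_100g > self.energy_kcal_per_100g + PROTEIN_ENERGY_TOL_KCAL:
            raise ValidationError(
                f"{self.item_id}: protein energy (4 x {self.protein_g_per_100g} g) "
                f"exceeds total energy {self.energy_kcal_per_100g} kcal/100 g"
            )
        lo, hi = NITROGEN_FACTOR_RANGE
        if not (lo <= self.nitrogen_factor <= hi):
            raise ValidationError(
                f"{self.item_id}: nitrogen factor {self.nitrogen_factor} outside "
                f"the plausible range [{lo}, {hi}]"
            )
        if self.density_g_per_ml <= 0:
            raise ValidationError(f"{self.item_id}: non-positive density")


class FoodCatalogue:
    """Item catalogue keyed by ``item_id`` with a consistent group scheme."""

    def __init__(self, items: Iterable[FoodItem]):
        self._items: dict[str, FoodItem] = {}
        group_cat: dict[str, str] = {}
        for it in items:
            if it.item_id in self._items:
                raise ValidationError(f"duplicate item_id {it.item_id!r}")
            prev = group_cat.setdefault(it.group, it.efp_category)
            if prev != it.efp_category:
                raise ValidationError(
                    f"group {it.group!r} maps to both {prev!r} and {it.efp_category!r}"
                )
            self._items[it.item_id] = it

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __iter__(self):
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    def get(self, item_id: str) -> FoodItem:
        try:
            return self._items[item_id]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id!r}") from None

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self:
            seen.setdefault(it.group)
        return list(seen)

    def replace_item(self, item: FoodItem) -> "FoodCatalogue":
        items = dict(self._items)
        items[item.item_id] = item
        return FoodCatalogue(items.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(it) for it in self]
        return pd.DataFrame(rows)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoodCatalogue":
        df = pd.read_csv(path, dtype={"item_id": str})
        items = []
        for row in df.itertuples(index=False):
            composite = bool(row.is_composite)
            items.append(
                FoodItem(
                    item_id=row.item_id,
                    name=row.name,
                    group=row.group,
                    efp_category=row.efp_category,
                    pyramid_group="" if pd.isna(row.pyramid_group) else str(row.pyramid_group),
                    intake_group=getattr(row, "intake_group", "") or "",
                    # composite rows carry no composition until recipe resolution
                    energy_kcal_per_100g=0.0 if composite else float(row.energy_kcal_per_100g),
                    protein_g_per_100g=0.0 if composite else float(row.protein_g_per_100g),
                    nitrogen_factor=(
                        DEFAULT_NITROGEN_FACTOR if composite or pd.isna(row.nitrogen_factor)
                        else float(row.nitrogen_factor)
                    ),
                    is_beverage=bool(row.is_beverage),
                    is_composite=composite,
                    density_g_per_ml=float(row.density_g_per_ml),
                )
            )
        return cls(items)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ConsumptionRecord:
    """One participant's reported amount of one item per reporting period."""

    participant_id: str
    item_id: str
    amount: float  # g (or ml for beverages) per reported period
    frequency_unit: str

    def __post_init__(self) -> None:
        if self.frequency_unit not in FREQUENCY_DIVISORS:
            raise ValidationError(
                f"unknown frequency unit {self.frequency_unit!r}; expected one of "
                f"{sorted(FREQUENCY_DIVISORS)}"
            )
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValidationError(f"amount must be finite and >= 0, got {self.amount}")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    gender: str
    age_years: int
    governorate: str
    weight_kg: float
    height_cm: float
    household_size: int
    n_rooms: int
    employment: str = ""
    marital_status: str = ""
    income_band: str = ""
    education: str = ""

    def __post_init__(self) -> None:
        if self.gender not in {"male", "female"}:
            raise ValidationError(f"{self.participant_id}: gender {self.gender!r}")
        if not (18 <= self.age_years <= 64):
            raise ValidationError(
                f"{self.participant_id}: age {self.age_years} outside the 18-64 eligibility window"
            )
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValidationError(f"{self.participant_id}: non-positive anthropometry")
        if self.household_size < 1 or self.n_rooms < 1:
            raise ValidationError(f"{self.participant_id}: household_size and n_rooms must be >= 1")


@dataclass(frozen=True)
class DailyIntake:
    participant_id: str
    item_id: str
    grams_per_day: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.grams_per_day) or self.grams_per_day < 0:
            raise ValidationError(
                f"grams_per_day must be finite and >= 0, got {self.grams_per_day}"
            )


def normalize_frequency(record: ConsumptionRecord, item: FoodItem) -> DailyIntake:
    """Convert a reported amount to grams per day.

    Weekly amounts are divided by 7 and monthly amounts by 30; beverage
    millilitres are converted to grams via the item density first.
    """
    divisor = FREQUENCY_DIVISORS[record.frequency_unit]
    amount_g = record.amount * item.density_g_per_ml if item.is_beverage else record.amount
    return DailyIntake(record.participant_id, record.item_id, amount_g / divisor)


def normalize_records(
    records: Iterable[ConsumptionRecord], catalogue: FoodCatalogue
) -> pd.DataFrame:
    """Normalize a batch of records to a tidy daily-intake table."""
    rows = []
    for rec in records:
        intake = normalize_frequency(rec, catalogue.get(rec.item_id))
        rows.append((intake.participant_id, intake.item_id, intake.grams_per_day))
    return pd.DataFrame(rows, columns=["participant_id", "item_id", "grams_per_day"])


def read_consumption_table(
    path: str | Path, catalogue: FoodCatalogue
) -> tuple[list[ConsumptionRecord], pd.DataFrame]:
    """Read a consumption CSV, returning (records, rejects).

    Every input row ends up either as a parsed record or as a row of the
    rejects table with a reason; counts are conserved.
    """
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "item_id": str, "frequency_unit": str},
        keep_default_na=False,
    )
    required = {"participant_id", "item_id", "amount", "frequency_unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"consumption table missing columns: {sorted(missing)}")

    records: list[ConsumptionRecord] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        reason = None
        try:
            amount = float(row["amount"])
        except (TypeError, ValueError):
            reason = f"malformed amount {row['amount']!r}"
            amount = float("nan")
        if reason is None and row["item_id"] not in catalogue:
            reason = f"unknown item_id {row['item_id']!r}"
        if reason is None:
            try:
                records.append(
                    ConsumptionRecord(
                        participant_id=row["participant_id"],
                        item_id=row["item_id"],
                        amount=amount,
                        frequency_unit=row["frequency_unit"],
                    )
                )
            except ValidationError as exc:
                reason = str(exc)
        if reason is not None:
            rejects.append({"row": int(idx), "reason": reason, **row.to_dict()})

    rejects_df = pd.DataFrame(
        rejects, columns=["row", "reason", "participant_id", "item_id", "amount", "frequency_unit"]
    )
    assert len(records) + len(rejects_df) == len(df)
    return records, rejects_df


def read_participant_table(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Participant(
                participant_id=row.participant_id,
                gender=row.gender,
                age_years=int(row.age_years),
                governorate=row.governorate,
                weight_kg=float(row.weight_kg),
                height_cm=float(row.height_cm),
                household_size=int(row.household_size),
                n_rooms=int(row.n_rooms),
                employment=getattr(row, "employment", ""),
                marital_status=getattr(row, "marital_status", ""),
                income_band=getattr(row, "income_band", ""),
                education=getattr(row, "education", ""),
            )
        )
    return out


def write_daily_intake(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical daily-intake ledger (full float precision)."""
    df.to_csv(
        path, index=False, float_format="%.17g",
        columns=["participant_id", "item_id", "grams_per_day"],
    )


def read_daily_intake(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"participant_id": str, "item_id": str},
        float_precision="round_trip",
    )
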