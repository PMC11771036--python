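"""Comparison against per-capita environmental limits and the Double Pyramid.

Two benchmarks are implemented:

* boundary ratios -- each cohort footprint expressed as a percentage of a
  per-capita sustainable limit (packaged defaults: 786 L water, 1,866 g
  CO2-eq and 27.4 g N per person per day);
* pyramid deviation -- food groups ranked by observed mean consumption and
  compared with the rank band the Double Pyramid recommends for their tier.
  A group whose observed rank is better (smaller) than its band is
  over-consumed, worse is under-consumed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._util import round_half_up
from .data_model import ValidationError

__all__ = [
    "EnvironmentalLimit",
    "PyramidSpec",
    "boundary_ratio",
    "boundary_ratios",
    "pyramid_deviation",
    "load_limits",
    "load_pyramid",
]

_METRICS = {"water", "ghge", "nitrogen"}


@dataclass(frozen=True)
class EnvironmentalLimit:
    metric: str
    value: float
    units: str
    citation: str = ""

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValidationError(f"unknown limit metric {self.metric!r}")
        if self.value <= 0:
            raise ValidationError(f"{self.metric}: limit must be > 0, got {self.value}")


@dataclass(frozen=True)
class PyramidSpec:
    """Ordered consumption tiers, most-recommended first.

    Each tier lists one or more pyramid groups.  A tier spanning several
    groups occupies a band of consumption ranks, so its groups are
    concordant anywhere inside that band.
    """

    tiers: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tier in self.tiers:
            for g in tier:
                if g in seen:
                    raise ValidationError(f"pyramid group {g!r} appears in more than one tier")
                seen.add(g)

    @property
    def groups(self) -> list[str]:
        return [g for tier in self.tiers for g in tier]

    def rank_bands(self) -> dict[str, tuple[int, int]]:
        """Recommended (best, worst) consumption rank per group."""
        bands = {}
        start = 1
        for tier in self.tiers:
            end = start + len(tier) - 1
            for g in tier:
                bands[g] = (start, end)
            start = end + 1
        return bands


def boundary_ratio(footprint: float, limit: EnvironmentalLimit) -> float:
    """Footprint as a percent of the per-capita limit (same per-day units)."""
    if footprint < 0:
        raise ValidationError(f"footprint must be >= 0, got {footprint}")
    return footprint / limit.value * 100.0


def boundary_ratios(
    totals: Mapping[str, float], limits: Mapping[str, EnvironmentalLimit]
) -> pd.DataFrame:
    """Boundary ratios for the three cohort footprints.

    ``totals`` uses the engine's ledger units (water_l, ghge_kg,
    nitrogen_g per day); GHGE is converted from kg to g to match the limit's
    g CO2-eq/cap/day before taking the ratio.
    """
    engine_units = {"water": ("water_l", 1.0), "ghge": ("ghge_kg", 1000.0),
                    "nitrogen": ("nitrogen_g", 1.0)}
    rows = []
    for metric, (col, to_limit_units) in engine_units.items():
        if metric not in limits:
            continue
        lim = limits[metric]
        value = totals[col] * to_limit_units
        pct = boundary_ratio(value, lim)
        rows.append(
            {
                "metric": metric,
                "footprint": value,
                "limit": lim.value,
                "units": lim.units,
                "pct_of_limit": pct,
                "pct_of_limit_display": round_half_up(pct, 0),
            }
        )
    return pd.DataFrame(rows)


def pyramid_deviation(mean_intakes: Mapping[str, float], spec: PyramidSpec) -> pd.DataFrame:
    """Rank observed group consumption against the recommended bands.

    ``mean_intakes`` maps each pyramid group to its cohort-mean intake in
    g/d.  Groups are ranked by descending mean; ties break lexicographically
    by group label so the report is independent of input order.
    """
    missing = [g for g in spec.groups if g not in mean_intakes]
    if missing:
        raise ValidationError(f"intake table missing pyramid groups: {missing}")
    ordered = sorted(spec.groups, key=lambda g: (-float(mean_intakes[g]), g))
    observed_rank = {g: i + 1 for i, g in enumerate(ordered)}
    bands = spec.rank_bands()
    rows = []
    for g in spec.groups:
        lo, hi = bands[g]
        rank = observed_rank[g]
        if rank < lo:
            status = "over-consumed"
        elif rank > hi:
            status = "under-consumed"
        else:
            status = "concordant"
        rows.append(
            {
                "pyramid_group": g,
                "mean_g_per_day": float(mean_intakes[g]),
                "observed_rank": rank,
                "recommended_rank_min": lo,
                "recommended_rank_max": hi,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def load_limits(path: str | Path) -> dict[str, EnvironmentalLimit]:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    out = {}
    for row in raw["limits"]:
        lim = EnvironmentalLimit(
            metric=row["metric"], value=float(row["value"]),
            units=row["units"], citation=row.get("citation", ""),
        )
        out[lim.metric] = lim
    return out


def load_pyramid(path: str | Path) -> PyramidSpec:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    tiers = sorted(raw["tiers"], key=lambda t: t["rank"])
    return PyramidSpec(tiers=tuple(tuple(t["groups"]) for t in tiers))
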