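"""End-to-end pipeline: ingest -> normalize -> footprints -> benchmarks -> report.

Every intermediate ledger is written as CSV at full precision; the Markdown
report only renders numbers already present in those ledgers (display
rounding happens there, never in the CSVs).  Reruns on identical inputs
produce byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import presets
from ._util import round_half_up
from .benchmarks import load_limits, load_pyramid
from .coefficients import CoefficientTable, read_recipes
from .cohort_stats import summarize_cohort
from .data_model import (
    FoodCatalogue,
    ValidationError,
    normalize_records,
    read_consumption_table,
    read_participant_table,
    write_daily_intake,
)
from .model import DietaryFootprintModel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    consumption_path: str | Path
    participants_path: str | Path
    outdir: str | Path
    catalogue_path: str | Path | None = None
    coefficients_path: str | Path | None = None
    recipes_path: str | Path | None = None
    limits_path: str | Path | None = None
    pyramid_path: str | Path | None = None
    reference_kcal: tuple[float, ...] = (1000.0, 2500.0)
    max_reject_fraction: float = 0.05

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.reference_kcal):
            raise ValidationError("reference kcal values must be > 0")
        for name in ("consumption_path", "participants_path", "catalogue_path",
                     "coefficients_path", "recipes_path", "limits_path", "pyramid_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except (ValidationError, KeyError, OSError) as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return out
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artefacts to ``config.outdir``.

    Returns the machine-readable results dict (also written as
    ``results.json``).  Raises :class:`PipelineError` on any validation
    failure; partial outputs written before the failure are retained next to
    a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        return _run(config, outdir)
    except Exception as exc:
        failed_marker.write_text(f"{exc}\n", encoding="utf-8")
        raise


def _run(config: RunConfig, outdir: Path) -> dict:
    # ingest
    catalogue = (
        FoodCatalogue.from_csv(config.catalogue_path)
        if config.catalogue_path else presets.default_catalogue()
    )
    coefficients = (
        CoefficientTable.from_csv(config.coefficients_path)
        if config.coefficients_path else presets.default_coefficients()
    )
    recipes = (
        read_recipes(config.recipes_path) if config.recipes_path else presets.default_recipes()
    )
    limits = load_limits(config.limits_path) if config.limits_path else presets.default_limits()
    pyramid = (
        load_pyramid(config.pyramid_path) if config.pyramid_path else presets.default_pyramid()
    )

    records, rejects = _stage("ingest")(read_consumption_table)(
        config.consumption_path, catalogue
    )
    participants = _stage("ingest")(read_participant_table)(config.participants_path)
    n_rows = len(records) + len(rejects)
    log.info("ingest: %d rows in, %d parsed, %d rejected", n_rows, len(records), len(rejects))
    rejects.to_csv(outdir / "rejects.csv", index=False)
    if n_rows and len(rejects) / n_rows > config.max_reject_fraction:
        raise PipelineError(
            f"stage 'ingest' failed: {len(rejects)}/{n_rows} rows rejected, above the "
            f"{config.max_reject_fraction:.0%} threshold; see rejects.csv"
        )

    # normalize
    intake = _stage("normalize")(normalize_records)(records, catalogue)
    write_daily_intake(intake, outdir / "daily_intake.csv")
    log.info("normalize: %d daily-intake rows", len(intake))

    # footprints (recipe resolution happens inside the model)
    model = DietaryFootprintModel(intake, catalogue, coefficients, recipes, participants)
    results = _stage("footprints")(model.fit)()
    results.person_footprints.to_csv(outdir / "person_footprints.csv", index=False)
    results.group_footprints.to_csv(outdir / "group_footprints.csv", index=False)
    results.percent_by_group.to_csv(outdir / "percent_contributions.csv", index=False)
    n_zero_energy = int(results.person_footprints["energy_kcal"].le(0).sum())
    if n_zero_energy:
        log.info("footprints: %d zero-energy participants excluded from per-kcal means",
                 n_zero_energy)

    # benchmarks
    ratios = _stage("benchmarks")(results.boundary_ratios)(limits)
    ratios.to_csv(outdir / "boundary_ratios.csv", index=False)
    deviation = _stage("benchmarks")(results.pyramid_deviation)(pyramid)
    deviation.to_csv(outdir / "pyramid_deviation.csv", index=False)

    # cohort summaries
    cat_frame = catalogue.to_frame()
    intake_with_groups = intake.merge(cat_frame[["item_id", "intake_group"]], on="item_id")
    summaries = _stage("summaries")(summarize_cohort)(
        participants, results.person_footprints, intake_with_groups
    )
    for name, df in summaries.items():
        df.to_csv(outdir / f"summary_{name}.csv", index=False)

    means = results.footprint_means()
    reference = {
        str(int(k)): results.per_reference_kcal(k) for k in config.reference_kcal
    }
    payload = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "n_participants": results.n,
        "n_rows_in": n_rows,
        "n_rows_rejected": len(rejects),
        "n_zero_energy": n_zero_energy,
        "footprint_means": {
            r["quantity"]: {"mean": r["mean"], "sd": r["sd"]}
            for r in means.to_dict("records")
        },
        "per_reference_kcal": reference,
        "category_footprints": results.category_footprints.to_dict("records"),
        "boundary_ratios": ratios.to_dict("records"),
        "pyramid_deviation": deviation.to_dict("records"),
    }
    (outdir / "results.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "report.md").write_text(
        _render_report(results, ratios, deviation, summaries), encoding="utf-8"
    )
    return payload


def _render_report(results, ratios, deviation, summaries) -> str:
    """Markdown report; renders ledger values only, with half-up display rounding."""
    L = ["# Dietary environmental footprint report", ""]
    L += [f"Participants: {results.n}", "", "## Cohort footprints (mean ± SD)", ""]
    L += ["| quantity | mean | SD |", "|---|---|---|"]
    for r in results.footprint_means().itertuples(index=False):
        L.append(f"| {r.quantity} | {round_half_up(r.mean, 2)} | {round_half_up(r.sd, 2)} |")
    L += ["", "## Footprints per food group (per capita per day)", ""]
    L += ["| group | category | GHGE kg CO2-eq | nitrogen g | water L |", "|---|---|---|---|---|"]
    for r in results.group_footprints.itertuples(index=False):
        L.append(
            f"| {r.group} | {r.efp_category} | {round_half_up(r.ghge_kg, 2)} "
            f"| {round_half_up(r.nitrogen_g, 2)} | {round_half_up(r.water_l, 2)} |"
        )
    for r in results.category_footprints.itertuples(index=False):
        L.append(
            f"| **{r.efp_category} total** |  | {round_half_up(r.ghge_kg, 2)} "
            f"| {round_half_up(r.nitrogen_g, 2)} | {round_half_up(r.water_l, 2)} |"
        )
    L += ["", "## Percent contributions", ""]
    L += ["| group | GHGE % | water % | nitrogen % |", "|---|---|---|---|"]
    for r in results.percent_by_group.itertuples(index=False):
        L.append(
            f"| {r.group} | {r.ghge_kg_pct_display} | {r.water_l_pct_display} "
            f"| {r.nitrogen_g_pct_display} |"
        )
    L += ["", "## Per-capita environmental limits", ""]
    L += ["| metric | footprint | limit | % of limit |", "|---|---|---|---|"]
    for r in ratios.itertuples(index=False):
        L.append(
            f"| {r.metric} | {round_half_up(r.footprint, 2)} {r.units.split('/')[0]} "
            f"| {r.limit} | {int(r.pct_of_limit_display)}% |"
        )
    L += ["", "## Double-Pyramid deviation", ""]
    L += ["| pyramid group | mean g/d | observed rank | recommended band | status |",
          "|---|---|---|---|---|"]
    for r in deviation.itertuples(index=False):
        L.append(
            f"| {r.pyramid_group} | {round_half_up(r.mean_g_per_day, 2)} | {r.observed_rank} "
            f"| {r.recommended_rank_min}-{r.recommended_rank_max} | {r.status} |"
        )
    L.append("")
    return "\n".join(L)
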