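"""Model API, end-to-end pipeline determinism and the CLI."""
import json

import pytest
from typer.testing import CliRunner

from dietprint import (
    DailyIntake,
    DietaryFootprintModel,
    GeneratorConfig,
    PipelineError,
    RunConfig,
    ValidationError,
    generate_cohort,
    person_footprint,
    run_pipeline,
    write_bundle,
)
from dietprint.cli import app


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    cohort = generate_cohort(GeneratorConfig(n=30, seed=9))
    write_bundle(cohort, outdir)
    return outdir, cohort


def test_model_matches_scalar_path(bundle):
    _, cohort = bundle
    model = DietaryFootprintModel(
        cohort.daily_intake, cohort.catalogue, cohort.coefficients, cohort.recipes
    )
    res = model.fit()
    pid = res.person_footprints["participant_id"].iloc[0]
    sub = cohort.daily_intake[cohort.daily_intake["participant_id"] == pid]
    intakes = [DailyIntake(pid, r.item_id, r.grams_per_day) for r in sub.itertuples(index=False)]
    pf = person_footprint(intakes, model.catalogue, model.coefficients)
    row = res.person_footprints.set_index("participant_id").loc[pid]
    assert row["water_l"] == pytest.approx(pf.water_l_per_day, rel=1e-12)
    assert row["nitrogen_g"] == pytest.approx(pf.nitrogen_g_per_day, rel=1e-12)
    assert "Dietary environmental footprints" in res.summary()


def test_pipeline_artifacts_and_percent_sums(bundle, tmp_path):
    outdir, _ = bundle
    run_out = tmp_path / "run"
    payload = run_pipeline(
        RunConfig(outdir / "consumption.csv", outdir / "participants.csv", run_out)
    )
    for name in ("daily_intake.csv", "person_footprints.csv", "group_footprints.csv",
                 "percent_contributions.csv", "boundary_ratios.csv",
                 "pyramid_deviation.csv", "results.json", "report.md"):
        assert (run_out / name).exists()
    import pandas as pd

    pct = pd.read_csv(run_out / "percent_contributions.csv")
    for col in ("water_l_pct", "ghge_kg_pct", "nitrogen_g_pct"):
        assert pct[col].sum() == pytest.approx(100.0, abs=0.1)
    assert payload["n_rows_rejected"] == 0
    assert payload["n_participants"] == 30


def test_pipeline_is_deterministic(bundle, tmp_path):
    outdir, _ = bundle
    outs = []
    for sub in ("r1", "r2"):
        run_pipeline(
            RunConfig(outdir / "consumption.csv", outdir / "participants.csv", tmp_path / sub)
        )
        outs.append((tmp_path / sub / "results.json").read_bytes())
    assert outs[0] == outs[1]


def test_missing_input_file_is_named(bundle, tmp_path):
    outdir, _ = bundle
    with pytest.raises(ValidationError, match="nope.csv"):
        RunConfig(outdir / "nope.csv", outdir / "participants.csv", tmp_path / "x")


def test_reject_fraction_guard(bundle, tmp_path):
    outdir, _ = bundle
    bad = tmp_path / "bad.csv"
    text = (outdir / "consumption.csv").read_text().splitlines()
    n_bad = int(len(text) * 0.1) + 1
    bad_rows = [f"p1,unknown_item_{i},10,daily" for i in range(n_bad)]
    bad.write_text("\n".join(text + bad_rows) + "\n")
    with pytest.raises(PipelineError, match="rejected"):
        run_pipeline(RunConfig(bad, outdir / "participants.csv", tmp_path / "badrun"))
    assert (tmp_path / "badrun" / "FAILED").exists()


def test_cli_generate_run_check(tmp_path):
    runner = CliRunner()
    gen_dir = tmp_path / "gen"
    out_dir = tmp_path / "out"
    r = runner.invoke(app, ["generate", str(gen_dir), "--n", "15", "--seed", "4"])
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        app,
        ["run", str(gen_dir / "consumption.csv"), str(gen_dir / "participants.csv"),
         str(out_dir)],
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(app, ["check", str(out_dir / "results.json")])
    assert r.exit_code == 0, r.output
    assert "passed" in r.output
    r = runner.invoke(
        app,
        ["run", str(gen_dir / "consumption.csv"), str(gen_dir / "participants.csv"),
         str(out_dir), "--coefficients", str(gen_dir / "missing.csv")],
    )
    assert r.exit_code == 1
    err = r.output + (r.stderr if r.stderr_bytes is not None else "")
    assert "missing.csv" in err


def test_results_json_consistency_check_catches_corruption(tmp_path):
    runner = CliRunner()
    gen_dir = tmp_path / "gen"
    out_dir = tmp_path / "out"
    runner.invoke(app, ["generate", str(gen_dir), "--n", "10", "--seed", "1"])
    runner.invoke(
        app,
        ["run", str(gen_dir / "consumption.csv"), str(gen_dir / "participants.csv"),
         str(out_dir)],
    )
    payload = json.loads((out_dir / "results.json").read_text())
    payload["boundary_ratios"][0]["pct_of_limit"] *= 2
    (out_dir / "results.json").write_text(json.dumps(payload))
    r = runner.invoke(app, ["check", str(out_dir / "results.json")])
    assert r.exit_code == 1
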