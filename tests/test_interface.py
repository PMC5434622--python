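import json

import pytest
from click.testing import CliRunner

from mscfate.cli import main
from mscfate.config import RunConfig, load_config, resolve_params
from mscfate.params import ParameterSet


def test_empty_file_gives_defaults(tmp_path):
    path = tmp_path / "empty.yaml"
    path.write_text("")
    cfg = load_config(path)
    assert cfg.params == ParameterSet()
    assert cfg.variant.mode == "noncooperative"
    assert cfg.seed == 0
    assert cfg.pa_per_kpa == 1000.0


def test_none_path_gives_defaults():
    assert load_config(None).params == ParameterSet()


def test_idempotent_override(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("params:\n  k5: 4.0\n")
    assert load_config(path).params == ParameterSet()


def test_real_override(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("params:\n  K1: 750.0\nseed: 17\n")
    cfg = load_config(path)
    assert cfg.params.K1 == 750.0
    assert cfg.seed == 17


def test_negative_parameter_rejected(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("params:\n  K1: -1.0\n")
    with pytest.raises(ValueError, match="K1.*> 0"):
        load_config(path)


def test_unknown_keys_named(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("sweeep: {}\n")
    with pytest.raises(ValueError, match="sweeep"):
        load_config(path)
    path.write_text("sweep:\n  n_pints: 3\n")
    with pytest.raises(ValueError, match="n_pints"):
        load_config(path)
    path.write_text("params:\n  q1: 2\n")
    with pytest.raises(ValueError, match="q1"):
        load_config(path)


def test_bad_variant_rejected(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("variant:\n  blocked: [NOTAGENE]\n")
    with pytest.raises(ValueError, match="NOTAGENE"):
        load_config(path)


def test_params_file_round_trip(tmp_path):
    pfile = tmp_path / "params.yaml"
    ParameterSet().with_indexed(10, 777.0).write_yaml(pfile)
    assert resolve_params(params_file=pfile).K1 == 777.0


def test_sidecar_is_full_resolved_config(tmp_path):
    cfg = RunConfig()
    sidecar = tmp_path / "run.config.json"
    cfg.write_sidecar(sidecar)
    data = json.loads(sidecar.read_text())
    assert data["params"]["K1"] == 600.0
    assert data["pa_per_kpa"] == 1000.0
    assert set(data) >= {"params", "variant", "seed", "sweep", "dose",
                         "robustness", "landscape", "sde"}


def test_cli_validation_exit_code(tmp_path):
    runner = CliRunner()
    result = runner.invoke(main, ["sweep", "--n", "-5",
                                  "--out", str(tmp_path)])
    assert result.exit_code == 2


def test_cli_dose_runs_and_writes(tmp_path):
    runner = CliRunner()
    result = runner.invoke(main, [
        "dose", "--first-s", "30", "--first-t", "0", "--second-s", "0.4",
        "--total-t", "50", "--out", str(tmp_path)])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "trajectory.csv").exists()
    assert (tmp_path / "dose.config.json").exists()
    assert "lineage" in result.output


def test_cli_bad_config_exit_code(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("params:\n  K1: -3\n")
    runner = CliRunner()
    result = runner.invoke(main, ["dose", "--first-s", "1", "--first-t", "0",
                                  "--second-s", "1",
                                  "--config", str(bad),
                                  "--out", str(tmp_path)])
    assert result.exit_code == 2


def test_reproduce_single_stage_manifest(tmp_path):
    from mscfate.reproduce import reproduce_paper

    cfg = RunConfig()
    cfg.sweep = dict(cfg.sweep, n_points=80)
    manifest = reproduce_paper(tmp_path, cfg, stages=["blocked_feedback"])
    assert manifest["ok"]
    assert [s["name"] for s in manifest["stages"]] == ["blocked_feedback"]
    stage = manifest["stages"][0]
    assert stage["status"] == "ok"
    assert stage["summary"]["n_memory_regions"] == 0
    assert stage["outputs"]                  # checksummed files recorded
    data = json.loads((tmp_path / "manifest.json").read_text())
    assert data["stages"][0]["name"] == "blocked_feedback"
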