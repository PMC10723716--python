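"""Batch orchestration and the command-line surface."""

import pandas as pd
import pytest

from caulotype.config import OpticsConfig, RunConfig
from caulotype.scenes import PRESETS, mixture_population
from caulotype.workflow import (
    WorkflowError,
    read_provenance_csv,
    run_annotate,
    run_simulate,
    run_train,
    run_validate,
)

# training at desk scale needs segmentable debris objects in the labels;
# a debris-enriched mixture keeps the tiny fixture dataset reliable
PRESETS.setdefault(
    "debris_rich",
    mixture_population(
        {"stalked": 0.40, "swarmer": 0.30, "predivisional": 0.05, "debris": 0.25},
        name="debris_rich",
    ),
)

TINY = OpticsConfig(frame_shape=(384, 384))


@pytest.fixture(scope="module")
def tiny_config():
    return RunConfig(optics=TINY, seed=5)


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory, tiny_config):
    out = tmp_path_factory.mktemp("data") / "train"
    manifest = run_simulate(tiny_config, out, {"debris_rich": 4}, n_cells=10)
    return out, manifest


@pytest.fixture(scope="module")
def tiny_models(tmp_path_factory, tiny_config, tiny_dataset):
    data_dir, _ = tiny_dataset
    models_dir = tmp_path_factory.mktemp("models")
    report = run_train(tiny_config, data_dir, models_dir)
    return models_dir, report


def test_simulate_writes_dataset_and_config(tiny_dataset):
    out, manifest = tiny_dataset
    assert len(manifest) == 4
    assert (out / "run_config.yaml").exists()
    assert (out / "manifest.csv").exists()
    for stem in manifest["stem"]:
        assert (out / f"{stem}.tif").exists()


def test_simulate_same_seed_is_identical(tmp_path, tiny_config, tiny_dataset):
    out, manifest = tiny_dataset
    again = run_simulate(tiny_config, tmp_path / "again", {"debris_rich": 4}, n_cells=10)
    pd.testing.assert_frame_equal(manifest, again)
    a = (out / "img_000.tif").read_bytes()
    b = (tmp_path / "again" / "img_000.tif").read_bytes()
    assert a == b


def test_train_produces_models_and_report(tiny_models):
    models_dir, report = tiny_models
    assert (models_dir / "pixel_model.joblib").exists()
    assert (models_dir / "cell_model.joblib").exists()
    assert (models_dir / "training_report.json").exists()
    assert report["mean_pixel_accuracy"] > 0.98
    assert set(report["object_class_counts"]) >= {"stalked", "swarmer", "debris"}


def test_train_requires_manifest(tmp_path, tiny_config):
    with pytest.raises(WorkflowError, match="manifest"):
        run_train(tiny_config, tmp_path, tmp_path / "m")


def test_annotate_batch_with_sample_sheet(tmp_path, tiny_config, tiny_dataset, tiny_models):
    data_dir, manifest = tiny_dataset
    models_dir, _ = tiny_models
    images = [data_dir / f"{stem}.tif" for stem in manifest["stem"]]
    sheet = pd.DataFrame({
        "image": manifest["stem"],
        "replicate": ["r1", "r1", "r2", "r2"],
        "condition": ["M2G"] * 4,
        "timepoint_h": [0.0, 24.0, 0.0, 24.0],
    })
    records = run_annotate(tiny_config, images, models_dir, tmp_path / "out", sheet)
    assert (tmp_path / "out" / "morpho_records.csv").exists()
    summary = read_provenance_csv(tmp_path / "out" / "population_summary.csv")
    assert len(summary) == 4   # one row per replicate x timepoint
    header = (tmp_path / "out" / "morpho_records.csv").read_text().splitlines()[:4]
    assert header[0].startswith("# caulotype")
    assert any("config_hash" in line for line in header)
    assert any("pixel_model" in line for line in header)
    assert set(records["image"]) == set(manifest["stem"])


def test_annotate_rerun_bit_identical(tmp_path, tiny_config, tiny_dataset, tiny_models):
    data_dir, manifest = tiny_dataset
    models_dir, _ = tiny_models
    images = [data_dir / f"{manifest['stem'][0]}.tif"]
    for sub in ("a", "b"):
        run_annotate(tiny_config, images, models_dir, tmp_path / sub)
    a = (tmp_path / "a" / "morpho_records.csv").read_bytes()
    b = (tmp_path / "b" / "morpho_records.csv").read_bytes()
    assert a == b


def test_annotate_empty_input_fails_without_partial_output(tmp_path, tiny_config, tiny_models):
    models_dir, _ = tiny_models
    out = tmp_path / "nothing"
    with pytest.raises(WorkflowError, match="no input images"):
        run_annotate(tiny_config, [], models_dir, out)
    assert not out.exists()


def test_validate_against_generator_truth(tmp_path, tiny_config, tiny_dataset, tiny_models):
    data_dir, manifest = tiny_dataset
    models_dir, _ = tiny_models
    stem = manifest["stem"][0]
    records = run_annotate(
        tiny_config, [data_dir / f"{stem}.tif"], models_dir, tmp_path / "out"
    )
    truth = pd.read_csv(data_dir / f"{stem}_records.csv")
    result = run_validate(tiny_config, records, truth, out_dir=tmp_path / "val")
    assert result["n_matched"] > 0
    assert 0.0 <= result["accuracy_sw_st"] <= 1.0
    assert (tmp_path / "val" / "confusion_matrix.csv").exists()
    assert (tmp_path / "val" / "validation.json").exists()


def test_config_yaml_roundtrip(tmp_path, tiny_config):
    path = tmp_path / "config.yaml"
    tiny_config.save(path)
    loaded = RunConfig.load(path)
    assert loaded.optics == tiny_config.optics
    assert loaded.hash() == tiny_config.hash()


def test_cli_simulate_and_help(tmp_path):
    from click.testing import CliRunner

    from caulotype.cli import main

    runner = CliRunner()
    assert runner.invoke(main, ["--help"]).exit_code == 0

    cfg = RunConfig(optics=OpticsConfig(frame_shape=(64, 64)))
    cfg_path = tmp_path / "cfg.yaml"
    cfg.save(cfg_path)
    result = runner.invoke(main, [
        "simulate", "--config", str(cfg_path), "--seed", "3",
        "--out", str(tmp_path / "sim"), "--preset", "exponential:2",
        "--n-cells", "0",
    ])
    assert result.exit_code == 0, result.output
    assert "wrote 2 images" in result.output


def test_cli_annotate_and_validate(tmp_path, tiny_config, tiny_dataset, tiny_models):
    from click.testing import CliRunner

    from caulotype.cli import main

    data_dir, manifest = tiny_dataset
    models_dir, _ = tiny_models
    cfg_path = tmp_path / "cfg.yaml"
    tiny_config.save(cfg_path)
    stem = manifest["stem"][0]
    runner = CliRunner()
    result = runner.invoke(main, [
        "annotate", "--config", str(cfg_path),
        "--models", str(models_dir), "--out", str(tmp_path / "ann"),
        str(data_dir / f"{stem}.tif"),
    ])
    assert result.exit_code == 0, result.output
    result = runner.invoke(main, [
        "validate", "--records", str(tmp_path / "ann" / "morpho_records.csv"),
        "--truth", str(data_dir / f"{stem}_records.csv"),
        "--out", str(tmp_path / "val"),
    ])
    assert result.exit_code == 0, result.output
    assert "accuracy" in result.output
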