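"""Batch orchestration: simulate / train / annotate / summarize / validate.

Every run writes its resolved configuration next to its outputs, and every
output CSV starts with a provenance comment block (config hash, model
hashes) so any artifact can be traced to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import pandas as pd

from caulotype.config import RunConfig
from caulotype.objects import CellRules, ObjectModel, StalkRules
from caulotype.pipeline import PipelineModels, annotate_image, train_models_from_dataset
from caulotype.pixels import PixelModel
from caulotype.popstats import sample_records_frame, summarize
from caulotype.render import load_image, load_truth, make_dataset
from caulotype.validate import (
    ExpertAnnotation,
    accuracy,
    annotation_from_truth,
    confusion,
    match_objects,
)

logger = logging.getLogger(__name__)

PIXEL_MODEL_FILE = "pixel_model.joblib"
CELL_MODEL_FILE = "cell_model.joblib"


class WorkflowError(RuntimeError):
    """A named, user-facing orchestration failure."""


def _file_hash(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


def _provenance_lines(config: RunConfig, models_dir: Path | None = None) -> list[str]:
    lines = [f"# caulotype v{config.version}", f"# config_hash={config.hash()}"]
    if models_dir is not None:
        for name in (PIXEL_MODEL_FILE, CELL_MODEL_FILE):
            p = models_dir / name
            if p.exists():
                lines.append(f"# model {name} sha1={_file_hash(p)}")
    return lines


def write_csv_with_provenance(
    df: pd.DataFrame, path: Path, config: RunConfig, models_dir: Path | None = None
) -> None:
    header = "\n".join(_provenance_lines(config, models_dir))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_provenance_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_simulate(
    config: RunConfig,
    out_dir: str | Path,
    presets: dict[str, int],
    n_cells: int = 60,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Generate a dataset of rendered fields with ground truth."""
    out = Path(out_dir)
    t0 = time.time()
    manifest = make_dataset(
        out, presets, n_cells=n_cells, optics=config.optics,
        base_seed=config.seed, overwrite=overwrite,
    )
    config.save(out / "run_config.yaml")
    logger.info("simulate: %d images in %.1fs", len(manifest), time.time() - t0)
    return manifest


def run_train(
    config: RunConfig,
    data_dir: str | Path,
    models_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Train pixel + cell-object models from a simulated dataset."""
    data = Path(data_dir)
    manifest_path = data / "manifest.csv"
    if not manifest_path.exists():
        raise WorkflowError(f"no manifest.csv in {data}")
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise WorkflowError(f"empty dataset in {data}")
    pairs = [
        (load_image(data / f"{row.stem}.tif"), load_truth(data, row.stem))
        for row in manifest.itertuples()
    ]
    t0 = time.time()
    models, report = train_models_from_dataset(
        pairs, config, seed=config.seed if seed is None else seed
    )
    mdir = Path(models_dir)
    mdir.mkdir(parents=True, exist_ok=True)
    models.pixel.save(mdir / PIXEL_MODEL_FILE)
    models.cell.save(mdir / CELL_MODEL_FILE)
    report["train_seconds"] = round(time.time() - t0, 1)
    (mdir / "training_report.json").write_text(json.dumps(report, indent=2))
    config.save(mdir / "run_config.yaml")
    logger.info("train: %s", report)
    return report


def load_models(models_dir: str | Path, config: RunConfig | None = None) -> PipelineModels:
    mdir = Path(models_dir)
    pixel = PixelModel.load(mdir / PIXEL_MODEL_FILE)
    cell_path = mdir / CELL_MODEL_FILE
    cell = ObjectModel.load(cell_path) if cell_path.exists() else CellRules()
    return PipelineModels(pixel=pixel, cell=cell, stalk=StalkRules())


def run_annotate(
    config: RunConfig,
    image_paths: Sequence[str | Path],
    models_dir: str | Path,
    out_dir: str | Path,
    sample_sheet: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate a batch of micrographs; returns the pooled record table.

    ``sample_sheet`` maps image stem -> replicate/condition/timepoint_h;
    without one, every image becomes its own replicate of one condition.
    """
    paths = [Path(p) for p in image_paths]
    if not paths:
        raise WorkflowError("no input images")
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise WorkflowError(f"missing image files: {missing[:3]}")

    models = load_models(models_dir, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    for p in paths:
        t0 = time.time()
        ann = annotate_image(load_image(p), models, config)
        rec = ann.records.copy()
        rec.insert(0, "image", p.stem)
        frames.append(rec)
        logger.info("annotate %s: %d objects in %.1fs", p.stem, len(rec), time.time() - t0)
    records = pd.concat(frames, ignore_index=True)

    if sample_sheet is not None:
        records = records.merge(sample_sheet, on="image", how="left", validate="many_to_one")
    else:
        records["replicate"] = records["image"]
        records["condition"] = "all"
        records["timepoint_h"] = 0.0

    write_csv_with_provenance(records, out / "morpho_records.csv", config, Path(models_dir))
    summary = sample_records_frame(summarize(records))
    write_csv_with_provenance(summary, out / "population_summary.csv", config, Path(models_dir))
    config.save(out / "run_config.yaml")
    return records


def run_validate(
    config: RunConfig,
    records: pd.DataFrame,
    reference: ExpertAnnotation | pd.DataFrame,
    out_dir: str | Path | None = None,
    max_dist_um: float = 1.0,
) -> dict:
    """Match predictions to a reference annotation and score agreement.

    ``records`` is a (single-image) morphometric record table; the
    reference is an :class:`ExpertAnnotation` or a generator truth record
    table. Returns the confusion matrix, overall accuracy and the
    Swarmer/Stalked-restricted accuracy.
    """
    if isinstance(reference, pd.DataFrame):
        reference = annotation_from_truth(reference)

    pred_pts = records[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    label_map = {"SW": "Swarmer", "ST": "Stalked", "PD": "Stalked",
                 "swarmer": "Swarmer", "stalked": "Stalked", "debris": "Debris"}
    pred_labels = [label_map[t] for t in records["final_type"]]

    match = match_objects(pred_pts, reference, max_dist_um)
    pairs = [(reference.labels[j], pred_labels[i]) for i, j in match.pairs]
    matrix = confusion(pairs, excluded_count=match.excluded_count)
    result = {
        "n_matched": len(pairs),
        "excluded_count": match.excluded_count,
        "accuracy_all": accuracy(matrix),
        "accuracy_sw_st": accuracy(matrix, restrict_to=("Swarmer", "Stalked")),
        "confusion": matrix,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_frame().to_csv(out / "confusion_matrix.csv")
        scalars = {k: v for k, v in result.items() if k != "confusion"}
        (out / "validation.json").write_text(json.dumps(scalars, indent=2))
    return result
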