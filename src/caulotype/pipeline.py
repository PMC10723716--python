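"""End-to-end annotation of single frames and model training from truth.

The per-frame sequence mirrors the staged workflow: pixel probabilities,
cell/stalk object segmentation, stalk keep/remove filtering, object
features, cell classification, medial-axis morphometrics with the
predivisional call, stalk-to-pole assignment, and the final SW/ST/PD (or
two-class) record table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from caulotype.config import RunConfig
from caulotype.features import extract_features, large_scale_background
from caulotype.morpho import (
    DegenerateCellError,
    assign_stalk,
    constriction,
    finalize_types,
    medial_axis,
)
from caulotype.objects import (
    CellRules,
    ObjectModel,
    StalkRules,
    attach_stalks_to_cells,
    cell_features,
    classify_cells,
    classify_stalks,
    focus_score_map,
    stalk_features,
    train_object_model,
)
from caulotype.pixels import (
    PixelModel,
    assemble_probability_map,
    candidate_mask,
    predict_pixels,
    train_pixel_model,
)
from caulotype.render import GroundTruthScene
from caulotype.segmentation import CellObject, StalkObject, segment_cells, segment_stalks

TRUTH_TO_OBJECT_CLASS = {
    "stalked": "stalked",
    "predivisional": "stalked",
    "swarmer": "swarmer",
    "debris": "debris",
}


@dataclass
class PipelineModels:
    pixel: PixelModel
    cell: ObjectModel | CellRules
    stalk: ObjectModel | StalkRules = field(default_factory=StalkRules)


@dataclass
class FrameAnnotation:
    records: pd.DataFrame
    cells: list[CellObject]
    stalks: list[StalkObject]


def annotate_image(
    image: np.ndarray,
    models: PipelineModels,
    config: RunConfig | None = None,
) -> FrameAnnotation:
    """Run the full annotation workflow on one micrograph."""
    config = config or RunConfig()
    seg = config.segmentation
    mor = config.morpho
    px = config.optics.pixel_size

    img32 = np.asarray(image, dtype=np.float32)
    background = large_scale_background(img32)
    prob_map = predict_pixels(models.pixel, image, background=background)
    cells = segment_cells(prob_map, seg, px)
    stalks = segment_stalks(prob_map, seg, px)

    lap, lap_scale = focus_score_map(image)
    for cell in cells:
        cell_features(cell, image, prob_map, lap, lap_scale)
    for stalk in stalks:
        stalk_features(stalk, cells, prob_map, px)

    if isinstance(models.stalk, StalkRules):
        models.stalk.classify(stalks)
    else:
        classify_stalks(models.stalk, stalks)

    attach_stalks_to_cells(cells, stalks, mor.attach_dist_um)

    if isinstance(models.cell, CellRules):
        models.cell.classify(cells)
    else:
        classify_cells(models.cell, cells)

    smoothed = ndi.gaussian_filter(img32, 0.75)
    morpho_by_cell = {}
    for cell in cells:
        if cell.class_ == "debris":
            continue
        try:
            axis = medial_axis(cell)
        except DegenerateCellError as exc:
            cell.class_ = "debris"
            cell.flags.append(f"degenerate:{exc}")
            continue
        degree, is_pd = constriction(
            axis, mor, image=image, pixel_size=px,
            smoothed=smoothed, background=background,
        )
        cell.poles_um = axis.poles
        morpho_by_cell[cell.id] = (axis, degree, is_pd)

    for stalk in stalks:
        if stalk.status == "keep":
            assign_stalk(stalk, cells, mor.r_max_um)

    records = finalize_types(cells, stalks, morpho_by_cell, scheme=config.scheme)
    return FrameAnnotation(records=records, cells=cells, stalks=stalks)


# --------------------------------------------------------------------------
# truth-supervised labelling and training


def label_cells_by_truth(
    cells: list[CellObject], truth: GroundTruthScene, min_overlap: float = 0.3
) -> list[str]:
    """Object-level labels from the majority truth instance under each mask."""
    class_by_id = dict(zip(truth.records["id"], truth.records["class"]))
    labels = []
    for cell in cells:
        under = truth.cell_instance_mask[cell.slices][cell.mask]
        ids, counts = np.unique(under[under > 0], return_counts=True)
        if len(ids) == 0 or counts.max() < min_overlap * cell.mask.sum():
            labels.append("debris")
            continue
        truth_id = int(ids[np.argmax(counts)])
        labels.append(TRUTH_TO_OBJECT_CLASS[class_by_id[truth_id]])
    return labels


def match_cells_to_truth(
    cells: list[CellObject], truth: GroundTruthScene, min_overlap: float = 0.3
) -> dict[int, int]:
    """Map segmented cell id -> truth cell id by majority mask overlap."""
    out = {}
    for cell in cells:
        under = truth.cell_instance_mask[cell.slices][cell.mask]
        ids, counts = np.unique(under[under > 0], return_counts=True)
        if len(ids) and counts.max() >= min_overlap * cell.mask.sum():
            out[cell.id] = int(ids[np.argmax(counts)])
    return out


def label_stalks_by_truth(
    stalks: list[StalkObject],
    truth: GroundTruthScene,
    pixel_size: float,
    min_hit_fraction: float = 0.5,
) -> list[str]:
    """keep/remove labels: does the measured skeleton trace a true stalk?"""
    dil = ndi.grey_dilation(truth.stalk_instance_mask, size=(5, 5))
    labels = []
    for stalk in stalks:
        samp = np.round(stalk.skeleton_um / pixel_size).astype(int)
        samp[:, 0] = np.clip(samp[:, 0], 0, dil.shape[0] - 1)
        samp[:, 1] = np.clip(samp[:, 1], 0, dil.shape[1] - 1)
        hits = dil[samp[:, 0], samp[:, 1]] > 0
        labels.append("keep" if hits.mean() >= min_hit_fraction else "remove")
    return labels


def train_models_from_dataset(
    pairs: Iterable[tuple[np.ndarray, GroundTruthScene]],
    config: RunConfig | None = None,
    seed: int = 11,
    cell_model_trees: int = 200,
) -> tuple[PipelineModels, dict]:
    """Train the pixel and cell-object models on (image, truth) pairs.

    Returns the models plus a training report with holdout-style
    accuracies measured against the generator truth on the training
    frames themselves (the report is descriptive; real evaluation happens
    on held-out frames).
    """
    config = config or RunConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no training images")

    hyper = config.pixel_train

    # cache candidate-pixel feature rows while the stacks stream through
    # pixel training, so the object-labelling pass below does not pay for
    # a second full feature extraction per frame
    cand_cache: list[tuple[np.ndarray, np.ndarray]] = []

    def _stacks():
        for img, _ in pairs:
            stack = extract_features(img, hyper.scales)
            idx = np.flatnonzero(candidate_mask(img).ravel())
            cand_cache.append((idx, stack.as_table()[idx].copy()))
            yield stack

    masks = (truth.semantic_mask for _, truth in pairs)
    pixel_model = train_pixel_model(_stacks(), masks, hyper, seed=seed)

    feats_rows: list[dict] = []
    labels: list[str] = []
    px = config.optics.pixel_size
    pixel_acc = []
    for (img, truth), (idx, rows) in zip(pairs, cand_cache):
        prob_map = assemble_probability_map(pixel_model, img.shape, idx, rows)
        pixel_acc.append(float((prob_map.argmax() == truth.semantic_mask).mean()))
        cells = segment_cells(prob_map, config.segmentation, px)
        stalks = segment_stalks(prob_map, config.segmentation, px)
        lap, lap_scale = focus_score_map(img)
        for cell in cells:
            cell_features(cell, img, prob_map, lap, lap_scale)
        for stalk in stalks:
            stalk_features(stalk, cells, prob_map, px)
        StalkRules().classify(stalks)
        attach_stalks_to_cells(cells, stalks, config.morpho.attach_dist_um)
        usable = [c for c in cells if "degenerate" not in c.flags]
        for cell, lab in zip(usable, label_cells_by_truth(usable, truth)):
            feats_rows.append(dict(cell.features))
            labels.append(lab)

    features = pd.DataFrame(feats_rows)
    cell_model = train_object_model(
        features, np.array(labels), target="cell",
        n_trees=cell_model_trees, seed=seed,
    )
    report = {
        "n_training_images": len(pairs),
        "mean_pixel_accuracy": float(np.mean(pixel_acc)),
        "n_training_objects": len(labels),
        "object_class_counts": pd.Series(labels).value_counts().to_dict(),
    }
    models = PipelineModels(pixel=pixel_model, cell=cell_model, stalk=StalkRules())
    return models, report
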