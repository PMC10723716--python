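"""Reference evaluation protocol on the default synthetic study conditions.

Everything here runs in memory and is shared by the test suite, the
acceptance script and the analysis drivers: train the models on a mixed
20-image training set, annotate a 20-image held-out test set (2048 x 2048
px at 0.065 µm/px, ~60 cells per field, mixture ST/SW/PD/debris =
0.50/0.35/0.10/0.05), score classification against the generator truth
acting as the expert annotator, and measure morphometric recovery,
predivisional detection, stalk-pole assignment and mixture recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from caulotype.config import OpticsConfig, RunConfig
from caulotype.morpho import medial_axis
from caulotype.pipeline import (
    PipelineModels,
    annotate_image,
    match_cells_to_truth,
    train_models_from_dataset,
)
from caulotype.popstats import anova_bonferroni
from caulotype.render import GroundTruthScene, render
from caulotype.scenes import CellSpec, SceneSpec, build_scene, circular_arc, mixture_population
from caulotype.segmentation import CellObject
from caulotype.validate import accuracy, annotation_from_truth, confusion, match_objects

#: training mix: nutrient-replete plus starved morphologies, as a
#: representative-variation training protocol
TRAIN_PRESETS = {"exponential": 10, "c_lim": 4, "p_lim": 6}

#: test mixture with a true stalked fraction of 0.70 among non-debris cells
MIXTURE_07 = mixture_population(
    {"stalked": 0.5415, "predivisional": 0.1235, "swarmer": 0.285, "debris": 0.05},
    name="mixture07",
)

TRUTH_COLLAPSE = {"stalked": "stalked", "predivisional": "stalked",
                  "swarmer": "swarmer", "debris": "debris"}


def _seeds(base_seed: int, n: int, stream: int) -> list[int]:
    state = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, stream]).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def build_default_models(
    base_seed: int = 1,
    n_train: int = 20,
    n_cells: int = 60,
    optics: OpticsConfig | None = None,
    config: RunConfig | None = None,
) -> tuple[PipelineModels, dict]:
    """Render the mixed training set and train pixel + object models."""
    optics = optics or OpticsConfig()
    config = config or RunConfig(optics=optics)
    presets: list[str] = []
    for name, count in TRAIN_PRESETS.items():
        presets.extend([name] * count)
    presets = presets[:n_train]
    seeds = _seeds(base_seed, len(presets), stream=101)
    pairs = (
        render(build_scene(p, n_cells, optics, s)) for p, s in zip(presets, seeds)
    )
    return train_models_from_dataset(pairs, config, seed=base_seed)


@dataclass
class TestSetEvaluation:
    cell_table: pd.DataFrame        # one row per matched segmented cell
    restricted_accuracy: float      # SW/ST accuracy after matching
    overall_accuracy: float
    confusion: object
    n_matched: int
    excluded_count: int
    assignment_correct: int
    assignment_total: int


def evaluate_test_set(
    models: PipelineModels,
    base_seed: int = 1,
    n_images: int = 20,
    n_cells: int = 60,
    preset: str = "test_default",
    optics: OpticsConfig | None = None,
    config: RunConfig | None = None,
) -> TestSetEvaluation:
    """Annotate held-out frames and score everything against the truth."""
    optics = optics or OpticsConfig()
    config = config or RunConfig(optics=optics)
    seeds = _seeds(base_seed, n_images, stream=202)

    rows = []
    pairs_for_confusion = []
    excluded = 0
    assign_ok = assign_tot = 0
    for seed in seeds:
        scene = build_scene(preset, n_cells, optics, seed)
        image, truth = render(scene)
        ann = annotate_image(image, models, config)
        matched = match_cells_to_truth(ann.cells, truth)
        truth_by_id = truth.records.set_index("id")
        rec_by_id = ann.records.set_index("cell_id")

        # confusion via point matching (truth acting as the expert)
        reference = annotation_from_truth(truth.records)
        pts = ann.records[["centroid_row", "centroid_col"]].to_numpy(float)
        label_map = {"SW": "Swarmer", "ST": "Stalked", "PD": "Stalked", "debris": "Debris"}
        pred_labels = [label_map[t] for t in ann.records["final_type"]]
        match = match_objects(pts, reference, max_dist_um=1.0)
        pairs_for_confusion += [
            (reference.labels[j], pred_labels[i]) for i, j in match.pairs
        ]
        excluded += match.excluded_count

        for cell in ann.cells:
            tid = matched.get(cell.id)
            if tid is None:
                continue
            trow = truth_by_id.loc[tid]
            rrow = rec_by_id.loc[cell.id]
            rows.append({
                "seed": seed,
                "cell_id": cell.id,
                "truth_id": tid,
                "true_class": TRUTH_COLLAPSE[trow["class"]],
                "true_raw_class": trow["class"],
                "pred_class": cell.class_,
                "final_type": rrow["final_type"],
                "true_length_um": trow["length_um"],
                "meas_length_um": rrow["cell_length_um"],
                "true_stalk_length_um": trow["stalk_length_um"],
                "meas_stalk_length_um": rrow["stalk_length_um"],
                "true_depth": trow["constriction_depth"],
                "degree": rrow["constriction_degree"],
                "is_pd": rrow["is_predivisional"],
            })

        ok, tot = _score_assignments(ann, matched, truth)
        assign_ok += ok
        assign_tot += tot

    matrix = confusion(pairs_for_confusion, excluded_count=excluded)
    return TestSetEvaluation(
        cell_table=pd.DataFrame(rows),
        restricted_accuracy=accuracy(matrix, restrict_to=("Swarmer", "Stalked")),
        overall_accuracy=accuracy(matrix),
        confusion=matrix,
        n_matched=len(pairs_for_confusion),
        excluded_count=excluded,
        assignment_correct=assign_ok,
        assignment_total=assign_tot,
    )


def _score_assignments(ann, matched: dict[int, int], truth: GroundTruthScene) -> tuple[int, int]:
    """Count pole-correct stalk assignments among assigned kept stalks."""
    truth_by_id = truth.records.set_index("id")
    cells_by_id = {c.id: c for c in ann.cells}
    ok = tot = 0
    for stalk in ann.stalks:
        if stalk.status != "keep" or stalk.assignment is None:
            continue
        cid, pole_name = stalk.assignment
        tid = matched.get(cid)
        if tid is None:
            continue
        trow = truth_by_id.loc[tid]
        tot += 1
        if trow["stalk_pole"] == "" or not isinstance(trow["stalk_pole"], str):
            continue  # assigned to a cell that truly has no stalk: wrong
        cell = cells_by_id[cid]
        if cell.poles_um is None:
            continue
        measured_pole = cell.poles_um[0] if pole_name == "pole1" else cell.poles_um[1]
        attach = np.array([
            trow[f"{trow['stalk_pole']}_row"], trow[f"{trow['stalk_pole']}_col"],
        ])
        other_name = "pole2" if trow["stalk_pole"] == "pole1" else "pole1"
        other = np.array([trow[f"{other_name}_row"], trow[f"{other_name}_col"]])
        if np.linalg.norm(measured_pole - attach) < np.linalg.norm(measured_pole - other):
            ok += 1
    return ok, tot


# --------------------------------------------------------------------------
# derived summary metrics


def length_recovery(table: pd.DataFrame, pixel_size: float = 0.065) -> dict:
    """Cell- and stalk-length error statistics on matched non-debris cells."""
    good = table[(table["true_raw_class"].isin(["stalked", "swarmer"]))
                 & (table["pred_class"] != "debris")
                 & np.isfinite(table["meas_length_um"])]
    err = good["meas_length_um"] - good["true_length_um"]
    tol = np.maximum(2 * pixel_size, 0.03 * good["true_length_um"])
    within = float((err.abs() <= tol).mean()) if len(good) else float("nan")

    stalked = table[(table["true_stalk_length_um"] > 0)
                    & (table["meas_stalk_length_um"] > 0)]
    rel = (stalked["meas_stalk_length_um"] - stalked["true_stalk_length_um"]) \
        / stalked["true_stalk_length_um"]
    return {
        "n_cells": int(len(good)),
        "frac_within_tolerance": within,
        "mean_signed_rel_error": float((err / good["true_length_um"]).mean()),
        "n_stalks": int(len(stalked)),
        "stalk_mean_signed_rel_error": float(rel.mean()) if len(stalked) else float("nan"),
    }


def pd_detection(table: pd.DataFrame, depth_min: float = 0.4) -> dict:
    """PD sensitivity at deep true constriction; false-PD rate on uniform rods."""
    nondebris = table[table["pred_class"] != "debris"]
    deep = nondebris[(nondebris["true_depth"] >= depth_min)]
    rods = nondebris[nondebris["true_depth"] == 0.0]
    return {
        "n_deep": int(len(deep)),
        "sensitivity": float(deep["is_pd"].mean()) if len(deep) else float("nan"),
        "n_rods": int(len(rods)),
        "false_pd_rate": float(rods["is_pd"].mean()) if len(rods) else float("nan"),
    }


def restricted_sw_st_accuracy_from_table(table: pd.DataFrame) -> float:
    """Brute-force per-pair tally, independent of the confusion-matrix path."""
    mask = table["true_class"].isin(["stalked", "swarmer"]) \
        & table["pred_class"].isin(["stalked", "swarmer"])
    sub = table[mask]
    if not len(sub):
        return float("nan")
    return float((sub["true_class"] == sub["pred_class"]).mean())


def evaluate_mixture_recovery(
    models: PipelineModels,
    base_seed: int = 1,
    n_fields: int = 10,
    n_cells: int = 200,
    optics: OpticsConfig | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Estimate the stalked fraction over fields drawn with a 0.70 truth."""
    optics = optics or OpticsConfig()
    config = config or RunConfig(optics=optics)
    seeds = _seeds(base_seed, n_fields, stream=303)
    stalked = counted = 0
    true_stalked = true_counted = 0
    for seed in seeds:
        scene = build_scene(MIXTURE_07, n_cells, optics, seed)
        image, truth = render(scene)
        ann = annotate_image(image, models, config)
        ft = ann.records["final_type"]
        stalked += int(ft.isin(["ST", "PD", "stalked"]).sum())
        counted += int((ft != "debris").sum())
        tc = truth.records["class"]
        true_stalked += int(tc.isin(["stalked", "predivisional"]).sum())
        true_counted += int((tc != "debris").sum())
    return {
        "estimated_fraction": stalked / counted if counted else float("nan"),
        "realized_true_fraction": true_stalked / true_counted,
        "target_fraction": 0.70,
        "n_counted": counted,
    }


def quarter_arc_length_error(optics: OpticsConfig | None = None) -> dict:
    """Analytic oracle: quarter-circle arc of radius 2 µm has length π µm."""
    optics = optics or OpticsConfig(frame_shape=(256, 256))
    radius = 2.0
    length = np.pi * radius / 2.0
    centerline = circular_arc(length, 1.0 / radius, n=64)
    cell = CellSpec(
        id=1, true_class="swarmer",
        centerline=centerline + np.array([8.0, 8.0]), width=0.8, curvature=1.0 / radius,
    )
    scene = SceneSpec(cells=[cell], optics=optics, seed=0, condition_preset="oracle")
    _, truth = render(scene)
    mask = truth.cell_instance_mask == 1
    sl = tuple(_bbox(mask))
    obj = CellObject(
        id=1, slices=sl, mask=mask[sl], centroid_um=np.zeros(2),
        area_um2=float(mask.sum()) * optics.pixel_size**2,
        contour_um=np.empty((0, 2)), pixel_size=optics.pixel_size,
    )
    axis = medial_axis(obj)
    return {
        "true_length_um": length,
        "measured_length_um": axis.length_um,
        "rel_error": abs(axis.length_um - length) / length,
    }


def _bbox(mask: np.ndarray) -> tuple[slice, slice]:
    rr, cc = np.nonzero(mask)
    return slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1)


def anova_null_calibration(
    n_sims: int = 1000, n_groups: int = 3, n_per_group: int = 10,
    alpha: float = 0.05, seed: int = 1,
) -> dict:
    """Type-I error of the ANOVA under the null (one shared normal)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 404]))
    hits = 0
    for _ in range(n_sims):
        groups = [rng.normal(size=n_per_group) for _ in range(n_groups)]
        res = anova_bonferroni(groups, alpha=alpha)
        hits += res.raw_p <= alpha
    return {"type_i_rate": hits / n_sims, "n_sims": n_sims, "alpha": alpha}
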