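"""Object features and cell/stalk classification."""

import numpy as np
import pandas as pd
import pytest

from caulotype.config import OpticsConfig
from caulotype.geometry import circular_arc
from caulotype.objects import (
    CELL_FEATURES,
    SENTINEL,
    CellRules,
    ObjectModel,
    StalkRules,
    cell_features,
    classify_cells,
    train_object_model,
)
from caulotype.pipeline import match_cells_to_truth
from caulotype.pixels import PixelProbabilityMap
from caulotype.render import render
from caulotype.scenes import CellSpec, SceneSpec, build_scene
from caulotype.segmentation import CellObject, segment_cells

PX = 0.065


def _cell_from_mask(mask, px=PX):
    rr, cc = np.nonzero(mask)
    sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
    return CellObject(
        id=1, slices=sl, mask=mask[sl],
        centroid_um=np.array([rr.mean(), cc.mean()]) * px,
        area_um2=float(mask.sum()) * px**2,
        contour_um=np.empty((0, 2)), pixel_size=px,
    )


def _flat_prob(shape):
    probs = np.zeros((3,) + shape, np.float32)
    probs[1] = 1.0
    return PixelProbabilityMap(probs=probs)


def test_disc_has_low_eccentricity_and_high_solidity():
    yy, xx = np.mgrid[:64, :64]
    mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 14**2
    cell = _cell_from_mask(mask)
    img = np.where(mask, 0.2, 0.8).astype(np.float32)
    feats = cell_features(cell, img, _flat_prob(mask.shape))
    assert feats["eccentricity"] < 0.15
    assert feats["solidity"] > 0.95


def test_capsule_skeleton_length_stops_inside_end_caps():
    """Raw skeleton of an extent-L capsule spans the cap centres: L - W."""
    cl = circular_arc(3.0, 0.0, n=48) + np.array([5.0, 5.0])
    cell_spec = CellSpec(id=1, true_class="swarmer", centerline=cl,
                         width=0.8, curvature=0.0)
    optics = OpticsConfig(frame_shape=(256, 256))
    scene = SceneSpec(cells=[cell_spec], optics=optics, seed=0, condition_preset="u")
    img, truth = render(scene)
    mask = truth.cell_instance_mask == 1
    cell = _cell_from_mask(mask)
    feats = cell_features(cell, img, _flat_prob(mask.shape))
    assert feats["skeleton_length_um"] == pytest.approx(3.0 - 0.8, rel=0.10)


def test_degenerate_object_flagged_and_demoted():
    mask = np.zeros((16, 16), bool)
    mask[8, 8] = True
    cell = _cell_from_mask(mask)
    feats = cell_features(cell, np.zeros((16, 16), np.float32), _flat_prob((16, 16)))
    assert cell.class_ == "debris"
    assert "degenerate" in cell.flags
    assert all(v == SENTINEL for v in feats.values())


def test_fallback_rules_stalk_length_and_focus():
    def make(feats):
        c = _cell_from_mask(np.ones((8, 8), bool))
        c.features = dict.fromkeys(CELL_FEATURES, 1.0)
        c.features.update(feats)
        return c

    rules = CellRules(stalk_length_um=0.8, debris_focus=3.0)
    stalked = make({"attached_stalk_length_um": 0.9, "focus_score": 10.0})
    swarmer = make({"attached_stalk_length_um": 0.2, "focus_score": 10.0})
    debris = make({"attached_stalk_length_um": 5.0, "focus_score": 1.0})
    rules.classify([stalked, swarmer, debris])
    assert stalked.class_ == "stalked"
    assert swarmer.class_ == "swarmer"
    assert debris.class_ == "debris"   # low focus wins regardless of stalk


def test_defocused_cell_scores_below_in_focus_population(small_models, small_config):
    """Focus scores separate rendered in-focus cells from defocused debris."""
    optics = small_config.optics
    scene = build_scene("test_default", 20, optics, seed=777)
    img, truth = render(scene)
    from caulotype.objects import focus_score_map
    from caulotype.pixels import predict_pixels

    pm = predict_pixels(small_models.pixel, img)
    cells = segment_cells(pm, small_config.segmentation, optics.pixel_size)
    lap, scale = focus_score_map(img)
    for c in cells:
        cell_features(c, img, pm, lap, scale)
    matched = match_cells_to_truth(cells, truth)
    classes = dict(zip(truth.records["id"], truth.records["class"]))
    blur = dict(zip(truth.records["id"], truth.records.get("constriction_depth", 0)))
    focus_in = [c.focus_score for c in cells
                if classes.get(matched.get(c.id)) in ("swarmer", "stalked", "predivisional")]
    defocused_ids = {
        cell.id for cell in scene.cells
        if cell.true_class == "debris" and cell.focus_blur_extra >= 3 * optics.psf_sigma
    }
    focus_out = [c.focus_score for c in cells if matched.get(c.id) in defocused_ids]
    if focus_out:   # strongly defocused debris may be dropped at the pixel stage
        assert max(focus_out) < min(focus_in)


def test_train_object_model_requires_all_classes():
    feats = pd.DataFrame({k: np.random.default_rng(0).normal(size=10)
                          for k in CELL_FEATURES})
    labels = np.array(["stalked"] * 5 + ["swarmer"] * 5)
    with pytest.raises(ValueError, match="debris"):
        train_object_model(feats, labels, target="cell")


def test_schema_mismatch_raises_versioning_error():
    rng = np.random.default_rng(0)
    feats = pd.DataFrame({k: rng.normal(size=12) for k in CELL_FEATURES})
    labels = np.array(["stalked", "swarmer", "debris"] * 4)
    model = train_object_model(feats, labels, target="cell")
    cell = _cell_from_mask(np.ones((8, 8), bool))
    cell.features = {"area_um2": 1.0}   # most features missing
    with pytest.raises(ValueError, match="missing features"):
        classify_cells(model, [cell])


def test_object_model_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    feats = pd.DataFrame({k: rng.normal(size=30) for k in CELL_FEATURES})
    labels = np.array(["stalked", "swarmer", "debris"] * 10)
    model = train_object_model(feats, labels, target="cell", seed=4)
    model.save(tmp_path / "m.joblib")
    back = ObjectModel.load(tmp_path / "m.joblib")
    assert back.feature_schema == model.feature_schema
    x = feats.iloc[:5]
    a = model.forest.predict(x.to_numpy())
    b = back.forest.predict(x.to_numpy())
    assert (a == b).all()


def test_trained_cell_model_accuracy_on_held_out_frame(
    annotated_held_out, small_models
):
    """The trained object classifier separates swarmer from stalked cells
    on a held-out synthetic frame."""
    ann, truth = annotated_held_out
    matched = match_cells_to_truth(ann.cells, truth)
    classes = dict(zip(truth.records["id"], truth.records["class"]))
    n_ok = n_tot = 0
    for cell in ann.cells:
        tid = matched.get(cell.id)
        if tid is None:
            continue
        true = {"stalked": "stalked", "predivisional": "stalked",
                "swarmer": "swarmer", "debris": "debris"}[classes[tid]]
        if true != "debris" and cell.class_ in ("stalked", "swarmer"):
            n_tot += 1
            n_ok += cell.class_ == true
    assert n_tot >= 8
    assert n_ok / n_tot >= 0.95


def test_count_conservation_after_classification(annotated_held_out):
    ann, _ = annotated_held_out
    classes = [c.class_ for c in ann.cells]
    assert all(c in ("stalked", "swarmer", "debris") for c in classes)
    n = len(classes)
    assert (classes.count("stalked") + classes.count("swarmer")
            + classes.count("debris")) == n


def test_stalk_rules_keep_requires_nearby_cell():
    from caulotype.segmentation import StalkObject

    near = StalkObject(id=1, skeleton_um=np.array([[0.0, 0.0], [0.0, 2.0]]),
                       length_um=2.0, mean_width_um=0.15)
    near.features = {"endpoint_cell_dist_um": 0.1, "mean_stalk_prob": 0.9}
    far = StalkObject(id=2, skeleton_um=np.array([[0.0, 0.0], [0.0, 2.0]]),
                      length_um=2.0, mean_width_um=0.15)
    far.features = {"endpoint_cell_dist_um": 2.0, "mean_stalk_prob": 0.9}
    StalkRules().classify([near, far])
    assert near.status == "keep"
    assert far.status == "remove" and far.assignment is None
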