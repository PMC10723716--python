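"""Object-level features and classification.

Cells are classified into {stalked, swarmer, debris}, stalks into
{keep, remove}. The default classifier is a random forest trained on
ground-truth-labelled synthetic objects; an explicit rule-based fallback
(thresholds on attached-stalk length and focus score) is provided for
deterministic tests and as a transparent baseline.

Debris is an object-level class: debris cells keep their pixels and
features, exclusion happens downstream in the population bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter as _perimeter
from skimage.morphology import convex_hull_image

from caulotype.config import CELL_CLASSES, STALK_STATUSES
from caulotype.geometry import arc_length
from caulotype.pixels import PixelProbabilityMap
from caulotype.segmentation import CellObject, StalkObject
from caulotype.skeleton import skeleton_longest_path

FORMAT_VERSION = 1
SENTINEL = -1.0

CELL_FEATURES = [
    "area_um2", "perimeter_um", "skeleton_length_um", "mean_width_um",
    "min_width_um", "solidity", "eccentricity", "mean_body_prob",
    "focus_score", "attached_stalk_count", "attached_stalk_length_um",
]
STALK_FEATURES = [
    "length_um", "mean_width_um", "straightness", "mean_stalk_prob",
    "endpoint_cell_dist_um",
]


def focus_score_map(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Laplacian-energy map and its robust background scale.

    The per-object focus score is the RMS Laplacian response inside the
    object divided by the image-wide robust (MAD) scale, so in-focus cells
    score high regardless of exposure.
    """
    img = np.asarray(image, dtype=np.float32)
    lap = ndi.laplace(ndi.gaussian_filter(img, 1.0))
    mad = np.median(np.abs(lap - np.median(lap)))
    return lap, 1.4826 * float(mad) + 1e-6


def cell_features(
    cell: CellObject,
    image: np.ndarray,
    prob_map: PixelProbabilityMap,
    lap: np.ndarray | None = None,
    lap_scale: float | None = None,
) -> dict[str, float]:
    """Geometry, intensity and focus features of one segmented cell."""
    px = cell.pixel_size
    n_px = int(cell.mask.sum())
    if n_px < 3:
        cell.flags.append("degenerate")
        cell.class_ = "debris"
        feats = {k: SENTINEL for k in CELL_FEATURES}
        cell.features.update(feats)
        return feats

    if lap is None or lap_scale is None:
        lap, lap_scale = focus_score_map(image)

    sl = cell.slices
    crop_lap = lap[sl][cell.mask]
    focus = float(np.sqrt(np.mean(crop_lap.astype(np.float64) ** 2)) / lap_scale)
    cell.focus_score = focus

    path = skeleton_longest_path(cell.mask)
    skel_len = arc_length(path.astype(float)) * px
    edt = ndi.distance_transform_edt(np.pad(cell.mask, 1))[1:-1, 1:-1]
    if len(path):
        widths = np.maximum(2.0 * (edt[tuple(path.T)] - 0.5), 1.0) * px
    else:
        widths = np.array([0.0])

    rr, cc = np.nonzero(cell.mask)
    hull_area = int(convex_hull_image(cell.mask).sum())
    solidity = n_px / hull_area if hull_area > 0 else 1.0
    ecc = _eccentricity(rr, cc)

    feats = {
        "area_um2": cell.area_um2,
        "perimeter_um": float(_perimeter(cell.mask)) * px,
        "skeleton_length_um": float(skel_len),
        "mean_width_um": float(widths.mean()),
        "min_width_um": float(widths.min()),
        "solidity": float(min(solidity, 1.0)),
        "eccentricity": float(ecc),
        "mean_body_prob": float(prob_map.probs[1][sl][cell.mask].mean()),
        "focus_score": focus,
        "attached_stalk_count": 0.0,
        "attached_stalk_length_um": 0.0,
    }
    cell.features.update(feats)
    return feats


def _eccentricity(rr: np.ndarray, cc: np.ndarray) -> float:
    pts = np.column_stack([rr, cc]).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    ev = np.linalg.eigvalsh(cov)
    a, b = np.sqrt(max(ev[1], 0.0)), np.sqrt(max(ev[0], 0.0))
    if a <= 0:
        return 0.0
    return float(np.sqrt(max(1.0 - (b / a) ** 2, 0.0)))


def stalk_features(
    stalk: StalkObject,
    cells: list[CellObject],
    prob_map: PixelProbabilityMap,
    pixel_size: float,
) -> dict[str, float]:
    """Shape and context features of one segmented stalk."""
    p1, p2 = stalk.endpoints_um
    chord = float(np.linalg.norm(p2 - p1))
    straightness = chord / stalk.length_um if stalk.length_um > 0 else 0.0

    samp = np.round(stalk.skeleton_um / pixel_size).astype(int)
    samp[:, 0] = np.clip(samp[:, 0], 0, prob_map.probs.shape[1] - 1)
    samp[:, 1] = np.clip(samp[:, 1], 0, prob_map.probs.shape[2] - 1)
    mean_prob = float(prob_map.probs[2][samp[:, 0], samp[:, 1]].mean())

    dist = np.inf
    for cell in cells:
        if len(cell.contour_um) == 0:
            continue
        for ep in (p1, p2):
            d = np.linalg.norm(cell.contour_um - ep, axis=1).min()
            dist = min(dist, float(d))
    feats = {
        "length_um": stalk.length_um,
        "mean_width_um": stalk.mean_width_um,
        "straightness": straightness,
        "mean_stalk_prob": mean_prob,
        "endpoint_cell_dist_um": dist if np.isfinite(dist) else SENTINEL,
    }
    stalk.features.update(feats)
    return feats


def attach_stalks_to_cells(
    cells: list[CellObject], stalks: list[StalkObject], attach_dist_um: float = 0.25
) -> None:
    """Fill the attached-stalk count/length features of each cell.

    A stalk counts as attached to the cell whose contour lies within
    ``attach_dist_um`` of either skeleton endpoint (closest cell wins).
    """
    for cell in cells:
        cell.features.setdefault("attached_stalk_count", 0.0)
        cell.features.setdefault("attached_stalk_length_um", 0.0)
    for stalk in stalks:
        if stalk.status == "remove":
            continue
        best, best_d = None, np.inf
        for cell in cells:
            if len(cell.contour_um) == 0:
                continue
            for ep in stalk.endpoints_um:
                d = float(np.linalg.norm(cell.contour_um - ep, axis=1).min())
                if d < best_d:
                    best, best_d = cell, d
        if best is not None and best_d <= attach_dist_um:
            best.features["attached_stalk_count"] += 1.0
            best.features["attached_stalk_length_um"] += stalk.length_um


# --------------------------------------------------------------------------
# classifiers


@dataclass
class ObjectModel:
    """Random-forest object classifier for cells or stalks."""

    forest: object
    target: str                       # "cell" | "stalk"
    feature_schema: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    format_version: int = FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self.__dict__, path)

    @classmethod
    def load(cls, path: str | Path) -> "ObjectModel":
        d = joblib.load(path)
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported object-model format: {d.get('format_version')}")
        return cls(**d)


def train_object_model(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    target: str,
    n_trees: int = 200,
    seed: int = 0,
) -> ObjectModel:
    """Fit an object classifier; every target class must be represented."""
    from sklearn.ensemble import RandomForestClassifier

    if target not in ("cell", "stalk"):
        raise ValueError("target must be 'cell' or 'stalk'")
    expected = CELL_CLASSES if target == "cell" else STALK_STATUSES
    schema = CELL_FEATURES if target == "cell" else STALK_FEATURES
    missing_cols = [c for c in schema if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table missing columns: {missing_cols}")
    y = np.asarray(labels)
    for cls in expected:
        if cls not in y:
            raise ValueError(f"class {cls!r} absent from the training labels")

    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed & 0x7FFFFFFF, n_jobs=1,
        class_weight="balanced",
    )
    forest.fit(features[list(schema)].to_numpy(dtype=np.float64), y)
    return ObjectModel(
        forest=forest, target=target, feature_schema=tuple(schema),
        classes=tuple(forest.classes_), seed=seed,
    )


def _predict(model: ObjectModel, feats: dict[str, float]) -> str:
    x = np.array([[feats[k] for k in model.feature_schema]], dtype=np.float64)
    return str(model.forest.predict(x)[0])


def classify_cells(model: ObjectModel, cells: list[CellObject]) -> list[CellObject]:
    if model.target != "cell":
        raise ValueError("model target is not 'cell'")
    for cell in cells:
        if cell.class_ == "debris" and "degenerate" in cell.flags:
            continue
        missing = [k for k in model.feature_schema if k not in cell.features]
        if missing:
            raise ValueError(f"cell {cell.id} missing features {missing}")
        cell.class_ = _predict(model, cell.features)
    return cells


def classify_stalks(model: ObjectModel, stalks: list[StalkObject]) -> list[StalkObject]:
    if model.target != "stalk":
        raise ValueError("model target is not 'stalk'")
    for stalk in stalks:
        missing = [k for k in model.feature_schema if k not in stalk.features]
        if missing:
            raise ValueError(f"stalk {stalk.id} missing features {missing}")
        stalk.status = _predict(model, stalk.features)
        if stalk.status == "remove":
            stalk.assignment = None
    return stalks


@dataclass(frozen=True)
class CellRules:
    """Deterministic fallback cell classifier.

    debris if the focus score is below ``debris_focus``; otherwise stalked
    iff the total attached stalk length reaches ``stalk_length_um``.
    """

    stalk_length_um: float = 0.8
    debris_focus: float = 3.0
    max_solidity_debris: float = 0.0   # reserved; solidity not used by default

    def classify(self, cells: list[CellObject]) -> list[CellObject]:
        for cell in cells:
            if "degenerate" in cell.flags:
                cell.class_ = "debris"
                continue
            if cell.features.get("focus_score", SENTINEL) < self.debris_focus:
                cell.class_ = "debris"
            elif cell.features.get("attached_stalk_length_um", 0.0) >= self.stalk_length_um:
                cell.class_ = "stalked"
            else:
                cell.class_ = "swarmer"
        return cells


@dataclass(frozen=True)
class StalkRules:
    """Deterministic fallback stalk filter."""

    max_endpoint_dist_um: float = 0.5
    min_mean_prob: float = 0.5

    def classify(self, stalks: list[StalkObject]) -> list[StalkObject]:
        for stalk in stalks:
            dist = stalk.features.get("endpoint_cell_dist_um", SENTINEL)
            prob = stalk.features.get("mean_stalk_prob", 1.0)
            ok = 0 <= dist <= self.max_endpoint_dist_um and prob >= self.min_mean_prob
            stalk.status = "keep" if ok else "remove"
            if stalk.status == "remove":
                stalk.assignment = None
        return stalks
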