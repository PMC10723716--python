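"""Object segmentation from pixel probability maps.

Cell bodies: threshold the body probability, fill holes, label connected
components, split touching cells with a marker-based watershed (markers =
h-maxima of the distance transform, so shallow waists such as division
constrictions do not split a cell), then apply area and border filters.

Stalks: threshold the stalk probability, thin each component to a one-pixel
skeleton, keep the longest branch as the stalk polyline (which prunes side
spurs), extend its ends to the mask boundary, and filter on length and
mean width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from caulotype.config import SegmentationConfig
from caulotype.geometry import arc_length
from caulotype.pixels import PixelProbabilityMap
from caulotype.skeleton import extend_to_boundary, skeleton_longest_path, smooth_path


@dataclass
class CellObject:
    """A segmented cell-body instance (class assigned downstream)."""

    id: int
    slices: tuple[slice, slice]        # bounding box in the frame
    mask: np.ndarray                   # bool crop within the bounding box
    centroid_um: np.ndarray            # (row, col) µm
    area_um2: float
    contour_um: np.ndarray             # closed polyline, µm
    pixel_size: float
    class_: Optional[str] = None       # stalked | swarmer | debris
    focus_score: Optional[float] = None
    features: dict = field(default_factory=dict)
    poles_um: Optional[tuple[np.ndarray, np.ndarray]] = None
    flags: list[str] = field(default_factory=list)

    @property
    def offset_px(self) -> np.ndarray:
        return np.array([self.slices[0].start, self.slices[1].start], dtype=float)


@dataclass
class StalkObject:
    """A segmented stalk instance."""

    id: int
    skeleton_um: np.ndarray            # polyline, µm
    length_um: float
    mean_width_um: float
    status: Optional[str] = None       # keep | remove
    assignment: Optional[tuple[int, str]] = None  # (cell id, pole1|pole2)
    features: dict = field(default_factory=dict)

    @property
    def endpoints_um(self) -> tuple[np.ndarray, np.ndarray]:
        return self.skeleton_um[0], self.skeleton_um[-1]


def _label_cells(prob_map: PixelProbabilityMap, params: SegmentationConfig, px: float) -> np.ndarray:
    """Label body components, splitting touching cells per component.

    Watershed markers are the h-maxima of the distance transform: a waist
    must be at least ``0.3 * watershed_min_separation_um`` shallower than
    its flanking lobes to split, so division constrictions stay one cell
    while genuinely touching cells separate. All morphology runs on
    per-component crops; only components with multiple markers pay for a
    watershed.
    """
    body = prob_map.probs[1] >= params.body_prob_threshold
    body = ndi.binary_fill_holes(body)
    struct = np.ones((3, 3)) if params.connectivity == 2 else None
    labels, n = ndi.label(body, structure=struct)
    if n == 0:
        return labels

    h = 0.30 * params.watershed_min_separation_um
    out = labels.copy()
    next_label = n + 1
    for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        if sl is None:
            continue
        crop = labels[sl] == lab
        dist = ndi.distance_transform_edt(np.pad(crop, 1), sampling=px)[1:-1, 1:-1]
        rec = reconstruction(np.clip(dist - h, 0, None), dist, method="dilation")
        maxima = local_maxima(rec, connectivity=2) & crop
        markers, n_markers = ndi.label(maxima, structure=np.ones((3, 3)))
        if n_markers <= 1:
            continue
        elevation = -ndi.gaussian_filter(prob_map.probs[1][sl], 1.0)
        split = watershed(elevation, markers=markers, mask=crop,
                          connectivity=params.connectivity)
        view = out[sl]
        for m in range(2, n_markers + 1):
            view[(split == m) & crop] = next_label
            next_label += 1
        crumbs = crop & (split == 0)
        if crumbs.any():
            extra, n_extra = ndi.label(crumbs, structure=struct)
            for m in range(1, n_extra + 1):
                view[extra == m] = next_label
                next_label += 1
    return out


def segment_cells(
    prob_map: PixelProbabilityMap,
    params: SegmentationConfig | None = None,
    pixel_size: float = 0.065,
) -> list[CellObject]:
    """Segment unclassified cell-body objects from a probability map."""
    params = params or SegmentationConfig()
    px = pixel_size
    labels = _label_cells(prob_map, params, px)
    if labels.max() == 0:
        return []

    min_px = params.min_cell_area_um2 / px**2
    objects: list[CellObject] = []
    next_id = 1
    for sl, lab in zip(ndi.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        crop = labels[sl] == lab
        area_px = int(crop.sum())
        if area_px < min_px:
            continue
        if params.exclude_border:
            touches = (
                sl[0].start == 0 or sl[1].start == 0
                or sl[0].stop == labels.shape[0] or sl[1].stop == labels.shape[1]
            )
            if touches:
                continue
        rr, cc = np.nonzero(crop)
        offset = np.array([sl[0].start, sl[1].start], dtype=float)
        centroid = (np.array([rr.mean(), cc.mean()]) + offset) * px
        padded = np.pad(crop, 1)
        contours = find_contours(padded.astype(float), 0.5)
        contour = max(contours, key=len) if contours else np.empty((0, 2))
        contour_um = (np.asarray(contour) - 1.0 + offset) * px
        objects.append(
            CellObject(
                id=next_id,
                slices=sl,
                mask=crop,
                centroid_um=centroid,
                area_um2=area_px * px**2,
                contour_um=contour_um,
                pixel_size=px,
            )
        )
        next_id += 1
    return objects


def segment_stalks(
    prob_map: PixelProbabilityMap,
    params: SegmentationConfig | None = None,
    pixel_size: float = 0.065,
) -> list[StalkObject]:
    """Segment stalk objects (keep/remove status assigned downstream)."""
    params = params or SegmentationConfig()
    px = pixel_size
    stalk = prob_map.probs[2] >= params.stalk_prob_threshold
    struct = np.ones((3, 3)) if params.connectivity == 2 else None
    labels, n = ndi.label(stalk, structure=struct)
    if n == 0:
        return []

    edt = ndi.distance_transform_edt(stalk, sampling=px)
    out: list[StalkObject] = []
    next_id = 1
    for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        if sl is None:
            continue
        crop = labels[sl] == lab
        path = skeleton_longest_path(crop)
        if len(path) < 2:
            continue
        sm = smooth_path(path, window=5)
        sm = extend_to_boundary(sm, crop)
        offset = np.array([sl[0].start, sl[1].start], dtype=float)
        poly_um = (sm + offset) * px
        length = arc_length(poly_um)
        if length < params.min_stalk_length_um:
            continue
        samp = (np.clip(np.round(path), 0, None).astype(int))
        vals = edt[samp[:, 0] + int(offset[0]), samp[:, 1] + int(offset[1])]
        widths = np.maximum(2.0 * (vals - 0.5 * px), px)
        mean_width = float(widths.mean()) if len(widths) else 0.0
        if mean_width > params.max_stalk_mean_width_um:
            continue
        out.append(
            StalkObject(
                id=next_id,
                skeleton_um=poly_um,
                length_um=float(length),
                mean_width_um=mean_width,
            )
        )
        next_id += 1
    return out
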