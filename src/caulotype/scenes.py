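"""Scene construction: sample cell populations and place them in a field.

A scene is a list of :class:`CellSpec` (cell bodies as constant-width
capsules along circular-arc centerlines, optional polar stalks, optional
mid-cell constriction) plus the optics used to render it. Class mixtures
and per-class morphology distributions come from named condition presets
emulating nutrient-replete growth, carbon/nitrogen starvation (shorter,
swarmer-enriched populations) and phosphate starvation (filamentous cells
with dramatically elongated stalks, virtually all stalked).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from caulotype.config import OpticsConfig
from caulotype.geometry import (
    arc_length,
    circular_arc,
    polyline_tangents,
    resample_polyline,
    transform,
    trim_polyline,
)

SWARMER = "swarmer"
STALKED = "stalked"
PREDIVISIONAL = "predivisional"
DEBRIS = "debris"
TRUE_CLASSES = (STALKED, SWARMER, PREDIVISIONAL, DEBRIS)

STALK_WIDTH_UM = 0.15


class PlacementError(RuntimeError):
    """Raised when a scene cannot fit the requested number of cells."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved} of {requested} cells without violating "
            f"the overlap tolerance; frame too small or population too dense"
        )


@dataclass(frozen=True)
class StalkSpec:
    pole: str                 # "pole1" | "pole2"
    polyline: np.ndarray      # (N, 2) µm, starts at the pole
    width: float = STALK_WIDTH_UM

    @property
    def length(self) -> float:
        return arc_length(self.polyline)


@dataclass(frozen=True)
class CellSpec:
    id: int
    true_class: str
    centerline: np.ndarray    # (N, 2) µm, pole to pole
    width: float
    curvature: float
    constriction_depth: float = 0.0
    constriction_position: float = 0.5   # fraction of arc length
    stalk: Optional[StalkSpec] = None
    focus_blur_extra: float = 0.0        # µm; >0 marks out-of-focus debris

    def __post_init__(self) -> None:
        if self.true_class not in TRUE_CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.true_class == SWARMER and self.stalk is not None:
            raise ValueError("swarmer cells carry no stalk")
        if self.true_class in (STALKED, PREDIVISIONAL) and self.stalk is None:
            raise ValueError(f"{self.true_class} cells require a stalk")
        if self.true_class != DEBRIS and arc_length(self.centerline) <= self.width:
            raise ValueError("centerline arc length must exceed width")

    @property
    def length(self) -> float:
        """Pole-to-pole cell length (µm) = centerline arc length."""
        return arc_length(self.centerline)

    @property
    def poles(self) -> tuple[np.ndarray, np.ndarray]:
        return self.centerline[0].copy(), self.centerline[-1].copy()

    def width_profile(self, s: np.ndarray) -> np.ndarray:
        """Width (µm) at arc-length positions ``s`` along the *trimmed* body.

        Constriction is a Gaussian-profile width reduction centred at
        ``constriction_position`` of the full arc length.
        """
        w = np.full_like(s, self.width, dtype=float)
        if self.constriction_depth > 0:
            s0 = self.constriction_position * self.length
            sigma = 0.22  # µm, waist half-width of the septum profile
            w *= 1.0 - self.constriction_depth * np.exp(-((s - s0) ** 2) / (2 * sigma**2))
        return w


@dataclass
class SceneSpec:
    cells: list[CellSpec]
    optics: OpticsConfig
    seed: int
    condition_preset: str = "custom"


# --------------------------------------------------------------------------
# population presets


@dataclass(frozen=True)
class Trunc:
    """Truncated-normal parameters (mean, sd, lo, hi)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            for _ in range(1000):
                x = rng.normal(self.mean, self.sd)
                if self.lo <= x <= self.hi:
                    out[i] = x
                    break
            else:  # pragma: no cover - pathological bounds
                out[i] = np.clip(self.mean, self.lo, self.hi)
        return out


@dataclass(frozen=True)
class MorphPreset:
    length: Trunc
    width: Trunc = Trunc(0.78, 0.05, 0.65, 0.92)
    curvature: Trunc = Trunc(0.30, 0.12, 0.0, 0.65)
    stalk_length: Optional[Trunc] = None
    constriction_depth: Optional[Trunc] = None
    constriction_position: Trunc = Trunc(0.5, 0.03, 0.42, 0.58)


@dataclass(frozen=True)
class PopulationParams:
    """Class mixture plus per-class morphology distributions."""

    mixture: dict[str, float]
    morphs: dict[str, MorphPreset]
    name: str = "custom"

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, not 1")
        for cls in self.mixture:
            if cls not in TRUE_CLASSES:
                raise ValueError(f"unknown class {cls!r} in mixture")


_EXPO_ST = MorphPreset(
    length=Trunc(2.6, 0.4, 1.7, 4.0),
    stalk_length=Trunc(1.2, 0.5, 0.6, 3.0),
)
_EXPO_SW = MorphPreset(length=Trunc(1.9, 0.3, 1.3, 2.8))
_EXPO_PD = MorphPreset(
    length=Trunc(3.2, 0.4, 2.4, 4.4),
    stalk_length=Trunc(1.2, 0.5, 0.6, 3.0),
    constriction_depth=Trunc(0.50, 0.10, 0.30, 0.75),
)
_DEBRIS = MorphPreset(length=Trunc(1.6, 0.5, 0.9, 3.0))


def _scaled(m: MorphPreset, f: float) -> MorphPreset:
    sl = m.stalk_length
    return replace(
        m,
        length=Trunc(m.length.mean * f, m.length.sd * f, m.length.lo * f, m.length.hi * f),
        stalk_length=None if sl is None else Trunc(sl.mean * f, sl.sd * f, sl.lo * f, sl.hi * f),
    )


def _population(name: str, mixture: dict[str, float], morphs: dict[str, MorphPreset]) -> PopulationParams:
    return PopulationParams(mixture=mixture, morphs=morphs, name=name)


_EXPO_MORPHS = {STALKED: _EXPO_ST, SWARMER: _EXPO_SW, PREDIVISIONAL: _EXPO_PD, DEBRIS: _DEBRIS}

PRESETS: dict[str, PopulationParams] = {
    # nutrient-replete exponential growth: ~70% stalked (ST + PD)
    "exponential": _population(
        "exponential",
        {STALKED: 0.50, SWARMER: 0.35, PREDIVISIONAL: 0.10, DEBRIS: 0.05},
        _EXPO_MORPHS,
    ),
    # C/N starvation: swarmer accumulation, ~15% shorter cells
    "c_lim": _population(
        "c_lim",
        {STALKED: 0.40, SWARMER: 0.48, PREDIVISIONAL: 0.07, DEBRIS: 0.05},
        {k: _scaled(m, 0.85) for k, m in _EXPO_MORPHS.items()},
    ),
    # P starvation: filamentous, long-stalked, virtually all stalked
    "p_lim": _population(
        "p_lim",
        {STALKED: 0.88, SWARMER: 0.0, PREDIVISIONAL: 0.07, DEBRIS: 0.05},
        {
            STALKED: MorphPreset(
                length=Trunc(4.5, 1.5, 2.5, 9.0),
                curvature=Trunc(0.20, 0.10, 0.0, 0.45),
                stalk_length=Trunc(8.0, 3.0, 3.0, 16.0),
            ),
            SWARMER: _EXPO_SW,
            PREDIVISIONAL: MorphPreset(
                length=Trunc(5.0, 1.5, 3.0, 9.0),
                curvature=Trunc(0.20, 0.10, 0.0, 0.45),
                stalk_length=Trunc(8.0, 3.0, 3.0, 16.0),
                constriction_depth=Trunc(0.50, 0.10, 0.30, 0.75),
            ),
            DEBRIS: _DEBRIS,
        },
    ),
}
PRESETS["n_lim"] = replace(PRESETS["c_lim"], name="n_lim")
#: default synthetic test mixture (same as exponential growth)
PRESETS["test_default"] = replace(PRESETS["exponential"], name="test_default")


def mixture_population(mixture: dict[str, float], name: str = "custom") -> PopulationParams:
    """Exponential-morphology population with a custom class mixture."""
    return _population(name, mixture, _EXPO_MORPHS)


# --------------------------------------------------------------------------
# scene building


def _sample_stalk(
    rng: np.random.Generator,
    centerline: np.ndarray,
    length: float,
    pole: str,
) -> StalkSpec:
    """Grow a gently wandering stalk outward from a pole."""
    tangents = polyline_tangents(centerline)
    if pole == "pole1":
        origin, direction = centerline[0], -tangents[0]
    else:
        origin, direction = centerline[-1], tangents[-1]
    step = 0.2
    n = max(int(np.ceil(length / step)), 2)
    angle = float(np.arctan2(direction[0], direction[1]))
    drift = rng.normal(0.0, 0.04)            # constant bend per step
    pts = [origin.copy()]
    remaining = length
    while remaining > 0:
        d = min(step, remaining)
        angle += drift + rng.normal(0.0, 0.05)
        pts.append(pts[-1] + d * np.array([np.sin(angle), np.cos(angle)]))
        remaining -= d
    poly = np.asarray(pts)
    # rescale to the exact requested arc length
    poly = origin + (poly - origin) * (length / max(arc_length(poly), 1e-9))
    return StalkSpec(pole=pole, polyline=poly, width=STALK_WIDTH_UM)


def _sample_cell(
    rng: np.random.Generator, cid: int, true_class: str, morph: MorphPreset, psf_sigma: float
) -> CellSpec:
    length = float(morph.length.sample(rng)[0])
    width = float(morph.width.sample(rng)[0])
    length = max(length, width * 1.3)
    curvature = float(morph.curvature.sample(rng)[0]) * rng.choice([-1.0, 1.0])
    centerline = circular_arc(length, curvature, n=max(int(length / 0.1), 8))

    depth, pos = 0.0, 0.5
    if true_class == PREDIVISIONAL and morph.constriction_depth is not None:
        depth = float(morph.constriction_depth.sample(rng)[0])
        pos = float(morph.constriction_position.sample(rng)[0])

    stalk = None
    if true_class in (STALKED, PREDIVISIONAL) and morph.stalk_length is not None:
        slen = float(morph.stalk_length.sample(rng)[0])
        pole = str(rng.choice(["pole1", "pole2"]))
        stalk = _sample_stalk(rng, centerline, slen, pole)

    blur_extra = 0.0
    if true_class == DEBRIS:
        if rng.random() < 0.5:
            # defocused cell-like object
            blur_extra = float(rng.uniform(3.0, 6.0)) * psf_sigma
        else:
            # small lysed fragment / blob
            length = float(rng.uniform(0.9, 1.8))
            width = float(rng.uniform(0.55, 0.85))
            length = max(length, width * 1.2)
            centerline = circular_arc(length, float(rng.uniform(-0.5, 0.5)), n=12)
            blur_extra = float(rng.uniform(0.5, 2.0)) * psf_sigma

    return CellSpec(
        id=cid,
        true_class=true_class,
        centerline=centerline,
        width=width,
        curvature=curvature,
        constriction_depth=depth,
        constriction_position=pos,
        stalk=stalk,
        focus_blur_extra=blur_extra,
    )


def _body_samples(cell: CellSpec) -> tuple[np.ndarray, np.ndarray]:
    """Coarse samples of the trimmed centerline and their radii, for overlap tests."""
    trimmed = trim_polyline(cell.centerline, cell.width / 2.0)
    pts = resample_polyline(trimmed, 0.15)
    return pts, np.full(len(pts), cell.width / 2.0)


def _geometry_extent(cell: CellSpec) -> np.ndarray:
    pts = [cell.centerline]
    if cell.stalk is not None:
        pts.append(cell.stalk.polyline)
    return np.vstack(pts)


def build_scene(
    population_params: PopulationParams | str,
    n_cells: int,
    optics: OpticsConfig | None = None,
    seed: int = 0,
    overlap_gap_um: float = 0.25,
    margin_um: float = 0.4,
    max_attempts: int = 300,
) -> SceneSpec:
    """Sample a reproducible scene of ``n_cells`` placed without body overlap.

    Class counts are multinomial draws from the mixture; each cell's
    geometry is sampled from its class preset and placed by rejection
    sampling so that no two non-debris bodies come closer than
    ``overlap_gap_um`` and all geometry stays ``margin_um`` inside the
    frame. Identical ``(params, n_cells, optics, seed)`` give identical
    scenes.
    """
    if isinstance(population_params, str):
        population_params = PRESETS[population_params]
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)

    classes = [c for c in TRUE_CLASSES if c in population_params.mixture]
    probs = np.array([population_params.mixture[c] for c in classes])
    counts = rng.multinomial(n_cells, probs) if n_cells else np.zeros(len(classes), int)

    order: list[str] = []
    for cls, k in zip(classes, counts):
        order.extend([cls] * int(k))
    rng.shuffle(order)

    field_rows, field_cols = optics.field_size_um
    placed: list[CellSpec] = []
    occ_pts: list[np.ndarray] = []
    occ_rad: list[np.ndarray] = []

    for i, cls in enumerate(order):
        proto = _sample_cell(rng, i + 1, cls, population_params.morphs[cls], optics.psf_sigma)
        ok = False
        for _ in range(max_attempts):
            angle = rng.uniform(0, 2 * np.pi)
            ext = transform(_geometry_extent(proto), angle, np.zeros(2))
            lo_off = margin_um - ext.min(axis=0)
            hi_off = np.array([field_rows, field_cols]) - margin_um - ext.max(axis=0)
            if np.any(hi_off <= lo_off):
                continue
            offset = rng.uniform(lo_off, hi_off)
            cand = _place(proto, angle, offset)
            if _fits(cand, occ_pts, occ_rad, overlap_gap_um):
                stalk_ok = True
                if cand.stalk is not None and occ_pts:
                    d = _min_dist(cand.stalk.polyline, occ_pts, occ_rad)
                    stalk_ok = d > cand.stalk.width / 2.0 + 0.05
                if stalk_ok:
                    placed.append(cand)
                    pts, rad = _body_samples(cand)
                    if cand.true_class != DEBRIS:
                        occ_pts.append(pts)
                        occ_rad.append(rad)
                    ok = True
                    break
        if not ok:
            raise PlacementError(requested=n_cells, achieved=len(placed))

    return SceneSpec(
        cells=placed, optics=optics, seed=seed, condition_preset=population_params.name
    )


def _place(cell: CellSpec, angle: float, offset: np.ndarray) -> CellSpec:
    centerline = transform(cell.centerline, angle, offset)
    stalk = cell.stalk
    if stalk is not None:
        stalk = replace(stalk, polyline=transform(stalk.polyline, angle, offset))
    return replace(cell, centerline=centerline, stalk=stalk)


def _min_dist(poly: np.ndarray, occ_pts: list[np.ndarray], occ_rad: list[np.ndarray]) -> float:
    pts = resample_polyline(poly, 0.15)
    allp = np.vstack(occ_pts)
    allr = np.concatenate(occ_rad)
    d = np.linalg.norm(pts[:, None, :] - allp[None, :, :], axis=2) - allr[None, :]
    return float(d.min())


def _fits(
    cell: CellSpec,
    occ_pts: list[np.ndarray],
    occ_rad: list[np.ndarray],
    gap: float,
) -> bool:
    if not occ_pts:
        return True
    pts, rad = _body_samples(cell)
    allp = np.vstack(occ_pts)
    allr = np.concatenate(occ_rad)
    d = np.linalg.norm(pts[:, None, :] - allp[None, :, :], axis=2)
    clearance = d - rad[:, None] - allr[None, :]
    return float(clearance.min()) > gap
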