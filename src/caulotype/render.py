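"""Phase-contrast rendering of scenes and ground-truth rasterization.

The optical model is deliberately simple but captures what the downstream
pipeline must cope with: dark cell bodies, fainter sub-resolution stalks,
a bright halo ring (difference-of-Gaussians approximation to the phase
ring), per-object defocus for debris, low-order illumination shading, and
signal-dependent (photon) plus additive (read) sensor noise.

Ground-truth masks are the noise-free rasterizations of the nominal
geometry; truth records carry the analytic polyline lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from caulotype.config import U16_MAX, OpticsConfig
from caulotype.geometry import cumulative_length, rasterize_tube, trim_polyline
from caulotype.scenes import PRESETS, SceneSpec, build_scene

logger = logging.getLogger(__name__)

SEMANTIC_BACKGROUND, SEMANTIC_BODY, SEMANTIC_STALK = 0, 1, 2

RECORD_COLUMNS = [
    "id", "class", "length_um", "stalk_length_um", "stalk_pole",
    "constriction_depth",
    "pole1_row", "pole1_col", "pole2_row", "pole2_col",
]


@dataclass
class GroundTruthScene:
    """Noise-free truth for one rendered field."""

    semantic_mask: np.ndarray        # uint8: 0 background, 1 cell body, 2 stalk
    cell_instance_mask: np.ndarray   # int32: cell id, 0 = none
    stalk_instance_mask: np.ndarray  # int32: owning cell id, 0 = none
    records: pd.DataFrame            # one row per cell, RECORD_COLUMNS


def _body_tube(cell, pixel_size, shape, soft):
    trimmed = trim_polyline(cell.centerline, cell.width / 2.0)
    s = cumulative_length(trimmed) + cell.width / 2.0
    radii = cell.width_profile(s) / 2.0
    radii = np.maximum(radii, pixel_size / 2.0)
    return rasterize_tube(trimmed, radii, pixel_size, shape, soft=soft)


def render(scene: SceneSpec) -> tuple[np.ndarray, GroundTruthScene]:
    """Render a scene to a 16-bit micrograph plus its ground truth.

    Reproducible: the noise stream is derived from ``scene.seed`` only.
    """
    optics = scene.optics
    shape = optics.frame_shape
    px = optics.pixel_size

    # densities per defocus group: blur_extra (µm) -> (body, stalk)
    groups: dict[float, list[np.ndarray]] = {}
    semantic = np.zeros(shape, dtype=np.uint8)
    cell_inst = np.zeros(shape, dtype=np.int32)
    stalk_inst = np.zeros(shape, dtype=np.int32)
    records = []

    for cell in scene.cells:
        key = round(cell.focus_blur_extra, 3)
        if key not in groups:
            groups[key] = [np.zeros(shape, np.float32), np.zeros(shape, np.float32)]
        body_d, stalk_d = groups[key]

        patch, win = _body_tube(cell, px, shape, soft=True)
        if patch.size:
            np.maximum(body_d[win], patch, out=body_d[win])
            hard = patch >= 0.5
            sub = semantic[win]
            sub[hard] = SEMANTIC_BODY
            ci = cell_inst[win]
            ci[hard & (ci == 0)] = cell.id

        stalk_len = 0.0
        if cell.stalk is not None:
            stalk_len = cell.stalk.length
            # extent-L convention, as for bodies: trim by the radius so the
            # rasterized stalk's tip-to-tip extent equals the polyline length
            stalk_cl = trim_polyline(cell.stalk.polyline, cell.stalk.width / 2.0)
            spatch, swin = rasterize_tube(
                stalk_cl, cell.stalk.width / 2.0, px, shape, soft=True
            )
            if spatch.size:
                np.maximum(stalk_d[swin], spatch, out=stalk_d[swin])
                shard = spatch >= 0.5
                sub = semantic[swin]
                place = shard & (sub != SEMANTIC_BODY)
                sub[place] = SEMANTIC_STALK
                si = stalk_inst[swin]
                si[place & (si == 0)] = cell.id

        p1, p2 = cell.poles
        records.append({
            "id": cell.id,
            "class": cell.true_class,
            "length_um": cell.length,
            "stalk_length_um": stalk_len,
            "stalk_pole": cell.stalk.pole if cell.stalk is not None else "",
            "constriction_depth": cell.constriction_depth,
            "pole1_row": p1[0], "pole1_col": p1[1],
            "pole2_row": p2[0], "pole2_col": p2[1],
        })

    blurred = np.zeros(shape, np.float32)
    halo = np.zeros(shape, np.float32)
    for extra, (body_d, stalk_d) in groups.items():
        density = np.maximum(body_d, optics.stalk_contrast_fraction * stalk_d)
        sig_psf = np.hypot(optics.psf_sigma, extra) / px
        sig_halo = np.hypot(optics.halo_sigma, extra) / px
        blurred += ndi.gaussian_filter(density, sig_psf)
        halo += ndi.gaussian_filter(density, sig_halo)

    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed) & 0x7FFFFFFF, 2113]))

    rows = (np.arange(shape[0]) / max(shape[0] - 1, 1)) - 0.5
    cols = (np.arange(shape[1]) / max(shape[1] - 1, 1)) - 0.5
    direction = rng.normal(size=2)
    direction /= np.linalg.norm(direction)
    shading = 1.0 + optics.illumination_gradient * 2.0 * (
        direction[0] * rows[:, None] + direction[1] * cols[None, :]
    )

    signal = (
        optics.background_level * shading
        - optics.cell_contrast * blurred
        + optics.halo_amplitude * optics.cell_contrast * halo
    )
    signal = np.clip(signal, 0.0, None)
    noise_sd = np.sqrt(optics.photon_noise_scale**2 * signal + optics.read_noise_sd**2)
    noisy = signal + rng.standard_normal(shape).astype(np.float32) * noise_sd

    n_clipped = int(np.count_nonzero((noisy < 0) | (noisy > U16_MAX)))
    if n_clipped:
        logger.warning("render: clipped %d pixels to the 16-bit range", n_clipped)
    image = np.clip(noisy, 0, U16_MAX).astype(np.uint16)

    truth = GroundTruthScene(
        semantic_mask=semantic,
        cell_instance_mask=cell_inst,
        stalk_instance_mask=stalk_inst,
        records=pd.DataFrame(records, columns=RECORD_COLUMNS),
    )
    return image, truth


# --------------------------------------------------------------------------
# dataset generation


def make_dataset(
    out_dir: str | Path,
    presets: dict[str, int] | str,
    n_cells: int = 60,
    optics: OpticsConfig | None = None,
    base_seed: int = 0,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Render a reproducible dataset of image/mask/record triples to disk.

    ``presets`` maps condition-preset names to image counts (a bare name
    means every image uses that preset — pass ``{"exponential": 72}`` for a
    72-image training-style set). Per-image seeds derive from ``base_seed``.
    Returns the manifest (also written as ``manifest.csv``).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(presets, str):
        presets = {presets: 1}

    n_images = sum(presets.values())
    seeds = [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(base_seed).generate_state(n_images)]
    optics = optics or OpticsConfig()

    rows = []
    idx = 0
    for preset_name, count in presets.items():
        for _ in range(count):
            seed = seeds[idx]
            stem = f"img_{idx:03d}"
            scene = build_scene(PRESETS[preset_name], n_cells, optics, seed)
            image, truth = render(scene)
            save_image(out / f"{stem}.tif", image)
            save_mask(out / f"{stem}_semantic.tif", truth.semantic_mask)
            save_mask(out / f"{stem}_cells.tif", truth.cell_instance_mask)
            save_mask(out / f"{stem}_stalks.tif", truth.stalk_instance_mask)
            rec = truth.records.copy()
            rec["seed"] = seed
            rec["preset"] = preset_name
            rec.to_csv(out / f"{stem}_records.csv", index=False)
            rows.append({
                "stem": stem, "preset": preset_name, "seed": seed,
                "n_cells": len(scene.cells),
            })
            idx += 1

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def save_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), image.astype(np.uint16))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), mask.astype(np.int32))


def load_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def load_truth(directory: str | Path, stem: str) -> GroundTruthScene:
    d = Path(directory)
    return GroundTruthScene(
        semantic_mask=tifffile.imread(str(d / f"{stem}_semantic.tif")).astype(np.uint8),
        cell_instance_mask=tifffile.imread(str(d / f"{stem}_cells.tif")).astype(np.int32),
        stalk_instance_mask=tifffile.imread(str(d / f"{stem}_stalks.tif")).astype(np.int32),
        records=pd.read_csv(d / f"{stem}_records.csv"),
    )
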