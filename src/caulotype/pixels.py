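"""Random-forest pixel classification: background / cell body / stalk.

Training subsamples a balanced set of pixels per class. Sampling is keyed
to each image's content digest (not its position in the list), and images
are pooled in digest order, so permuting the training set leaves the model
— and therefore all predictions — unchanged.

Prediction uses a background prescreen: pixels whose locally smoothed
intensity sits within the noise band of a large-scale background estimate
are assigned background directly, and the forest is evaluated only on the
remaining candidate pixels (a generously dilated superset of everything
with contrast, including halos and defocused debris). This keeps per-frame
prediction tractable without touching the decision function on any pixel
that could plausibly be foreground.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import joblib
import numpy as np
import tifffile
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from caulotype.config import SEMANTIC_CLASSES, PixelTrainConfig
from caulotype.features import FeatureStack, extract_features, large_scale_background

FORMAT_VERSION = 1


@dataclass
class PixelProbabilityMap:
    """Per-pixel class probabilities, class axis ordered as ``class_names``."""

    probs: np.ndarray             # (3, rows, cols) float32, sums to 1 per pixel
    class_names: tuple[str, ...] = SEMANTIC_CLASSES

    def argmax(self) -> np.ndarray:
        """Per-pixel winning class index; ties break toward the lower index
        (background < cell body < stalk)."""
        return np.argmax(self.probs, axis=0).astype(np.uint8)

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.probs.astype(np.float32),
                         photometric="minisblack")

    @classmethod
    def load(cls, path: str | Path) -> "PixelProbabilityMap":
        return cls(probs=tifffile.imread(str(path)).astype(np.float32))


@dataclass
class PixelModel:
    forest: RandomForestClassifier
    scales: tuple[float, ...]
    class_order: tuple[str, ...]
    seed: int
    hyper: PixelTrainConfig
    training_hash: str
    format_version: int = FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": self.format_version,
                "class_order": self.class_order,
                "scales": self.scales,
                "seed": self.seed,
                "hyper": self.hyper,
                "training_hash": self.training_hash,
                "forest": self.forest,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PixelModel":
        d = joblib.load(path)
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported pixel-model format: {d.get('format_version')}")
        return cls(
            forest=d["forest"], scales=tuple(d["scales"]),
            class_order=tuple(d["class_order"]), seed=d["seed"],
            hyper=d["hyper"], training_hash=d["training_hash"],
        )


def _digest(stack: FeatureStack, mask: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(stack.channels[0]).tobytes())
    h.update(np.ascontiguousarray(mask).tobytes())
    return h.hexdigest()


def _sample_image(
    stack: FeatureStack, mask: np.ndarray, cap_per_image: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced per-image pixel sample; background is drawn half from the
    dilated neighbourhood of foreground (halo pixels are the hard negatives)."""
    table = stack.as_table()
    flat = mask.ravel()
    xs, ys = [], []
    near_fg = ndi.binary_dilation(mask > 0, iterations=1, structure=np.ones((3, 3)))
    near_fg = ndi.maximum_filter(near_fg, size=15).ravel()
    for label in range(len(SEMANTIC_CLASSES)):
        idx = np.flatnonzero(flat == label)
        if len(idx) == 0:
            continue
        if label == 0:
            halo = np.flatnonzero((flat == 0) & near_fg)
            far = np.flatnonzero((flat == 0) & ~near_fg)
            take_halo = min(len(halo), cap_per_image // 2)
            take_far = min(len(far), cap_per_image - take_halo)
            chosen = np.concatenate([
                rng.choice(halo, take_halo, replace=False) if take_halo else np.empty(0, int),
                rng.choice(far, take_far, replace=False) if take_far else np.empty(0, int),
            ]).astype(int)
        else:
            chosen = rng.choice(idx, min(len(idx), cap_per_image), replace=False)
        xs.append(table[chosen])
        ys.append(np.full(len(chosen), label, dtype=np.int64))
    if not xs:
        return np.empty((0, stack.n_channels), np.float32), np.empty(0, np.int64)
    return np.vstack(xs), np.concatenate(ys)


def train_pixel_model(
    stacks: Iterable[FeatureStack],
    semantic_masks: Iterable[np.ndarray],
    hyper: PixelTrainConfig | None = None,
    seed: int | None = None,
) -> PixelModel:
    """Fit the three-class pixel forest on balanced subsamples.

    ``stacks``/``semantic_masks`` may be lazy iterables; each stack is
    sampled and released before the next is materialized.
    """
    hyper = hyper or PixelTrainConfig()
    seed = hyper.seed if seed is None else seed

    # oversample per image, then trim to the pooled cap after the count is
    # known; stacks are sampled as they stream so only one stays resident
    raw: list[tuple[str, dict[int, tuple[np.ndarray, np.ndarray]]]] = []
    scales: tuple[float, ...] | None = None
    for stack, mask in zip(stacks, semantic_masks):
        if stack.channels.shape[1:] != mask.shape:
            raise ValueError("feature stack and semantic mask shapes differ")
        if scales is None:
            scales = stack.scales
        elif stack.scales != scales:
            raise ValueError("all stacks must share the same scales")
        dig = _digest(stack, mask)
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, int(dig[:8], 16)])
        )
        x, y = _sample_image(stack, mask, hyper.class_cap, rng)
        per_class = {
            int(lab): (x[y == lab], y[y == lab]) for lab in np.unique(y)
        }
        raw.append((dig, per_class))
    if not raw:
        raise ValueError("no training images")

    raw.sort(key=lambda t: t[0])
    cap_per_image = max(int(np.ceil(hyper.class_cap / len(raw))), 1)
    xs, ys = [], []
    for _, per_class in raw:
        for lab in sorted(per_class):
            x, y = per_class[lab]
            xs.append(x[:cap_per_image])
            ys.append(y[:cap_per_image])
    X = np.vstack(xs)
    y = np.concatenate(ys)

    present = set(np.unique(y).tolist())
    for label, name in enumerate(SEMANTIC_CLASSES):
        if label not in present:
            raise ValueError(f"class {name!r} absent from the pooled training pixels")

    forest = RandomForestClassifier(
        n_estimators=hyper.n_trees,
        max_depth=hyper.max_depth,
        random_state=seed & 0x7FFFFFFF,
        n_jobs=1,
    )
    forest.fit(X, y)

    h = hashlib.sha1()
    for dig, _ in raw:
        h.update(dig.encode())
    return PixelModel(
        forest=forest,
        scales=scales,
        class_order=SEMANTIC_CLASSES,
        seed=seed,
        hyper=hyper,
        training_hash=h.hexdigest(),
    )


def candidate_mask(
    image: np.ndarray,
    n_sigma: float = 4.0,
    dilation_px: int = 8,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Prescreen: pixels whose smoothed local contrast exceeds the noise band.

    Contrast is measured against a large-scale background estimate (which
    absorbs illumination shading); the noise band is a robust (MAD) scale
    of the residual. Isolated supra-threshold speckles are removed (a real
    structure is contiguous after smoothing) before the generous dilation
    that keeps faint surroundings of any detection.
    """
    img = np.asarray(image, dtype=np.float32)
    sm = ndi.gaussian_filter(img, 1.5)
    bg = large_scale_background(img) if background is None else background
    resid = sm - bg
    mad = np.median(np.abs(resid - np.median(resid)))
    sd = 1.4826 * float(mad) + 1e-6
    cand = np.abs(resid) > n_sigma * sd
    neighbours = ndi.uniform_filter(cand.astype(np.float32), size=3)
    cand &= neighbours >= 4.5 / 9.0   # at least 5 of 9 in the 3x3 block
    return ndi.maximum_filter(cand, size=2 * dilation_px + 1)


def assemble_probability_map(
    model: PixelModel,
    shape: tuple[int, int],
    cand_idx: np.ndarray,
    rows: np.ndarray,
) -> PixelProbabilityMap:
    """Probability map from forest output at candidate pixels; everything
    outside the candidate set is background with probability 1."""
    probs = np.zeros((len(model.class_order),) + tuple(shape), dtype=np.float32)
    probs[0] = 1.0
    if len(cand_idx):
        p = model.forest.predict_proba(rows).astype(np.float32)
        flatp = probs.reshape(len(model.class_order), -1)
        flatp[:, cand_idx] = 0.0
        for k, cls in enumerate(model.forest.classes_):
            flatp[int(cls), cand_idx] = p[:, k]
        flatp[:, cand_idx] /= np.maximum(
            flatp[:, cand_idx].sum(axis=0, keepdims=True), 1e-12
        )
    return PixelProbabilityMap(probs=probs, class_names=model.class_order)


def predict_pixels(
    model: PixelModel,
    image: np.ndarray,
    stack: FeatureStack | None = None,
    prescreen: bool = True,
    background: np.ndarray | None = None,
) -> PixelProbabilityMap:
    """Per-pixel class probabilities for one micrograph (deterministic)."""
    if stack is None:
        stack = extract_features(image, model.scales)
    if stack.scales != model.scales:
        raise ValueError(
            f"feature scales {stack.scales} do not match model scales {model.scales}"
        )
    if stack.n_channels != model.forest.n_features_in_:
        raise ValueError("feature stack channel count does not match the model")

    shape = stack.channels.shape[1:]
    if prescreen:
        cand = candidate_mask(image, background=background)
    else:
        cand = np.ones(shape, dtype=bool)
    idx = np.flatnonzero(cand.ravel())
    return assemble_probability_map(model, shape, idx, stack.as_table()[idx])
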