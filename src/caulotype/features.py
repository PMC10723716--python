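"""Multi-scale filter-bank pixel features.

For every scale sigma (in pixels) the stack holds Gaussian smoothing,
gradient magnitude, Laplacian, and the larger/smaller Hessian eigenvalue,
plus one raw-intensity channel: ``n_types * n_scales + 1`` channels in the
trainable-segmentation style. Boundaries are handled by reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

FILTER_TYPES = ("gaussian", "gradient_magnitude", "laplacian", "hessian_max", "hessian_min")


@dataclass
class FeatureStack:
    channels: np.ndarray          # (n_channels, rows, cols) float32
    channel_names: list[str]
    scales: tuple[float, ...]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    def as_table(self) -> np.ndarray:
        """Flatten to (n_pixels, n_channels) for a classifier."""
        f, r, c = self.channels.shape
        return self.channels.reshape(f, r * c).T


def _scale_channels(img: np.ndarray, sigma: float) -> list[np.ndarray]:
    g = ndi.gaussian_filter(img, sigma, mode="reflect")
    gr = ndi.gaussian_filter(img, sigma, order=(1, 0), mode="reflect")
    gc = ndi.gaussian_filter(img, sigma, order=(0, 1), mode="reflect")
    hrr = ndi.gaussian_filter(img, sigma, order=(2, 0), mode="reflect")
    hcc = ndi.gaussian_filter(img, sigma, order=(0, 2), mode="reflect")
    hrc = ndi.gaussian_filter(img, sigma, order=(1, 1), mode="reflect")
    grad = np.hypot(gr, gc)
    lap = hrr + hcc
    mean = 0.5 * (hrr + hcc)
    disc = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
    return [g, grad, lap, mean + disc, mean - disc]


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    r = (-img.shape[0]) % f
    c = (-img.shape[1]) % f
    if r or c:
        img = np.pad(img, ((0, r), (0, c)), mode="reflect")
    h, w = img.shape
    return img.reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def extract_features(image: np.ndarray, scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)) -> FeatureStack:
    """Compute the filter-bank feature stack of a 2-D micrograph.

    Scales up to 2 px are computed at full resolution. Larger scales use a
    decimated pyramid (block-mean downsampling by the largest power of two
    that keeps the effective sigma >= 2 px, bilinear upsampling back): at
    those scales the responses are smooth, so decimation changes them
    negligibly while cutting the dominant convolution cost.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be non-empty and positive")
    bad = ~np.isfinite(img)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"image contains {int(bad.sum())} non-finite pixels (first at row {r}, col {c})"
        )

    stack = np.empty((1 + len(FILTER_TYPES) * len(scales),) + img.shape, np.float32)
    stack[0] = img
    names = ["raw"]
    pos = 1
    pyramids: dict[int, np.ndarray] = {1: img}
    for s in scales:
        f = 1
        while s / (2 * f) >= 2.0 and min(img.shape) // (2 * f) >= 32:
            f *= 2
        if f == 1:
            for ch in _scale_channels(img, s):
                stack[pos] = ch
                pos += 1
        else:
            if f not in pyramids:
                pyramids[f] = _block_mean(img, f)
            small = pyramids[f]
            zoom = (img.shape[0] / small.shape[0], img.shape[1] / small.shape[1])
            for ch in _scale_channels(small, s / f):
                stack[pos] = ndi.zoom(ch, zoom, order=1, mode="reflect", grid_mode=True)
                pos += 1
        names += [f"{t}_s{s:g}" for t in FILTER_TYPES]

    return FeatureStack(channels=stack, channel_names=names, scales=tuple(scales))


def large_scale_background(image: np.ndarray, sigma: float = 40.0, factor: int = 8) -> np.ndarray:
    """Fast large-scale background estimate (decimated Gaussian)."""
    img = np.asarray(image, dtype=np.float32)
    small = _block_mean(img, factor)
    sm = ndi.gaussian_filter(small, sigma / factor, mode="reflect")
    zoom = (img.shape[0] / sm.shape[0], img.shape[1] / sm.shape[1])
    return ndi.zoom(sm, zoom, order=1, mode="reflect", grid_mode=True)
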