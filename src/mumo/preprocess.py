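"""Image standardisation and tiling.

Pathology tiles are colour-normalised by Reinhard colour transfer (matching
per-channel mean/std in the decorrelated lαβ space) followed by grey-world
white balance, to unify staining across slides and centres. Radiology lesion
ROIs are intensity-normalised with *dynamic windows*: per-lesion-type
percentile ranges estimated on the training split and applied as a linear
window map to [0, 1]. ROIs are tiled into "bags" (large tiles) subdivided
into "words" (small patches) for the multiple-instance feature hierarchy.

Coordinates are 0-based, half-open ``(x0, y0, x1, y1)`` rectangles; boundary
bags that do not fit are discarded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ChannelStats",
    "Window",
    "TileGrid",
    "compute_channel_stats",
    "reinhard_normalize",
    "white_balance",
    "dynamic_window",
    "apply_window",
    "tile_roi",
    "save_windows",
    "load_windows",
]

# Ruderman/Reinhard RGB -> LMS and LMS(log) -> lab decorrelation matrices.
_RGB2LMS = np.array([
    [0.3811, 0.5783, 0.0402],
    [0.1967, 0.7244, 0.0782],
    [0.0241, 0.1288, 0.8444],
])
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array([
    [1.0, 1.0, 1.0],
    [1.0, 1.0, -2.0],
    [1.0, -1.0, 0.0],
])
_LAB2LMS = np.linalg.inv(_LMS2LAB)
_LOG_EPS = 1e-6


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and standard deviation in lαβ space."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self):
        if any(s < 0 for s in self.std):
            raise ValueError("channel standard deviations must be >= 0")


def _as_float_rgb(image: np.ndarray) -> tuple[np.ndarray, bool]:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0, True
    return image.astype(np.float64), False


def _to_lab(rgb: np.ndarray) -> np.ndarray:
    lms = rgb @ _RGB2LMS.T
    return np.log10(np.maximum(lms, _LOG_EPS)) @ _LMS2LAB.T


def _from_lab(lab: np.ndarray) -> np.ndarray:
    lms = np.power(10.0, lab @ _LAB2LMS.T)
    return lms @ _LMS2RGB.T


def compute_channel_stats(image: np.ndarray) -> ChannelStats:
    """lαβ channel statistics of an RGB image (the Reinhard source/target)."""
    rgb, _ = _as_float_rgb(image)
    lab = _to_lab(rgb)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    return ChannelStats(tuple(mean), tuple(std))


def reinhard_normalize(image: np.ndarray, target: ChannelStats) -> np.ndarray:
    """Reinhard colour transfer towards ``target`` channel statistics.

    Per lαβ channel, ``x' = (x - mu_src) / sigma_src * sigma_tgt + mu_tgt``.
    A degenerate source channel (sigma 0, e.g. a constant image) uses
    sigma_src = 1, so constant images land exactly on the target means.
    Output matches the input's dtype convention (uint8 in -> uint8 out).
    """
    rgb, was_uint8 = _as_float_rgb(image)
    lab = _to_lab(rgb)
    flat = lab.reshape(-1, 3)
    mu_src = flat.mean(axis=0)
    sigma_src = flat.std(axis=0)
    sigma_src = np.where(sigma_src < 1e-12, 1.0, sigma_src)
    mu_tgt = np.asarray(target.mean)
    sigma_tgt = np.asarray(target.std)
    lab_out = (lab - mu_src) / sigma_src * sigma_tgt + mu_tgt
    out = np.clip(_from_lab(lab_out), 0.0, 1.0)
    if was_uint8:
        return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    return out


def white_balance(image: np.ndarray) -> np.ndarray:
    """Grey-world white balance: scale each channel mean to the global mean.

    A grey image is a fixed point; the map is idempotent. An all-zero image
    is returned unchanged with a warning.
    """
    rgb, was_uint8 = _as_float_rgb(image)
    channel_means = rgb.reshape(-1, 3).mean(axis=0)
    if np.all(channel_means < 1e-12):
        warnings.warn("white_balance: all-zero image returned unchanged")
        return np.asarray(image).copy()
    global_mean = channel_means.mean()
    gains = np.where(channel_means < 1e-12, 1.0, global_mean / channel_means)
    out = np.clip(rgb * gains, 0.0, 1.0)
    if was_uint8:
        return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    return out


@dataclass(frozen=True)
class Window:
    """An intensity window ``[low, high)`` used to normalise lesion images."""

    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"window low ({self.low}) must be < high ({self.high})")


def dynamic_window(intensities: np.ndarray, lo_pct: float = 0.5,
                   hi_pct: float = 99.5) -> Window:
    """Percentile window over a sample of lesion voxels.

    Uses the linear-interpolation percentile definition. A constant sample is
    widened by ±0.5 so the window stays valid.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("dynamic_window: empty intensity sample")
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")
    lo = float(np.percentile(x, lo_pct))
    hi = float(np.percentile(x, hi_pct))
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return Window(lo, hi)


def apply_window(image: np.ndarray, w: Window) -> np.ndarray:
    """Linearly rescale intensities into [0, 1], clipping outside the window."""
    x = np.asarray(image, dtype=np.float64)
    return np.clip((x - w.low) / (w.high - w.low), 0.0, 1.0)


def save_windows(windows: dict[str, Window], path: str | Path) -> None:
    """Cache per-lesion-type windows to a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump({k: [w.low, w.high] for k, w in sorted(windows.items())}, fh,
                  indent=2)


def load_windows(path: str | Path) -> dict[str, Window]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: Window(lo, hi) for k, (lo, hi) in raw.items()}


@dataclass(frozen=True)
class TileGrid:
    """Bag rectangles with nested word rectangles (half-open pixel coords)."""

    bags: tuple[tuple[int, int, int, int], ...]
    words: tuple[tuple[tuple[int, int, int, int], ...], ...]

    @property
    def n_bags(self) -> int:
        return len(self.bags)


def tile_roi(roi: tuple[int, int, int, int], bag_size: int,
             word_size: int) -> TileGrid:
    """Tile an ROI into a regular grid of bags, each fully tiled by words.

    Bags are anchored at the ROI origin; partial boundary bags are discarded.
    ``bag_size`` must be divisible by ``word_size``.
    """
    x0, y0, x1, y1 = roi
    if bag_size % word_size != 0:
        raise ValueError("bag_size must be divisible by word_size")
    w, h = x1 - x0, y1 - y0
    if w < bag_size or h < bag_size:
        raise ValueError(
            f"ROI {w}x{h} is smaller than one {bag_size}x{bag_size} bag")
    bags = []
    words = []
    for by in range(y0, y1 - bag_size + 1, bag_size):
        for bx in range(x0, x1 - bag_size + 1, bag_size):
            bags.append((bx, by, bx + bag_size, by + bag_size))
            bag_words = []
            for wy in range(by, by + bag_size, word_size):
                for wx in range(bx, bx + bag_size, word_size):
                    bag_words.append((wx, wy, wx + word_size, wy + word_size))
            words.append(tuple(bag_words))
    return TileGrid(bags=tuple(bags), words=tuple(words))
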