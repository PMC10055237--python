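"""Masking augmentation and the modified-YUV color transform.

Training-time augmentation randomly blanks one contiguous time block on a few
ROI rows of the initial spatiotemporal map, emulating transient occlusion /
detector dropout, after which the map is moved from RGB into a
luminance/chrominance space that concentrates the pulsatile signal in the Y
(brightness) channel and decouples it from chromatic illumination changes.

The modified-YUV transform is the fixed 3x3 matrix

    | Y |   |  0.299   0.587   0.114 | | R |
    | U | = | -0.169  -0.331   0.5   | | G |
    | V |   |  0.5    -0.419  -0.081 | | B |

applied per cell (or per pixel when operating on raw frames).  A classical
YUV variant (U = 0.492 (B - Y), V = 0.877 (R - Y)) and an RGB pass-through are
provided so color-space ablations run through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidStateError
from .roi_maps import SpatioTemporalMap

#: Modified-YUV matrix, rows Y/U/V, columns R/G/B.
MODIFIED_YUV_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.169, -0.331, 0.5],
        [0.5, -0.419, -0.081],
    ]
)

#: Classical YUV: Y as above, U = 0.492 (B - Y), V = 0.877 (R - Y).
YUV_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.492 * -0.299, 0.492 * -0.587, 0.492 * (1 - 0.114)],
        [0.877 * (1 - 0.299), 0.877 * -0.587, 0.877 * -0.114],
    ]
)

CHANNEL_SPACES = ("RGB", "YUV", "modifiedYUV")


@dataclass
class MaskSpec:
    """Random-masking parameters.

    time_fraction : maximal fraction of frames covered by the masked block
        (default 0.10).
    roi_fraction : maximal fraction of ROI rows masked (default 0.25; with
        N=4 rows that is one row).
    fill_value : intensity written into masked cells (default 0).
    seed : RNG seed; identical spec + map give identical output.
    """

    time_fraction: float = 0.10
    roi_fraction: float = 0.25
    fill_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.time_fraction <= 1.0 and 0.0 <= self.roi_fraction <= 1.0):
            raise ValueError("mask fractions must lie in [0, 1]")


def random_mask(stmap: SpatioTemporalMap, spec: MaskSpec, rng: np.random.Generator | None = None) -> SpatioTemporalMap:
    """Blank one contiguous time block on randomly chosen ROI rows.

    The block spans ``floor(time_fraction * T)`` frames starting at a uniform
    random offset, on ``floor(roi_fraction * N)`` distinct random rows; all
    three channels of the selected cells are set to ``fill_value``.  A zero
    fraction in either dimension leaves the map untouched.  Training-only:
    inference paths never call this.
    """
    if stmap.channel_space != "RGB":
        raise InvalidStateError("random_mask expects an RGB map (augment before the color transform)")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, t = stmap.n_rois, stmap.frame_count
    block = int(np.floor(spec.time_fraction * t))
    n_rows = int(np.floor(spec.roi_fraction * n))
    out = stmap.copy()
    if block == 0 or n_rows == 0:
        return out
    start = int(rng.integers(0, t - block + 1))
    rows = rng.choice(n, size=n_rows, replace=False)
    out.values[rows[:, None], np.arange(start, start + block)[None, :], :] = spec.fill_value
    return out


def _apply_matrix(stmap: SpatioTemporalMap, matrix: np.ndarray, tag: str) -> SpatioTemporalMap:
    if stmap.channel_space != "RGB":
        raise InvalidStateError(f"input is already in {stmap.channel_space}; expected RGB")
    values = stmap.values @ matrix.T
    return SpatioTemporalMap(values=values, channel_space=tag, fps=stmap.fps, roi_names=stmap.roi_names)


def rgb_to_modified_yuv(stmap: SpatioTemporalMap) -> SpatioTemporalMap:
    """Apply the modified-YUV matrix per cell; tags the map ``modifiedYUV``."""
    return _apply_matrix(stmap, MODIFIED_YUV_MATRIX, "modifiedYUV")


def rgb_to_yuv(stmap: SpatioTemporalMap) -> SpatioTemporalMap:
    """Apply the classical YUV matrix per cell; tags the map ``YUV``."""
    return _apply_matrix(stmap, YUV_MATRIX, "YUV")


def convert_colorspace(stmap: SpatioTemporalMap, mode: str) -> SpatioTemporalMap:
    """Dispatch on the color-space ablation axis: RGB, YUV or modifiedYUV."""
    if mode == "RGB":
        if stmap.channel_space != "RGB":
            raise InvalidStateError(f"input is already in {stmap.channel_space}; expected RGB")
        return stmap.copy()
    if mode == "YUV":
        return rgb_to_yuv(stmap)
    if mode == "modifiedYUV":
        return rgb_to_modified_yuv(stmap)
    raise ValueError(f"unknown color space {mode!r}; choose from {CHANNEL_SPACES}")


def frames_to_modified_yuv(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel modified-YUV transform of raw ``... x 3`` RGB frame data."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[-1] != 3:
        raise ValueError("last axis must hold the 3 RGB channels")
    return pixels @ MODIFIED_YUV_MATRIX.T
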