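"""Regions of interest and the initial spatiotemporal map.

A facial video clip is reduced to an ``N x T x 3`` array of per-ROI,
per-frame, per-channel mean pixel values — the *initial spatiotemporal map*
``f(n, t)``.  Four skin regions rich in vascular signal (forehead, left cheek,
right cheek, chin band) are delineated from 68-point facial landmarks and each
region's pixels are spatially averaged per frame:

    f(n, t) = sum_{(x,y) in R(n)} V(x, y, t) / A(n)

where ``R(n)`` is the n-th ROI, ``A(n)`` its pixel count and ``V(x, y, t)``
the pixel value at frame ``t``.  Spatial averaging suppresses sensor noise
while preserving the blood-volume-pulse component shared by all pixels of a
skin patch.

Coordinate convention: 0-based pixel indices, origin at the top-left corner,
x rightward, y downward.  Masks are half-open pixel grids; a polygon covers a
pixel when the pixel's *center* ``(x + 0.5, y + 0.5)`` falls inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

ROI_NAMES = ("forehead", "left_cheek", "right_cheek", "chin")

# iBUG-68 indices of the seven anchor landmarks used by the default ROI recipe:
# mid left brow, mid right brow, left eye outer corner, right eye outer corner,
# nose bottom, left mouth corner, right mouth corner.
ANCHOR_POINTS = (19, 24, 36, 45, 33, 48, 54)


@dataclass
class FrameSequence:
    """A decoded video clip: ``T x H x W x 3`` RGB intensities in [0, 255].

    Pixel values are kept as floats so that synthetic clips round-trip exactly;
    integer-coded video decodes to the same range.
    """

    pixels: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4 or self.pixels.shape[-1] != 3:
            raise ValueError(f"pixels must be T x H x W x 3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def frame_count(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_size(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass
class LandmarkTrack:
    """Per-frame 68-point facial landmarks; NaN coordinates flag a failed frame."""

    points: np.ndarray  # T x 68 x 2, columns (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (68, 2):
            raise ValueError(f"points must be T x 68 x 2, got shape {self.points.shape}")

    @property
    def frame_count(self) -> int:
        return self.points.shape[0]

    def missing_frames(self) -> np.ndarray:
        """Boolean mask of frames whose anchor landmarks are missing (NaN)."""
        anchors = self.points[:, list(ANCHOR_POINTS), :]
        return np.isnan(anchors).any(axis=(1, 2))


@dataclass
class RoiMaskSet:
    """Per-frame binary masks for N ROIs plus the retained-frame index.

    ``masks`` has shape ``T_valid x N x H x W``; ``valid_frames`` maps each
    retained row back to the source frame index, so dropped (failed-detection)
    frames are excluded from every downstream stage.
    """

    masks: np.ndarray  # T_valid x N x H x W, bool
    valid_frames: np.ndarray  # T_valid source frame indices
    roi_names: tuple[str, ...] = ROI_NAMES

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.valid_frames = np.asarray(self.valid_frames, dtype=int)
        if self.masks.ndim != 4:
            raise ValueError("masks must be T x N x H x W")
        if self.masks.shape[0] != self.valid_frames.shape[0]:
            raise ValueError("masks and valid_frames disagree in frame count")

    @property
    def n_rois(self) -> int:
        return self.masks.shape[1]

    def pixel_counts(self) -> np.ndarray:
        """A(n) per retained frame: ``T_valid x N`` pixel counts."""
        return self.masks.sum(axis=(2, 3))


@dataclass
class SpatioTemporalMap:
    """N ROIs x T frames x 3 channels of per-ROI mean values.

    ``channel_space`` tracks which color space the values live in; it changes
    only through :mod:`videobp.augment_colorspace`.
    """

    values: np.ndarray  # N x T x 3
    channel_space: str = "RGB"
    fps: float | None = None
    roi_names: tuple[str, ...] = ROI_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[-1] != 3:
            raise ValueError(f"values must be N x T x 3, got shape {self.values.shape}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def frame_count(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "SpatioTemporalMap":
        return SpatioTemporalMap(self.values.copy(), self.channel_space, self.fps, self.roi_names)


def polygon_mask(polygon: np.ndarray, frame_size: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to an H x W boolean mask.

    A pixel belongs to the mask when its center ``(x + 0.5, y + 0.5)`` lies
    inside the polygon (even-odd / crossing-number rule, vectorized over the
    grid).  With integer-coordinate polygons, pixel centers never sit on an
    edge, so the rule is unambiguous and a rectangle ``[x0,x1] x [y0,y1]``
    covers exactly the half-open pixel range ``[x0, x1) x [y0, y1)``.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be an M x 2 array with M >= 3")
    h, w = frame_size
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    px, py = np.meshgrid(xs, ys)  # H x W
    inside = np.zeros((h, w), dtype=bool)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        crosses = ((y0 > py) != (y1 > py)) & (px < (x1 - x0) * (py - y0) / (y1 - y0 + 1e-300) + x0)
        inside ^= crosses
        x0, y0 = x1, y1
    return inside


def _default_roi_polygons(frame_points: np.ndarray) -> list[np.ndarray]:
    """Four rectangular ROI polygons from one frame's 68 landmarks.

    Anchor-arithmetic recipe (a documented choice; the anchor indices are in
    :data:`ANCHOR_POINTS`): with brow mids p19/p24, eye outer corners p36/p45,
    nose bottom p33 and mouth corners p48/p54, let ``yb`` be the mean brow
    height and ``nh = y33 - yb`` the brow-to-nose drop.  Then

    - forehead:     x in [x19, x24],  y in [yb - 0.5 nh, yb - 0.1 nh]
    - left cheek:   x in [x36, x48],  y in [y36 + 0.3 nh, y48]
    - right cheek:  x in [x54, x45],  y in [y45 + 0.3 nh, y54]
    - chin band:    x in [x48, x54],  y in [ym + 0.2 nh, ym + 0.6 nh],
      ym = (y48 + y54) / 2

    which keeps all four regions on skin and clear of eyes, nose and mouth.
    """
    p = frame_points
    (x19, y19), (x24, y24) = p[19], p[24]
    (x36, y36), (x45, y45) = p[36], p[45]
    (_, y33) = p[33]
    (x48, y48), (x54, y54) = p[48], p[54]
    yb = 0.5 * (y19 + y24)
    nh = y33 - yb
    if nh <= 0:
        raise ValueError("degenerate landmark geometry: nose bottom above brow line")
    ym = 0.5 * (y48 + y54)

    def rect(xa, xb, ya, yb_) -> np.ndarray:
        return np.array([[xa, ya], [xb, ya], [xb, yb_], [xa, yb_]], dtype=float)

    return [
        rect(x19, x24, yb - 0.5 * nh, yb - 0.1 * nh),
        rect(x36, x48, y36 + 0.3 * nh, y48),
        rect(x54, x45, y45 + 0.3 * nh, y54),
        rect(x48, x54, ym + 0.2 * nh, ym + 0.6 * nh),
    ]


def landmarks_to_rois(track: LandmarkTrack, frame_size: tuple[int, int]) -> RoiMaskSet:
    """Delineate the four skin ROIs from per-frame landmarks.

    Frames whose anchor landmarks are missing (NaN) are flagged, excluded from
    all ROIs and reported with a warning; downstream maps are built only over
    the retained frames.

    Raises
    ------
    ValueError
        If every frame fails, or a polygon rasterizes to an empty mask
        (landmarks outside the frame).
    """
    missing = track.missing_frames()
    valid = np.flatnonzero(~missing)
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} frame(s) with missing landmarks: "
            f"{np.flatnonzero(missing).tolist()}",
            stacklevel=2,
        )
    if valid.size == 0:
        raise ValueError("all frames have missing landmarks; no ROIs can be built")

    h, w = frame_size
    masks = np.zeros((valid.size, len(ROI_NAMES), h, w), dtype=bool)
    for row, t in enumerate(valid):
        polys = _default_roi_polygons(track.points[t])
        for n, poly in enumerate(polys):
            m = polygon_mask(poly, frame_size)
            if not m.any():
                raise ValueError(f"ROI '{ROI_NAMES[n]}' is empty in frame {int(t)} (landmarks outside frame?)")
            masks[row, n] = m
    return RoiMaskSet(masks=masks, valid_frames=valid)


def compute_spatiotemporal_map(frames: FrameSequence, rois: RoiMaskSet) -> SpatioTemporalMap:
    """Spatially average each ROI per frame: the initial spatiotemporal map.

    ``values[n, t, c]`` is the mean of channel-``c`` intensities over ROI
    ``R(n)`` at retained frame ``t`` (sum over the mask divided by the pixel
    count ``A(n)``).  Output channel space is RGB.

    Raises
    ------
    ValueError
        If frame indices run outside the clip, or an ROI is empty at some
        frame (the error names the ROI and the frame).
    """
    if rois.valid_frames.size and rois.valid_frames.max() >= frames.frame_count:
        raise ValueError("ROI frame indices exceed the frame sequence length")
    if rois.masks.shape[2:] != frames.frame_size:
        raise ValueError("mask frame size differs from the frame sequence")

    counts = rois.pixel_counts()  # T_valid x N
    for t_row, t_src in enumerate(rois.valid_frames):
        for n in range(rois.n_rois):
            if counts[t_row, n] == 0:
                raise ValueError(f"empty ROI '{rois.roi_names[n]}' (index {n}) at frame {int(t_src)}")

    pix = frames.pixels[rois.valid_frames]  # T_valid x H x W x 3
    # sum over masked pixels: (T,N,H,W) x (T,H,W,C) -> (N,T,C)
    sums = np.einsum("tnhw,thwc->ntc", rois.masks.astype(float), pix)
    values = sums / counts.T[:, :, None]
    return SpatioTemporalMap(values=values, channel_space="RGB", fps=frames.fps, roi_names=rois.roi_names)
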