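"""Spatiotemporal feature-map slices.

The augmented map ``g(n, t)`` (N ROI rows) is expanded to one row per
*non-empty subset* of the ROIs — ``S = 2^N - 1`` rows, each the unweighted
mean of its member-ROI signals — then cut into consecutive fixed-length time
windows of ``cl`` frames and min-max normalized to [0, 1] per slice and
channel.  Each resulting ``S x cl x 3`` array is one network input; subset
averaging denoises by pooling regions while keeping every region combination
visible to the model.

Canonical subset order is by increasing binary encoding: subset index
``m in 1..2^N-1`` includes ROI ``n`` (0-based) iff bit ``n`` of ``m`` is set,
so singletons appear at positions 1, 2, 4, ... and the full set comes last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi_maps import SpatioTemporalMap

MAX_ROIS = 8  # S = 2^N - 1 rows; 8 ROIs already mean 255 rows


@dataclass
class STSlice:
    """One ``S x cl x 3`` spatiotemporal feature-map slice.

    ``slice_index`` m covers source frames ``[m * cl, (m + 1) * cl)``.
    After :func:`normalize_slices` all values lie in [0, 1].
    """

    values: np.ndarray  # S x cl x 3
    slice_index: int
    frame_range: tuple[int, int]
    channel_space: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[-1] != 3:
            raise ValueError(f"slice values must be S x cl x 3, got {self.values.shape}")

    @property
    def n_subsets(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


def enumerate_subsets(n_rois: int) -> list[tuple[int, ...]]:
    """All non-empty subsets of ``{0, .., n_rois-1}`` in binary-encoding order."""
    if not (1 <= n_rois <= MAX_ROIS):
        raise ValueError(f"n_rois must lie in [1, {MAX_ROIS}], got {n_rois}")
    return [tuple(n for n in range(n_rois) if m >> n & 1) for m in range(1, 2**n_rois)]


def subset_signal(stmap: SpatioTemporalMap, subset: tuple[int, ...]) -> np.ndarray:
    """Unweighted mean over the member-ROI rows: a ``T x 3`` signal."""
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    idx = list(subset)
    if len(set(idx)) != len(idx) or min(idx) < 0 or max(idx) >= stmap.n_rois:
        raise ValueError(f"invalid subset {subset} for a map with {stmap.n_rois} ROIs")
    return stmap.values[idx].mean(axis=0)


def expand_subsets(stmap: SpatioTemporalMap) -> np.ndarray:
    """Stack all ``2^N - 1`` subset signals: an ``S x T x 3`` array."""
    subsets = enumerate_subsets(stmap.n_rois)
    return np.stack([subset_signal(stmap, s) for s in subsets], axis=0)


def build_slices(stmap: SpatioTemporalMap, cl: int, step: int | None = None) -> list[STSlice]:
    """Window the subset-expanded map into ``S x cl x 3`` slices.

    Default is non-overlapping windows (step = cl): ``M = floor(T / cl)``
    slices tiling the first ``M * cl`` frames, trailing remainder dropped.
    ``step < cl`` gives overlapping windows (exposed for experimentation).
    A single window of length T (``cl = T``) is the no-slicing ablation mode.
    """
    if cl < 1:
        raise ValueError("cl must be a positive number of frames")
    t = stmap.frame_count
    if t < cl:
        raise ValueError(f"video too short: {t} frames < slice length {cl}")
    if step is None:
        step = cl
    if step < 1:
        raise ValueError("step must be positive")
    expanded = expand_subsets(stmap)  # S x T x 3
    slices = []
    m = 0
    start = 0
    while start + cl <= t:
        slices.append(
            STSlice(
                values=expanded[:, start : start + cl, :].copy(),
                slice_index=m,
                frame_range=(start, start + cl),
                channel_space=stmap.channel_space,
            )
        )
        m += 1
        start += step
    return slices


def normalize_slices(slices: list[STSlice]) -> list[STSlice]:
    """Min-max scale each slice to [0, 1], independently per channel.

    The per-channel extrema are taken over all ``S x cl`` cells of the slice.
    A constant channel (max == min) carries no waveform information and maps
    to all zeros.
    """
    out = []
    for s in slices:
        v = s.values.copy()
        lo = v.min(axis=(0, 1), keepdims=True)
        hi = v.max(axis=(0, 1), keepdims=True)
        span = hi - lo
        flat = span == 0
        span = np.where(flat, 1.0, span)
        v = (v - lo) / span
        v[np.broadcast_to(flat, v.shape)] = 0.0
        out.append(STSlice(values=v, slice_index=s.slice_index, frame_range=s.frame_range, channel_space=s.channel_space))
    return out


def slices_from_map(stmap: SpatioTemporalMap, cl: int, step: int | None = None, normalize: bool = True) -> list[STSlice]:
    """Convenience: window then (by default) normalize."""
    slices = build_slices(stmap, cl, step=step)
    return normalize_slices(slices) if normalize else slices


def slices_to_array(slices: list[STSlice]) -> np.ndarray:
    """Stack M slices into an ``M x S x cl x 3`` array (network input)."""
    if not slices:
        raise ValueError("need at least one slice")
    shapes = {s.values.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {shapes}")
    return np.stack([s.values for s in slices], axis=0)


def save_slices(path, slices: list[STSlice], subject_id: str, n_rois: int, fps: float | None = None) -> None:
    """Serialize slices to an NPZ container (the training-set interchange format)."""
    arr = slices_to_array(slices)
    np.savez_compressed(
        path,
        sts=arr,
        cl=np.array(arr.shape[2]),
        n_rois=np.array(n_rois),
        channel_space=np.array(slices[0].channel_space),
        subject_id=np.array(subject_id),
        fps=np.array(-1.0 if fps is None else fps),
    )


def load_slices(path) -> dict:
    """Load an NPZ slice container; returns array plus attributes."""
    with np.load(path, allow_pickle=False) as z:
        fps = float(z["fps"])
        return {
            "sts": z["sts"],
            "cl": int(z["cl"]),
            "n_rois": int(z["n_rois"]),
            "channel_space": str(z["channel_space"]),
            "subject_id": str(z["subject_id"]),
            "fps": None if fps < 0 else fps,
        }
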