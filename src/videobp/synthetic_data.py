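"""Seeded synthetic pulsatile "facial videos" with known SBP/DBP.

Real facial-video BP datasets are scarce and private, so every pipeline stage
here is exercised on synthetic clips: four rectangular skin ROIs whose pixel
intensities carry a periodic blood-volume-pulse waveform, additive sensor
noise, slow illumination drift, optional motion jitter, and a static
background.  In *fast mode* (the default) pixel rendering is skipped and the
per-ROI mean traces are emitted directly — full frames are only needed to
test the ROI-averaging stage itself.

The BP -> waveform map is an invented, documented stand-in (no public
generative model links BP to facial BVP morphology); it is deliberately
simple, monotone, and invertible in expectation so that learning BP back from
the signal is a well-posed parameter-recovery task:

- pulse amplitude is affine in pulse pressure:
  ``A = 1.5 + 0.06 * (sbp - dbp)`` intensity units;
- the systolic-upstroke fraction of the cardiac cycle falls linearly with
  SBP: ``u = 0.42 - 0.0022 * (sbp - 90)`` (stiffer, higher-pressure systems
  have steeper upstrokes);
- the dicrotic-wave relative amplitude grows linearly with DBP:
  ``d = 0.08 + 0.004 * (dbp - 50)`` (higher diastolic pressure sustains the
  reflected wave);
- after the systolic peak the waveform decays exponentially with time
  constant 0.20 cycles, with the dicrotic bump centered 0.22 cycles past the
  peak.

Heart rate is drawn uniformly in 60-100 bpm independent of BP — a nuisance
factor the estimator must ignore.  Label ranges follow clinical spans: SBP in
[90, 160) mmHg, DBP in [50, 100) mmHg, sampled per 4-group weights that
default to a central peak (imbalanced, as in real cohorts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bpe_net import DBP_EDGES, SBP_EDGES
from .roi_maps import FrameSequence, ROI_NAMES, RoiMaskSet, SpatioTemporalMap

# Documented waveform constants (see module docstring).
PULSE_AMP_BASE = 1.5
PULSE_AMP_PER_MMHG = 0.06
UPSTROKE_AT_90 = 0.42
UPSTROKE_SLOPE_PER_MMHG = 0.0022
DICROTIC_BASE = 0.08
DICROTIC_PER_MMHG = 0.004
DECAY_TAU_CYCLES = 0.20
DICROTIC_DELAY_CYCLES = 0.22
DICROTIC_WIDTH_CYCLES = 0.07

#: Per-channel pulsatile gain (rPPG is strongest in green) and per-ROI
#: perfusion factors / baseline skin tones (RGB, intensity units).
CHANNEL_GAIN = np.array([0.70, 1.00, 0.55])
ROI_PERFUSION = np.array([1.00, 0.90, 0.90, 0.80])
ROI_BASELINE = np.array(
    [
        [152.0, 112.0, 96.0],
        [148.0, 108.0, 92.0],
        [148.0, 108.0, 92.0],
        [144.0, 104.0, 88.0],
    ]
)

#: Relative (row0, row1, col0, col1) bounds of the four rectangular ROIs.
ROI_LAYOUT = (
    (0.12, 0.30, 0.20, 0.80),  # forehead
    (0.45, 0.68, 0.12, 0.40),  # left cheek
    (0.45, 0.68, 0.60, 0.88),  # right cheek
    (0.78, 0.93, 0.30, 0.70),  # chin band
)

MIN_FRAME_SIZE = 32
SBP_MIN, SBP_MAX = SBP_EDGES[0], SBP_EDGES[-1]
DBP_MIN, DBP_MAX = DBP_EDGES[0], DBP_EDGES[-1]
MIN_PULSE_PRESSURE = 10.0  # mmHg margin kept between sampled SBP and DBP


@dataclass
class SynthConfig:
    """Generator settings; a config plus its seed fixes the dataset exactly.

    Defaults mirror the acquisition protocol the pipeline targets: 15 s clips
    at 30 fps, 64 x 64 frames, imbalanced 4-group BP label weights peaking in
    the normal range, 1 intensity-unit pixel noise, 1 unit of slow
    illumination drift, no motion jitter.
    """

    n_subjects: int = 8
    duration_s: float = 15.0
    fps: float = 30.0
    frame_size: tuple[int, int] = (64, 64)
    sbp_group_weights: tuple[float, ...] = (0.15, 0.45, 0.30, 0.10)
    dbp_group_weights: tuple[float, ...] = (0.15, 0.40, 0.35, 0.10)
    noise_sd: float = 1.0
    illumination_drift_amp: float = 1.0
    motion_jitter_px: float = 0.0
    render: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if min(self.noise_sd, self.illumination_drift_amp, self.motion_jitter_px) < 0:
            raise ValueError("noise/drift/jitter amplitudes must be >= 0")
        for w in (self.sbp_group_weights, self.dbp_group_weights):
            if len(w) != 4 or min(w) < 0 or sum(w) <= 0:
                raise ValueError("group weights must be 4 non-negative values with positive sum")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class SynthSubject:
    """One synthetic subject: labels, nuisance parameters, signals."""

    subject_id: str
    sbp: float
    dbp: float
    heart_rate: float
    fps: float
    roi_traces: np.ndarray  # N x T x 3 ground-truth ROI means
    frames: FrameSequence | None = None
    roi_masks: RoiMaskSet | None = None

    def stmap(self) -> SpatioTemporalMap:
        """The subject's ground-truth initial spatiotemporal map (RGB)."""
        return SpatioTemporalMap(values=self.roi_traces, channel_space="RGB", fps=self.fps)


def _waveform_shape(phase: np.ndarray, upstroke: float, dicrotic: float) -> np.ndarray:
    """Unit-amplitude pulse shape over cycle phase in [0, 1)."""
    w = np.empty_like(phase)
    rising = phase < upstroke
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / upstroke))
    ph = phase[~rising]
    decay = np.exp(-(ph - upstroke) / DECAY_TAU_CYCLES)
    bump = dicrotic * np.exp(-(((ph - upstroke - DICROTIC_DELAY_CYCLES) / DICROTIC_WIDTH_CYCLES) ** 2))
    w[~rising] = decay + bump
    return w


def generate_pulse_waveform(
    sbp: float,
    dbp: float,
    heart_rate: float,
    fps: float,
    duration_s: float,
    seed: int | None = None,
    phase0: float | None = None,
) -> np.ndarray:
    """Per-frame blood-volume-pulse amplitude series for given BP and HR.

    Amplitude, upstroke fraction and dicrotic amplitude follow the fixed
    affine maps documented in the module docstring; the starting cycle phase
    is drawn from ``seed`` (or given explicitly), everything else is
    deterministic.
    """
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration_s must be positive")
    if sbp <= dbp:
        raise ValueError(f"need sbp > dbp, got sbp={sbp}, dbp={dbp}")
    if not (SBP_MIN <= sbp <= SBP_MAX and DBP_MIN <= dbp <= DBP_MAX):
        raise ValueError(f"BP outside supported ranges [{SBP_MIN},{SBP_MAX}] / [{DBP_MIN},{DBP_MAX}]")
    if not (40.0 <= heart_rate <= 180.0):
        raise ValueError(f"heart_rate {heart_rate} outside plausible range")
    if duration_s * heart_rate / 60.0 < 2.0:
        raise ValueError("clip must span at least two heartbeats")
    if phase0 is None:
        phase0 = float(np.random.default_rng(seed).uniform(0.0, 1.0))
    t = np.arange(int(round(duration_s * fps))) / fps
    phase = (t * heart_rate / 60.0 + phase0) % 1.0
    amp = PULSE_AMP_BASE + PULSE_AMP_PER_MMHG * (sbp - dbp)
    upstroke = UPSTROKE_AT_90 - UPSTROKE_SLOPE_PER_MMHG * (sbp - 90.0)
    dicrotic = DICROTIC_BASE + DICROTIC_PER_MMHG * (dbp - 50.0)
    return amp * _waveform_shape(phase, upstroke, dicrotic)


def _draw_bp(rng: np.random.Generator, config: SynthConfig) -> tuple[float, float]:
    """Sample (sbp, dbp) from the per-group weights; resample the pair until
    the pulse-pressure margin holds (rare for the default weights)."""
    sw = np.asarray(config.sbp_group_weights, dtype=float)
    dw = np.asarray(config.dbp_group_weights, dtype=float)
    sw = sw / sw.sum()
    dw = dw / dw.sum()
    for _ in range(1000):
        gs = rng.choice(4, p=sw)
        gd = rng.choice(4, p=dw)
        sbp = float(rng.uniform(SBP_EDGES[gs], SBP_EDGES[gs + 1]))
        dbp = float(rng.uniform(DBP_EDGES[gd], DBP_EDGES[gd + 1]))
        if sbp > dbp + MIN_PULSE_PRESSURE:
            return sbp, dbp
    raise RuntimeError("could not sample a valid BP pair; check group weights")


def _roi_rects(frame_size: tuple[int, int]) -> list[tuple[int, int, int, int]]:
    h, w = frame_size
    if h < MIN_FRAME_SIZE or w < MIN_FRAME_SIZE:
        raise ValueError(f"frame_size {frame_size} too small to place 4 disjoint ROIs (min {MIN_FRAME_SIZE})")
    rects = []
    for r0, r1, c0, c1 in ROI_LAYOUT:
        rects.append((int(round(r0 * h)), int(round(r1 * h)), int(round(c0 * w)), int(round(c1 * w))))
    return rects


def _synthetic_landmarks(frame_size: tuple[int, int]) -> np.ndarray:
    """A plausible static 68-point layout for the synthetic face (x, y)."""
    h, w = frame_size
    pts = np.zeros((68, 2))
    theta = np.linspace(0, np.pi, 17)
    pts[0:17, 0] = w * (0.5 - 0.42 * np.cos(theta))  # jaw arc
    pts[0:17, 1] = h * (0.45 + 0.45 * np.sin(theta))
    pts[17:22] = np.column_stack([w * np.linspace(0.22, 0.42, 5), np.full(5, 0.33 * h)])  # left brow
    pts[22:27] = np.column_stack([w * np.linspace(0.58, 0.78, 5), np.full(5, 0.33 * h)])  # right brow
    pts[27:31] = np.column_stack([np.full(4, 0.5 * w), h * np.linspace(0.38, 0.52, 4)])  # nose bridge
    pts[31:36] = np.column_stack([w * np.linspace(0.42, 0.58, 5), np.full(5, 0.56 * h)])  # nose base
    pts[36:42] = np.column_stack([w * np.linspace(0.24, 0.40, 6), np.full(6, 0.40 * h)])  # left eye
    pts[42:48] = np.column_stack([w * np.linspace(0.60, 0.76, 6), np.full(6, 0.40 * h)])  # right eye
    mouth_theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    pts[48:68, 0] = w * (0.5 + 0.14 * np.cos(mouth_theta))
    pts[48:68, 1] = h * (0.72 + 0.05 * np.sin(mouth_theta))
    pts[48] = (0.35 * w, 0.72 * h)  # mouth corners pinned for the anchor set
    pts[54] = (0.65 * w, 0.72 * h)
    pts[33] = (0.5 * w, 0.58 * h)  # nose bottom anchor
    return pts


def render_subject(config: SynthConfig, subject_index: int) -> SynthSubject:
    """Generate one subject (fast mode by default; ``config.render`` draws pixels).

    Per-ROI mean traces are ``baseline + perfusion * channel_gain * pulse +
    drift (+ noise)``; in render mode the same model is drawn per pixel, the
    masks track any motion jitter, and ``roi_traces`` are recomputed from the
    rendered frames so they are exactly consistent with them.
    """
    if subject_index < 0 or subject_index >= config.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside [0, {config.n_subjects})")
    rng = np.random.default_rng([config.seed, subject_index])
    sbp, dbp = _draw_bp(rng, config)
    heart_rate = float(rng.uniform(60.0, 100.0))
    t_frames = config.n_frames
    pulse = generate_pulse_waveform(
        sbp, dbp, heart_rate, config.fps, config.duration_s, phase0=float(rng.uniform(0.0, 1.0))
    )
    tsec = np.arange(t_frames) / config.fps
    drift_freq = float(rng.uniform(0.05, 0.15))
    drift_phase = float(rng.uniform(0.0, 2.0 * np.pi))
    drift = config.illumination_drift_amp * np.sin(2.0 * np.pi * drift_freq * tsec + drift_phase)

    rects = _roi_rects(config.frame_size)
    areas = np.array([(r1 - r0) * (c1 - c0) for r0, r1, c0, c1 in rects], dtype=float)
    subject_id = f"synth{subject_index:04d}"

    # noise-free per-ROI mean signal, N x T x 3
    clean = (
        ROI_BASELINE[:, None, :]
        + (ROI_PERFUSION[:, None] * pulse[None, :])[:, :, None] * CHANNEL_GAIN[None, None, :]
        + drift[None, :, None]
    )

    if not config.render:
        trace_noise = rng.normal(0.0, 1.0, size=clean.shape) * (config.noise_sd / np.sqrt(areas))[:, None, None]
        return SynthSubject(
            subject_id=subject_id,
            sbp=sbp,
            dbp=dbp,
            heart_rate=heart_rate,
            fps=config.fps,
            roi_traces=clean + trace_noise,
        )

    h, w = config.frame_size
    background = np.clip(60.0 + rng.normal(0.0, 5.0, size=(h, w, 3)), 0.0, 255.0)
    frames = np.empty((t_frames, h, w, 3))
    masks = np.zeros((t_frames, len(rects), h, w), dtype=bool)
    for t in range(t_frames):
        frames[t] = background
        if config.motion_jitter_px > 0:
            dy, dx = np.round(rng.normal(0.0, config.motion_jitter_px, size=2)).astype(int)
        else:
            dy = dx = 0
        for n, (r0, r1, c0, c1) in enumerate(rects):
            r0j, r1j = np.clip([r0 + dy, r1 + dy], 0, h)
            c0j, c1j = np.clip([c0 + dx, c1 + dx], 0, w)
            if r1j <= r0j or c1j <= c0j:
                raise ValueError("motion jitter pushed an ROI out of the frame; reduce motion_jitter_px")
            masks[t, n, r0j:r1j, c0j:c1j] = True
            block = (
                ROI_BASELINE[n]
                + ROI_PERFUSION[n] * pulse[t] * CHANNEL_GAIN
                + drift[t]
                + rng.normal(0.0, config.noise_sd, size=(r1j - r0j, c1j - c0j, 3))
            )
            frames[t, r0j:r1j, c0j:c1j, :] = block
    frames = np.clip(frames, 0.0, 255.0)
    mask_set = RoiMaskSet(masks=masks, valid_frames=np.arange(t_frames), roi_names=ROI_NAMES)
    counts = mask_set.pixel_counts()  # T x N
    sums = np.einsum("tnhw,thwc->ntc", masks.astype(float), frames)
    traces = sums / counts.T[:, :, None]
    return SynthSubject(
        subject_id=subject_id,
        sbp=sbp,
        dbp=dbp,
        heart_rate=heart_rate,
        fps=config.fps,
        roi_traces=traces,
        frames=FrameSequence(pixels=frames, fps=config.fps),
        roi_masks=mask_set,
    )


def generate_dataset(config: SynthConfig) -> list[SynthSubject]:
    """All subjects for a config — a pure function of (config, seed)."""
    return [render_subject(config, i) for i in range(config.n_subjects)]


def write_dataset(subjects: list[SynthSubject], out_dir) -> Path:
    """Persist a synthetic dataset; returns the manifest path.

    Layout: ``labels.csv`` (subject_id, sbp, dbp), per-subject NPZ trace
    containers (and frame containers when rendered), per-subject landmark and
    ROI-mask JSON sidecars, and ``manifest.json`` listing every file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    labels = pd.DataFrame(
        [{"subject_id": s.subject_id, "sbp": s.sbp, "dbp": s.dbp} for s in subjects]
    )
    labels_path = out / "labels.csv"
    labels.to_csv(labels_path, index=False)

    for s in subjects:
        entry: dict[str, str] = {}
        traces_path = out / f"{s.subject_id}_traces.npz"
        np.savez_compressed(traces_path, roi_traces=s.roi_traces, fps=np.array(s.fps), heart_rate=np.array(s.heart_rate))
        entry["traces"] = traces_path.name
        if s.frames is not None:
            frames_path = out / f"{s.subject_id}_frames.npz"
            np.savez_compressed(frames_path, pixels=s.frames.pixels, fps=np.array(s.fps))
            entry["frames"] = frames_path.name
            h, w = s.frames.frame_size
            lm = _synthetic_landmarks((h, w))
            lm_path = out / f"{s.subject_id}_landmarks.json"
            lm_path.write_text(
                json.dumps(
                    [{"frame": int(t), "points": lm.tolist()} for t in range(s.frames.frame_count)]
                )
            )
            entry["landmarks"] = lm_path.name
        if s.roi_masks is not None:
            masks_path = out / f"{s.subject_id}_masks.json"
            per_frame = []
            for row, t in enumerate(s.roi_masks.valid_frames):
                rois = []
                for n in range(s.roi_masks.n_rois):
                    ys, xs = np.nonzero(s.roi_masks.masks[row, n])
                    rois.append(
                        {
                            "name": s.roi_masks.roi_names[n],
                            "y0": int(ys.min()),
                            "y1": int(ys.max()) + 1,
                            "x0": int(xs.min()),
                            "x1": int(xs.max()) + 1,
                        }
                    )
                per_frame.append({"frame": int(t), "rois": rois})
            masks_path.write_text(json.dumps(per_frame))
            entry["masks"] = masks_path.name
        files[s.subject_id] = entry

    manifest = {"labels": labels_path.name, "n_subjects": len(subjects), "subjects": files}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def make_records(subjects: list[SynthSubject]):
    """Training records (one per subject) carrying the ground-truth RGB map."""
    from .training import BPRecord

    return [
        BPRecord(subject_id=s.subject_id, sbp=s.sbp, dbp=s.dbp, stmap=s.stmap())
        for s in subjects
    ]
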