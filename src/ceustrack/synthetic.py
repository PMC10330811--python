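"""Synthetic contrast-enhanced ultrasound (CEUS) scene generator.

Clinical CEUS cine-loops are hard to track for three reasons: the lesion's
brightness changes dramatically as microbubble contrast washes in and out,
surrounding tissue can enhance on a similar schedule and mimic the lesion,
and transient acoustic shadows can black out large parts of the frame.
This module renders grayscale videos that exhibit exactly those phenomena
together with an analytic ground-truth trajectory, so every stage of the
tracker can be tested quantitatively without clinical data.

The scene model:

* lesion: a smooth radial blob (raised-cosine edge) whose intensity follows
  a wash-in/wash-out time-intensity curve (TIC);
* background: a different TIC modulated by a smooth multiplicative speckle
  texture; the texture slowly decorrelates over the video (two texture
  fields cross-faded), emulating the appearance change that perfusion
  causes in real tissue;
* motion: the whole scene translates rigidly with a per-axis breathing
  sinusoid plus an optional linear drift;
* distractors: additional blobs at fixed offsets from the lesion (they move
  with the tissue) with their own TICs — a look-alike uses the lesion's;
* shadows: whole-frame multiplicative attenuation over a frame interval;
* noise: additive Gaussian, clipped to [0, 1].

Everything is deterministic given ``SceneSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import BoundingBox, FrameSequence, save_annotations, save_sequence

__all__ = [
    "PerfusionCurve",
    "Distractor",
    "ShadowEvent",
    "SceneSpec",
    "GroundTruth",
    "evaluate_tic",
    "lesion_trajectory",
    "render_video",
    "export_fixture",
    "default_scene",
]


@dataclass(frozen=True)
class PerfusionCurve:
    """Log-normal bolus time-intensity curve.

    Intensity rises from ``baseline`` to ``peak`` at ``peak_time`` and
    decays back toward ``baseline``.  The rise and decay speeds are set by
    ``wash_in_rate`` and ``wash_out_rate`` (1/s): the log-normal shape
    parameter on each side of the peak is ``1 / (rate * peak_time)``, so a
    larger rate gives a steeper limb.
    """

    wash_in_rate: float = 0.5
    peak_time: float = 20.0
    wash_out_rate: float = 0.1
    baseline: float = 0.1
    peak: float = 0.8

    def __post_init__(self) -> None:
        if self.wash_in_rate <= 0 or self.wash_out_rate <= 0 or self.peak_time <= 0:
            raise ValueError("rates and peak_time must be positive")
        if not (0.0 <= self.baseline <= self.peak <= 1.0):
            raise ValueError("need 0 <= baseline <= peak <= 1")

    def __call__(self, t) -> np.ndarray | float:
        return evaluate_tic(self, t)


def evaluate_tic(curve: PerfusionCurve, t) -> np.ndarray | float:
    """Evaluate a perfusion curve at time ``t`` (seconds, scalar or array).

    ``I(t) = baseline + (peak - baseline) * exp(-ln(t/t_p)^2 / (2 s^2))``
    with ``s = 1/(wash_in_rate * t_p)`` before the peak and
    ``1/(wash_out_rate * t_p)`` after.  ``I(0) = baseline`` exactly and
    ``I(t) -> baseline`` as ``t -> inf``; the result is clipped to [0, 1].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.full(t_arr.shape, curve.baseline, dtype=float)
    pos = t_arr > 0
    if np.any(pos):
        tp = curve.peak_time
        log_ratio = np.log(t_arr[pos] / tp)
        s_in = 1.0 / (curve.wash_in_rate * tp)
        s_out = 1.0 / (curve.wash_out_rate * tp)
        s = np.where(t_arr[pos] < tp, s_in, s_out)
        bolus = np.exp(-(log_ratio**2) / (2.0 * s**2))
        out[pos] = curve.baseline + (curve.peak - curve.baseline) * bolus
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class Distractor:
    """A blob at a fixed offset from the lesion that moves with the tissue."""

    offset: tuple[float, float]  # (dx, dy) pixels from the lesion center
    radius: float
    curve: PerfusionCurve


@dataclass(frozen=True)
class ShadowEvent:
    """Transient acoustic shadow: frames in [start, start+duration) are
    multiplied by ``1 - attenuation``."""

    start: int
    duration: int
    attenuation: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.attenuation <= 1.0):
            raise ValueError("attenuation must be in [0, 1]")
        if self.duration < 0 or self.start < 0:
            raise ValueError("shadow interval must be non-negative")

    def covers(self, frame: int) -> bool:
        return self.start <= frame < self.start + self.duration


@dataclass
class SceneSpec:
    """Full parameterization of a synthetic CEUS scene.

    ``t0`` is the scene-clock offset of frame 0 in seconds: clinical
    annotation starts when the lesion first becomes visible, i.e. shortly
    after contrast arrival, not at injection time.
    """

    frame_shape: tuple[int, int] = (192, 256)  # (height, width)
    n_frames: int = 200
    fps: float = 15.0
    lesion_radius: float = 12.0
    lesion_curve: PerfusionCurve = field(
        default_factory=lambda: PerfusionCurve(
            wash_in_rate=0.5, peak_time=4.0, wash_out_rate=0.15, baseline=0.10, peak=0.90
        )
    )
    background_curve: PerfusionCurve = field(
        default_factory=lambda: PerfusionCurve(
            wash_in_rate=0.25, peak_time=8.0, wash_out_rate=0.15, baseline=0.15, peak=0.45
        )
    )
    t0: float = 0.5
    lesion_center0: tuple[float, float] | None = None  # defaults to frame center
    breathing_amplitude: tuple[float, float] = (15.0, 5.0)  # (ax, ay) pixels
    breathing_period: float = 40.0  # frames
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # pixels/frame
    distractors: Sequence[Distractor] = ()
    shadow_events: Sequence[ShadowEvent] = ()
    noise_sd: float = 0.02
    texture_amplitude: float = 0.25  # relative multiplicative speckle contrast
    texture_scale: float = 2.5  # Gaussian smoothing of the speckle field, px
    texture_decorrelation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for ev in self.shadow_events:
            if ev.start + ev.duration > self.n_frames:
                raise ValueError(
                    f"shadow event {ev} extends past the last frame ({self.n_frames})"
                )

    @property
    def center0(self) -> np.ndarray:
        if self.lesion_center0 is not None:
            return np.asarray(self.lesion_center0, dtype=float)
        h, w = self.frame_shape
        return np.array([w / 2.0, h / 2.0])

    def box_size(self) -> float:
        return 2.0 * self.lesion_radius


@dataclass
class GroundTruth:
    """Per-frame true lesion boxes plus the sparse-label stride."""

    boxes: list[BoundingBox]
    label_stride: int = 10

    def __len__(self) -> int:
        return len(self.boxes)

    def sparse(self) -> dict[int, BoundingBox]:
        """Every ``label_stride``-th frame, as a clinical annotator would mark."""
        return {i: b for i, b in enumerate(self.boxes) if i % self.label_stride == 0}

    def dense(self) -> dict[int, BoundingBox]:
        return dict(enumerate(self.boxes))


def lesion_trajectory(spec: SceneSpec) -> np.ndarray:
    """Analytic lesion-center positions, shape (n_frames, 2) as (x, y).

    ``c(t) = c0 + a * sin(2*pi*t/T) + v*t`` per axis, with t in frames.
    """
    t = np.arange(spec.n_frames, dtype=float)
    amp = np.asarray(spec.breathing_amplitude, dtype=float)
    drift = np.asarray(spec.drift_velocity, dtype=float)
    osc = amp[None, :] * np.sin(2.0 * np.pi * t / spec.breathing_period)[:, None]
    return spec.center0[None, :] + osc + drift[None, :] * t[:, None]


def _blob_profile(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, radius: float) -> np.ndarray:
    """Raised-cosine radial blob: 1 in the core, cosine taper to 0 at radius."""
    r = np.hypot(xx - cx, yy - cy)
    edge = 0.35 * radius  # taper width
    core = radius - edge
    w = np.zeros_like(r)
    w[r <= core] = 1.0
    band = (r > core) & (r < radius)
    w[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - core) / edge))
    return w


def _speckle_field(rng: np.random.Generator, shape: tuple[int, int], scale: float, amplitude: float) -> np.ndarray:
    """Zero-mean smooth multiplicative texture with the given RMS contrast."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=scale, mode="reflect")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return amplitude * smooth / sd


def render_video(spec: SceneSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render the scene; returns the frames and the exact ground truth.

    Raises if the lesion box ever leaves the frame, naming the first
    offending frame.
    """
    h, w = spec.frame_shape
    centers = lesion_trajectory(spec)
    half = spec.lesion_radius
    for i, (cx, cy) in enumerate(centers):
        if cx - half < 0 or cy - half < 0 or cx + half > w or cy + half > h:
            raise ValueError(
                f"lesion leaves the frame at frame {i}: center=({cx:.1f},{cy:.1f}), "
                f"radius={half}, frame={h}x{w}"
            )

    rng = np.random.default_rng(spec.seed)
    # texture canvas large enough for the maximal rigid shift
    shifts = centers - spec.center0[None, :]
    pad = int(np.ceil(np.abs(shifts).max())) + 4 if spec.n_frames > 1 else 4
    canvas_shape = (h + 2 * pad, w + 2 * pad)
    tex_a = _speckle_field(rng, canvas_shape, spec.texture_scale, spec.texture_amplitude)
    tex_b = _speckle_field(rng, canvas_shape, spec.texture_scale, spec.texture_amplitude)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    times = spec.t0 + np.arange(spec.n_frames) / spec.fps
    lesion_I = evaluate_tic(spec.lesion_curve, times)
    bg_I = evaluate_tic(spec.background_curve, times)
    lesion_I = np.atleast_1d(lesion_I)
    bg_I = np.atleast_1d(bg_I)

    frames = np.empty((spec.n_frames, h, w), dtype=float)
    boxes: list[BoundingBox] = []
    size = spec.box_size()
    for i in range(spec.n_frames):
        dx, dy = shifts[i]
        # sample the rigidly translated texture (cubic interpolation)
        coords = np.array([yy + pad - dy, xx + pad - dx])
        if spec.texture_decorrelation and spec.n_frames > 1:
            m = i / (spec.n_frames - 1)
        else:
            m = 0.0
        tex = (1.0 - m) * ndimage.map_coordinates(tex_a, coords, order=3, mode="nearest")
        if m > 0:
            tex = tex + m * ndimage.map_coordinates(tex_b, coords, order=3, mode="nearest")

        frame = bg_I[i] * (1.0 + tex)

        cx, cy = centers[i]
        blob = _blob_profile(xx, yy, cx, cy, spec.lesion_radius)
        frame = frame * (1.0 - blob) + blob * lesion_I[i] * (1.0 + 0.5 * tex)
        for d in spec.distractors:
            dcx, dcy = cx + d.offset[0], cy + d.offset[1]
            dblob = _blob_profile(xx, yy, dcx, dcy, d.radius)
            dI = evaluate_tic(d.curve, float(times[i]))
            frame = frame * (1.0 - dblob) + dblob * dI * (1.0 + 0.5 * tex)

        for ev in spec.shadow_events:
            if ev.covers(i):
                frame = frame * (1.0 - ev.attenuation)

        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)
        boxes.append(BoundingBox(float(cx), float(cy), size, size))

    seq = FrameSequence(frames, fps=spec.fps, origin=f"synthetic(seed={spec.seed})")
    return seq, GroundTruth(boxes=boxes, label_stride=10)


def export_fixture(
    seq: FrameSequence,
    gt: GroundTruth,
    dir_path: str | Path,
    fmt: str = "png",
) -> dict[str, object]:
    """Write frames plus a sparse annotation CSV; round-trips through
    :mod:`ceustrack.io` readers."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        files = save_sequence(seq, dir_path, fmt="png")
    else:
        files = save_sequence(seq, dir_path / "frames.tiff", fmt="tiff")
    ann_path = save_annotations(gt.sparse(), dir_path / "annotations.csv")
    return {"frames": files, "annotations": ann_path}


def default_scene(seed: int = 0) -> SceneSpec:
    """The package's reference test scene: 200 frames of 256x192 video with
    breathing motion (amplitude 15 px lateral / 5 px axial, period 40
    frames), a wash-in/wash-out lesion TIC against a slower background TIC
    (the lesion starts hypoechoic, crosses the background intensity around
    frame 10 and hyperenhances afterwards — the contrast inversion that
    makes a frozen frame-0 template stale), one look-alike distractor
    ~59 px from the lesion, and two 10-frame whole-frame shadow events."""
    lesion_curve = PerfusionCurve(
        wash_in_rate=0.5, peak_time=4.0, wash_out_rate=0.15, baseline=0.10, peak=0.90
    )
    return SceneSpec(
        distractors=(
            Distractor(offset=(48.0, -34.0), radius=12.0, curve=lesion_curve),
        ),
        shadow_events=(ShadowEvent(70, 10, 0.9), ShadowEvent(140, 10, 0.9)),
        seed=seed,
    )
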