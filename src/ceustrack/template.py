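"""Online adaptive template update with abnormal-frame suspension.

Contrast wash-in and wash-out change the lesion's appearance continuously,
so a frame-0 template goes stale.  The template is therefore refreshed by
linear superposition

    T_hat = (1 - gamma) * T_hat_prev + gamma * Z,

where ``Z`` is the patch (raw intensities for the NCC backend, features
for the learned one — the formula is the same) at the accepted lesion
location of the most recent processed frame.  Updates trigger every 5
frames, matching the ~15 fps cadence of clinical loops.

``gamma`` is either fixed at 0.7 or adapted from the time-intensity curve
(TIC) recorded over the tracked ROI: the relative intensity growth since
the last update, clamped to [0.1, 0.9] so the template neither freezes
nor is replaced outright.

Transient shadows would pollute the template, so frames whose ROI mean
intensity falls below a threshold eta are flagged abnormal and no match or
update is performed on them.  By default eta is relative — 0.35 times the
rolling median of the last 25 TIC samples — with an absolute override.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Template",
    "TicRecorder",
    "compute_gamma",
    "update_template",
    "should_update",
    "detect_abnormal",
]

UPDATE_STRIDE = 5
GAMMA_FIXED = 0.7
GAMMA_MIN = 0.1
GAMMA_MAX = 0.9
ETA_RELATIVE_FACTOR = 0.35
ETA_WINDOW = 25
_EPS = 1e-6


@dataclass
class Template:
    """Current matching template with its update bookkeeping."""

    data: np.ndarray  # raw patch (NCC) or feature map (learned backend)
    gamma: float = GAMMA_FIXED
    last_update_frame: int = 0
    source: str = "initial"  # "initial" | "updated"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("template contains non-finite values")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass
class TicRecorder:
    """Per-frame mean ROI intensity — the tracker's own TIC.

    ``reference`` holds the ROI intensity at the most recent template
    update; the adaptive gamma is the relative growth since then.
    """

    window: int = ETA_WINDOW
    samples: list[float] = field(default_factory=list)
    frame_indices: list[int] = field(default_factory=list)
    reference: float | None = None

    def record(self, frame_index: int, mean_intensity: float) -> None:
        v = float(mean_intensity)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"TIC sample {v} outside [0, 1]")
        if self.frame_indices and frame_index <= self.frame_indices[-1]:
            raise ValueError("TIC samples must arrive in frame order")
        self.samples.append(v)
        self.frame_indices.append(int(frame_index))
        if self.reference is None:
            self.reference = v

    @property
    def current(self) -> float:
        if not self.samples:
            raise ValueError("TIC has no samples yet")
        return self.samples[-1]

    def rolling_median(self) -> float:
        if not self.samples:
            raise ValueError("TIC has no samples yet")
        return float(np.median(self.samples[-self.window :]))

    def mark_update(self) -> None:
        """Remember the current intensity as the reference for gamma."""
        self.reference = self.current

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "mean_intensity"])
            for i, v in zip(self.frame_indices, self.samples):
                writer.writerow([i, repr(v)])


def compute_gamma(tic: TicRecorder, mode: str = "fixed") -> float:
    """Update weight gamma from the TIC.

    ``"fixed"`` returns 0.7.  ``"adaptive"`` returns the relative intensity
    growth since the last update, ``|I_now - I_ref| / max(I_ref, eps)``,
    clamped to [0.1, 0.9].
    """
    if not tic.samples:
        raise ValueError("cannot compute gamma from an empty TIC")
    if mode == "fixed":
        return GAMMA_FIXED
    if mode == "adaptive":
        i_ref = tic.reference if tic.reference is not None else tic.samples[0]
        growth = abs(tic.current - i_ref) / max(i_ref, _EPS)
        return float(np.clip(growth, GAMMA_MIN, GAMMA_MAX))
    raise ValueError(f"unknown gamma mode {mode!r}")


def update_template(tmpl: Template, new_data: np.ndarray, gamma: float) -> Template:
    """Element-wise convex combination ``(1-gamma)*old + gamma*new``."""
    new_data = np.asarray(new_data, dtype=float)
    if new_data.shape != tmpl.data.shape:
        raise ValueError(
            f"template shape {tmpl.data.shape} != new data shape {new_data.shape}"
        )
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    blended = (1.0 - gamma) * tmpl.data + gamma * new_data
    return replace(tmpl, data=blended, gamma=float(gamma), source="updated")


def should_update(frame_index: int, last_update_frame: int, abnormal: bool) -> bool:
    """True when at least 5 frames have passed since the last update and the
    current frame is not abnormal."""
    if frame_index < last_update_frame:
        raise ValueError("frame indices must be non-decreasing")
    return (frame_index - last_update_frame >= UPDATE_STRIDE) and not abnormal


def detect_abnormal(
    tic: TicRecorder,
    eta_mode: str = "relative",
    eta_abs: float = 0.05,
) -> bool:
    """Is the current frame abnormal (shadowed)?

    ``"relative"``: current intensity < 0.35 x rolling median of the last
    25 samples.  ``"absolute"``: current intensity < ``eta_abs``.
    """
    current = tic.current
    if eta_mode == "relative":
        return current < ETA_RELATIVE_FACTOR * tic.rolling_median()
    if eta_mode == "absolute":
        return current < eta_abs
    raise ValueError(f"unknown eta mode {eta_mode!r}")
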