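"""Per-frame tracking pipeline.

Each frame is processed in five stages:

1. *Motion prior* — Lucas-Kanade flow over the previous ROI gives a
   position measurement that drives a constant-velocity Kalman filter;
   its filtered position l_c centers the search region (replacing the
   constant-position assumption of a plain Siamese matcher).
2. *Abnormal check* — if the ROI mean intensity at l_c falls below the
   shadow threshold eta, the frame is abnormal: the output box is the
   Kalman prediction and neither matching nor template update runs.
3. *Matching* — the search window is cropped at l_c, correlated with the
   template, the score map upsampled to pixel resolution and fused with
   the Gaussian motion attention (multiplicative by default; candidates
   with attention below 1e-4 are excluded); the fused argmax is the new
   center.
4. *Filter refresh* — the matched center re-updates the Kalman filter
   with a small measurement covariance (closing the loop).
5. *Template update* — the ROI TIC is appended and the template is
   refreshed every 5 frames on normal frames.

Boxes keep their initial size throughout: lesions in CEUS loops
essentially translate, so the tracker estimates translation only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import motion, template as template_mod
from .io import BoundingBox, FrameSequence
from .matcher import FeatureMap, get_backend

__all__ = ["TrackerConfig", "TrackResult", "Tracker", "run"]


@dataclass
class TrackerConfig:
    backend: str = "ncc"
    weights: str | None = None  # checkpoint path for the learned backend
    template_margin: int = 8  # context pixels around the box in the template
    search_radius: int = 32  # search window extends this far beyond the template
    flow_window: int = 15
    flow_patch_grid: tuple[int, int] = (4, 4)
    q: float = 0.25  # white-acceleration process noise (px^2/frame^4)
    r_flow: float = 4.0  # measurement noise of the flow measurement (px^2)
    r_match: float = 1.0  # measurement noise of the matched center (px^2)
    attention_threshold: float = motion.ATTENTION_THRESHOLD
    update_stride: int = template_mod.UPDATE_STRIDE
    gamma_mode: str = "fixed"  # "fixed" (0.7) | "adaptive" (TIC growth)
    eta_mode: str = "relative"  # "relative" | "absolute"
    eta_abs: float = 0.05
    fusion: str = "masked-argmax"  # "masked-argmax" | "multiplicative"
    use_attention: bool = True  # temporal motion attention (TMA) on/off
    use_template_update: bool = True  # template update + abnormal handling (TU)
    close_loop: bool = True  # feed the matched center back into the filter

    def __post_init__(self) -> None:
        if self.backend not in ("ncc", "learned"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.fusion not in ("multiplicative", "masked-argmax"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.gamma_mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown gamma mode {self.gamma_mode!r}")
        if self.eta_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown eta mode {self.eta_mode!r}")


@dataclass
class TrackResult:
    """Per-frame tracking records plus the wall-clock throughput."""

    boxes: list[BoundingBox] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    sigmas: list[float] = field(default_factory=list)
    abnormal: list[bool] = field(default_factory=list)
    measurement_used: list[bool] = field(default_factory=list)
    pred_centers: list[np.ndarray] = field(default_factory=list)  # Kalman l_c
    fps: float = float("nan")

    def __len__(self) -> int:
        return len(self.boxes)

    def centers(self) -> np.ndarray:
        return np.array([[b.cx, b.cy] for b in self.boxes])

    def boxes_dict(self) -> dict[int, BoundingBox]:
        return dict(enumerate(self.boxes))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self.boxes)),
                "cx": [b.cx for b in self.boxes],
                "cy": [b.cy for b in self.boxes],
                "w": [b.w for b in self.boxes],
                "h": [b.h for b in self.boxes],
                "score": self.scores,
                "abnormal": self.abnormal,
                "sigma": self.sigmas,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _odd(n: float) -> int:
    n = int(round(n))
    return n if n % 2 == 1 else n + 1


class Tracker:
    """Stateful per-frame tracker; see the module docstring for the stages."""

    def __init__(self, frame0: np.ndarray, box0: BoundingBox, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        frame0 = np.asarray(frame0, dtype=float)
        if not box0.inside(frame0.shape):
            raise ValueError(f"initial box {box0} outside frame {frame0.shape}")
        if box0.w < 2 or box0.h < 2:
            raise ValueError(f"initial box too small: {box0}")
        self.backend = get_backend(self.config.backend, self.config.weights)
        self.box_w, self.box_h = box0.w, box0.h
        self.frame_shape = frame0.shape

        m = self.config.template_margin
        self.templ_size = (_odd(box0.h + 2 * m), _odd(box0.w + 2 * m))  # (h, w)
        if self.templ_size[0] > frame0.shape[0] or self.templ_size[1] > frame0.shape[1]:
            raise ValueError(
                f"template patch {self.templ_size} larger than frame {frame0.shape}"
            )
        s = 2 * self.config.search_radius
        # the search window never exceeds the frame itself
        self.search_size = (
            min(self.templ_size[0] + s, frame0.shape[0]),
            min(self.templ_size[1] + s, frame0.shape[1]),
        )

        center = box0.center
        patch, _ = self._extract(frame0, center, self.templ_size)
        feat = self.backend.embed(patch)
        self.template = template_mod.Template(data=feat.data, gamma=template_mod.GAMMA_FIXED)
        self._feat_geometry = (feat.stride, feat.offset)

        self.params = motion.KalmanParams.default(q=self.config.q, r=self.config.r_flow)
        self.state = motion.MotionState.initial(center)
        self.tic = template_mod.TicRecorder()
        self.tic.record(0, self._roi_mean(frame0, center))
        self.history: list[float] = []
        self.prev_frame = frame0
        self.prev_center = center.copy()
        self.prev_abnormal = False
        self.frame_index = 0
        self.update_frames: list[int] = [0]  # frames whose patch entered the template

        self.result = TrackResult()
        self._append_record(box0.center, score=1.0, sigma=float("nan"), abnormal=False, meas=False)

    # ------------------------------------------------------------------
    def _clamp_center(self, center: np.ndarray, size_hw: tuple[float, float]) -> np.ndarray:
        h, w = size_hw
        H, W = self.frame_shape
        cx = float(np.clip(center[0], w / 2.0, W - w / 2.0))
        cy = float(np.clip(center[1], h / 2.0, H - h / 2.0))
        return np.array([cx, cy])

    def _extract(self, frame: np.ndarray, center: np.ndarray, size_hw: tuple[int, int]):
        """Crop a (h, w) patch near ``center``, slid inside the frame.

        Returns the patch and the image coordinates (x0, y0) of its
        top-left pixel.
        """
        h, w = size_hw
        H, W = frame.shape
        if h > H or w > W:
            raise ValueError(f"patch {size_hw} larger than frame {frame.shape}")
        x0 = int(round(center[0] - (w - 1) / 2.0))
        y0 = int(round(center[1] - (h - 1) / 2.0))
        x0 = min(max(x0, 0), W - w)
        y0 = min(max(y0, 0), H - h)
        return frame[y0 : y0 + h, x0 : x0 + w], (x0, y0)

    def _roi_mean(self, frame: np.ndarray, center: np.ndarray) -> float:
        size = (max(int(round(self.box_h)), 1), max(int(round(self.box_w)), 1))
        c = self._clamp_center(center, size)
        patch, _ = self._extract(frame, c, size)
        return float(np.clip(patch.mean(), 0.0, 1.0))

    def _template_feature_map(self) -> FeatureMap:
        stride, offset = self._feat_geometry
        return FeatureMap(data=self.template.data, stride=stride, offset=offset)

    def _append_record(self, center, score, sigma, abnormal, meas, pred_center=None) -> None:
        self.result.boxes.append(
            BoundingBox(float(center[0]), float(center[1]), self.box_w, self.box_h)
        )
        self.result.scores.append(float(score))
        self.result.sigmas.append(float(sigma))
        self.result.abnormal.append(bool(abnormal))
        self.result.measurement_used.append(bool(meas))
        if pred_center is None:
            pred_center = np.asarray(center, dtype=float)
        self.result.pred_centers.append(np.asarray(pred_center, dtype=float).copy())

    # ------------------------------------------------------------------
    def step(self, frame: np.ndarray) -> BoundingBox:
        frame = np.asarray(frame, dtype=float)
        if frame.shape != self.frame_shape:
            raise ValueError(
                f"frame {self.frame_index + 1} shape {frame.shape} != {self.frame_shape}"
            )
        cfg = self.config
        t = self.frame_index + 1
        measurement_used = False
        sigma_used = float("nan")

        # -- stage 1: motion prior -------------------------------------
        if cfg.use_attention:
            state_pred = motion.kf_predict(self.state, self.params)
            l_c = self._clamp_center(state_pred.position, (self.box_h, self.box_w))
        else:
            state_pred = self.state
            l_c = self.prev_center.copy()

        # -- stage 2: abnormal (shadow) check --------------------------
        roi_now = self._roi_mean(frame, l_c)
        self.tic.record(t, roi_now)
        abnormal = cfg.use_template_update and template_mod.detect_abnormal(
            self.tic, cfg.eta_mode, cfg.eta_abs
        )

        if abnormal:
            # predict-only propagation: reposition from motion information
            if cfg.use_attention:
                self.state = state_pred
            new_center = l_c
            score = float("nan")
        else:
            if cfg.use_attention:
                if not self.prev_abnormal:
                    roi_box = BoundingBox(
                        *self._clamp_center(self.prev_center, (self.box_h, self.box_w)),
                        self.box_w,
                        self.box_h,
                    )
                    fl = flow_mod.roi_flow(
                        self.prev_frame,
                        frame,
                        roi_box,
                        patch_grid=cfg.flow_patch_grid,
                        window_size=cfg.flow_window,
                    )
                    z = motion.flow_to_measurement(self.prev_center, fl)
                else:
                    z = None  # intensity constancy known to be violated
                if z is not None:
                    self.state = motion.kf_update(state_pred, z, self.params)
                    measurement_used = True
                else:
                    self.state = state_pred
                l_c = self._clamp_center(self.state.position, (self.box_h, self.box_w))

            # -- stage 3: matching -------------------------------------
            search, (sx0, sy0) = self._extract(frame, l_c, self.search_size)
            sf = self.backend.embed(search)
            smap = self.backend.correlate(self._template_feature_map(), sf).upsampled()
            if smap.flat:
                new_center = l_c
                score = 0.0
            else:
                origin_img = (sx0 + smap.origin[0], sy0 + smap.origin[1])
                if cfg.use_attention:
                    # history jitter, widened by the filter's own position
                    # uncertainty so re-localization after a shadow searches
                    # as far as the prediction may have drifted
                    pos_sd = float(np.sqrt(max(np.linalg.eigvalsh(self.state.P[:2, :2]).max(), 0.0)))
                    sigma_raw = max(motion.sigma_from_history(self.history), pos_sd)
                    sigma_used = float(np.clip(sigma_raw, motion.SIGMA_MIN, motion.SIGMA_MAX))
                    att = motion.attention_map(
                        l_c,
                        sigma_raw,
                        smap.values.shape,
                        origin=origin_img,
                        step=smap.step,
                        threshold=cfg.attention_threshold,
                    )
                    if cfg.fusion == "multiplicative":
                        v = smap.values
                        rng_v = v.max() - v.min()
                        norm = (v - v.min()) / rng_v if rng_v > 0 else np.ones_like(v)
                        fused = norm * att.values
                    else:  # masked-argmax
                        fused = smap.values.astype(float).copy()
                    fused = np.where(att.valid_mask, fused, -np.inf)
                else:
                    fused = smap.values

                if not np.isfinite(fused).any():
                    new_center = l_c
                    score = float(smap.values.max())
                else:
                    new_center, score = self._fused_argmax(fused, smap, origin_img, l_c)

            # -- stage 4: close the loop -------------------------------
            if cfg.use_attention and cfg.close_loop and not smap.flat:
                self.state = motion.kf_update(
                    self.state, new_center, self.params, R=cfg.r_match * np.eye(2)
                )

            # -- stage 5: TIC + template update ------------------------
            if cfg.use_template_update and template_mod.should_update(
                t, self.template.last_update_frame, abnormal
            ):
                gamma = template_mod.compute_gamma(self.tic, cfg.gamma_mode)
                patch, _ = self._extract(frame, new_center, self.templ_size)
                z_feat = self.backend.embed(patch)
                self.template = template_mod.update_template(self.template, z_feat.data, gamma)
                self.template.last_update_frame = t
                self.tic.mark_update()
                self.update_frames.append(t)

        self.history.append(float(np.linalg.norm(new_center - self.prev_center)))
        self.prev_center = np.asarray(new_center, dtype=float)
        self.prev_frame = frame
        self.prev_abnormal = abnormal
        self.frame_index = t
        self._append_record(new_center, score, sigma_used, abnormal, measurement_used, l_c)
        return self.result.boxes[-1]

    def _fused_argmax(self, fused, smap, origin_img, l_c):
        """Deterministic argmax: ties broken by distance to l_c, then row-major."""
        maxv = fused.max()
        cand = np.argwhere(fused == maxv)
        xs = origin_img[0] + smap.step * cand[:, 1]
        ys = origin_img[1] + smap.step * cand[:, 0]
        d = np.hypot(xs - l_c[0], ys - l_c[1])
        # lexicographic: distance, row, col
        best = min(range(len(cand)), key=lambda k: (d[k], cand[k, 0], cand[k, 1]))
        center = np.array([xs[best], ys[best]])
        i, j = cand[best]
        return center, float(smap.values[i, j])


def run(
    seq: FrameSequence | Sequence[np.ndarray],
    box0: BoundingBox,
    config: TrackerConfig | None = None,
) -> TrackResult:
    """Track through a whole sequence; deterministic for the NCC backend."""
    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq, dtype=float)
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    t_start = time.perf_counter()
    tracker = Tracker(frames[0], box0, config)
    for i in range(1, len(frames)):
        try:
            tracker.step(frames[i])
        except Exception as exc:
            raise RuntimeError(f"tracking failed at frame {i}: {exc}") from exc
    elapsed = time.perf_counter() - t_start
    tracker.result.fps = len(frames) / elapsed if elapsed > 0 else float("inf")
    return tracker.result
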