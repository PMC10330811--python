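"""Minimal numpy CNN for the learned Siamese branch.

A small fully-convolutional feature extractor (five conv layers with
16, 32, 64, 128 and 64 channels, interleaved ReLU and 2x2 max-pooling,
no padding) embeds template and search patches into a shared feature
space; cross-correlating the two embeddings yields the score map.  The
network is trained offline with a logistic loss on the score map: cells
whose candidate center lies within a small radius of the true target
center are positive, all others negative, with the two classes weighted
to contribute equally.

Everything here — im2col convolution, backprop, SGD with momentum and
weight decay, Adam — is implemented directly on numpy arrays; the layer
schedule and all optimizer hyperparameters are config-exposed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "Backbone",
    "TrainConfig",
    "logistic_score_loss",
    "cross_correlate",
    "cross_correlate_backward",
    "train_backbone",
    "save_checkpoint",
    "load_checkpoint",
]

# (kind, kernel, stride, out_channels, relu)
DEFAULT_SCHEDULE: tuple[tuple, ...] = (
    ("conv", 11, 2, 16, True),
    ("pool", 2, 2, None, False),
    ("conv", 5, 1, 32, True),
    ("pool", 2, 2, None, False),
    ("conv", 3, 1, 64, True),
    ("conv", 3, 1, 128, True),
    ("conv", 3, 1, 64, False),
)


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # "conv" | "pool"
    kernel: int
    stride: int
    out_channels: int | None
    relu: bool


def _as_specs(schedule: Sequence[tuple]) -> list[LayerSpec]:
    return [LayerSpec(*entry) for entry in schedule]


def _im2col(x: np.ndarray, k: int | tuple[int, int], stride: int) -> tuple[np.ndarray, tuple[int, int]]:
    """(C, H, W) -> (L, C*kh*kw) matrix of patch rows; L = Ho*Wo."""
    kh, kw = (k, k) if isinstance(k, int) else k
    C, H, W = x.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, Ho, Wo, kh, kw)
    cols = win.transpose(1, 2, 0, 3, 4).reshape(Ho * Wo, C * kh * kw)
    return np.ascontiguousarray(cols), (Ho, Wo)


def _col2im(dcols: np.ndarray, x_shape: tuple[int, int, int], k: int | tuple[int, int], stride: int) -> np.ndarray:
    kh, kw = (k, k) if isinstance(k, int) else k
    C, H, W = x_shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    d = dcols.reshape(Ho, Wo, C, kh, kw)
    dx = np.zeros(x_shape)
    for a in range(kh):
        for b in range(kw):
            dx[:, a : a + Ho * stride : stride, b : b + Wo * stride : stride] += d[
                :, :, :, a, b
            ].transpose(2, 0, 1)
    return dx


class Backbone:
    """Fully-convolutional feature extractor with shared Siamese weights."""

    def __init__(
        self,
        schedule: Sequence[tuple] = DEFAULT_SCHEDULE,
        in_channels: int = 1,
        seed: int = 0,
    ) -> None:
        self.specs = _as_specs(schedule)
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = in_channels
        for i, spec in enumerate(self.specs):
            if spec.kind == "conv":
                fan_in = c_in * spec.kernel * spec.kernel
                w = rng.standard_normal((spec.out_channels, fan_in)) * np.sqrt(2.0 / fan_in)
                self.params[f"W{i}"] = w
                self.params[f"b{i}"] = np.zeros(spec.out_channels)
                c_in = spec.out_channels
        self.out_channels = c_in
        # learnable affine on the centered score map (the 'adjust' head):
        # raw correlations carry a large DC offset, so the head sees
        # a * (raw - mean(raw)) + b
        self.params["adjust_a"] = np.array([1.0])
        self.params["adjust_b"] = np.array([0.0])

    # -- geometry -------------------------------------------------------
    def geometry(self) -> tuple[int, float]:
        """Total stride and the image offset (px) of feature cell (0, 0)."""
        step, origin = 1.0, 0.0
        for spec in self.specs:
            origin += (spec.kernel - 1) / 2.0 * step
            step *= spec.stride
        return int(step), origin

    def min_input(self) -> int:
        """Smallest square input that yields a 1x1 feature map."""
        size = 1
        for spec in reversed(self.specs):
            size = (size - 1) * spec.stride + spec.kernel
        return size

    def output_size(self, n: int) -> int:
        for spec in self.specs:
            n = (n - spec.kernel) // spec.stride + 1
            if n < 1:
                raise ValueError(
                    f"input too small for backbone; minimum is {self.min_input()} px"
                )
        return n

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (C_in, H, W) in [0,1]. Returns features (and a backprop cache)."""
        if x.ndim == 2:
            x = x[None]
        cache: list[tuple] = []
        for i, spec in enumerate(self.specs):
            if spec.kind == "conv":
                cols, (Ho, Wo) = _im2col(x, spec.kernel, spec.stride)
                pre = cols @ self.params[f"W{i}"].T + self.params[f"b{i}"]
                out = pre.reshape(Ho, Wo, spec.out_channels).transpose(2, 0, 1)
                if spec.relu:
                    mask = out > 0
                    out = out * mask
                else:
                    mask = None
                if want_cache:
                    cache.append(("conv", i, x.shape, cols, mask))
                x = out
            else:  # pool
                C, H, W = x.shape
                H2, W2 = H // spec.kernel, W // spec.kernel
                xr = x[:, : H2 * spec.kernel, : W2 * spec.kernel].reshape(
                    C, H2, spec.kernel, W2, spec.kernel
                )
                out = xr.max(axis=(2, 4))
                if want_cache:
                    argmask = xr == out[:, :, None, :, None]
                    cache.append(("pool", i, x.shape, xr.shape, argmask))
                x = out
        return (x, cache) if want_cache else x

    def score_map(self, templ_feat: np.ndarray, search_feat: np.ndarray) -> np.ndarray:
        """Adjusted score map ``a * (corr - mean(corr)) + b``.

        Per-map centering removes the DC offset of raw feature
        correlations; the affine is learned with the backbone.  Both
        operations are monotone, so the argmax equals the raw one."""
        raw = cross_correlate(templ_feat, search_feat)
        a = float(self.params["adjust_a"][0])
        b = float(self.params["adjust_b"][0])
        return a * (raw - raw.mean()) + b

    def backward(self, dout: np.ndarray, cache: list[tuple]) -> dict[str, np.ndarray]:
        """Backprop dL/dfeatures through the cached forward pass.

        Returns parameter gradients; the input gradient is discarded (the
        raw image is not optimized).
        """
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d = dout
        for entry in reversed(cache):
            if entry[0] == "conv":
                _, i, x_shape, cols, mask = entry
                spec = self.specs[i]
                if mask is not None:
                    d = d * mask
                dmat = d.transpose(1, 2, 0).reshape(-1, spec.out_channels)
                grads[f"W{i}"] += dmat.T @ cols
                grads[f"b{i}"] += dmat.sum(axis=0)
                dcols = dmat @ self.params[f"W{i}"]
                d = _col2im(dcols, x_shape, spec.kernel, spec.stride)
            else:
                _, i, x_shape, xr_shape, argmask = entry
                spec = self.specs[i]
                C, H, W = x_shape
                dxr = argmask * d[:, :, None, :, None]
                dx = np.zeros(x_shape)
                H2, W2 = xr_shape[1], xr_shape[3]
                dx[:, : H2 * spec.kernel, : W2 * spec.kernel] = dxr.reshape(
                    C, H2 * spec.kernel, W2 * spec.kernel
                )
                d = dx
        return grads


def cross_correlate(templ: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Valid sliding inner product over channels: (C,ht,wt) x (C,Hs,Ws) ->
    (Hs-ht+1, Ws-wt+1)."""
    C, ht, wt = templ.shape
    Cs = search.shape[0]
    if Cs != C:
        raise ValueError(f"channel mismatch: template {C}, search {Cs}")
    if search.shape[1] < ht or search.shape[2] < wt:
        raise ValueError("search feature map smaller than template feature map")
    cols, (Ho, Wo) = _im2col(search, (ht, wt), 1)
    # im2col rows are (C, kh, kw) flattened with C slowest, matching reshape
    score = cols @ templ.reshape(C * ht * wt)
    return score.reshape(Ho, Wo)


def cross_correlate_backward(
    dscore: np.ndarray, templ: np.ndarray, search: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the sliding inner product w.r.t. both feature maps."""
    C, ht, wt = templ.shape
    win = np.lib.stride_tricks.sliding_window_view(search, (ht, wt), axis=(1, 2))
    dtempl = np.einsum("cijab,ij->cab", win, dscore)
    dcols = np.outer(dscore.reshape(-1), templ.reshape(-1))
    dsearch = _col2im(dcols, search.shape, (ht, wt), 1)
    return dtempl, dsearch


def logistic_score_loss(
    score: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-balanced logistic loss on a score map.

    ``labels`` is +/-1 per cell.  Positive and negative cells each carry
    half the total weight, so an all-zero score map costs exactly log 2.
    Returns (loss, dloss/dscore).
    """
    y = labels.astype(float)
    n_pos = max(int((y > 0).sum()), 1)
    n_neg = max(int((y < 0).sum()), 1)
    w = np.where(y > 0, 0.5 / n_pos, 0.5 / n_neg)
    if not (y > 0).any():
        w = np.where(y < 0, 1.0 / n_neg, 0.0)
    if not (y < 0).any():
        w = np.where(y > 0, 1.0 / n_pos, 0.0)
    margin = -y * score
    loss = float(np.sum(w * np.logaddexp(0.0, margin)))
    dscore = -y * w * _sigmoid(margin)
    return loss, dscore


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class TrainConfig:
    """Offline training hyperparameters.

    The default learning rate of 1e-7 is deliberately conservative and is
    tuned to clinical-scale data; desk-scale smoke runs on synthetic pairs
    should pass a larger value explicitly (see docs/methods.md).
    """

    lr: float = 1e-7
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 8
    epochs: int = 200
    optimizer: str = "sgd"  # "sgd" | "adam"
    pos_radius_px: float = 16.0
    seed: int = 0


@dataclass
class TrainResult:
    backbone: Backbone
    batch_losses: list[float]
    epoch_losses: list[float]


class _Optimizer:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v2 = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        self.t += 1
        for k in params:
            g = grads[k] + cfg.weight_decay * params[k]
            if cfg.optimizer == "sgd":
                self.vel[k] = cfg.momentum * self.vel[k] + g
                params[k] -= cfg.lr * self.vel[k]
            elif cfg.optimizer == "adam":
                b1, b2, eps = 0.9, 0.999, 1e-8
                self.m[k] = b1 * self.m[k] + (1 - b1) * g
                self.v2[k] = b2 * self.v2[k] + (1 - b2) * g * g
                mhat = self.m[k] / (1 - b1**self.t)
                vhat = self.v2[k] / (1 - b2**self.t)
                params[k] -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
            else:
                raise ValueError(f"unknown optimizer {cfg.optimizer!r}")


def _score_cell_centers(
    backbone: Backbone, templ_px: int, search_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Image-coordinate (x, y) offsets of each score cell's candidate center
    relative to the search-patch center."""
    stride, origin = backbone.geometry()
    ft = backbone.output_size(templ_px)
    fs = backbone.output_size(search_px)
    n = fs - ft + 1
    idx = np.arange(n)
    centers = origin + stride * (idx + (ft - 1) / 2.0) - (search_px - 1) / 2.0
    return centers, centers  # identical for square geometry


def train_backbone(
    pair_sampler: Iterable[tuple[np.ndarray, np.ndarray, tuple[float, float]]],
    config: TrainConfig,
    backbone: Backbone | None = None,
    checkpoint_dir: str | Path | None = None,
) -> TrainResult:
    """Train the Siamese backbone on (template, search, true-offset) triples.

    ``true_offset`` is the target-center offset (x, y) in pixels from the
    search-patch center.  Pairs are shuffled per epoch with the config
    seed; the per-batch loss curve and a final checkpoint are written to
    ``checkpoint_dir`` when given.
    """
    pairs = list(pair_sampler)
    if not pairs:
        raise ValueError("pair sampler produced no training pairs")
    if backbone is None:
        backbone = Backbone(seed=config.seed)
    opt = _Optimizer(backbone.params, config)
    rng = np.random.default_rng(config.seed)

    batch_losses: list[float] = []
    epoch_losses: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        ep_losses = []
        for start in range(0, len(pairs), config.batch_size):
            batch = [pairs[i] for i in order[start : start + config.batch_size]]
            grads = {k: np.zeros_like(v) for k, v in backbone.params.items()}
            loss_sum = 0.0
            for templ_img, search_img, offset in batch:
                tf, tcache = backbone.forward(np.asarray(templ_img, float), True)
                sf, scache = backbone.forward(np.asarray(search_img, float), True)
                raw = cross_correlate(tf, sf)
                centered = raw - raw.mean()
                a = float(backbone.params["adjust_a"][0])
                score = a * centered + float(backbone.params["adjust_b"][0])
                cx_off, cy_off = _score_cell_centers(
                    backbone, templ_img.shape[-1], search_img.shape[-1]
                )
                d2 = (cx_off[None, :] - offset[0]) ** 2 + (cy_off[:, None] - offset[1]) ** 2
                labels = np.where(np.sqrt(d2) <= config.pos_radius_px, 1.0, -1.0)
                loss, dscore = logistic_score_loss(score, labels)
                loss_sum += loss
                grads["adjust_a"] += np.array([float(np.sum(dscore * centered))])
                grads["adjust_b"] += np.array([float(np.sum(dscore))])
                draw = a * (dscore - dscore.mean())  # backprop through centering
                dtf, dsf = cross_correlate_backward(draw, tf, sf)
                for k, v in backbone.backward(dtf, tcache).items():
                    grads[k] += v
                for k, v in backbone.backward(dsf, scache).items():
                    grads[k] += v
            n = len(batch)
            for k in grads:
                grads[k] /= n
            opt.step(backbone.params, grads)
            batch_losses.append(loss_sum / n)
            ep_losses.append(loss_sum / n)
        epoch_losses.append(float(np.mean(ep_losses)))

    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(backbone, checkpoint_dir / "backbone.npz")
        with open(checkpoint_dir / "loss_curve.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["batch", "loss"])
            for i, l in enumerate(batch_losses):
                writer.writerow([i, l])
    return TrainResult(backbone=backbone, batch_losses=batch_losses, epoch_losses=epoch_losses)


def synthetic_pair_sampler(
    n_pairs: int,
    templ_px: int = 97,
    search_px: int = 193,
    max_offset: float = 24.0,
    seed: int = 0,
):
    """Training triples (template, search, true-offset) from synthetic scenes.

    Templates are cut at the true lesion center of one frame; the search
    patch is cut in a nearby frame at the lesion center plus a uniform
    jitter up to ``max_offset`` px, so the target sits at ``-jitter``
    relative to the search-patch center.  Desk-scale counterpart of
    sampling annotated clinical video clips.
    """
    from .synthetic import SceneSpec, lesion_trajectory, render_video

    rng = np.random.default_rng(seed)
    pairs = []
    n_scenes = max(1, n_pairs // 16)
    margin = search_px // 2 + int(max_offset) + 2
    shape = (2 * margin + 48, 2 * margin + 64)
    for s in range(n_scenes):
        spec = SceneSpec(
            frame_shape=shape,
            n_frames=20,
            breathing_amplitude=(8.0, 4.0),
            breathing_period=20.0,
            noise_sd=0.02,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        seq, gt = render_video(spec)
        centers = lesion_trajectory(spec)
        while len(pairs) < (s + 1) * n_pairs // n_scenes:
            ia, ib = rng.integers(0, len(seq), size=2)
            ca, cb = centers[ia], centers[ib]
            jitter = rng.uniform(-max_offset, max_offset, size=2)
            sc = np.round(cb + jitter).astype(int)
            tc = np.round(ca).astype(int)
            tpatch = _crop(seq[ia], tc, templ_px)
            spatch = _crop(seq[ib], sc, search_px)
            if tpatch is None or spatch is None:
                continue
            true_off = (float(cb[0] - sc[0]), float(cb[1] - sc[1]))
            pairs.append((tpatch, spatch, true_off))
    return pairs[:n_pairs]


def _crop(frame: np.ndarray, center: np.ndarray, size: int) -> np.ndarray | None:
    half = size // 2
    x0, y0 = int(center[0]) - half, int(center[1]) - half
    if x0 < 0 or y0 < 0 or y0 + size > frame.shape[0] or x0 + size > frame.shape[1]:
        return None
    return frame[y0 : y0 + size, x0 : x0 + size].copy()


CHECKPOINT_VERSION = "ceustrack-backbone-v1"


def save_checkpoint(backbone: Backbone, path: str | Path) -> Path:
    path = Path(path)
    schedule = np.array(
        [
            (s.kind, s.kernel, s.stride, -1 if s.out_channels is None else s.out_channels, int(s.relu))
            for s in backbone.specs
        ],
        dtype=object,
    )
    np.savez(
        path,
        __version__=CHECKPOINT_VERSION,
        __in_channels__=backbone.in_channels,
        __schedule__=schedule,
        **backbone.params,
    )
    return path


def load_checkpoint(path: str | Path) -> Backbone:
    with np.load(path, allow_pickle=True) as data:
        version = str(data["__version__"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version!r}")
        schedule = [
            (str(k), int(ker), int(st), None if int(oc) < 0 else int(oc), bool(int(r)))
            for k, ker, st, oc, r in data["__schedule__"]
        ]
        bb = Backbone(schedule=schedule, in_channels=int(data["__in_channels__"]))
        for key in bb.params:
            bb.params[key] = data[key]
    return bb
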