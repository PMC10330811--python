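"""Siamese template matching: feature embedding and cross-correlation.

Two interchangeable backends produce the score map ``s(z, x) = phi(z) * phi(x)``
(valid sliding cross-correlation of the embedded template ``z`` over the
embedded search region ``x``):

* ``"ncc"`` — phi is the identity (raw intensities, stride 1) and the
  correlation is zero-mean, unit-norm normalized cross-correlation, so
  scores live in [-1, 1] and a perfect copy scores exactly 1.  This
  backend is training-free and fully deterministic; it is the default.
* ``"learned"`` — phi is the five-layer convolutional network of
  :mod:`ceustrack.nn` (channels 16, 32, 64, 128, 64) trained offline; the
  correlation is the plain inner product in feature space.

Both backends report the affine map from score-map cells to image
coordinates, so the tracker can fuse scores with the motion attention on
one grid; learned-backend score maps are bicubically upsampled to pixel
resolution before fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from . import nn

__all__ = ["FeatureMap", "ScoreMap", "NCCBackend", "LearnedBackend", "get_backend"]

FLAT_EPS = 1e-8


@dataclass
class FeatureMap:
    """Embedded patch: (channels, height, width) grid plus the geometry
    needed to map feature cells back to patch pixels."""

    data: np.ndarray
    stride: int  # pixels per feature cell
    offset: float  # patch-pixel coordinate of feature cell (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class ScoreMap:
    """Similarity scores over candidate template placements.

    Cell (i, j) scores the candidate whose *center* sits at search-patch
    coordinate ``origin + step * (j, i)`` (x, y).  ``flat`` marks a
    degenerate correlation (e.g. an all-equal template under NCC).
    """

    values: np.ndarray
    origin: tuple[float, float]
    step: float
    flat: bool = False

    def candidate_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) of candidate centers: xs per column, ys per row."""
        rows, cols = self.values.shape
        xs = self.origin[0] + self.step * np.arange(cols)
        ys = self.origin[1] + self.step * np.arange(rows)
        return xs, ys

    def peak(self) -> tuple[float, np.ndarray]:
        """(peak score, candidate center (x, y) in search-patch coords)."""
        idx = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        xs, ys = self.candidate_coords()
        return float(self.values[idx]), np.array([xs[idx[1]], ys[idx[0]]])

    def upsampled(self) -> "ScoreMap":
        """Bicubic upsampling to one-pixel candidate spacing (no-op at step 1)."""
        if self.step == 1.0:
            return self
        rows, cols = self.values.shape
        n_x = int(round((cols - 1) * self.step)) + 1
        n_y = int(round((rows - 1) * self.step)) + 1
        jj, ii = np.meshgrid(np.arange(n_x) / self.step, np.arange(n_y) / self.step)
        vals = ndimage.map_coordinates(self.values, [ii, jj], order=3, mode="nearest")
        return ScoreMap(values=vals, origin=self.origin, step=1.0, flat=self.flat)


class NCCBackend:
    """Training-free backend: identity embedding + normalized cross-correlation."""

    name = "ncc"
    stride = 1

    def embed(self, patch: np.ndarray) -> FeatureMap:
        patch = np.asarray(patch, dtype=float)
        if patch.ndim != 2:
            raise ValueError("NCC backend expects a 2-D grayscale patch")
        if patch.shape[0] < 1 or patch.shape[1] < 1:
            raise ValueError("empty patch")
        return FeatureMap(data=patch[None], stride=1, offset=0.0)

    def correlate(self, template_feat: FeatureMap, search_feat: FeatureMap) -> ScoreMap:
        t = template_feat.data[0]
        s = search_feat.data[0]
        th, tw = t.shape
        if th > s.shape[0] or tw > s.shape[1]:
            raise ValueError(
                f"template {t.shape} larger than search region {s.shape}"
            )
        origin = ((tw - 1) / 2.0, (th - 1) / 2.0)
        if t.std() < FLAT_EPS:
            shape = (s.shape[0] - th + 1, s.shape[1] - tw + 1)
            return ScoreMap(np.zeros(shape), origin=origin, step=1.0, flat=True)
        scores = match_template(s, t, pad_input=False)
        scores = np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)
        return ScoreMap(np.clip(scores, -1.0, 1.0), origin=origin, step=1.0)


class LearnedBackend:
    """Convolutional backend around a (trained) :class:`ceustrack.nn.Backbone`."""

    name = "learned"

    def __init__(self, backbone: nn.Backbone | None = None):
        self.backbone = backbone if backbone is not None else nn.Backbone()
        self.stride, self._offset = self.backbone.geometry()

    @classmethod
    def from_checkpoint(cls, path) -> "LearnedBackend":
        return cls(nn.load_checkpoint(path))

    def embed(self, patch: np.ndarray) -> FeatureMap:
        patch = np.asarray(patch, dtype=float)
        min_in = self.backbone.min_input()
        if patch.shape[-1] < min_in or patch.shape[-2] < min_in:
            raise ValueError(
                f"patch {patch.shape} below backbone minimum input {min_in}x{min_in}"
            )
        feat = self.backbone.forward(patch)
        return FeatureMap(data=feat, stride=self.stride, offset=self._offset)

    def correlate(self, template_feat: FeatureMap, search_feat: FeatureMap) -> ScoreMap:
        t, s = template_feat.data, search_feat.data
        if t.shape[0] != s.shape[0]:
            raise ValueError("template/search channel mismatch")
        if t.shape[1] > s.shape[1] or t.shape[2] > s.shape[2]:
            raise ValueError("template feature map larger than search feature map")
        scores = self.backbone.score_map(t, s)
        _, th, tw = t.shape
        origin_x = self._offset + self.stride * (tw - 1) / 2.0
        origin_y = self._offset + self.stride * (th - 1) / 2.0
        return ScoreMap(scores, origin=(origin_x, origin_y), step=float(self.stride))


def get_backend(name: str, weights=None):
    if name == "ncc":
        return NCCBackend()
    if name == "learned":
        if weights is None:
            return LearnedBackend()
        return LearnedBackend.from_checkpoint(weights)
    raise ValueError(f"unknown backend {name!r} (expected 'ncc' or 'learned')")
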