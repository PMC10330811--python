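"""Frame-sequence and annotation I/O.

Conventions shared by every module in the package:

* images are 2-D float arrays with intensities in ``[0, 1]``;
* coordinates are 0-based with ``x`` the column index and ``y`` the row
  index, both measured at pixel centers;
* a bounding box is given by its center ``(cx, cy)`` and its size
  ``(w, h)`` in pixels.

Annotation files are plain CSV with the header
``frame_index,cx,cy,w,h`` and one row per labeled frame.  Sparse labels
(e.g. one box every 10 frames) are the normal case for clinical
cine-loops, so a loaded annotation map only contains the frames that are
actually present in the file.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "BoundingBox",
    "FrameSequence",
    "load_sequence",
    "save_sequence",
    "load_annotations",
    "save_annotations",
    "extract_dicom_cine",
]

ANNOTATION_HEADER = ("frame_index", "cx", "cy", "w", "h")

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: center ``(cx, cy)`` and size ``(w, h)`` in pixels."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box size must be positive, got w={self.w}, h={self.h}")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy], dtype=float)

    def to_corner(self) -> tuple[float, float, float, float]:
        """Return ``(x0, y0, w, h)`` with ``(x0, y0)`` the top-left corner."""
        return (self.cx - self.w / 2.0, self.cy - self.h / 2.0, self.w, self.h)

    @classmethod
    def from_corner(cls, x0: float, y0: float, w: float, h: float) -> "BoundingBox":
        return cls(x0 + w / 2.0, y0 + h / 2.0, w, h)

    def moved_to(self, cx: float, cy: float) -> "BoundingBox":
        return replace(self, cx=float(cx), cy=float(cy))

    def inside(self, shape: tuple[int, int]) -> bool:
        """True when the box lies fully inside a ``(height, width)`` frame."""
        x0, y0, w, h = self.to_corner()
        return x0 >= 0 and y0 >= 0 and x0 + w <= shape[1] and y0 + h <= shape[0]


@dataclass
class FrameSequence:
    """Ordered grayscale frames, all the same shape, intensities in [0, 1]."""

    frames: np.ndarray  # (n_frames, height, width) float
    fps: float = 15.0
    origin: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) stack")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(len(self)) / self.fps


def _normalize(img: np.ndarray) -> np.ndarray:
    """Map an integer image to float [0, 1] by its dtype range."""
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return img.astype(float) / info.max
    return np.clip(img.astype(float), 0.0, 1.0)


def _numeric_key(name: str) -> tuple:
    """Natural-sort key: split into text and integer runs."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def load_sequence(path: str | Path, fps: float = 15.0) -> FrameSequence:
    """Load a frame stack from a directory of images, a multi-page TIFF,
    or a ``.npy``/``.npz`` array file.

    Directory frames are ordered by natural (numeric-aware) filename sort.
    Integer images are normalized to [0, 1] by their dtype range.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=lambda p: _numeric_key(p.name),
        )
        if not files:
            raise ValueError(f"no image files found in {path}")
        frames = [_normalize(iio.imread(f)) for f in files]
    elif path.suffix.lower() in {".tif", ".tiff"}:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_normalize(f) for f in stack]
    elif path.suffix.lower() == ".npy":
        stack = np.load(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_normalize(np.asarray(f)) for f in stack]
    elif path.suffix.lower() == ".npz":
        with np.load(path) as data:
            key = sorted(data.files)[0]
            stack = data[key]
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_normalize(np.asarray(f)) for f in stack]
    else:
        raise ValueError(f"unsupported sequence source: {path}")

    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
    if any(f.ndim != 2 for f in frames):
        raise ValueError("frames must be single-channel grayscale")
    return FrameSequence(np.stack(frames), fps=fps, origin=str(path))


def save_sequence(seq: FrameSequence, path: str | Path, fmt: str = "png") -> list[Path]:
    """Write a sequence as numbered 8-bit PNGs (``fmt='png'``) or a single
    multi-page TIFF (``fmt='tiff'``). Returns the written file paths."""
    path = Path(path)
    data8 = np.clip(np.round(seq.frames * 255.0), 0, 255).astype(np.uint8)
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        out = []
        for i, frame in enumerate(data8):
            f = path / f"frame_{i:05d}.png"
            iio.imwrite(f, frame)
            out.append(f)
        return out
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data8)
        return [path]
    raise ValueError(f"unknown format {fmt!r}")


def load_annotations(path: str | Path) -> dict[int, BoundingBox]:
    """Read a sparse annotation CSV into ``{frame_index: BoundingBox}``."""
    path = Path(path)
    boxes: dict[int, BoundingBox] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty annotation file")
        if tuple(h.strip() for h in header) != ANNOTATION_HEADER:
            raise ValueError(f"{path}: expected header {','.join(ANNOTATION_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                idx = int(row[0])
                cx, cy, w, h = (float(v) for v in row[1:5])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if w <= 0 or h <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive box size w={w}, h={h}")
            if idx in boxes:
                raise ValueError(f"{path}:{lineno}: duplicate frame index {idx}")
            boxes[idx] = BoundingBox(cx, cy, w, h)
    return boxes


def save_annotations(boxes: Mapping[int, BoundingBox], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for idx in sorted(boxes):
            b = boxes[idx]
            writer.writerow([idx, repr(b.cx), repr(b.cy), repr(b.w), repr(b.h)])
    return path


def extract_dicom_cine(
    path: str | Path,
    crop: tuple[int, int, int, int] | str = "auto",
    fps: float | None = None,
) -> FrameSequence:
    """Extract the CEUS pane from a multi-frame DICOM cine-loop.

    ``crop`` is ``(x0, y0, w, h)`` in pixels, or ``"auto"`` to use the
    file's ultrasound-region coordinates (SequenceOfUltrasoundRegions).
    Color frames are converted to luminance. Read-only: no DICOM is ever
    written by this package.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    try:
        pixels = ds.pixel_array
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"{path}: no decodable pixel data") from exc

    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim == 4:  # (frames, h, w, rgb) -> luminance
        pixels = pixels @ np.array([0.299, 0.587, 0.114])
    if pixels.ndim != 3:
        raise ValueError(f"{path}: unsupported pixel layout {pixels.shape}")

    n, H, W = pixels.shape
    if crop == "auto":
        regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
        if not regions:
            raise ValueError(
                f"{path}: crop='auto' requires SequenceOfUltrasoundRegions; "
                "pass an explicit (x0, y0, w, h) crop instead"
            )
        r = regions[0]
        x0, y0 = int(r.RegionLocationMinX0), int(r.RegionLocationMinY0)
        w = int(r.RegionLocationMaxX1) - x0 + 1
        h = int(r.RegionLocationMaxY1) - y0 + 1
    else:
        x0, y0, w, h = (int(v) for v in crop)
    if x0 < 0 or y0 < 0 or w <= 0 or h <= 0 or x0 + w > W or y0 + h > H:
        raise ValueError(
            f"{path}: crop ({x0},{y0},{w},{h}) outside {H}x{W} frames"
        )

    cropped = pixels[:, y0 : y0 + h, x0 : x0 + w].astype(float)
    peak = cropped.max()
    if peak > 0:
        cropped = cropped / peak
    if fps is None:
        fps = float(getattr(ds, "CineRate", 0) or getattr(ds, "RecommendedDisplayFrameRate", 0) or 15.0)
    return FrameSequence(cropped, fps=fps, origin=str(path))
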