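"""Background modelling, subtraction and segmentation of cyprid images.

The imaging stage turns a fixed-camera grayscale sequence (dark animals on a
bright, static arena) into labelled foreground segments. The background is
recovered by an iterative brighten-only update: starting from the first frame,
any pixel of a later frame that is brighter than the current background by more
than ``diff_threshold`` replaces it; passes over the whole sequence repeat
until a pass changes nothing. Because the animals are strictly darker than the
arena, a pixel is restored to true background intensity as soon as the animal
uncovers it in any frame.

Coordinates follow image convention throughout the package: 0-based, ``x``
rightward (columns), ``y`` downward (rows); centroids are real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import InvalidInputError

__all__ = [
    "GrayFrame",
    "BackgroundModel",
    "Segment",
    "build_background",
    "segment_frame",
    "compute_centroid",
    "read_frames",
    "write_background",
    "segments_to_table",
]


@dataclass(frozen=True)
class GrayFrame:
    """One grayscale frame of a sequence."""

    index: int
    pixels: np.ndarray
    time_s: float = 0.0

    @classmethod
    def from_array(cls, index: int, pixels: np.ndarray, frame_rate: float = 33.0) -> "GrayFrame":
        return cls(index=index, pixels=np.asarray(pixels), time_s=index / frame_rate)


@dataclass
class BackgroundModel:
    """Static background estimate plus the threshold used to build it."""

    pixels: np.ndarray
    diff_threshold: float
    converged: bool
    passes: int = 0


@dataclass
class Segment:
    """A connected foreground component.

    ``coords`` is an ``(n, 2)`` integer array of ``(x, y)`` pixel coordinates.
    """

    label: int
    coords: np.ndarray
    shape: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> tuple[float, float]:
        return compute_centroid(self.coords)

    @cached_property
    def flat(self) -> frozenset:
        """Pixel set as flattened raster indices (y * width + x)."""
        w = self.shape[1]
        return frozenset((self.coords[:, 1] * w + self.coords[:, 0]).tolist())


def _as_array(frame) -> np.ndarray:
    px = frame.pixels if isinstance(frame, GrayFrame) else np.asarray(frame)
    if px.ndim != 2:
        raise InvalidInputError(f"expected 2-D grayscale frame, got shape {px.shape}")
    return np.asarray(px, dtype=np.float64)


def build_background(
    frames: Sequence,
    diff_threshold: float = 30.0,
    max_passes: int = 50,
) -> BackgroundModel:
    """Estimate the static background of a sequence.

    Start from frame 0; in each pass, every subsequent frame is compared with
    the current background and pixels brighter by more than ``diff_threshold``
    are copied in. Iterate until a full pass changes no pixel (the fixed
    point), or ``max_passes`` is reached, in which case the model is flagged
    unconverged.
    """
    arrays = [_as_array(f) for f in frames]
    if len(arrays) < 2:
        raise InvalidInputError("background modelling needs at least 2 frames")
    shape = arrays[0].shape
    for i, a in enumerate(arrays[1:], start=1):
        if a.shape != shape:
            raise InvalidInputError(f"frame {i} shape {a.shape} != frame 0 shape {shape}")

    bg = arrays[0].copy()
    converged = False
    passes = 0
    for _ in range(max_passes):
        passes += 1
        changed = False
        for a in arrays[1:]:
            mask = (a - bg) > diff_threshold
            if mask.any():
                bg[mask] = a[mask]
                changed = True
        if not changed:
            converged = True
            break
    return BackgroundModel(pixels=bg, diff_threshold=diff_threshold,
                           converged=converged, passes=passes)


def compute_centroid(pixel_coords) -> tuple[float, float]:
    """Mean of pixel coordinates: ((sum x_i)/n, (sum y_i)/n)."""
    coords = np.asarray(sorted(pixel_coords) if isinstance(pixel_coords, (set, frozenset))
                        else pixel_coords, dtype=np.float64)
    if coords.size == 0:
        raise InvalidInputError("centroid of an empty pixel set is undefined")
    coords = coords.reshape(-1, 2)
    return float(coords[:, 0].mean()), float(coords[:, 1].mean())


def segment_frame(
    frame,
    bg: BackgroundModel,
    bin_threshold: float = 70.0,
    min_area: int = 5,
) -> list[Segment]:
    """Threshold (background - frame) and label 8-connected components.

    Components smaller than ``min_area`` pixels are discarded; survivors are
    relabelled 1..K in raster order.
    """
    a = _as_array(frame)
    if a.shape != bg.pixels.shape:
        raise InvalidInputError(
            f"frame shape {a.shape} != background shape {bg.pixels.shape}")
    fg = (bg.pixels - a) > bin_threshold
    labelled = sk_label(fg, connectivity=2)
    segments: list[Segment] = []
    next_label = 1
    for region in regionprops(labelled):
        if region.num_pixels < min_area:
            continue
        rc = region.coords  # (n, 2) as (row, col)
        coords = np.stack([rc[:, 1], rc[:, 0]], axis=1)
        segments.append(Segment(label=next_label, coords=coords, shape=a.shape))
        next_label += 1
    return segments


# ---------------------------------------------------------------------------
# I/O


def read_frames(path: str | Path, frame_rate: float = 33.0,
                invert: bool = False) -> list[GrayFrame]:
    """Read an image sequence as grayscale frames.

    ``path`` may be a directory of numbered PNG/TIFF files (lexicographic
    order = temporal order) or a single multi-page TIFF.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise InvalidInputError(f"no PNG/TIFF images found in {path}")
        stacks = [np.asarray(iio.imread(f)) for f in files]
    elif path.is_file():
        arr = np.asarray(iio.imread(path))
        stacks = [arr[i] for i in range(arr.shape[0])] if arr.ndim == 3 and \
            arr.shape[-1] not in (3, 4) else [arr]
    else:
        raise InvalidInputError(f"no such file or directory: {path}")

    frames = []
    for i, px in enumerate(stacks):
        if px.ndim == 3:  # RGB(A) input: collapse to luminance-like mean
            px = px[..., :3].mean(axis=-1)
        px = px.astype(np.float64)
        if invert:
            px = 255.0 - px
        frames.append(GrayFrame(index=i, pixels=px, time_s=i / frame_rate))
    return frames


def write_background(bg: BackgroundModel, path: str | Path) -> None:
    """Write the background estimate as an 8-bit PNG."""
    px = np.clip(np.rint(bg.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), px)


def segments_to_table(per_frame: Iterable[tuple[int, list[Segment]]]) -> pd.DataFrame:
    """Flatten (frame, segments) pairs into a frame/label/size/xc/yc table."""
    rows = []
    for frame_idx, segments in per_frame:
        for s in segments:
            xc, yc = s.centroid
            rows.append((frame_idx, s.label, s.size, xc, yc))
    return pd.DataFrame(rows, columns=["frame", "label", "size", "xc", "yc"])
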