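"""Image encodings of scanpaths and density overlays.

Two single-channel encodings of a trial's first m fixations:

* **facial scanpath** — each fixation drawn as a disc at its (scaled)
  screen position; disc radius is duration squared divided by a constant
  (amplifying duration differences), brightness falls linearly with
  fixation order so earlier fixations are brighter, and overlapping discs
  combine by per-pixel maximum to preserve the brightness-order code.
* **ROI sequence** — an m x 10 one-hot matrix, one row per fixation in
  temporal order (first at the top), one column per ROI; duration is
  deliberately omitted.  Rasterized by block replication.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .core import FaceTemplate, Trial

__all__ = [
    "Encoder",
    "ScanpathImage",
    "DensityMap",
    "render_facial_scanpath",
    "render_roi_sequence",
    "decode_roi_sequence",
    "overlay_density",
]

#: Disc radius (frame px) = duration_ms**2 / RADIUS_CONSTANT.  The default
#: puts a median ~250 ms fixation at ~41 px, about 4% of the frame width,
#: so most discs stay within the face box.
DEFAULT_RADIUS_CONSTANT = 1500.0
DEFAULT_RESOLUTION = 128
DEFAULT_CELL_SIZE = 8


class Encoder(str, enum.Enum):
    FACIAL_SCANPATH = "facial_scanpath"
    ROI_SEQUENCE = "roi_sequence"


@dataclass
class ScanpathImage:
    """A rendered scanpath with its provenance."""

    pixels: np.ndarray  # 2-D float array in [0, 1]
    encoder: Encoder
    m: int
    subject_id: str
    trial_id: str
    label: int
    logical: np.ndarray | None = None  # (m, 10) indicator, ROI-sequence only

    def to_png(self, path: str | Path) -> None:
        arr = np.clip(self.pixels, 0.0, 1.0)
        Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)


@dataclass
class DensityMap:
    """Cell/pixel-wise overlay of many trials' indicator content."""

    cells: np.ndarray
    n_trials: int
    normalization: str = "count"  # or "proportion"

    def to_png(self, path: str | Path) -> None:
        peak = self.cells.max()
        arr = self.cells / peak if peak > 0 else self.cells
        Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.cells, delimiter=",", fmt="%.6g")


def render_facial_scanpath(
    trial: Trial,
    m: int,
    radius_constant: float = DEFAULT_RADIUS_CONSTANT,
    resolution: int = DEFAULT_RESOLUTION,
    template: FaceTemplate | None = None,
) -> ScanpathImage:
    """Render the first m fixations as bright-to-dim discs on black.

    Fixation k (1-based) gets intensity 1 - (k-1)/m; a zero-duration
    fixation has zero radius and leaves no disc.  Discs are clipped to the
    canvas and overlaps keep the brighter (earlier) value.
    """
    if len(trial) < m:
        raise ValueError(f"trial has {len(trial)} fixations, fewer than m={m}")
    if radius_constant <= 0:
        raise ValueError("radius_constant must be positive")
    if template is None:
        template = FaceTemplate.default()
    sx = resolution / template.width
    sy = resolution / template.height
    img = np.zeros((resolution, resolution), dtype=float)
    yy, xx = np.mgrid[0:resolution, 0:resolution]
    for k, fix in enumerate(trial.fixations[:m], start=1):
        if fix.duration <= 0:
            continue
        radius_frame = fix.duration**2 / radius_constant
        r = radius_frame * sx  # rendered-pixel radius, x-scale convention
        cx, cy = fix.x * sx, fix.y * sy
        intensity = 1.0 - (k - 1) / m
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        img[mask] = np.maximum(img[mask], intensity)
    return ScanpathImage(img, Encoder.FACIAL_SCANPATH, m,
                         trial.subject_id, trial.trial_id, trial.label)


def render_roi_sequence(
    trial: Trial, m: int, cell_size: int = DEFAULT_CELL_SIZE
) -> ScanpathImage:
    """Render the first m ROI codes as an m x 10 one-hot raster.

    Row k (top = first fixation) has its single on-cell in the column of
    fixation k's ROI; each logical cell becomes a cell_size x cell_size
    pixel block.
    """
    if len(trial) < m:
        raise ValueError(f"trial has {len(trial)} fixations, fewer than m={m}")
    codes = trial.roi_sequence(m)
    logical = np.zeros((m, 10), dtype=float)
    logical[np.arange(m), codes - 1] = 1.0
    raster = np.kron(logical, np.ones((cell_size, cell_size)))
    return ScanpathImage(raster, Encoder.ROI_SEQUENCE, m,
                         trial.subject_id, trial.trial_id, trial.label,
                         logical=logical)


def decode_roi_sequence(image: ScanpathImage) -> np.ndarray:
    """Recover the ROI codes encoded in an ROI-sequence image (exact)."""
    if image.encoder is not Encoder.ROI_SEQUENCE:
        raise ValueError("decode_roi_sequence expects an ROI-sequence image")
    logical = image.logical
    if logical is None:
        m = image.m
        cs = image.pixels.shape[0] // m
        logical = image.pixels.reshape(m, cs, 10, cs).mean(axis=(1, 3))
    return logical.argmax(axis=1) + 1


def _indicator(item: Trial | ScanpathImage, encoder: Encoder, m: int, **render_kw) -> np.ndarray:
    if isinstance(item, Trial):
        if encoder is Encoder.ROI_SEQUENCE:
            item = render_roi_sequence(item, m, **render_kw)
        else:
            item = render_facial_scanpath(item, m, **render_kw)
    if item.encoder is not encoder or item.m != m:
        raise ValueError("overlay items must share one encoder and m")
    if encoder is Encoder.ROI_SEQUENCE:
        return item.logical
    return (item.pixels > 0).astype(float)


def overlay_density(
    items: Sequence[Trial | ScanpathImage],
    encoder: Encoder,
    m: int,
    normalization: str = "count",
    **render_kw,
) -> DensityMap:
    """Cell-wise (ROI sequence) or pixel-wise (facial scanpath) sum of
    indicator content over trials; ``proportion`` divides by n_trials."""
    if len(items) == 0:
        raise ValueError("overlay_density needs at least one item")
    if normalization not in ("count", "proportion"):
        raise ValueError(f"unknown normalization {normalization!r}")
    total = None
    for item in items:
        ind = _indicator(item, encoder, m, **render_kw)
        total = ind.copy() if total is None else total + ind
    if normalization == "proportion":
        total = total / len(items)
    return DensityMap(total, n_trials=len(items), normalization=normalization)
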