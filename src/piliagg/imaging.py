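"""Binarization: simulation projections and micrograph preprocessing.

Both branches of the analysis reduce their input to the same object, a
:class:`BinaryImage` occupancy field ``phi`` (1 = cell region, 0 = void):

* simulated configurations are projected onto the x-y plane, each cell body
  drawn as a filled disk of radius ``sigma_B`` with periodic wrap;
* phase-contrast-like micrographs are adaptively thresholded (cells darker
  than the local background) and cleaned by morphological opening/closing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_local
from skimage.morphology import closing, disk, opening

__all__ = [
    "BinaryImage",
    "project_state_to_binary",
    "project_points_to_binary",
    "preprocess_micrograph",
]


@dataclass
class BinaryImage:
    """2D occupancy field with physical pixel size.

    ``periodic`` marks simulation projections (torus topology); micrographs
    are non-periodic.
    """

    pixels: np.ndarray  # 2D bool
    pixel_size: float = 1.0
    periodic: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2D array")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("pixels must be strictly binary")
            px = px.astype(bool)
        self.pixels = px
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_fraction(self) -> float:
        return float(self.pixels.mean())


def project_points_to_binary(
    centers_xy: np.ndarray,
    box_xy: np.ndarray,
    radius: float,
    pixel_size: float = 1.0,
) -> BinaryImage:
    """Rasterize disks of ``radius`` at the given (x, y) centers, periodically.

    A pixel is foreground iff its center lies within ``radius`` of some disk
    center (minimum-image distance).  Pixel centers sit at
    ``(i + 1/2) * pixel_size``.
    """
    box_xy = np.asarray(box_xy, dtype=float)
    if pixel_size >= min(box_xy):
        raise ValueError("pixel_size must be smaller than the box")
    nx = int(round(box_xy[0] / pixel_size))
    ny = int(round(box_xy[1] / pixel_size))
    img = np.zeros((ny, nx), dtype=bool)  # row = y, col = x
    centers = np.atleast_2d(np.asarray(centers_xy, dtype=float))
    if centers.size == 0:
        return BinaryImage(img, pixel_size, periodic=True)
    r_px = radius / pixel_size
    span = int(np.ceil(r_px)) + 1
    for cx, cy in centers:
        icx = cx / pixel_size - 0.5  # fractional pixel index of the center
        icy = cy / pixel_size - 0.5
        ix = np.arange(int(np.floor(icx)) - span, int(np.floor(icx)) + span + 2)
        iy = np.arange(int(np.floor(icy)) - span, int(np.floor(icy)) + span + 2)
        dx = ix - icx
        dy = iy - icy
        mask = dy[:, None] ** 2 + dx[None, :] ** 2 <= r_px**2
        img[np.ix_(iy % ny, ix % nx)] |= mask
    return BinaryImage(img, pixel_size, periodic=True)


def project_state_to_binary(state, pixel_size: float = 1.0, body_radius: float = 5.0) -> BinaryImage:
    """x-y projection of a simulation state: one disk per cell body."""
    return project_points_to_binary(
        state.positions[:, :2], state.box[:2], body_radius, pixel_size
    )


def preprocess_micrograph(
    image: np.ndarray,
    block_size: int = 51,
    offset: float | None = None,
    opening_radius: int = 1,
    closing_radius: int = 2,
    dark_foreground: bool = True,
    pixel_size: float = 1.0,
) -> BinaryImage:
    """Adaptive-threshold segmentation of a grayscale micrograph.

    The per-pixel threshold is the local mean over a ``block_size`` square
    minus ``offset`` (default 2% of the image's dynamic range); with
    ``dark_foreground`` (phase contrast) a pixel is cell region when its
    intensity falls below that threshold.  Binary opening then closing with
    disk structuring elements removes salt-and-pepper noise.  A constant
    image yields an all-background mask (offset > 0), not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if block_size <= 1 or block_size % 2 == 0:
        raise ValueError("block_size must be odd and > 1")
    if offset is None:
        offset = 0.02 * float(img.max() - img.min())
    local_mean = threshold_local(img, block_size=block_size, method="mean", offset=0.0)
    if dark_foreground:
        fg = img < local_mean - offset
    else:
        fg = img > local_mean + offset
    if opening_radius > 0:
        fg = opening(fg, disk(opening_radius))
    if closing_radius > 0:
        fg = closing(fg, disk(closing_radius))
    return BinaryImage(fg, pixel_size, periodic=False)
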