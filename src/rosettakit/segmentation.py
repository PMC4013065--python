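"""Colour-based segmentation of top-down rosette photographs.

The pipeline mirrors a standard greenhouse imaging workflow: classify
every pixel by its nearest colour exemplar, clean the binary image with
morphological erosion/dilation, and drop any foreground outside the pot
region.  The result is a :class:`BinaryMask` carrying a pixels-per-mm
scale factor so downstream measurements can be reported in physical
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.morphology import disk


class ConfigurationError(ValueError):
    """Raised for invalid segmentation parameters (empty samples, bad region...)."""


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground grid plus a pixels-per-mm calibration.

    ``grid[r, c]`` is True where the plant is present.  Coordinates are
    row-major with the origin at the top-left; ``scale_factor`` is in
    pixels per millimetre and must be finite and positive.
    """

    grid: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("mask grid must be a non-empty 2-D array")
        if not (math.isfinite(self.scale_factor) and self.scale_factor > 0):
            raise ValueError(f"scale_factor must be finite and > 0, got {self.scale_factor}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ColourSamples:
    """Foreground and background RGB exemplars for nearest-neighbour labelling."""

    foreground: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        for name in ("foreground", "background"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 0:
                raise ConfigurationError(f"{name} colour sample set is empty")
            if arr.shape[1] != 3:
                raise ConfigurationError(f"{name} samples must be (R,G,B) triples")
            if arr.min() < 0 or arr.max() > 255:
                raise ConfigurationError(f"{name} samples must lie in [0, 255]")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class PotRegion:
    """Axis-aligned rectangle (in pixel coordinates) delimiting one pot.

    ``x`` is the column axis, ``y`` the row axis; the rectangle spans
    ``[x0, x1] x [y0, y1]`` inclusive of both edges.
    """

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ConfigurationError(
                f"degenerate pot region ({self.x0},{self.y0})-({self.x1},{self.y1})"
            )

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            (cols >= self.x0) & (cols <= self.x1) & (rows >= self.y0) & (rows <= self.y1)
        )


def classify_nearest_neighbour(
    image: np.ndarray, samples: ColourSamples, scale_factor: float = 1.0
) -> BinaryMask:
    """Label each pixel by its nearest RGB exemplar (Euclidean distance).

    A pixel is foreground iff its nearest exemplar belongs to the
    foreground set; exact distance ties are resolved to background
    (conservative).  All pixels are classified directly — this is the
    fixed point of the exemplar-seeded region growing used by commercial
    tray-imaging software.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("image must be a non-empty H x W x 3 RGB array")
    pixels = image.reshape(-1, 3)
    fg_tree = cKDTree(samples.foreground)
    bg_tree = cKDTree(samples.background)
    d_fg, _ = fg_tree.query(pixels, k=1)
    d_bg, _ = bg_tree.query(pixels, k=1)
    # strict inequality: ties go to background
    grid = (d_fg < d_bg).reshape(image.shape[:2])
    return BinaryMask(grid=grid, scale_factor=scale_factor)


def morphological_cleanup(
    mask: BinaryMask, erosion_radius: int = 1, dilation_radius: int = 1
) -> BinaryMask:
    """Erode then dilate with disc structuring elements.

    Erosion removes small and isolated regions incorrectly labelled as
    plant; the subsequent dilation restores pixels at the object border.
    Radius 0 for either step means that step is skipped.
    """
    if erosion_radius < 0 or dilation_radius < 0:
        raise ValueError("radii must be >= 0")
    grid = mask.grid
    if erosion_radius > 0:
        grid = binary_erosion(grid, structure=disk(erosion_radius))
    if dilation_radius > 0:
        grid = binary_dilation(grid, structure=disk(dilation_radius))
    return replace(mask, grid=grid)


def filter_by_pot_region(mask: BinaryMask, region: PotRegion) -> BinaryMask:
    """Delete all foreground pixels outside the pot region."""
    h, w = mask.shape
    if region.x0 < 0 or region.y0 < 0 or region.x1 >= w or region.y1 >= h:
        raise ConfigurationError("pot region extends outside the image bounds")
    keep = np.zeros(mask.shape, dtype=bool)
    keep[region.y0 : region.y1 + 1, region.x0 : region.x1 + 1] = True
    return replace(mask, grid=mask.grid & keep)


def calibrate(mask: BinaryMask, reference_length_px: float, reference_length_mm: float) -> BinaryMask:
    """Set the scale factor from an internal length reference.

    ``scale_factor = reference_length_px / reference_length_mm`` in
    pixels per millimetre.
    """
    if reference_length_px <= 0 or reference_length_mm <= 0:
        raise ValueError("reference lengths must be > 0")
    return replace(mask, scale_factor=reference_length_px / reference_length_mm)


def segment_image(
    image: np.ndarray,
    samples: ColourSamples,
    erosion_radius: int = 1,
    dilation_radius: int = 1,
    pot_region: PotRegion | None = None,
    scale_factor: float = 1.0,
) -> BinaryMask:
    """Full segmentation pipeline: classify, clean up, filter by pot."""
    mask = classify_nearest_neighbour(image, samples, scale_factor=scale_factor)
    mask = morphological_cleanup(mask, erosion_radius, dilation_radius)
    if pot_region is not None:
        mask = filter_by_pot_region(mask, pot_region)
    return mask
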