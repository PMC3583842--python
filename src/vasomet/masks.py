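"""Binary pixel masks and vessel-mask refinement.

The universal data currency is the :class:`PixelMask`: a 2-D boolean lattice
over a section grid together with a um/pixel calibration.  Vessel masks
produced by conservative ("under-") thresholding of an endothelial stain are
refined by a fixed binary-morphology sequence -- dilate x3, fill holes,
erode x2 -- whose net effect on a hole-free convex blob is a one-pixel
dilation; the refined mask is then connected-component labeled so each
microvessel has an identity for the Voronoi-domain step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np
from scipy import ndimage

from .errors import (
    CalibrationMismatchError,
    EmptyROIError,
    ShapeMismatchError,
    ValidationError,
)

__all__ = [
    "PixelMask",
    "LabeledVesselMap",
    "SectionBundle",
    "threshold_mask",
    "refine_vessel_mask",
    "label_components",
    "validate_section",
]

#: 3x3 square structuring element: one "iteration" of binary dilate/erode,
#: matching the classical image-analysis default.
SQUARE_3x3 = np.ones((3, 3), dtype=bool)

#: 4-connected structure used for hole filling (background connectivity dual
#: to 8-connected foreground, so filling cannot leak through diagonal gaps).
CROSS_3x3 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class PixelMask:
    """A binary raster over a section grid with physical calibration.

    Parameters
    ----------
    grid
        2-D boolean array, True on foreground pixels.
    pixel_size_um
        Physical edge length of one pixel in micrometres; must be positive.
    """

    grid: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise ValidationError(f"mask grid must be a non-empty 2-D array, got shape {grid.shape}")
        if grid.dtype != bool:
            grid = grid.astype(bool)
        object.__setattr__(self, "grid", grid)
        if not (float(self.pixel_size_um) > 0):
            raise ValidationError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        object.__setattr__(self, "pixel_size_um", float(self.pixel_size_um))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_true(self) -> int:
        return int(self.grid.sum())

    def area_um2(self) -> float:
        """Physical foreground area in um^2."""
        return self.n_true * self.pixel_size_um**2

    def with_grid(self, grid: np.ndarray) -> "PixelMask":
        """A new mask on the same calibration with a different grid."""
        return PixelMask(grid, self.pixel_size_um)


@dataclass(frozen=True)
class LabeledVesselMap:
    """Connected-component labeling of a refined vessel mask.

    ``labels`` is an integer lattice: 0 for background, k in 1..n_components
    for the k-th microvessel in raster-scan discovery order.
    """

    labels: np.ndarray
    n_components: int
    pixel_size_um: float
    connectivity: int = 8

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def as_mask(self) -> PixelMask:
        """The union of all components as a plain vessel mask."""
        return PixelMask(self.labels > 0, self.pixel_size_um)


def threshold_mask(
    image: np.ndarray,
    threshold: float,
    polarity: Literal["above", "below"] = "above",
    pixel_size_um: float = 1.0,
) -> PixelMask:
    """Binarize a grayscale stain image with a strict scalar threshold.

    ``polarity="above"`` marks pixels strictly greater than ``threshold``;
    ``"below"`` marks pixels strictly smaller.  Strictness means a pixel
    exactly at the threshold is never foreground, so a conservative
    (under-)threshold can be dialled by the threshold value alone.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got {image.ndim} dimensions")
    if not np.isfinite(image).all():
        raise ValidationError("image contains NaN or infinite pixels")
    if polarity == "above":
        grid = image > threshold
    elif polarity == "below":
        grid = image < threshold
    else:
        raise ValidationError(f"polarity must be 'above' or 'below', got {polarity!r}")
    return PixelMask(grid, pixel_size_um)


def _dilate(grid: np.ndarray, iterations: int) -> np.ndarray:
    # outside-image pixels are background: the frame cannot seed dilation
    return ndimage.binary_dilation(grid, structure=SQUARE_3x3, iterations=iterations, border_value=0)


def _erode(grid: np.ndarray, iterations: int) -> np.ndarray:
    # outside-image pixels are foreground: the frame does not erode inward,
    # so an all-true mask is a fixed point of the refinement sequence
    return ndimage.binary_erosion(grid, structure=SQUARE_3x3, iterations=iterations, border_value=1)


def refine_vessel_mask(raw: PixelMask) -> PixelMask:
    """Consolidate a fragmented, under-thresholded vessel mask.

    Applies exactly: dilate x3 (3x3 square), fill holes (4-connected
    background), erode x2 (3x3 square).  Fragments of one vessel lying within
    a few pixels of each other fuse into a single component, enclosed lumina
    are filled, and the net effect on a hole-free convex blob is a one-pixel
    dilation of its boundary.
    """
    grid = _dilate(raw.grid, 3)
    grid = ndimage.binary_fill_holes(grid, structure=CROSS_3x3)
    grid = _erode(grid, 2)
    return raw.with_grid(grid)


def label_components(mask: PixelMask, connectivity: int = 8) -> LabeledVesselMap:
    """Label connected foreground components in raster-scan discovery order.

    ``connectivity`` is 8 (default; diagonal neighbours connect) or 4.
    """
    if connectivity == 8:
        structure = SQUARE_3x3
    elif connectivity == 4:
        structure = CROSS_3x3
    else:
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(mask.grid, structure=structure)
    labels = _canonical_relabel(labels, n)
    return LabeledVesselMap(labels, int(n), mask.pixel_size_um, connectivity=connectivity)


def _canonical_relabel(labels: np.ndarray, n: int) -> np.ndarray:
    """Renumber labels 1..n by the raster position of each component's first pixel."""
    if n == 0:
        return labels
    flat = labels.ravel()
    values, first = np.unique(flat, return_index=True)
    order = first[values > 0].argsort()
    lut = np.zeros(n + 1, dtype=labels.dtype)
    lut[values[values > 0][order]] = np.arange(1, n + 1)
    return lut[labels]


@dataclass(frozen=True)
class SectionBundle:
    """A validated, registered set of masks for one section.

    All member masks share grid dimensions and calibration.  The ROI is the
    evaluable tumor area: every fraction downstream uses it as denominator,
    and vessel/marker analysis is restricted to it.
    """

    roi: PixelMask
    vessels: Optional[PixelMask] = None
    markers: Mapping[str, PixelMask] = field(default_factory=dict)
    section_id: str = "section"

    @property
    def pixel_size_um(self) -> float:
        return self.roi.pixel_size_um

    @property
    def shape(self) -> tuple[int, int]:
        return self.roi.shape


def validate_section(
    roi: PixelMask,
    vessels: Optional[PixelMask] = None,
    markers: Optional[Mapping[str, PixelMask]] = None,
    section_id: str = "section",
) -> SectionBundle:
    """Check registration preconditions and assemble a section bundle.

    Raises
    ------
    ShapeMismatchError
        If any mask's grid dimensions differ from the ROI's.
    CalibrationMismatchError
        If any mask's pixel size differs from the ROI's.
    EmptyROIError
        If the ROI has no foreground pixels.
    ValidationError
        If neither a vessel mask nor any marker mask is supplied.
    """
    markers = dict(markers or {})
    if vessels is None and not markers:
        raise ValidationError("a section needs at least one vessel or marker mask besides the ROI")
    if roi.n_true == 0:
        raise EmptyROIError(f"{section_id}: ROI mask has no foreground pixels")
    named = {"vessels": vessels, **markers} if vessels is not None else dict(markers)
    for name, mask in named.items():
        if mask.shape != roi.shape:
            raise ShapeMismatchError(
                f"{section_id}: mask {name!r} has shape {mask.shape}, ROI has {roi.shape}"
            )
        if mask.pixel_size_um != roi.pixel_size_um:
            raise CalibrationMismatchError(
                f"{section_id}: mask {name!r} calibrated at {mask.pixel_size_um} um/px, "
                f"ROI at {roi.pixel_size_um} um/px"
            )
    return SectionBundle(roi=roi, vessels=vessels, markers=markers, section_id=section_id)
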