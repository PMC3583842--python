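"""Marker positive fractions and the overlap coefficient (OC).

Marker expression is quantified as the positive fraction of the evaluable
tumor area.  Spatial association between two binary markers is summarized by
the overlap coefficient

    OC = (|A ∩ B| / |B|) / (|A \\ B| / |ROI \\ B|),

the density of marker A inside the reference marker B divided by its density
in B-negative tumor tissue.  OC = 1 means A is distributed indifferently to
B; OC > 1 means colocalization; OC < 1 means avoidance.  When A lies
entirely inside B the denominator vanishes and OC is undefined (reported as
NaN); when A is entirely outside B the coefficient is exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateReferenceError, EmptyROIError
from .masks import PixelMask

__all__ = ["MarkerFraction", "OCResult", "positive_fraction", "overlap_coefficient"]


@dataclass(frozen=True)
class MarkerFraction:
    """Positive fraction of the evaluable tumor area for one marker."""

    marker: str
    fraction: float
    n_positive: int
    n_roi: int


@dataclass(frozen=True)
class OCResult:
    """Overlap coefficient of marker A against reference marker B.

    Stores the four pixel counts the coefficient is computed from, so the
    value is always reproducible as
    ``(n_a_in_b / n_b) / (n_a_out_b / n_roi_out_b)``.
    ``oc`` is NaN when A colocalizes perfectly with B (zero denominator).
    """

    marker_a: str
    marker_b: str
    oc: float
    n_a_in_b: int
    n_a_out_b: int
    n_b: int
    n_roi_out_b: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.oc)


def positive_fraction(marker: PixelMask, roi: PixelMask, name: str = "marker") -> MarkerFraction:
    """Fraction of ROI pixels positive for the marker (marker clipped to ROI)."""
    n_roi = roi.n_true
    if n_roi == 0:
        raise EmptyROIError("positive fraction over an empty ROI is undefined")
    n_pos = int((marker.grid & roi.grid).sum())
    return MarkerFraction(name, n_pos / n_roi, n_pos, n_roi)


def overlap_coefficient(
    a: PixelMask,
    b: PixelMask,
    roi: PixelMask,
    name_a: str = "A",
    name_b: str = "B",
) -> OCResult:
    """Overlap coefficient of marker ``a`` with reference marker ``b``.

    All masks are clipped to the ROI before counting; the "entire tumor
    area" of the formula is the evaluable ROI.

    Raises
    ------
    DegenerateReferenceError
        If the reference B is empty within the ROI or covers the whole ROI,
        in which case one of the densities has no support.
    """
    roi_grid = roi.grid
    a_grid = a.grid & roi_grid
    b_grid = b.grid & roi_grid
    n_b = int(b_grid.sum())
    n_roi_out_b = int((roi_grid & ~b_grid).sum())
    if n_b == 0:
        raise DegenerateReferenceError(f"reference marker {name_b!r} is empty within the ROI")
    if n_roi_out_b == 0:
        raise DegenerateReferenceError(f"reference marker {name_b!r} covers the entire ROI")
    n_a_in_b = int((a_grid & b_grid).sum())
    n_a_out_b = int((a_grid & ~b_grid).sum())
    if n_a_out_b == 0:
        oc = float("nan")  # perfect colocalization: density ratio undefined
    else:
        oc = (n_a_in_b / n_b) / (n_a_out_b / n_roi_out_b)
    return OCResult(name_a, name_b, oc, n_a_in_b, n_a_out_b, n_b, n_roi_out_b)
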