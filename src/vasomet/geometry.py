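"""Microvascular domains, intercapillary distances and diffusion-limited fractions.

Each microvessel's *microvascular domain* is its generalized Voronoi cell:
the set of ROI pixels closer (Euclidean, pixel-center to pixel-center) to
that vessel than to any other.  The domain area, corrected by subtracting the
vessel's own pixels, is converted to an intercapillary distance (ICD): the
diameter of the circle with the same area, ``2*sqrt(area/pi)``.  The
per-section distribution of ICDs summarizes vessel spacing; its standard
deviation captures vascular heterogeneity.

The calibrated Euclidean distance map (distance of every tissue pixel to the
nearest vessel pixel) yields the diffusion-limited fraction DLF_c: the share
of evaluable tumor pixels lying strictly beyond a cutoff c (80 and 120 um by
default), a surrogate for chronically hypoxic tissue.  Distances are kept at
full floating precision; an optional helper quantizes a map to an 8-bit-like
level scale for fidelity comparisons with legacy tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import NoVesselError, ValidationError
from .masks import LabeledVesselMap, PixelMask

__all__ = [
    "DomainMap",
    "DistanceMap",
    "ICDDistribution",
    "DLFResult",
    "voronoi_domains",
    "corrected_domain_areas",
    "icd_from_area",
    "icd_distribution",
    "distance_map",
    "diffusion_limited_fraction",
    "mean_distance_in_region",
    "domain_table",
    "quantize_distance_map",
]


@dataclass(frozen=True)
class DomainMap:
    """Per-pixel nearest-vessel assignment restricted to the ROI.

    ``assignment[i, j]`` is the label of the Euclidean-nearest vessel
    component for ROI pixels and 0 outside the ROI.  Ties go to the smallest
    component label, which makes the map deterministic.
    """

    assignment: np.ndarray
    n_components: int
    pixel_size_um: float


@dataclass(frozen=True)
class DistanceMap:
    """Calibrated Euclidean distance (um) to the nearest vessel pixel.

    Defined on the full grid; only ROI pixels are meaningful downstream.
    Exactly 0 on vessel pixels and 1-Lipschitz in the calibrated metric.
    """

    dist_um: np.ndarray
    pixel_size_um: float


@dataclass(frozen=True)
class ICDDistribution:
    """Per-domain intercapillary distances with their mean and SD.

    One ICD per vessel component owning at least one ROI pixel.  The SD uses
    the sample (n-1) denominator and is NaN when fewer than two domains exist.
    """

    icd_um: np.ndarray
    mean_um: float
    sd_um: float

    @property
    def n_domains(self) -> int:
        return self.icd_um.size


@dataclass(frozen=True)
class DLFResult:
    """Fraction of ROI pixels strictly farther than ``cutoff_um`` from a vessel."""

    cutoff_um: float
    fraction: float
    n_roi: int
    n_beyond: int


def voronoi_domains(vessels: LabeledVesselMap, roi: PixelMask) -> DomainMap:
    """Assign every ROI pixel to its Euclidean-nearest vessel component.

    Components are swept in increasing label order with a strict
    smaller-distance update, so equidistant pixels keep the smallest label.
    Distances are compared as exact squared integers (pixel units), making
    the tie rule immune to floating-point noise.
    """
    if vessels.n_components == 0:
        raise NoVesselError("cannot build microvascular domains: no vessel components")
    if roi.n_true == 0:
        raise ValidationError("ROI is empty")
    best_d2 = np.full(vessels.shape, np.iinfo(np.int64).max, dtype=np.int64)
    assignment = np.zeros(vessels.shape, dtype=np.int32)
    for label in range(1, vessels.n_components + 1):
        d = ndimage.distance_transform_edt(vessels.labels != label)
        d2 = np.rint(d * d).astype(np.int64)  # squared EDT distances are integers
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        assignment[closer] = label
    assignment[~roi.grid] = 0
    return DomainMap(assignment, vessels.n_components, vessels.pixel_size_um)


def corrected_domain_areas(domains: DomainMap, vessels: LabeledVesselMap, roi: PixelMask) -> np.ndarray:
    """Vessel-corrected domain areas in um^2, indexed by label-1.

    area(k) = (ROI pixels assigned to k  -  vessel-k pixels inside ROI) * px^2,
    floored at zero.  Subtracting the vessel's own footprint matters when a
    vessel occupies a sizeable share of its domain.
    """
    if domains.assignment.shape != vessels.shape:
        raise ValidationError("domain map and vessel map are on different grids")
    n = domains.n_components
    assigned = np.bincount(domains.assignment.ravel(), minlength=n + 1)[1:]
    vessel_in_roi = np.bincount(
        (vessels.labels * roi.grid).ravel(), minlength=n + 1
    )[1:]
    px2 = domains.pixel_size_um**2
    return np.maximum(assigned - vessel_in_roi, 0).astype(float) * px2


def icd_from_area(area_um2: float) -> float:
    """Diameter of the circle whose area equals ``area_um2``: ``2*sqrt(A/pi)``."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area < 0):
        raise ValidationError("domain area cannot be negative")
    return 2.0 * np.sqrt(area / np.pi)


def icd_distribution(domains: DomainMap, vessels: LabeledVesselMap, roi: PixelMask) -> ICDDistribution:
    """Per-domain ICDs with mean and sample SD.

    Only components owning at least one ROI pixel contribute.  A domain
    fully occupied by its vessel keeps an ICD of 0 so that domain areas stay
    conservative.
    """
    areas = corrected_domain_areas(domains, vessels, roi)
    n = domains.n_components
    assigned = np.bincount(domains.assignment.ravel(), minlength=n + 1)[1:]
    areas = areas[assigned > 0]
    if areas.size == 0:
        raise NoVesselError("no vessel component owns any ROI pixel")
    icds = icd_from_area(areas)
    mean = float(np.mean(icds))
    sd = float(np.std(icds, ddof=1)) if icds.size > 1 else float("nan")
    return ICDDistribution(icds, mean, sd)


def distance_map(vessels: PixelMask, roi: PixelMask | None = None) -> DistanceMap:
    """Exact Euclidean distance (um) from every pixel to the nearest vessel pixel."""
    if vessels.n_true == 0:
        raise NoVesselError("cannot build a distance map: vessel mask is empty")
    dist = ndimage.distance_transform_edt(~vessels.grid) * vessels.pixel_size_um
    return DistanceMap(dist, vessels.pixel_size_um)


def diffusion_limited_fraction(dmap: DistanceMap, roi: PixelMask, cutoff_um: float) -> DLFResult:
    """Share of ROI pixels strictly beyond ``cutoff_um`` from the nearest vessel."""
    if cutoff_um < 0:
        raise ValidationError("cutoff must be non-negative")
    roi_dist = dmap.dist_um[roi.grid]
    n_roi = roi_dist.size
    if n_roi == 0:
        raise ValidationError("ROI is empty")
    n_beyond = int((roi_dist > cutoff_um).sum())
    return DLFResult(float(cutoff_um), n_beyond / n_roi, n_roi, n_beyond)


def mean_distance_in_region(
    dmap: DistanceMap, region: PixelMask, roi: PixelMask
) -> tuple[float, float]:
    """Mean diffusion distance inside ``region`` and in its ROI complement.

    Returns ``(mean_in, mean_out)`` in um; an empty side is reported as NaN.
    Comparing the two means for a marker mask asks whether the marker prefers
    poorly- or well-vascularized tissue.
    """
    inside = region.grid & roi.grid
    outside = roi.grid & ~region.grid
    mean_in = float(dmap.dist_um[inside].mean()) if inside.any() else float("nan")
    mean_out = float(dmap.dist_um[outside].mean()) if outside.any() else float("nan")
    return mean_in, mean_out


def domain_table(domains: DomainMap, vessels: LabeledVesselMap, roi: PixelMask) -> pd.DataFrame:
    """Per-domain table: label, raw pixel count, vessel pixels, corrected area, ICD."""
    n = domains.n_components
    assigned = np.bincount(domains.assignment.ravel(), minlength=n + 1)[1:]
    vessel_in_roi = np.bincount((vessels.labels * roi.grid).ravel(), minlength=n + 1)[1:]
    corrected = corrected_domain_areas(domains, vessels, roi)
    return pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "domain_px": assigned,
            "vessel_px_in_roi": vessel_in_roi,
            "corrected_area_um2": corrected,
            "icd_um": icd_from_area(corrected),
        }
    )


def quantize_distance_map(dmap: DistanceMap, levels: int = 256) -> DistanceMap:
    """Round a distance map onto ``levels`` equal steps over its maximum.

    Fidelity mode for comparisons with 8-bit legacy distance maps; the
    default pipeline never quantizes.
    """
    if levels < 2:
        raise ValidationError("need at least 2 quantization levels")
    dmax = float(dmap.dist_um.max())
    if dmax == 0:
        return dmap
    step = dmax / (levels - 1)
    return DistanceMap(np.rint(dmap.dist_um / step) * step, dmap.pixel_size_um)
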