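"""Synthetic registered section generator with known ground truth.

Real inputs to the pipeline are registered binary masks segmented from
immunostained serial sections of astrocytic tumors.  No such scans ship with
the package, so this module fabricates whole mask sets whose generating
parameters are known exactly:

* **Vessels** are unions of disks around centers drawn from one of three
  point processes: a regular lattice (homogeneous vasculature, the
  lower-grade phenotype), a uniform (binomial/Poisson-type) scatter, or a
  parent-offspring clustered process (heterogeneous vasculature with large
  avascular voids, the high-grade phenotype).
* **Markers** are driven by the true distance-to-vessel map.  An ``above``
  distance rule (positive beyond a threshold) emulates chronic-hypoxia
  markers such as GLUT-1/CA IX that accumulate far from vessels; a ``below``
  rule emulates proliferation/mTOR markers enriched near vessels.  Optional
  independent pixel flips add segmentation noise.  A ``random`` rule gives a
  spatially indifferent marker.

Cohorts mirror the two-entity study design: two groups of sections, each
drawn from its own section template, all seeds derived deterministically
from one master seed.  Ground truth (process type and parameters, rule
thresholds, realized vessel counts) is returned alongside the masks so
parameter-recovery and power analyses can be scored.

Default sizes are desk-scale study conditions: 128x128 grids at 4 um/px
(a 512 um field), lattice spacing 16 px (64 um) and matched expected vessel
counts across processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Mapping, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import DistanceMap, distance_map
from .masks import PixelMask, SectionBundle, validate_section

__all__ = [
    "RegularLattice",
    "UniformRandom",
    "ClusteredProcess",
    "DistanceRule",
    "RandomRule",
    "SectionSpec",
    "CohortSpec",
    "generate_vessels",
    "generate_marker",
    "generate_section",
    "generate_cohort",
    "recover_distance_threshold",
]


@dataclass(frozen=True)
class RegularLattice:
    """Vessel centers on a square lattice with the given spacing (pixels).

    Centers sit at ``spacing//2 + k*spacing`` along each axis, so a 100 px
    axis with spacing 20 carries 5 centers.
    """

    spacing_px: int

    def centers(self, shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        s = self.spacing_px
        if s < 1:
            raise ValidationError("lattice spacing must be >= 1 px")
        rows = np.arange(s // 2, shape[0], s)
        cols = np.arange(s // 2, shape[1], s)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def expected_count(self, shape: Tuple[int, int]) -> float:
        return len(range(self.spacing_px // 2, shape[0], self.spacing_px)) * len(
            range(self.spacing_px // 2, shape[1], self.spacing_px)
        )


@dataclass(frozen=True)
class UniformRandom:
    """``n_vessels`` centers placed uniformly at random over the grid."""

    n_vessels: int

    def centers(self, shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        if self.n_vessels < 1:
            raise ValidationError("need at least one vessel")
        rows = rng.integers(0, shape[0], self.n_vessels)
        cols = rng.integers(0, shape[1], self.n_vessels)
        return np.column_stack([rows, cols])

    def expected_count(self, shape: Tuple[int, int]) -> float:
        return float(self.n_vessels)


@dataclass(frozen=True)
class ClusteredProcess:
    """Parent-offspring (Thomas-type) clustered vessel centers.

    ``n_parents`` cluster seeds are placed uniformly; each spawns a Poisson
    number of offspring (mean ``offspring_per_parent``) with isotropic
    Gaussian displacement of scale ``cluster_radius_px``.  Clustering at a
    fixed expected vessel count leaves large avascular voids, inflating both
    the spread of intercapillary distances and the diffusion-limited tails.
    """

    n_parents: int
    offspring_per_parent: float
    cluster_radius_px: float

    def centers(self, shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        if self.n_parents < 1 or self.offspring_per_parent <= 0 or self.cluster_radius_px < 0:
            raise ValidationError("clustered process parameters must be positive")
        pts: List[np.ndarray] = []
        parents = np.column_stack(
            [rng.integers(0, shape[0], self.n_parents), rng.integers(0, shape[1], self.n_parents)]
        )
        for p in parents:
            k = rng.poisson(self.offspring_per_parent)
            if k == 0:
                continue
            offs = p + rng.normal(0.0, self.cluster_radius_px, size=(k, 2))
            pts.append(np.rint(offs).astype(int))
        if not pts:  # degenerate draw: keep the parents so the section has vessels
            return parents
        centers = np.concatenate(pts)
        keep = (
            (centers[:, 0] >= 0)
            & (centers[:, 0] < shape[0])
            & (centers[:, 1] >= 0)
            & (centers[:, 1] < shape[1])
        )
        centers = centers[keep]
        return centers if centers.size else parents

    def expected_count(self, shape: Tuple[int, int]) -> float:
        return self.n_parents * self.offspring_per_parent


VesselProcess = Union[RegularLattice, UniformRandom, ClusteredProcess]


@dataclass(frozen=True)
class DistanceRule:
    """Marker positivity driven by distance to the nearest vessel.

    ``direction="above"`` marks pixels with distance strictly greater than
    ``threshold_um``; ``"below"`` marks distance <= threshold.  Each pixel's
    state is then flipped independently with probability ``flip_prob``.
    """

    threshold_um: float
    direction: Literal["above", "below"] = "above"
    flip_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_um < 0:
            raise ValidationError("distance threshold must be non-negative")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValidationError("flip probability must lie in [0, 1]")
        if self.direction not in ("above", "below"):
            raise ValidationError("direction must be 'above' or 'below'")


@dataclass(frozen=True)
class RandomRule:
    """Spatially indifferent marker: each ROI pixel positive with ``fraction``."""

    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("fraction must lie in [0, 1]")


MarkerRule = Union[DistanceRule, RandomRule]


@dataclass(frozen=True)
class SectionSpec:
    """Generating parameters for one synthetic section."""

    shape: Tuple[int, int] = (128, 128)
    pixel_size_um: float = 4.0
    vessel_process: VesselProcess = RegularLattice(16)
    vessel_radius_px: int = 1
    marker_rules: Mapping[str, MarkerRule] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_radius_px < 0:
            raise ValidationError("vessel radius must be non-negative")
        if self.vessel_radius_px >= min(self.shape):
            raise ValidationError("vessel radius must be smaller than the grid extent")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic study: section templates and group sizes."""

    group_a: SectionSpec
    group_b: SectionSpec
    n_a: int = 10
    n_b: int = 11
    master_seed: int = 0
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValidationError("each group needs at least one section")


def _disk_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    keep = rr**2 + cc**2 <= radius**2
    return np.column_stack([rr[keep], cc[keep]])


def generate_vessels(spec: SectionSpec) -> PixelMask:
    """Vessel mask: union of disks of ``vessel_radius_px`` at sampled centers."""
    rng = np.random.default_rng(spec.seed)
    centers = spec.vessel_process.centers(spec.shape, rng)
    grid = np.zeros(spec.shape, dtype=bool)
    offs = _disk_offsets(spec.vessel_radius_px)
    px = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    keep = (
        (px[:, 0] >= 0) & (px[:, 0] < spec.shape[0]) & (px[:, 1] >= 0) & (px[:, 1] < spec.shape[1])
    )
    px = px[keep]
    grid[px[:, 0], px[:, 1]] = True
    return PixelMask(grid, spec.pixel_size_um)


def generate_marker(
    dmap: DistanceMap,
    rule: MarkerRule,
    seed: int,
    roi: PixelMask,
) -> PixelMask:
    """Marker mask from a rule applied to the true distance map, clipped to ROI."""
    rng = np.random.default_rng(seed)
    if isinstance(rule, DistanceRule):
        if rule.direction == "above":
            grid = dmap.dist_um > rule.threshold_um
        else:
            grid = dmap.dist_um <= rule.threshold_um
        if rule.flip_prob > 0:
            flips = rng.random(grid.shape) < rule.flip_prob
            grid = grid ^ flips
    elif isinstance(rule, RandomRule):
        grid = rng.random(dmap.dist_um.shape) < rule.fraction
    else:
        raise ValidationError(f"unknown marker rule {rule!r}")
    return PixelMask(grid & roi.grid, roi.pixel_size_um)


def generate_section(spec: SectionSpec, section_id: str = "section") -> tuple[SectionBundle, dict]:
    """One registered section bundle (full-frame ROI) plus its ground truth."""
    ss = np.random.SeedSequence(spec.seed)
    vessel_seed, *marker_seeds = ss.generate_state(1 + max(len(spec.marker_rules), 1))
    vessels = generate_vessels(replace(spec, seed=int(vessel_seed) % 2**31))
    roi = PixelMask(np.ones(spec.shape, dtype=bool), spec.pixel_size_um)
    dmap = distance_map(vessels)
    markers: Dict[str, PixelMask] = {}
    truth: dict = {
        "section_id": section_id,
        "process": type(spec.vessel_process).__name__,
        "expected_vessels": spec.vessel_process.expected_count(spec.shape),
        "rules": dict(spec.marker_rules),
        "seed": spec.seed,
    }
    for (name, rule), mseed in zip(spec.marker_rules.items(), marker_seeds):
        markers[name] = generate_marker(dmap, rule, int(mseed) % 2**31, roi)
    bundle = validate_section(roi=roi, vessels=vessels, markers=markers, section_id=section_id)
    return bundle, truth


def generate_cohort(spec: CohortSpec) -> tuple[List[Tuple[str, SectionBundle]], pd.DataFrame]:
    """A two-group cohort of section bundles with a ground-truth table.

    Returns ``(sections, truth)`` where ``sections`` is a list of
    ``(group_name, bundle)`` and ``truth`` one row per section.  Per-section
    seeds are spawned deterministically from the master seed, so the whole
    cohort is bit-reproducible.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    child_seeds = ss.generate_state(spec.n_a + spec.n_b)
    sections: List[Tuple[str, SectionBundle]] = []
    rows = []
    plan = [(spec.name_a, spec.group_a)] * spec.n_a + [(spec.name_b, spec.group_b)] * spec.n_b
    for i, ((group, template), child) in enumerate(zip(plan, child_seeds)):
        sid = f"{group}{i:02d}"
        child_spec = replace(template, seed=int(child) % 2**31)
        bundle, truth = generate_section(child_spec, section_id=sid)
        truth["group"] = group
        rows.append(truth)
        sections.append((group, bundle))
    return sections, pd.DataFrame(rows)


def recover_distance_threshold(dmap: DistanceMap, marker: PixelMask, roi: PixelMask) -> float:
    """Recover the threshold of a noiseless 'above' distance rule.

    Sweeping the diffusion-limited-fraction cutoff until the tail fraction
    matches the marker's positive fraction pins the generating threshold down
    to one pixel-distance quantum; the closed form of that sweep is the
    largest distance attained by any marker-negative ROI pixel.
    """
    negative = roi.grid & ~marker.grid
    if not negative.any():
        raise ValidationError("marker covers the whole ROI; threshold unidentifiable")
    return float(dmap.dist_um[negative].max())
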