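"""Model layer: per-section morphometry and cohort comparison.

The two entry points follow the estimator/results idiom of statistical
modelling packages:

* :class:`SectionMorphometry` is built from one validated
  :class:`~vasomet.masks.SectionBundle`; ``fit()`` runs the per-section
  pipeline (vessel refinement -> component labeling -> Voronoi domains and
  intercapillary distances -> distance map and diffusion-limited fractions ->
  marker fractions -> overlap coefficients -> marker in/out mean distances)
  and returns a :class:`SectionResults` carrying every scalar plus the
  intermediate maps.
* :class:`CohortStudy` is built from a list of fitted sections with group
  labels; ``fit()`` runs the study's inferential layer (two-sided
  Mann-Whitney U between groups per variable, paired Wilcoxon on marker
  in/out mean distances, Spearman correlations across sections) and returns
  a :class:`CohortResults` with a ``summary()`` table.

Two internal consistency checks run on every fitted section: vessel-corrected
domain areas plus in-ROI vessel area must reproduce the ROI area exactly, and
the diffusion-limited fraction must be non-increasing in the cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import geometry, synthetic
from .colocalization import MarkerFraction, overlap_coefficient, positive_fraction
from .errors import DegenerateReferenceError, ValidationError
from .geometry import DistanceMap, DLFResult, DomainMap, ICDDistribution
from .masks import LabeledVesselMap, SectionBundle, label_components, refine_vessel_mask
from .stats import TestResult, mann_whitney_u, spearman_rho, wilcoxon_signed_rank

logger = logging.getLogger("vasomet")

__all__ = ["SectionConfig", "SectionMorphometry", "SectionResults", "CohortStudy", "CohortResults"]


@dataclass(frozen=True)
class SectionConfig:
    """Tunables of the per-section pipeline, logged into every report.

    ``dlf_cutoffs_um`` defaults to the classical diffusion-limit surrogates
    of 80 and 120 um.  ``oc_reference`` names the reference marker for the
    headline overlap coefficients (GLUT-1 when present, as the most abundant
    chronic-hypoxia marker); the full pairwise matrix is computed regardless.
    """

    dlf_cutoffs_um: Tuple[float, ...] = (80.0, 120.0)
    connectivity: int = 8
    refine_vessels: bool = True
    oc_reference: Optional[str] = None
    exact_test_max_n: int = 12

    def resolve_reference(self, markers: Sequence[str]) -> Optional[str]:
        if self.oc_reference is not None:
            return self.oc_reference if self.oc_reference in markers else None
        for candidate in ("GLUT1", "GLUT-1", "glut1"):
            if candidate in markers:
                return candidate
        return None


@dataclass
class SectionResults:
    """All morphometric scalars and maps for one fitted section."""

    section_id: str
    config: SectionConfig
    pixel_size_um: float
    n_roi_px: int
    vessels: Optional[LabeledVesselMap]
    domain_map: Optional[DomainMap]
    distance_map: Optional[DistanceMap]
    icd: Optional[ICDDistribution]
    dlf: Dict[float, DLFResult] = field(default_factory=dict)
    marker_fractions: Dict[str, MarkerFraction] = field(default_factory=dict)
    oc_matrix: Optional[pd.DataFrame] = None
    mean_distances: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        """Flat scalar view (one row of a cohort table)."""
        row: Dict[str, float] = {"n_roi_px": self.n_roi_px, "pixel_size_um": self.pixel_size_um}
        if self.icd is not None:
            row["icd_mean_um"] = self.icd.mean_um
            row["icd_sd_um"] = self.icd.sd_um
            row["n_domains"] = self.icd.n_domains
        for cutoff, res in self.dlf.items():
            row[f"dlf_{cutoff:g}"] = res.fraction
        for name, mf in self.marker_fractions.items():
            row[f"frac_{name}"] = mf.fraction
        for name, (din, dout) in self.mean_distances.items():
            row[f"dist_in_{name}"] = din
            row[f"dist_out_{name}"] = dout
        return pd.Series(row, name=self.section_id)

    def summary(self) -> str:
        lines = [f"Section morphometry: {self.section_id}", "=" * 40]
        lines.append(f"ROI area: {self.n_roi_px} px @ {self.pixel_size_um} um/px")
        if self.vessels is not None:
            lines.append(f"Vessel components: {self.vessels.n_components}")
        if self.icd is not None:
            lines.append(
                f"ICD mean {self.icd.mean_um:.1f} um, SD {self.icd.sd_um:.1f} um "
                f"({self.icd.n_domains} domains)"
            )
        for cutoff, res in self.dlf.items():
            lines.append(f"DLF_{cutoff:g}: {res.fraction:.4f}")
        for name, mf in self.marker_fractions.items():
            lines.append(f"{name}: positive fraction {mf.fraction:.4f}")
        for name, (din, dout) in self.mean_distances.items():
            lines.append(f"{name}: mean distance in {din:.1f} um / out {dout:.1f} um")
        if self.oc_matrix is not None and not self.oc_matrix.empty:
            lines.append("Overlap coefficients (rows: A, cols: reference B):")
            lines.append(self.oc_matrix.round(3).to_string())
        return "\n".join(lines)

    def plot_maps(self):
        """Quick-look panel of vessel labels, domains and the distance map."""
        import matplotlib.pyplot as plt

        panels = [
            ("vessels", None if self.vessels is None else self.vessels.labels > 0, "gray"),
            ("domains", None if self.domain_map is None else self.domain_map.assignment, "tab20"),
            ("distance (um)", None if self.distance_map is None else self.distance_map.dist_um, "magma"),
        ]
        panels = [(t, img, c) for t, img, c in panels if img is not None]
        fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 4))
        for ax, (title, img, cmap) in zip(np.atleast_1d(axes), panels):
            ax.imshow(img, cmap=cmap, interpolation="nearest")
            ax.set_title(title)
            ax.axis("off")
        fig.suptitle(self.section_id)
        return fig


class SectionMorphometry:
    """Per-section morphometry model over a validated mask bundle."""

    def __init__(self, bundle: SectionBundle, config: SectionConfig | None = None):
        self.bundle = bundle
        self.config = config or SectionConfig()

    @classmethod
    def from_manifest(cls, path, config: SectionConfig | None = None) -> "SectionMorphometry":
        from .io import read_section_manifest

        return cls(read_section_manifest(path), config)

    def fit(self) -> SectionResults:
        bundle, cfg = self.bundle, self.config
        roi = bundle.roi
        vessels_lab: Optional[LabeledVesselMap] = None
        domains: Optional[DomainMap] = None
        dmap: Optional[DistanceMap] = None
        icd: Optional[ICDDistribution] = None
        dlf: Dict[float, DLFResult] = {}

        if bundle.vessels is not None and bundle.vessels.n_true > 0:
            vessel_mask = refine_vessel_mask(bundle.vessels) if cfg.refine_vessels else bundle.vessels
            vessels_lab = label_components(vessel_mask, connectivity=cfg.connectivity)
            domains = geometry.voronoi_domains(vessels_lab, roi)
            icd = geometry.icd_distribution(domains, vessels_lab, roi)
            self._check_conservation(domains, vessels_lab, roi)
            dmap = geometry.distance_map(vessel_mask)
            for cutoff in sorted(cfg.dlf_cutoffs_um):
                dlf[cutoff] = geometry.diffusion_limited_fraction(dmap, roi, cutoff)
            self._check_dlf_monotone(dlf)

        fractions: Dict[str, MarkerFraction] = {}
        mean_dists: Dict[str, Tuple[float, float]] = {}
        for name, mask in bundle.markers.items():
            fractions[name] = positive_fraction(mask, roi, name=name)
            if dmap is not None:
                mean_dists[name] = geometry.mean_distance_in_region(dmap, mask, roi)

        oc_matrix = self._oc_matrix(bundle) if len(bundle.markers) >= 2 else None

        return SectionResults(
            section_id=bundle.section_id,
            config=cfg,
            pixel_size_um=bundle.pixel_size_um,
            n_roi_px=roi.n_true,
            vessels=vessels_lab,
            domain_map=domains,
            distance_map=dmap,
            icd=icd,
            dlf=dlf,
            marker_fractions=fractions,
            oc_matrix=oc_matrix,
            mean_distances=mean_dists,
        )

    def _oc_matrix(self, bundle: SectionBundle) -> pd.DataFrame:
        names = list(bundle.markers)
        mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
        for name_b in names:
            for name_a in names:
                if name_a == name_b:
                    continue
                try:
                    res = overlap_coefficient(
                        bundle.markers[name_a], bundle.markers[name_b], bundle.roi, name_a, name_b
                    )
                    mat.loc[name_a, name_b] = res.oc
                except DegenerateReferenceError:
                    logger.warning(
                        "%s: OC(%s | %s) skipped: degenerate reference",
                        bundle.section_id, name_a, name_b,
                    )
        return mat

    @staticmethod
    def _check_conservation(domains: DomainMap, vessels: LabeledVesselMap, roi) -> None:
        areas = geometry.corrected_domain_areas(domains, vessels, roi)
        vessel_in_roi = int(((vessels.labels > 0) & roi.grid).sum())
        px2 = domains.pixel_size_um**2
        total = areas.sum() + vessel_in_roi * px2
        expected = roi.n_true * px2
        if not math.isclose(total, expected, rel_tol=0, abs_tol=1e-6 * max(expected, 1.0)):
            raise AssertionError(
                f"domain-area conservation violated: {total} != {expected}"
            )

    @staticmethod
    def _check_dlf_monotone(dlf: Mapping[float, DLFResult]) -> None:
        cutoffs = sorted(dlf)
        fracs = [dlf[c].fraction for c in cutoffs]
        if any(f1 < f2 for f1, f2 in zip(fracs, fracs[1:])):
            raise AssertionError("DLF must be non-increasing in the cutoff")


#: Cohort-table variables entered into between-group tests when present.
_GROUP_TEST_PREFIXES = ("icd_mean_um", "icd_sd_um", "dlf_", "frac_")


@dataclass
class CohortResults:
    """Cohort-level tables: per-section scalars, group tests, correlations."""

    section_table: pd.DataFrame
    groups: pd.Series
    group_tests: pd.DataFrame
    paired_tests: pd.DataFrame
    spearman_rho: pd.DataFrame
    spearman_p: pd.DataFrame

    def summary(self) -> str:
        lines = ["Cohort comparison", "=" * 40]
        counts = self.groups.value_counts()
        lines.append("Groups: " + ", ".join(f"{g} (n={n})" for g, n in counts.items()))
        if not self.group_tests.empty:
            lines.append("\nBetween-group Mann-Whitney U tests:")
            lines.append(self.group_tests.round(4).to_string(index=False))
        if not self.paired_tests.empty:
            lines.append("\nPaired Wilcoxon tests (marker-positive vs -negative mean distance):")
            lines.append(self.paired_tests.round(4).to_string(index=False))
        if not self.spearman_rho.empty:
            lines.append("\nSpearman rho across sections:")
            lines.append(self.spearman_rho.round(2).to_string())
        return "\n".join(lines)

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        table = self.section_table.copy()
        table.insert(0, "group", self.groups)
        table.to_csv(directory / "sections.csv", na_rep="NA")
        self.group_tests.to_csv(directory / "group_tests.csv", index=False, na_rep="NA")
        self.paired_tests.to_csv(directory / "paired_tests.csv", index=False, na_rep="NA")
        self.spearman_rho.to_csv(directory / "spearman_rho.csv", na_rep="NA")
        self.spearman_p.to_csv(directory / "spearman_p.csv", na_rep="NA")


class CohortStudy:
    """Cohort-level inferential model over fitted section results."""

    def __init__(self, results: Sequence[SectionResults], groups: Sequence[str]):
        if len(results) != len(groups):
            raise ValidationError("one group label per section is required")
        if len(results) < 2:
            raise ValidationError("a cohort needs at least two sections")
        self.results = list(results)
        self.groups = list(groups)

    @classmethod
    def from_bundles(
        cls,
        sections: Sequence[Tuple[str, SectionBundle]],
        config: SectionConfig | None = None,
    ) -> "CohortStudy":
        results = [SectionMorphometry(bundle, config).fit() for _, bundle in sections]
        return cls(results, [group for group, _ in sections])

    @classmethod
    def from_spec(
        cls, spec: "synthetic.CohortSpec", config: SectionConfig | None = None
    ) -> "CohortStudy":
        sections, _ = synthetic.generate_cohort(spec)
        return cls.from_bundles(sections, config)

    def fit(self) -> CohortResults:
        table = pd.DataFrame([r.to_series() for r in self.results])
        groups = pd.Series(self.groups, index=table.index, name="group")
        group_names = list(dict.fromkeys(self.groups))

        group_tests = self._group_tests(table, groups, group_names)
        paired = self._paired_tests(table)
        rho, p = self._spearman_matrix(table)
        return CohortResults(table, groups, group_tests, paired, rho, p)

    def _group_tests(
        self, table: pd.DataFrame, groups: pd.Series, group_names: List[str]
    ) -> pd.DataFrame:
        rows = []
        if len(group_names) != 2:
            logger.warning("between-group tests need exactly 2 groups, got %d; skipped", len(group_names))
            return pd.DataFrame(rows)
        ga, gb = group_names
        for col in table.columns:
            if not col.startswith(_GROUP_TEST_PREFIXES):
                continue
            a = table.loc[groups == ga, col].dropna().to_numpy()
            b = table.loc[groups == gb, col].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                logger.warning("variable %s: a group is empty after dropping NaNs; skipped", col)
                continue
            res = mann_whitney_u(a, b)
            rows.append(
                {
                    "variable": col,
                    "group_a": ga, "group_b": gb,
                    "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                    "n_a": a.size, "n_b": b.size,
                    "test": res.method, "statistic": res.statistic, "p_value": res.p_value,
                    "approach": res.approach,
                }
            )
        return pd.DataFrame(rows)

    def _paired_tests(self, table: pd.DataFrame) -> pd.DataFrame:
        rows = []
        markers = [c.removeprefix("dist_in_") for c in table.columns if c.startswith("dist_in_")]
        for name in markers:
            pair = table[[f"dist_in_{name}", f"dist_out_{name}"]].dropna()
            if len(pair) < 2:
                logger.warning("marker %s: fewer than 2 complete in/out pairs; skipped", name)
                continue
            din = pair[f"dist_in_{name}"].to_numpy()
            dout = pair[f"dist_out_{name}"].to_numpy()
            if np.all(din == dout):
                logger.warning("marker %s: all in/out differences zero; skipped", name)
                continue
            res = wilcoxon_signed_rank(din, dout)
            rows.append(
                {
                    "marker": name,
                    "mean_in_um": float(din.mean()), "mean_out_um": float(dout.mean()),
                    "n_pairs": len(pair),
                    "test": res.method, "statistic": res.statistic, "p_value": res.p_value,
                    "approach": res.approach,
                }
            )
        return pd.DataFrame(rows)

    def _spearman_matrix(self, table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
        cols = [c for c in table.columns if c.startswith(_GROUP_TEST_PREFIXES)]
        rho = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
        pmat = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
        for c in cols:
            rho.loc[c, c] = 1.0
            pmat.loc[c, c] = 0.0
        for ca, cb in combinations(cols, 2):
            pair = table[[ca, cb]].dropna()
            if len(pair) < 3:
                continue
            res = spearman_rho(pair[ca].to_numpy(), pair[cb].to_numpy())
            rho.loc[ca, cb] = rho.loc[cb, ca] = res.statistic
            pmat.loc[ca, cb] = pmat.loc[cb, ca] = res.p_value
        return rho, pmat
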