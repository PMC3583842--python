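# Methods

This note records the quantitative model `vasomet` implements, the
conventions it fixes where several are defensible, what the synthetic-data
generator does and does not emulate, and the package's known limits.

## Inputs and assumptions

The unit of analysis is one *section*: a set of binary masks on a common
pixel grid with one µm/px calibration — an evaluable-tumor ROI, a microvessel
mask (endothelial stain), and zero or more marker masks. The package assumes
the masks are already registered to pixel-level correspondence and already
curated: non-vessel endothelial staining, debris and gross necrosis are
expected to have been excluded upstream by whoever drew the ROI and vessel
masks. No automated artifact rejection, color deconvolution or elastic
registration is attempted. Thresholding support is limited to a strict
scalar comparison (`>` for polarity "above"); conservative
("under-")thresholding is achieved by the threshold value, not by any
heuristic.

## Vessel-mask refinement

Under-thresholded vessel masks fragment single vessels into nearby specks.
The refinement applies exactly: binary dilation ×3, fill holes, erosion ×2,
with a 3×3 square structuring element (one pass per iteration, the classical
binary-operations default). Fill-holes uses 4-connected background — the
dual of the 8-connected foreground — so filling cannot leak through diagonal
gaps. On a hole-free convex blob the sequence reduces to a single one-pixel
dilation; this identity is enforced by tests.

Border convention: dilation treats outside-image pixels as background (the
frame never seeds growth); erosion treats them as foreground (the frame is
never eaten, so an all-true mask is a fixed point). The one-pixel-dilation
identity therefore holds exactly whenever the ×3-dilated shape stays inside
the frame.

Connected components default to 8-connectivity (4 available) and are
numbered 1..n in raster-scan discovery order, which makes labelings
deterministic and translation-equivariant.

## Microvascular domains and intercapillary distances

Every ROI pixel is assigned to the vessel component whose nearest pixel
(center-to-center Euclidean distance) is closest — the generalized Voronoi
tessellation of the labeled vessel mask. Implementation: one exact Euclidean
distance transform per component, compared as exact integer squared
distances, swept in increasing label order with strict improvement; ties
therefore go to the smallest label, and assignments match exhaustive search
bit-for-bit (verified on random instances). Per-component transforms keep
the tie rule exact; cost is O(components × pixels), ample at desk scale
(hundreds of vessels on multi-megapixel grids).

The domain area is corrected by subtracting the component's own in-ROI
vessel pixels, floored at zero, and converted to an intercapillary distance
ICD = 2·√(area/π) (diameter of the equal-area circle). Conservation —
Σ corrected areas + in-ROI vessel area = ROI area — holds exactly and is
asserted on every fitted section. Domains whose vessel fills them keep
ICD = 0 rather than being dropped. The per-section summary reports the mean
and the sample (n−1) standard deviation of the per-domain ICDs; with a
single domain the SD is NaN. Domains truncated by the ROI or image border
carry no edge correction.

## Distance maps and diffusion-limited fractions

The distance map is the exact (not chamfer) Euclidean distance transform of
the vessel mask, scaled to µm, at full floating precision. A legacy mode
(`quantize_distance_map`) rounds onto 256 levels over the section maximum
for comparison with 8-bit tooling; the pipeline itself never quantizes.

DLF_c is the fraction of ROI pixels with distance *strictly* greater than
the cutoff; defaults are 80 and 120 µm, the conventional bounds for
oxygen-diffusion-limited tissue. DLF is non-increasing in the cutoff and
under vessel addition; both laws are asserted in tests, the first also at
fit time.

## Marker fractions and the overlap coefficient

Marker masks are clipped to the ROI before any counting; "the tumor area"
is always the evaluable ROI. Expression is the positive fraction of ROI
pixels. Spatial association of marker A with reference B is

OC = (|A∩B| / |B|) / (|A∖B| / |R∖B|).

Conventions fixed here: |A∖B| = 0 with A nonempty (and the degenerate A = ∅)
returns NaN ("perfect colocalization", serialized NA); |A∩B| = 0 with
|A∖B| > 0 returns exactly 0; |B| = 0 or B ⊇ R raises a degenerate-reference
error, and the cohort layer records NA for such pairs. Cohort-mean OCs
average defined values only. The full pairwise matrix is computed; GLUT-1,
when present, is treated as the reference marker of chronic hypoxia in
reporting.

## Statistics

Spearman's ρ (midranks; two-sided p via the t approximation, exact n!
permutation optional for n ≤ 9), two-sided Mann–Whitney U (exact null for
n₁+n₂ ≤ 12 tie-free, otherwise normal approximation with continuity and tie
correction), and the Wilcoxon signed-rank test (zeros dropped; exact
sign-flip enumeration over midranks for ≤ 12 informative pairs — valid under
tied |differences| — otherwise normal approximation). The exact/asymptotic
switch at total n = 12 keeps the small-cohort regime (groups of ~10) exact
where tie-free. Every result records which branch produced its p-value.
Constant input yields an undefined-correlation sentinel rather than an
error; all-zero paired differences raise.

The suite calibrates empirical type-I error of the asymptotic branches at
α = 0.05 over 5 000 null replicates with 25 observations per group/pairs —
the regime those branches actually serve; the exact branches are instead
verified against full enumerations, where their achieved size is an analytic
property of the discrete null, not an implementation behaviour.

## Synthetic sections and cohorts

The generator emulates the structure the pipeline measures, not histology:

* **Vessels** = unions of radius-r disks at centers from a regular lattice
  (origin at spacing/2), a uniform random scatter, or a parent–offspring
  clustered process (uniform parents, Poisson offspring, Gaussian spread).
  Clustering at matched expected count creates avascular voids — the
  heterogeneous, hypoxia-prone phenotype.
* **Markers** = thresholds on the true distance map ("above" = far-from-vessel
  hypoxia markers, "below" = perivascular proliferation markers) with
  independent per-pixel flip noise, or spatially indifferent random masks.
* **Cohorts** = two groups of sections drawn from per-group templates, all
  child seeds spawned from one master seed (bit-reproducible).

Default study conditions, chosen once at desk scale: 128×128 grids at
4 µm/px (512 µm field), lattice spacing 16 px (64 µm; ICD ≈ 70 µm, plausible
for well-vascularized tissue), clustered process with 6 parents × 11
expected offspring and 6 px spread (matched expected count ≈ 64), group
sizes 10 vs 11 — mirroring a two-entity study at reduced resolution. Power
and ordering checks use 50 replicate cohorts.

What passing tests on these data do *not* show: robustness to segmentation
bias, stain variability, registration error beyond the pixel level,
necrosis (perinecrotic marker geometry is represented only through the
far-from-vessel rule), or 3-D vessel continuity across sections. The ROI is
full-frame in synthetic sections, so ROI-shape effects are exercised only in
unit tests.

## Numerical choices and degenerate inputs

* Distances compared as exact integers (squared pixel offsets); no
  floating-point tie ambiguity anywhere in the Voronoi step.
* Strict inequalities throughout (thresholding, DLF tails), documented per
  operation.
* Empty ROI, empty vessel mask, shape or calibration mismatch, degenerate OC
  reference and all-zero paired differences raise typed exceptions; empty
  region sides and undefined correlations return NaN sentinels.
* Sections lacking vessel masks yield marker-only reports; lacking markers,
  vascular-only reports. Between-group tests are skipped (with a logged
  warning) unless exactly two groups are present.

## Limitations

Single 2-D sections only; no perfusion or oxygen-tension modelling — DLF is
a geometric surrogate; OC is binary-mask-based by design (no
intensity-based Pearson/Manders analysis); no multiple-testing correction is
applied, matching the descriptive small-cohort setting the pipeline serves.
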