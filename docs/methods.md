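# Methods

`octquant` quantifies three indices of the inner retina from 3D SD-OCT
volumes — layer thickness, optical intensity ratio, and the
optical-intensity attenuation coefficient (OIAC) — per macular quadrant,
and supplies the statistical machinery to compare them between two subject
groups. Because clinical volumes of this kind are rarely shareable, the
package ships a ground-truthed synthetic generator that reproduces the
statistical structure the analysis assumes; every recovery and calibration
claim in the test suite is made against that generator, and this note is
explicit about what that does and does not demonstrate.

## The measurement model

A volume is a grid `intensity[x, y, z]` of raw 16-bit arbitrary units
(AU), x the fast scan axis, y the B-scan index, z depth. Eleven surfaces
(ILM … Bruch's membrane) delimit ten layers; surfaces are stored in
fractional voxel units so segmentations exchange across resolutions. A
layer slab occupies the half-open voxel range `[ceil(top), ceil(bottom))`,
which makes voxel counting, thickness additivity (GCC = mRNFL + GCIPL,
exactly) and flattening-invariance reproducible.

* **Thickness** (μm): slab voxel count × axial pitch (2.3 μm on the
  reference instrument).
* **Intensity ratio** (unitless): per-A-line mean AU of the layer over the
  mean AU of the reference layer, then averaged per quadrant. Raw AU is
  meaningless across scans; the ratio removes the scan-level gain.
* **OIAC** (mm⁻¹): per A-line,

      mu = ln(R * beta + 1) / (2 d)

  with `R` the ratio of *integrated* (summed) signal of the layer over the
  reference layer, `d` the thickness in mm, and `beta` a constant. The
  natural log is used: the formula descends from two-way Beer–Lambert
  attenuation, whose derivations are written in ln, and the base is a pure
  rescaling (the choice is isolated in `AnalysisConfig.log_base`).
  "Integrated" means summed, not averaged — a mean-based R would change
  with `d` and break the derivation. A-lines with `d = 0` (the foveal pit)
  or an empty reference slab are excluded from quadrant means and tallied,
  never imputed: imputing zero would bias means, and `d → 0` makes `mu`
  diverge.

### Why beta must be calibrated

Under the layered Beer–Lambert model, the integrated ratio of a layer with
attenuation `mu` and thickness `d` over a deeper reference layer is
`R = K (e^{2 mu d} − 1) / (2 mu)`, where `K` collects the backscatter
fractions and the fixed transmission between the layer and the reference.
Substituting into the OIAC formula shows it is **exact** — `mu_measured =
mu` for every `d` — precisely when `beta = 2 mu / K`. With any other beta
the measured OIAC acquires a spurious dependence on thickness; in the
extreme it degenerates to a monotone transform of `1/d` and merely
re-measures thickness. The package therefore offers `fit_beta` in two
modes:

* **truth mode** (phantoms): least-squares beta against the known
  generative attenuation; a single calibration point is solved
  algebraically.
* **decorrelation mode** (cohorts): grid search for the beta that zeroes
  the correlation between per-subject OIAC and thickness — attenuation is
  a tissue property and should not depend on how thick the layer happens
  to be. This is the route a real study takes, and `run_pipeline` applies
  it per cohort by default (`beta_calibration="decorrelate"`, fit on the
  square-average mRNFL R and d across subjects). The package default
  `beta = 2.3` is used only when calibration is disabled; it is an
  instrument-specific constant, not a universal one.

### Reference-layer selection

Across subjects, a candidate layer's mean intensity varies partly with the
scanner's image-quality score. For each candidate the procedure computes
the across-subject mean, SD and variance, the r² against quality, and the
quality-adjusted variance `var × (1 − r²)`, adjusted SD and adjusted CV
(adjusted SD / mean). The layer with the lowest adjusted CV is the most
quality-independent normalization target. `select_reference_layer`
implements one policy refinement: the three lowest adjusted CVs are
shortlisted, and a preferred layer (default RPE) is chosen if it is on the
shortlist — the RPE is bright, assumed uniformly scattering, and is not
touched by inner-retina disease, so when it is competitive it is the safer
choice. `prefer=None` gives the pure minimum rule (used by the recovery
study).

## Geometry

The fovea is the A-line minimizing the ILM-to-RNFL/GCL distance within the
central third of both en-face axes (the pit is where the inner layers
vanish); ties break by distance to the scan center, then scan order. A
flat inner-layer profile raises an error rather than guessing. The 5.0 mm
square centered there is split by the two axis-aligned midlines through
the fovea into SN/IN/ST/IT quadrants. Nasal vs temporal depends on
laterality; the stored-scan convention (OD: +x is nasal; slow axis runs
inferior→superior) is asserted by an exact mirror-invariance test:
x-mirroring a scan and flipping OD↔OS must reproduce every anatomical
label set bit-for-bit (offsets exactly on the midlines are assigned
temporal/inferior so the swap is exact). The global Average is the mean
over all labeled unmasked A-lines of the square — not the mean of the four
quadrant means — so it stays meaningful when masking or clipping makes
quadrants unequal; the area-weighted identity between the two is a tested
invariant. Whether the source figure's demarcation used midlines or
diagonals cannot be settled from text; midlines are consistent with
quadrants named superior/inferior × nasal/temporal, and the split lives in
one function (`make_quadrant_grid`) so the alternative is a local change.

## Segmentation stand-in

The published analysis used a 3D graph-based segmenter whose reproduction
is not this package's goal (external surface sets can be imported to
bypass segmentation entirely). The built-in stand-in runs per B-scan: each
boundary is the minimal-cost path through a signed axial-gradient cost
image (median-filtered, 5×5 default) under a smoothness constraint
(|Δz| ≤ 3 voxels per A-line), found sequentially from the ILM downward
inside a search band relative to the boundary above. Bands with
non-negative minimum gaps make non-crossing a construction property, not a
post-hoc check. Featureless volumes raise an error; weak-edge and
band-escape B-scans are flagged for QC, as are crossings, implausible
total-retina thickness, and inner-layer collapse beyond what a foveal pit
explains.

Known limitation: at the pit center the inner boundaries coincide and
leave no local gradient evidence, so paths there can latch onto deeper
edges (errors up to tens of voxels on ~1–3% of A-lines near the pit).
This is inherent to edge-based search without a shape prior; the affected
A-lines are the same ones excluded from OIAC anyway (d ≈ 0), the
thickness bias is shared by both cohorts' groups, and cohort studies can
(and the replicate studies do) use the generator's true surfaces. On
planar or merely bowed/rippled geometry the segmenter is exact to one
voxel noise-free and ~1.3 voxels mean absolute error under default
speckle.

Flattening shifts each A-line by an integer voxel offset so a chosen
boundary (default OS/RPE, the outer-band anchor; the anchoring boundary is
a package convention, configurable) sits at constant depth. Integer shifts
keep every inter-boundary voxel count — hence every thickness map —
bit-identical, which is a tested invariant. Rolled-in voxels are zero
filled and recorded in a pad mask that all intensity statistics exclude.

## The phantom

Noise-free expected intensity at depth z inside layer l is
`I0 · b_l · exp(−2 ∫ mu dz)` (two-way Beer–Lambert), with vitreous above
(dark, nearly transparent) and a rapidly attenuated sub-RPE region below
(avoids ambiguity at the bottom boundary). Speckle is multiplicative
Gamma(k, 1/k) per voxel — unit mean, so expected intensity is unbiased,
with SNR ~ √k; k = 12 by default. Defaults (units as stated):

* grid 128×64×256 voxels at 46.88×93.76×2.3 μm — the instrument's 6×6 mm
  field of view at a desk-scale transverse pitch; the full 512×256×992 at
  11.72×23.44×2.3 μm is supported but not required by the tests. Cohort
  studies use 48×24×176 at 125×250×2.3 μm for the same reason. The axial
  pitch is never coarsened because thickness arithmetic is defined on it.
* layer thicknesses (μm): RNFL 30, GCL 32, IPL 30, INL 30, OPL 28, ONL 55,
  ELM 9, ISOS 15, OS 14, RPE 23 (≈266 μm retina), with a ±3% smooth
  ripple, parabolic axial bowing (25 μm), and a foveal pit that removes
  85 μm from RNFL+GCL+IPL at the center with a Gaussian radial profile
  (half-depth radius 0.6 mm).
* attenuation (mm⁻¹): RNFL 4.0, GCL/IPL 2.2, INL 1.8, OPL 2.2, ONL 0.9,
  ELM 2.5, ISOS 3.5, OS 3.0, RPE 7.0 — the physically plausible retinal
  scale, scattering layers high, nuclear layers low.
* backscatter fractions: RPE highest (0.75), vitreous lowest (0.02), with
  bright/dark alternation so every boundary carries a signed edge.
* quality score: q = 45 + 10·ln(speckle shape), clipped to [0, 100]
  (≈70 ± 6.5 across a default cohort); per-layer backscatter is modulated
  by a coupling coefficient times (q − 70) plus independent jitter, giving
  the reference-layer procedure designed structure to recover. The
  instrument's true noise statistics are unpublished; these values are
  chosen for testability, not device fidelity.

Cohorts draw per-subject speckle shape (log-normal), global per-layer-group
thickness offsets (mRNFL 3.8 μm, GCIPL 4.8 μm, outer retina 7 μm SD),
attenuation offsets (mRNFL 0.38, GCIPL 0.27 mm⁻¹ SD), age/sex/laterality,
and apply the patient-group effect: per-quadrant thickness deltas (mRNFL
SN −4.2, IN −5.1, ST −1.5, IT −1.3 μm; GCIPL about half that), smoothed so
the segmenter never sees step edges, plus a smaller attenuation increase
(mRNFL +0.18 mm⁻¹). These defaults emulate the nasal-predominant
inner-layer thinning pattern and effect-to-spread ratios of the clinical
comparison the package models; deltas that would drive a layer negative
are clamped at one voxel and flagged. Everything is deterministic given
the cohort seed (per-subject child seeds via `SeedSequence.spawn`).

What the phantom does **not** emulate: vascular shadows, motion artifacts
and "black bands", pathology-deformed anatomy, instrument roll-off, or
rigorous photon transport. Passing recovery tests therefore shows the
*pipeline arithmetic* is faithful — not that the segmenter or the indices
are robust on clinical data with those artifacts.

## Statistics

Every variable is screened per group with a Kolmogorov–Smirnov normality
test using the Lilliefors correction (mean and SD are estimated, so plain
KS p-values would be anti-conservative); `statsmodels` provides the
corrected p-values. Variables normal in both groups (p > 0.05) get the
classic equal-variance unpaired t-test (Welch is a config option); others
get the two-sided Mann–Whitney U — exact enumeration for small tie-free
samples, otherwise the normal approximation with tie correction and no
continuity correction (the convention of the major commercial package;
also what makes identical samples give p = 1 exactly). Pearson correlation
(two-sided t-based p) relates intensity ratio to thickness per group. The
2×2 chi-square uses no continuity correction by default (Yates is an
option); exact reproduction of any published p depends on that unstated
choice, so none is claimed. No multiple-testing correction is applied by
default (a Holm option exists), matching the modeled analysis.

ROC analysis computes AUC through the Mann–Whitney identity and its
standard error by the DeLong structural-components (midrank) estimator,
implemented in-package and cross-checked against the brute-force all-pairs
U count; orientation is chosen per variable so the reported AUC ≥ 0.5, and
the flip is recorded. Correlated AUCs from the same subjects are compared
with the paired DeLong z-test. Monte-Carlo studies at the modeled study's
group sizes (38/39) verify type-I calibration of both the gated two-sample
comparison and the paired AUC test within binomial error of the nominal
0.05 at 2000 replicates.

## Pipeline and problem sizes

`run_pipeline` chains simulate → segment (or import/truth surfaces) →
flatten → quantify → calibrate beta → compare → report, writes tidy CSVs
(per-subject metrics; thickness/ratio/OIAC group tables; correlation; ROC;
paired AUC contrasts), a QC summary, the serialized configuration with its
hash and seed, and a markdown report; reruns with the same configuration
are bit-identical. The designed-effect replicate study (100 seeded cohorts
of 38 + 39 subjects) renders speckled volumes and quantifies them on the
generator's true surfaces — the pipeline's external-surfaces mode — because
the property under test is the statistical pattern, which does not require
re-running the segmenter 7 700 times; segmentation accuracy is established
separately on its own phantoms, and the single-cohort pipeline tests do
exercise the full segment-then-quantify path. Replicates use the small
cohort grid; recovery studies use the 128×64×256 desk grid. These sizes
are the package's own test-design choices and are stated here so they can
be scaled up.

## Numerical choices and degenerate inputs

* Surfaces are validated (ordered, in-grid) on construction and on read;
  readers reject rather than repair. Crossing reports name the first
  offending A-line.
* Surface files round depths to 3 decimals of a voxel (round-trip error
  ≤ 5×10⁻⁴ voxel).
* Quadrant labels use strict inequalities on the midlines so
  mirror-invariance is exact; empty regions after masking come back NaN
  ("missing"), never 0.
* The decorrelation beta search runs on a 400-point log grid over
  [10⁻², 10³]; a flat objective returns the minimizer plus a warning and
  the full trace rather than failing.
* Degenerate statistical inputs (constant samples, single-class labels,
  zero marginals, mismatched subjects) raise errors with the reason named.
* The NRRD codec is intentionally minimal: 3D uint16, raw encoding,
  little-endian — exactly the volume interchange this package needs —
  with multi-page TIFF as the second, fully general route.
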