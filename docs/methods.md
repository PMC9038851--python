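# Methods

This note documents the models, defaults and numerical choices behind
`fovsharp`, and what the synthetic data can and cannot establish.

## Geometry and conventions

Volumes are HU-valued 3-D arrays on regular grids; voxel indices are
0-based and the physical position of voxel `(i, j, k)` is
`origin + (i·dx, j·dy, k·dz)` (voxel-centre convention). The slice axis
is the third index; gradients and the sharpness metric act in-plane
only. NIfTI-1 is the interchange format (float32 storage); DICOM series
are read-only input, and only axis-aligned axial grids are supported —
gantry-tilted or oblique reconstructions are out of scope. The FOV
diameter of a square isotropic grid is `matrix × spacing`, so the
in-plane voxel size of a reconstruction is `fov_diameter / matrix`.

Paired reconstructions of one acquisition share a frame of reference and
a z-grid, so "alignment" is pure grid resampling; no registration is
performed or needed.

## Sharpness metric

Per voxel, sharpness is the in-plane gradient magnitude
`sqrt(gx² + gy²)` with `gx, gy` central differences (one-sided at array
borders) in HU/mm — physical units make values comparable across grids
with different voxel sizes. Per slice, the metric is the **sum** of
gradient magnitudes over the significant-edge set (a `mean` per-voxel
normalisation and an `rss` variant, `sqrt(Σ(gx²+gy²))`, are config
options; the reading "magnitude per voxel, then summed" is the default
because a per-position gradient profile is the natural object the metric
integrates). Slices with an empty edge set score 0 and are excluded from
volume means rather than counted as zeros.

Significant edges are ROI voxels whose gradient magnitude exceeds an
Otsu threshold computed on the in-ROI gradient distribution, pooled over
the volume by default so all slices are scored against one common
threshold (`per-slice` scope is available). For pair comparisons the
edge mask is derived **once, from the small-FOV volume**, and applied to
both volumes; deriving a mask per volume would let each volume pick its
own favourable edge set and bias the comparison. A union-of-masks
variant is available.

Two invariances characterise the metric and are enforced by tests:
adding a constant HU offset changes nothing (gradients are
differences), and scaling intensities by `c > 0` scales the metric by
`c` exactly, because the Otsu threshold scales along with the data.

The per-pair significance test is a one-sided unpaired Student *t*-test
of the small-FOV per-slice values against the large-FOV values.
Neighbouring slices are correlated, so its nominal degrees of freedom
are optimistic; this is reported as-is (a known limitation, not
corrected) alongside the per-slice paired differences.

## Segmentation

The analysis ROI is built fully automatically:

1. **Body**: Otsu threshold on the whole volume (air vs. everything
   else), largest 3-D 26-connected component, slice-wise hole filling.
   This assumes air dominates the histogram, which a CT FOV guarantees.
2. **Bone**: second-stage Otsu on in-body HU values; connected
   components below `min_voxels = 50` are dropped as speckle. A fixed-HU
   fallback (`fixed_hu`, e.g. 300) exists for volumes where
   contrast-filled vessels contaminate the upper class.
3. **ROI**: body minus a physical safety margin — the body is eroded by
   `dilation_radius_mm` (default 2.0 mm) at the air boundary and the
   bone mask is dilated by the same radius. Both operations use the
   Euclidean distance transform with anisotropic spacing, so the margin
   is metrically exact on any grid.

Vessel-wall calcifications are deliberately **not** excluded: they are
vascular features whose edge degradation is exactly what the metric
should register. With the default second-stage Otsu on a
soft-tissue/bone histogram the threshold lands well above contrast
(~350 HU) and usually above calcification (~800 HU); large calcified
plaques can in principle be claimed by the bone mask, which the
`min_voxels` filter and the QC proxy make visible rather than silent.

`bone_removal_quality` is an automated stand-in for visual QC of bone
segmentation: the fraction of in-body voxels ≥ 700 HU belonging to
large (> 200-voxel) components — bone-calibre objects — captured by the
bone mask, with an eligibility cutoff of 0.98. It mimics an
"almost perfect bone removal" screen; it is a proxy and has not been
validated against human QC decisions.

### Otsu implementation

Thresholds are bin-edge values: candidate splits lie between adjacent
occupied histogram bins (256 bins by default for samples; precomputed
`(counts, centers)` histograms are accepted), the between-class variance
`ω₀ω₁(μ₀−μ₁)²` is maximised exhaustively, and the returned threshold
separates classes as `x < t` vs `x ≥ t`. Splits whose variance is
within 1e-10 relative of the maximum are treated as tied — adjacent
splits separated only by empty bins produce exactly this situation — and
the lowest threshold wins, making the tie-break independent of
floating-point summation order.

## Resampling

Large-FOV volumes are evaluated at the small-FOV voxel positions with
prefiltered b-spline interpolation (order 3 by default — "b-spline"
unqualified conventionally means cubic in imaging — orders 0–5
available), mirror boundary handling. Sampling at source voxel centres
reproduces the source exactly, and polynomial images up to the spline
degree are reproduced on interior voxels; the mirror-boundary prefilter
transient decays geometrically (ratio ≈ 0.268/voxel for cubic), which
matters only within ~15 voxels of a volume face. Target voxels outside
the source extent are filled with air (−1000 HU) and tracked in a
validity mask which downstream metric code intersects with the ROI. In
valid use the large FOV contains the small grid entirely; more than 1%
out-of-extent voxels is an error, and passing the volumes in the
reverse (resolution-losing) order triggers a direction warning instead.

## Phantom and reconstruction simulator

The phantom is a 2-D leg cross-section extruded along z: a soft-tissue
ellipse (40 HU) in air (−1000 HU), cortical-bone circles (1200 HU),
contrast-filled vessel circles (350 HU, radii restricted to the
femoral-to-pedal calibre range 0.3–6 mm), and mural calcification arcs
(800 HU) straddling vessel walls. Later structures overwrite earlier
ones, so rendering is order-deterministic. An optional linear vessel
taper along z (up to ~15% in the random generator) gives slices
non-identical content. Ground truth is rendered at ≤ 0.1 mm; each voxel
takes the HU of the last structure containing its centre.

Imaging a truth volume at a FOV proceeds as: (1) in-plane Gaussian blur
of FWHM `psf_fwhm` (default 0.6 mm — the detector-limited, FOV-
independent resolution of a modern MDCT, matching 0.6 mm collimation);
(2) area averaging over the voxel aperture `fov/512`, implemented as a
separable fractional-width box filter followed by sampling at the voxel
centres of the 512 grid centred on the phantom; (3) additive white
Gaussian noise (default sd 10 HU), seeded. The effective in-plane blur
is ≈ `sqrt(psf_fwhm² + voxel²)` FWHM, monotone in FOV — the minimal
model of the fact that a full-body FOV cannot use the scanner's full
resolution. Keeping the aperture in the averaging step (rather than
folding it into the Gaussian a second time) makes the zero-PSF,
zero-noise limit exactly a block average, which the tests exploit. Not
modelled, deliberately: filtered back projection or iterative
reconstruction, the reconstruction kernel, beam hardening, scatter,
tube-current modulation, z-axis blur, or contrast-timing effects on
vessel HU. Consequently the absolute metric values of simulated volumes
are not comparable to clinical ones; only their FOV ordering and
relative differences are meaningful.

## Rating simulator

Ordinal 1–5 scores are drawn from a discretised latent normal: per
(vessel level, FOV) cell a latent `N(mean, sd)` draw is rounded
half-up and clipped to [1, 5]; a score of 1 is flagged non-diagnostic.
The default cell moments are the published per-segment Likert means and
standard deviations of the reference reader study (femoral 4.02 ± 0.65
large / 4.70 ± 0.48 small, popliteal 3.82 ± 0.63 / 4.65 ± 0.52, crural
3.06 ± 0.72 / 4.18 ± 0.72, pedal 2.79 ± 0.73 / 3.87 ± 0.82), with
n = 100 exams and 3 readers. Rounding and clipping bias the discrete
mean relative to the latent mean (by up to ~0.05 for cells near the
scale end, e.g. 4.70 ± 0.48); the published moments are used as latent
parameters anyway, keeping the calibration transparent, and recovery
tests budget for the bias. The model draws readers independently —
there is no reader-specific leniency or exam-level correlation — so the
simulated ICC(2,k) (~0.7) reflects only the shared cell means, and is
expected to sit below a real study's agreement (0.82 in the reference
study). Tests therefore treat the ICC machinery (checked against
independent ANOVA oracles and `pingouin`) separately from the
simulator's agreement level, which is not a calibration target.

## Reader-study statistics

- **Exclusion**: non-diagnostic segments are excluded before analysis.
  Default policy `per-segment-pair` removes both FOV members of any
  (exam, side, level, reader) with a score of 1, preserving pairing for
  the signed-rank test; `per-rating` removes only the offending rows.
- **ICC(2,k)**: two-way ANOVA mean squares (targets = rating units,
  raters = readers), `ICC = (MSR − MSE) / (MSR + (MSC − MSE)/n)`;
  95% CI by the McGraw–Wong F-based construction with Satterthwaite
  degrees of freedom on the single-rater bound and a Spearman–Brown
  step-up (which is exact for this form). Incomplete matrices are
  rejected — never imputed — and the pipeline drops incomplete targets
  explicitly. Reliability bands: < 0.5 poor, 0.5–0.75 moderate,
  0.75–0.9 good, > 0.9 excellent (so 0.82 reports as "good"; note that
  the older Landis–Koch vocabulary would call the same value "almost
  perfect" — the banding above is the one implemented).
- **Wilcoxon tests**: the signed-rank statistic is W⁺ with zeros
  dropped and tied |d| ranks averaged; the null distribution is exact
  (dynamic programming over doubled ranks, so ties are handled exactly)
  up to n = 25 and a tie-corrected normal approximation beyond, no
  continuity correction. The rank-sum test enumerates group assignments
  exactly while `C(n, n_A) ≤ 2·10⁵` and otherwise uses the
  tie-corrected normal approximation. Two-sided p-values are twice the
  smaller tail, capped at 1.
- **Summaries**: per (level, FOV) mean, sample sd, median and IQR
  (linear-interpolation quartiles); Δmean = small − large; the paired
  tests per level run on pooled (exam, side) scores, small vs large.
  The *t*-test reported next to the signed-rank test is a paired
  Student *t*-test (both FOVs score the same segments). Side
  differences use the rank-sum test. No multiple-testing correction is
  applied (α = 0.05 throughout), and summary outputs state this.

## Pipeline defaults and problem sizes

End-to-end runs are reproducible from a serialisable `RunConfig` plus a
seed; all randomness flows through explicit integer seeds. The
simulated objective arm defaults to phantom pairs at FOV 423 vs 220 mm,
6 slices of 0.4 mm increment (matching a typical run-off reconstruction
increment), PSF 0.6 mm, noise 10 HU; property and acceptance checks use
20 random phantoms, enough for stable fractions while a full run stays
in the minutes range on one CPU. The subjective arm defaults to the
study size, 100 exams × 3 readers.

## What passing tests show — and what they do not

The synthetic pipeline establishes internal correctness (oracle
equivalence of every statistical primitive, metric invariances,
geometric exactness of resampling) and the qualitative physical effect
(small-FOV reconstructions score sharper on essentially all slices,
significantly, over many random phantoms). It does **not** reproduce
clinical effect sizes: the published objective mean difference of 2.1
(range 1.19–3.08) on 17 clinical datasets depends on the clinical
images, scanner kernel and the (unstated) normalisation of that number,
and no simulator choice here can validate against it. Likewise the
automated bone-removal QC proxy cannot be validated against the visual
17-of-100 eligibility screen of the reference study.
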