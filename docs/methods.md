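# Methods

## Problem and approach

Radiomic features computed from differently sized volumes of interest
(VOIs) disagree even when the underlying tissue is homogeneous: some
features scale with the number of voxels outright (energy, the
non-uniformity counts), and the rest drift because the per-ROI intensity
range — and with it the number of occupied gray levels after
discretization — grows with the sample size. `radiomap` quantifies this
effect and evaluates the parametric-feature-map correction: compute every
feature over small, equally sized blocks of the whole volume, store the
block values as coarse per-feature images, and summarize a VOI by the
mean of the map voxels it contains. Each map voxel then has identical
support, so for stationary texture the map summary is unbiased in the VOI
size and only its sampling variance depends on the VOI.

Agreement across VOI sizes is measured per feature with the overall
concordance correlation coefficient (OCCC) over subjects, using the
population-moment (1/n) convention of Lin's original estimator; a
compatibility flag (`ddof=1`) reproduces the sample-moment convention of
standard epidemiology packages, which differs slightly in how the
variance terms balance the mean-shift penalty. No confidence intervals
are attached: the analysis uses point OCCCs and the inclusive
reproducibility rule OCCC ≥ 0.85. (A bootstrap could be added, but the
classification rule itself is a point-value threshold.)

## Feature definitions

The 93-entry registry covers 18 first-order, 24 GLCM, 14 GLDM, 16 GLRLM,
16 GLSZM and 5 NGTDM features under their established
`family_FeatureName` names. Conventions that matter:

- **Discretization**: fixed bin width, `level = floor((x − min(ROI))/w) + 1`,
  then re-indexing of occupied bins to consecutive levels 1..N_g (empty
  bins are dropped before matrix construction). The default bin width is
  25 intensity units — the widely published recommendation for
  unnormalized images — and fully configurable. No intensity
  normalization or resampling is applied before extraction by default.
- **Aggregation**: GLCM and GLRLM are computed per direction over the 13
  unique 3-D direction vectors (Chebyshev distance 1), the GLCM
  symmetrized, per-direction features averaged. Directions yielding no
  voxel pair (possible for single-slice blocks) are dropped from the
  average. GLSZM zones and GLDM dependences use 26-connectivity; GLDM
  uses alpha = 0 and distance 1, NGTDM distance 1.
- **Moments**: population (1/N) denominators; skewness m3/m2^1.5 and
  uncorrected kurtosis m4/m2^2 (a Gaussian scores about 3).
- **Degenerate rules**, each a named constant with a test: entropy terms
  use 0·log 0 = 0 (all logs base 2); skewness/kurtosis of a constant
  sample are 0; correlation-type GLCM features are 1 at zero variance;
  NGTDM coarseness is capped at 10^6 when Σ p_i s_i = 0; percentiles
  interpolate linearly; the median of an even sample is the midpoint.
- Shape features are excluded by design: the VOI size is varied
  deliberately, so VOI geometry carries no tissue information.

Every matrix family is verified against an independent brute-force
enumerator (explicit Python loops over voxel pairs, runs, flood-filled
zones, neighbourhoods) to 1e-10 relative on random ROIs, including ROIs
with irregular masks.

## Parametric maps

Blocks are non-overlapping tiles anchored at the volume origin; the block
edge in source voxels is `round(block_size / spacing)` per axis (at least
one voxel). The study default is 5 mm in-plane — chosen so that every VOI
diameter (10/20/30 mm) is a multiple of the block size — and one slice in
z, matching the anisotropic acquisition. Trailing partial blocks become
NaN in every map rather than features over a smaller support, so each
finite map voxel summarizes the same number of voxels; the policy is
configurable. VOI "copying" re-rasterizes the same physical sphere
(centre mm, diameter mm) on the coarse map geometry — no mask resampling,
no interpolation — and the map summary is the plain arithmetic mean of
the non-missing covered map voxels. A 10-mm sphere on a ~5 mm grid can
cover no map-voxel centre; this is reported as a named coverage error
(and excluded listwise in the agreement step), never imputed, because
poorer map behaviour at small VOI sizes is part of the phenomenon under
study.

## Synthetic cohort

The phantom replaces an in-vivo cohort that is not publicly available.
Each subject's parenchyma is a stationary correlated Gaussian field:
white noise convolved with a Gaussian kernel of physical correlation
length (default range 3–6 mm, on the order of the texture that 5-mm
blocks average over), standardized and scaled to the subject's texture
SD, plus the subject's base mean, plus i.i.d. voxelwise scanner noise,
all scaled by a scanner gain. Between-subject heterogeneity is mandatory
— the OCCC degenerates when subjects are exchangeable — with defaults
base mean ~ N(300, 40) and texture SD ~ N(25, 6) (clipped at 0).
Bright tubular vessel segments (default 2–3 per subject, radius
1.5–3 mm, length 20–40 mm, +120 intensity) are rasterized into a
companion mask; VOI placement rejects centres whose largest sphere
touches a vessel, mimicking how readers avoid major vessels when
segmenting normal parenchyma. Noise is Gaussian rather than Rician: the
analysis is intensity-scale-agnostic and magnitude-MRI noise modelling is
out of scope.

Three scanner presets are geometry/noise/gain parameterizations only (no
pulse-sequence physics): two with 1.125 mm in-plane spacing and a 5.5 mm
slice step (5 mm slices + 0.5 mm gap), one with 1.09375 mm in-plane and a
6.6 mm step, the latter noisier and lower-gain as a 1.5-T-like analog.
The noise SDs (6, 4, 9) were set once to span a plausible SNR range
(~30–75 relative to the base mean) and expose the expected link between
SNR and map-extraction reproducibility; no quantitative SNR target
exists to calibrate against. "Sequence" is a single analog axis
(`seq1`): users can duplicate presets with different texture settings to
emulate sequence contrast.

Rendered volumes default to 56 × 56 × 11 voxels (~63 × 63 × 61 mm), the
smallest extent that comfortably hosts a 30-mm sphere with margin while
leaving room for vessel-free placement; this keeps the full study at
desk scale (about 7 minutes for 40 subjects × 3 scanners × 93 features
on one CPU). All randomness flows from a single master seed through
`numpy` seed sequences: cohort sampling, rendering, and VOI placement are
bit-reproducible.

## What the phantom does and does not show

The phantom is stationary away from vessels, so VOI-size effects are
attributable purely to support size (sample-extremum-driven gray-level
counts, count-type features, estimator bias at small N) — exactly the
mechanism map extraction corrects. Passing the headline checks therefore
demonstrates the mechanism, not in-vivo performance: real parenchyma has
nonstationary anatomy, partial-volume and bias-field effects, Rician
noise and sequence-dependent contrast, none of which are simulated, and
real per-feature OCCC values will differ. Conversely the phantom's
determinism makes the qualitative signatures (map ≥ conventional;
excluding the smallest VOI helps both routes) reproducible to the bit
given a seed.

## Design choices on genuinely open points

- **Concentric VOIs**: whether the three sphere sizes should share a
  centre per subject is not externally fixed; concentric placement is
  adopted so that size is the only varying factor, and reports flag the
  choice.
- **Voxel-centre inclusion** (centre strictly inside the radius) for
  sphere rasterization, matching common segmentation rasterizers; the
  mask-nesting invariant for concentric spheres follows directly.
- **Grid anchoring** at the volume origin and the NaN partial-block
  policy are recorded in the map manifest, since block-edge policies are
  tool-specific in practice.
- **Index convention**: arrays are (x, y, z) with z the slice axis;
  voxel centre of index (i, j, k) is `origin + (i + 0.5) · spacing`. All
  physical computation goes through the geometry, never raw indices.

## Known limitations

- Map computation iterates blocks in Python; a ~60-volume cohort with
  all 93 maps is minutes, clinical-resolution stacks would be hours. A
  crop-to-VOI acceleration (with edge caveats) is a possible extension,
  deliberately not implemented.
- Only the arithmetic mean is supported as the map-VOI summary; median
  or trimmed summaries are future flags.
- The GLCM MCC eigen-decomposition and the Imc features follow one of
  several published conventions; the brute-force oracles pin the
  implemented convention rather than adjudicating between tools.
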