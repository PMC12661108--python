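# Methods

## Problem and approach

Prostate radiotherapy planning needs the gland aligned between a
diagnostic axial T2-weighted MRI (where the prostate is well seen) and the
planning CT (where it is nearly iso-intense with surrounding soft tissue).
Direct global intensity registration is unreliable here: the MRI covers a
small field of view (FOV) around the gland while the CT covers the whole
pelvis, the modalities look nothing alike, and the prostate moves relative
to bone with bladder and rectal filling. `prostalign` sidesteps the direct
MRI–CT comparison entirely: both modalities are registered to a *pair of
probabilistic atlases* that live on the same standardized grid and are
therefore inherently co-registered at a fixed anchor point. Composing the
two single-modality registrations yields a prostate-specific MRI→CT rigid
map.

All registrations are translation-only by default. Rotation is supported
throughout the transform algebra (composition, inversion, file I/O,
resampling), and an optional small-angle refinement stage
(`estimate_rotation=True`; intrinsic z-y-x Euler angles limited to ±5°,
rotating about the atlas anchor so the angles stay decoupled from the
translation) can be enabled — but it is off by default, keeping the
method rigid in the strictest sense, which matches how manual clinical
fusion of this kind is typically performed at the prostate.

### Coordinate conventions

World coordinates are LPS in millimetres (x = left–right, y =
anterior–posterior, z = superior–inferior), with 0-based voxel indices
referring to voxel centers. NIfTI affines are written and read verbatim in
this convention. Transform files are plain-text 4×4 row-major homogeneous
matrices mapping MRI world points to CT world points; the direction is
recorded in a `#` header comment because neither direction is a universal
clinical convention.

## Atlas construction

The reference volume is 400 × 400 × 100 mm with the anchor at its
geometric center (200, 200, 50) mm. The grid spacing is not dictated by
the reference extent; the default is 2 mm isotropic, which keeps the CT
atlas sharp enough to drive registration while the full volume stays at
2 × 10⁶ voxels. For each training case the prostate-segmentation centroid
is computed (unweighted mean of foreground voxel-center world
coordinates), the translation `anchor − centroid` is applied, and the
image is resampled onto the reference grid (trilinear for intensities,
nearest-neighbor for masks). The atlas is the voxelwise mean of the
aligned images, and the prostate-probability map is the voxelwise mean of
the aligned binary masks.

Two details matter in practice:

* **Intensity normalization.** MRI intensities are scanner-arbitrary, so
  each case is mapped linearly so its 1st/99th percentiles land on 0/1,
  then clipped — robust to outlier voxels and enough to make cross-case
  averaging meaningful. CT is already calibrated in Hounsfield units and
  is only clipped to [−1000, 1500] HU.
* **Partial coverage.** A small-FOV case does not see most of the
  reference volume. Voxels outside a case's FOV are excluded from that
  voxel's average through a per-voxel coverage counter rather than
  averaging in fill values, which would otherwise drag the atlas
  periphery toward the fill (0 for MRI, −1000 HU for CT).

## Registration

**MRI side.** With a prostate segmentation given (in the clinic from a
learned segmenter; in tests from the phantom generator or band
thresholding), the MRI→atlas transform is closed-form: the translation
taking the mask centroid onto the anchor.

**CT side.** Two steps:

1. *Landmark initialization.* Bone is thresholded at ≥ 300 HU and split
   into 6-connected components. Among components whose centroids lie in
   the middle axial third of the volume, the two largest with a
   left–right centroid separation ≥ 60 mm are taken as the femoral
   heads. The prostate is estimated at their midpoint plus a fixed offset
   (default (0, +25, +10) mm — posterior and superior in LPS), and the
   rough CT→atlas translation maps that estimate onto the anchor. The
   femoral heads were chosen as the landmark because they are large,
   bilateral, and survive FOV truncation; if detection fails (no bone,
   or no laterally separated pair) the pipeline falls back to
   volume-center initialization and flags it in the report rather than
   aborting.
2. *Multi-stage optimization.* The cost over a cubic region of interest
   (ROI, half-width 50 mm about the anchor, sampled on a lattice at the
   stage's spacing) is

   `cost(T) = w_i (1 − NCC) + w_s (2 − NMI)`, `w_i = w_s = 0.5`,

   where NCC is the Pearson correlation between atlas and transformed-CT
   ROI samples and NMI = (H(A)+H(B))/H(A,B) is Studholme's normalized
   mutual information from a 32 × 32 joint histogram (equal-width bins
   over each image's ROI range). NMI ranges from 1 (independent) to 2
   (identical), so the cost is bounded and exactly 0 for identical ROIs.
   One metric per family — a correlation term that rewards matching
   contrast and a histogram term that tolerates nonlinear intensity
   relationships — keeps the combination well-scaled without tuning.
   A constant ROI in either image makes NCC undefined and raises a
   degenerate-similarity error.

   The default schedule is: stage 1, exhaustive translation grid ±20 mm
   at 4 mm steps around the initialization, ROI sampled at 4 mm; stage 2,
   Nelder–Mead over the three translation components at 2 mm sampling,
   convergence tolerance 0.5 mm; stage 3, Nelder–Mead at 1 mm sampling,
   tolerance 0.1 mm. Nelder–Mead termination is purely spatial (simplex
   diameter below the stage tolerance): the sampled cost has an
   interpolation-noise floor, so a function-value criterion either never
   fires or fires spuriously. Iterations are capped at 200 per stage;
   hitting the cap returns the best-so-far with a warning flag in the
   diagnostics. Grid ties are broken by cost, then smaller step from the
   initialization, then lexicographic order, making results reproducible.

   Costs at different stages are computed on different sampling lattices
   and are not directly comparable, so a running best is maintained at
   the finest stage's sampling: each stage's result is re-scored there
   and kept only if it improves. The reported across-stage trace is this
   running best, which is non-increasing by construction; within-stage
   traces (grid scan, simplex descent) are recorded and non-increasing as
   well.

**Fusion.** `fuse(t_mri, t_ct) = t_ct⁻¹ ∘ t_mri` maps MRI world points
through the shared atlas frame into CT world coordinates.

## Synthetic pelvic phantom

No public paired MRI/CT prostate dataset with ground-truth alignment
exists at this scale, so the package carries a seeded digital phantom:
analytic organs (prostate ellipsoid; bladder sphere; rectum cylinder with
an optional superior gas column; two femoral-head spheres; a superior
pelvic-ring bone shell; an elliptic soft-tissue body) rasterized at voxel
centers, with modality-specific intensities (CT: soft tissue 40 HU, fat
−90, bone 700, urine 10, gas −1000; MRI arbitrary units: prostate 180,
urine 250, muscle 80, bone 40, gas 5; the prostate is deliberately
iso-intense with soft tissue on CT), additive Gaussian noise (MRI σ = 8,
CT σ = 15 HU — strong enough that registration is nontrivial, weak enough
that it is solvable), and a known rigid MRI→CT offset. The CT covers a
400 × 400 × 200 mm pelvis at 2 mm; the MRI covers 240 × 240 × 120 mm at
1.5 × 1.5 × 3 mm around the prostate, its center jittered up to 10 mm from
the gland — reproducing the FOV mismatch that defeats global
mutual-information registration. CT values are clipped to [−1024, 2000] HU.

Every stochastic choice that shapes a case (offset, anatomy jitter, gas
fraction, FOV jitter) is drawn when the *spec* is created; the spec's own
seed drives only the noise. Identical spec + seed therefore reproduces a
case bit-exactly, and specs differing only in seed differ only in noise.

Two spec factories define the study conditions:

* `offset_spec` — default anatomy, rigid offset uniform in ±15 mm per
  axis. This is the parameter-recovery condition: the unknown is the
  offset, and the recovered transform is compared against exact ground
  truth at the prostate centroid (target registration error, TRE).
* `random_spec` — additionally draws per-organ position jitter
  (σ = 1 mm per axis), ±10 % organ size variation, and rectal gas
  fraction uniform in [0, 0.7]. This is used for atlas training cohorts,
  where anatomical variation is the point of averaging.

A limitation worth stating precisely: when the held-out case's organs are
jittered *relative to its prostate*, the similarity optimum is displaced
by roughly the mean organ displacement — the anatomy simply no longer
determines the prostate position more accurately than the jitter. This is
a property of rigid intensity registration as such, not of the
implementation (physiologic change between scan sessions limits rigid
fusion in the clinic the same way). The acceptance script therefore
reports the varied-anatomy battery separately from the
parameter-recovery battery; expect the former's TRE to sit near the
jitter floor (≈ 2–3 mm median) rather than the sub-millimetre recovery of
the fixed-anatomy condition. The phantom also does not model MR physics
(bias fields, Rician noise), deformation, or implants.

## Variability statistics

For multi-rater validation, each registration's "position" is the MRI
prostate centroid mapped into CT coordinates. The consensus `P_avg` is
the mean of manual rater positions (for translation-only transforms this
equals the position under the mean translation — both interpretations of
"averaging the registrations" coincide, which is why the position-based
definition was fixed; it stays well-defined if rotations are ever
enabled). `D_PPro` is the automated result's distance from the consensus,
`D_intra` a rater's round-1↔round-2 distance at matching workflow mode,
`D_inter` the maximum rater distance from the consensus. The automated
result is classified acceptable when `D_PPro` does not exceed the
observed intra-rater (per-case minimum) or inter-rater variability;
equality counts as acceptable ("falls within the range"). Cohorts are
summarized by median and IQR using linear-interpolation percentiles (the
convention is recorded in output metadata). The System Usability Scale is
scored conventionally (odd items `r − 1`, even items `5 − r`, sum × 2.5)
with scores strictly above 68 classified above average.

The rater-study emulation draws rater positions as truth plus independent
per-axis Gaussian jitter (default σ = 1.5 mm, a plausible expert
variability scale). Under this model the intra-rater distance is
σ√2 · χ₃ and, with an exact automated transform and six rater entries,
`D_PPro` is σ/√6 · χ₃ — both with closed-form medians the metric suite
must recover. The inter-rater statistic (max of six correlated deviations
from their mean) has no convenient closed form; its reference median is
computed by direct Monte-Carlo simulation of the statistic itself
(2 × 10⁵ draws, independent RNG stream, never touching the suite's code
path). Agreement is asserted within distribution-free order-statistic
confidence bounds on the sample median.

## Problem sizes and numerical choices

The shipped batteries use a 10-case atlas cohort, 20-case recovery and
FOV-mismatch batteries, a 10-case varied-anatomy battery, and 500
emulated rater cases — sizes chosen so the full acceptance run completes
in minutes on one core while keeping Monte-Carlo error well below the
tolerances being checked. Resampling uses trilinear interpolation
(nearest-neighbor for masks) with declared out-of-FOV fill values (MRI 0,
CT −1000 HU); similarity moments are accumulated in double precision over
float32 samples; empty masks, constant ROIs, non-finite transforms and
non-orthonormal rotations raise typed errors rather than propagating
NaNs.
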