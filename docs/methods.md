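# Methods

## Surface extraction

Structures arrive as integer label maps (NIfTI or MGZ; FreeSurfer aseg
IDs by default: amygdala 18/54, hippocampus 17/53, lateral ventricle
4/43, configurable via a JSON label map). The binary mask of one label is
zero-padded by one voxel and contoured with scikit-image's marching cubes
at iso-level 0.5; vertices are mapped to world millimetres through the
image affine. A mask that touches the volume border is rejected (the
structure is presumably clipped by the field of view) rather than closed
artificially. No smoothing is applied by default — the extraction is then
fully deterministic; optional Taubin smoothing (10 iterations) is
available behind a flag and is recorded in provenance. Inferior-horn and
choroid-plexus labels are *not* merged into the lateral ventricle by
default; the label map is the single place to change that.

Under the linear-interpolation marching-cubes convention, a single
labelled voxel yields the dual octahedron through the half-way points to
its neighbours (enclosed volume 1/6 mm³ for 1 mm isotropic voxels), not
the 1 mm³ voxel cube that blocky extractors produce. This
convention-dependent offset vanishes rapidly with structure size: for
digitized balls the enclosed mesh volume is within 15% of the voxel-count
volume at radius 6 and the relative error decreases with radius (tested).

Surfaces with speck components (< 1% of total enclosed volume, as
produced occasionally by noisy segmentations) are discarded with a
warning, keeping the largest component; a genuinely fragmented surface is
an error. Winding is unified and flipped to outward if the signed volume
is negative; orientation problems are repaired, never rejected. Spectra
require closed + edge-manifold + single-component, enforced by an
exhaustive edge-accounting validation report.

## Spectra

Linear (P1) Lagrange FEM: the stiffness matrix is the cotangent matrix
(edge weight (cot α + cot β)/2), the mass matrix is the consistent P1
mass (per-triangle |T|/6 diagonal, |T|/12 off-diagonal). A lumped
(diagonal, |T|/3) mass is available behind a flag. Higher-order elements
buy accuracy per vertex but complicate assembly; P1 with the consistent
mass reaches < 0.3% relative error on the first 8 sphere eigenvalues at
subdivision 4 (2562 vertices), comfortably inside every tolerance used
here, and the convergence tests pin the discretization error empirically.

The generalized eigenproblem A f = λ B f is solved with ARPACK
shift-invert Lanczos at shift σ = −0.01 (A − σB is positive definite on a
closed surface), requesting l+2 pairs with a seeded deterministic start
vector so repeat runs agree to solver tolerance. The constant mode's
near-zero eigenvalue is identified relative to the first eigenvalue that
is non-zero on the scale of the largest computed one (ratio 1e-6) and
discarded; two or more near-zero eigenvalues mean a disconnected surface
and raise. Normalization λ′ = vol^(2/D)·λ is applied after dropping the
zero mode, with vol the area of the exact mesh handed to the solver
(post-smoothing when smoothing is enabled). Eigenfunctions, when
requested, are B-orthonormal as returned by the solver and satisfy
‖Af − λBf‖/‖Bf‖ ≤ 1e-6 (tested).

Absolute eigenvalues of any FEM discretization depend on element order
and mesh density; the contract here is the invariance and convergence
behaviour (isometry invariance to 1e-6, scale invariance of the
normalized spectrum to 1e-8, 2% agreement between subdivision levels),
not bit-agreement with any other implementation.

## Asymmetry measures

Shape asymmetry is the Mahalanobis distance between left and right
descriptors under the *fixed* diagonal covariance Σᵢᵢ = i² (no covariance
estimation from data): Y_s = sqrt(Σᵢ (λ_L,i − λ_R,i)²/i²), 1-based. It is
a metric on descriptor space and symmetric in the hemispheres, capturing
directional and undirectional asymmetry jointly without distinguishing
them. Volumetric asymmetry defaults to the absolute difference |L − R| in
mm³: plausible cohort magnitudes (hundreds of mm³ for hippocampus,
thousands for ventricles) correspond to raw differences, and head size is
controlled in the regression through ICV rather than by normalizing the
measure itself. The normalized laterality index |L−R|/(L+R) is available
behind a flag.

## Cohort statistics

Sample filters, applied in order and each logged per subject: missing
FSIQ; age > 35 years; scan quality flagged poor; FSIQ farther than 2 SD
from the pre-filter sample mean (mean/SD computed over the full input
sample, so one gross outlier does not move the band for the others).

Each of the six outcomes (3 structures × {shape, volumetric}) is fitted
by OLS on: diagnosis (coded 1 = control, 0 = ASD, so **negative β ⇒ ASD >
controls**), sex (1 = female, 0 = male, so negative β ⇒ males > females),
age (linear), site dummies (alphabetically first site as reference; site
terms reported jointly via an F-test, not individually), ICV and FSIQ.
The design matrix is built explicitly (no formula layer) and is checked
for ≥ 2 subjects per diagnosis group and per site and for full column
rank, naming collinear terms on failure. Optional interaction terms
(diagnosis:sex, diagnosis:age, sex:age) are off in the headline model.

The quadratic-age check is a likelihood-ratio test between the linear
model and the same model plus age² (internally centered age, which leaves
the fit and hence the LRT unchanged while conditioning the design),
2·Δloglik against χ²(1). Bonferroni correction uses family size m = 6 by
default (configurable; the report prints the m used). Subgroup contrasts
use Welch's t-test with Satterthwaite degrees of freedom (scipy).

## Synthetic data

The generator produces the three kinds of input the pipeline needs, all
deterministic under a seed:

* **Mirrored mesh pairs** — left is a base genus-0 mesh; right is its
  exact mirror with a smooth deformation of amplitude a (fraction of mean
  radius). `bump` indents a compact random patch along its axis with a C¹
  cosine-squared kernel, emulating a focal change; an excessive amplitude
  pushes the patch through its own rim, which is detected via inverted
  face normals and raised. `bend` shears the shape proportionally to z²
  (volume preserving in the continuum); `stretch` scales along a random
  axis. `compensate_volume` rescales uniformly back to the base volume —
  since the normalized spectrum is scale invariant this produces a pair
  with shape asymmetry but < 1% volumetric asymmetry, the dissociation a
  focal pathology would produce.
* **Label volumes** — mirrored digitized balls or two-lobe blobs with
  distinct left/right labels; the right mask is the exact voxel mirror of
  the left, so digitization symmetry is perfect by construction.
* **Cohort tables** — covariates drawn from realistic marginals
  (defaults: n = 948, 85% male, 46% ASD, age ≈ 16 ± 6.2 truncated to
  [6, 35] years, FSIQ ≈ 108 ± 13, ICV ≈ 1.33×10⁶ ± 2.6×10⁵ mm³, 17
  equally likely sites with Gaussian site offsets of SD 0.2), outcomes
  generated as the analysis model's linear predictor plus Gaussian noise
  (residual SD 1 by default), true coefficients stored in
  `DataFrame.attrs`.

What the generator does *not* emulate: real subcortical anatomy (shapes
are deformed spheres, not hippocampi), MRI intensities or segmentation
error, non-Gaussian or heteroscedastic outcome noise, site-by-covariate
confounding, and the empirically skewed distribution of real asymmetry
outcomes (simulated outcomes are Gaussian and may be negative). Passing
tests therefore demonstrate correctness and calibration of the geometry
and statistics under the stated model — not robustness to real-data
pathologies such as segmentation failure or scanner-specific bias.

## Numerical choices and problem sizes

Eigensolver tolerance is ARPACK's default (machine precision), shift
σ = −0.01, start vector from a seeded generator; mirror-pair asymmetry
noise floors are ~1e-13. Degenerate faces (area < 1e-12 mm²) are rejected
by index at assembly. CSV outputs render floats at %.10g so identical
runs are byte-identical.

Simulation sizes used by the test suite and acceptance script: type-I
error of the diagnosis term over 1000 null cohorts of n = 300 (4 sites);
LRT null calibration over 500 cohorts of n = 400; LRT power and
sign-convention checks at n = 2000; Welch null uniformity over 2000
replicates (30 vs 45, unequal variances); spectra on icospheres at
subdivisions 3–5 (642–10242 vertices) and digitized balls of radius 8
voxels. These sizes give stable Monte-Carlo bands (99% binomial band
around 0.05 at 1000 replicates is ±0.018) while keeping the whole suite
fast.

## Known limitations

* Only 2D boundary-surface spectra; no tetrahedral (solid) spectra, so
  the descriptor ignores internal structure by design.
* P1 elements: absolute eigenvalues carry O(h²) discretization bias;
  comparisons are meaningful within a consistent meshing pipeline.
* Whether to smooth marching-cubes output before spectra is a real
  degree of freedom; the default is unsmoothed for determinism, and
  descriptors from smoothed vs unsmoothed meshes should not be mixed
  within one analysis.
* Site enters as fixed dummies; no mixed-effects or harmonization
  (scanner-batch correction) is attempted.
* The volumetric asymmetry convention (absolute difference vs normalized
  index) changes the scale of that outcome; analyses must use one
  convention throughout.
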