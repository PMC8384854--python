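# Methods

This note documents the models, numerical choices, and design decisions
behind `nautimorph`, in the spirit of a package methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis pipeline

### Landmarking

Suture lines and whorl cross-sections arrive as densely sampled closed
polylines (≥ 500 points; the generator emits 512).  Arc length is computed
piecewise-linearly — no spline fitting, so there is no spline dialect to
pin down, and the discretization error is second-order in the sampling step
(≈ 1e-5 relative at 512 points).  `resample_equidistant` places k landmarks
at arc-length positions i·L/k on closed curves (i·L/(k−1) on open ones).

The starting landmark on a closed curve is anatomical and deterministic:
the **ventral rule** starts at the vertex farthest from the coiling axis
(for 3D sutures, distance √(x²+y²) from the z axis; for 2D sections the
first coordinate is the radial distance), ties broken by smallest vertex
index.  Curve orientation is taken as given; the generator emits all curves
with a consistent counterclockwise parameterization.  Whether one should
landmark the full closed suture or only one half up to the plane of
bilateral symmetry is a digitization choice; the full closed curve is the
default here, and nothing downstream depends on that choice.

### Bending energy and sliding

The thin-plate-spline bending-energy matrix of a reference configuration
X (k × d) is the Schur complement of the affine block of the bordered TPS
system: with K_ij = U(‖x_i − x_j‖), P = [1 | X], and Q₂ an orthonormal
basis of the null space of Pᵀ (from a complete QR of P),

    B = Q₂ (Q₂ᵀ K Q₂)⁻¹ Q₂ᵀ .

Kernels are U(r) = r² log r in 2D and U(r) = −r in 3D (U(0) = 0); with
these signs B is symmetric positive-semidefinite in both dimensions, and
B·P = 0 holds exactly by construction, so affine transforms of the
reference have zero energy.  The null-space route is better conditioned
than inverting the full bordered matrix and is independent of the dense
bordered-system solve used as the oracle in the tests.

Sliding minimizes Σ_c (x_c + t⊙u_c)ᵀ B (x_c + t⊙u_c) over sliding
magnitudes t along the unit tangents u of each configuration's **own**
curve (tangent-line sliding; all landmarked structures here are curves).
Each iteration solves the resulting linear system for the free landmarks
(a 1e-12-scaled ridge guards rank deficiency), displaces along tangents,
re-projects onto the polyline, and backtracks (halving the step) if the
projected energy rose — so energy is non-increasing across iterations by
construction.  Two deliberate choices:

* **Trust region.** Each magnitude is capped at half the mean landmark
  spacing per iteration.  On smooth near-elliptical outlines the bending
  energy is almost flat along whole-curve reparameterizations (for a circle,
  sliding all landmarks by a constant arc is exactly a rotation, which the
  energy ignores); without the cap the quadratic step travels far along that
  valley on the strength of noise, scattering the correspondence.  The cap
  keeps sliding a local correction to the already-good equidistant start;
  it does not change any minimum, only the path taken to it.
* **Reference choice.** The reference individual is the configuration of
  median centroid size among all configurations of a character (ties broken
  by label) — a deterministic middle-of-the-road choice that avoids the
  smallest (noisiest) and largest shells.  Landmark 0 (the ventral start) is
  fixed by default.  Defaults: max_iter = 10, tol = 1e-8 relative energy
  decrease.

Fixed landmarks need not lie on the sliding curve; sliding landmarks
farther than 0.1% of the curve length from the curve are rejected as input
errors.

### Procrustes alignment and ordination

Full generalized Procrustes: center, scale to unit centroid size, then
iterate "rotate all onto the consensus / recompute the renormalized mean"
until the consensus moves < 1e-10.  Rotations are proper only (the smallest
singular direction is flipped when the unconstrained optimum would be a
reflection): conchs are chiral and mirroring would fabricate similarity.
After convergence the whole aligned set is rotated into a canonical frame —
the consensus is aligned to its principal axes with a deterministic sign
rule (largest-magnitude loading positive, last axis flipped if needed to
keep the rotation proper).  This makes the output, and therefore all PC
scores, reproducible bit-for-bit regardless of how the inputs were
positioned, scaled, or oriented.

Residuals are defined as aligned − mean(aligned), so their mean is exactly
zero; the consensus reported is the renormalized mean (unit centroid size).
The two differ by O(variance) in scale only, and PCA re-centers anyway.
PCA is the covariance eigendecomposition of the residual vectors via SVD,
no variable rescaling, all min(n−1, p) components retained — variance
fractions sum to one and Euclidean distances over all PC scores equal
residual-space distances exactly.  Eigenvector sign is fixed by making each
loading's largest-magnitude element positive.

The pooled-ontogeny PCA (every chamber and section of every specimen in one
shape space) is the default; stage analyses slice that pooled space rather
than refitting per stage, so a specimen's configurations trace a trajectory
through a common ordination.

### Trees

Canonical neighbor joining on the Q criterion, with deterministic
tie-breaking (lexicographically smallest pair of cluster keys, a cluster's
key being its smallest tip label) and negative branch lengths clamped to
zero with the deficit moved to the sibling (configurable off).  On additive
matrices the algorithm recovers the generating tree exactly; this is
theorem-backed and tested against simulated random trees.  Trees are
unrooted; serialization roots arbitrarily at the final join.  The Newick
writer is deterministic (6-decimal lengths, labels quoted when they contain
reserved characters) so write → read → write is byte-identical; traversal is
iterative because ontogenetic-series trees are deeply unbalanced.  Tip sets
at a stage are individual configurations — two chambers and two
cross-sections per specimen — labeled specimen + chamber/section.

Septal spacing is a scalar, so its tree distance is the absolute angle
difference between configuration tips.

"Deepest bipartition" of a pooled tree means the unrooted internal edge of
maximum total length (the two child edges of a degree-2 serialization root
are one unrooted edge and their lengths are summed).

### Septal statistics

Spacing series element j is the angle of chamber j + 2 (chamber 1 is
excluded from all analyses; chambers are numbered from 2).  Stages per
chamber: mature = last two chambers regardless of size; pre-hatching =
conch diameter < 30 mm among the rest; juvenile–submature otherwise.  The
boundary lies exactly at 30 mm on the juvenile side ("< 30" / "≥ 30").

One-way fixed-effects ANOVA is computed from the classical sums of squares
with the upper-tail F probability; the degenerate all-identical case is
defined as F = 0, p = 1.  Pairwise comparisons are Tukey–Kramer on the
studentized-range distribution (scipy's exact implementation) with the
unbalanced-n standard error; p-values, intervals, and the significance flag
all derive from the same quantile, so they cannot disagree.  With two
groups the procedure reduces analytically to the pooled-variance t-test
(q = √2·|t|), which the tests verify to 1e-6.  Groups with a single
observation are excluded with a logged warning.  Chambers are pooled within
specimen and stage, as is conventional for this design; no repeated-measures
correction is applied, so p-values should be read as descriptive when
chambers within a specimen are strongly autocorrelated.

Hatching detection scans the spacing series for the first angle at least
20% below the running maximum of the preceding angles within the first 12
chambers and reports that chamber; a series with no qualifying drop returns
"not detected".  The 20% threshold is configurable; "steep" is inherently
qualitative and 20% cleanly separates the hatching drop from plateau noise
at the default noise level.

## The synthetic generator

The generator emulates the statistical structure of a CT-based comparative
study of modern nautilids — nine species/populations, two specimens each —
without reproducing any real specimen.

**Coiling.**  Raup-style logarithmic spiral about the z axis: conch
diameter d(θ) = d₀ · W^(θ/360°), with W ≈ 3 per revolution and d₀ ≈ 18 mm,
giving mature diameters around 130–250 mm over ~2.2 revolutions and ~33
chambers — the range seen in museum specimens.  Conch diameter of a chamber
or section is the maximum distance across the spiral in the median plane at
that position (the standard conchometric convention; the venter radius plus
the venter half a whorl back).

**Cross-sections.**  The whorl outline is an ellipse between the venter and
the umbilical seam (umbilical_ratio u sets the inner edge at u·r_venter),
polar-modulated by low-order harmonics: R(t) = 1 + c₁cos t + Σ_j c_j cos jt,
j = 2…6.  Generation fails loudly, naming the parameter, if the modulation
approaches zero (self-intersection) or the outline would cross the coiling
axis.

**Ontogeny.**  Two shape processes are superimposed:

* an **embryonic component** (c₁ = 0.25, c₂ += 0.35) present below the
  hatching diameter (30 mm, matching the pre-hatching stage rule) and shed
  abruptly at hatching — in real nautilids hatching is an abrupt ecological
  transition and leaves the largest single shape discontinuity of ontogeny;
* a **species component** (section aspect ratio and the cos 3t–cos 5t
  harmonics) that unfolds linearly with diameter between 5 mm and 150 mm,
  so juveniles of all species converge on a shared embryonic shape and
  adults diverge.

The suture is the outline-following closed 3D curve at each septal
position, displaced adapically by one shallow lateral lobe per flank
(lobe depth = suture_lobe_amplitude × whorl height × sin²t, converted to a
rotational offset at the whorl center radius), with the outline shape frozen
at the chamber's diameter so a single suture never straddles the hatching
transition.

**Septal schedule.**  Angles (element j = chamber j + 2): a monotone ramp
from 0.35·angle_pre to angle_pre peaking at chamber h − 1 (h = hatching
chamber, 7 or 8), a first post-peak angle clipped at least 20% below the
peak (the hatching drop), a stationary Gaussian band centered on the
species' angle_mid ∈ [20°, 30°], and a strictly decreasing crowded tail.
Crowding fractions (0.38 + 0.22 per position from the end) are anchored to
a band-center reference of 25°, not to the species' own angle_mid: terminal
crowding is modeled as a shared maturity signal, which is what makes
spacing non-diagnostic at the mature stage while angle_mid differences make
it strongly diagnostic in middle ontogeny and the shared ramp makes it
non-diagnostic before hatching.

**Variation and noise.**  Per-specimen parameters are the species means
perturbed multiplicatively by per-parameter coefficients of variation
(z truncated at ±3; hard invariants re-clipped).  Measurement noise is
isotropic and band-limited: a 6-harmonic random Fourier series per
coordinate with total variance landmark_noise_sd² (default 0.05 mm).
White noise per dense sample would be comparable to the 0.1–0.5 mm
polyline segment length and corrupt arc length — the very substrate of the
landmarking — whereas band-limited noise emulates smooth digitization and
biological irregularity while keeping curves rectifiable.  Because the
noise is absolute (mm) and shells at 20 mm are small, relative noise is
larger early in ontogeny, as with real CT voxel error.

**Calibration.**  The nine species shape means sit on a max-min-optimized
9-point design in the four effectively orthogonal section-shape dimensions
(ellipticity and the cos 3t/4t/5t harmonics; the aspect ratio and the
cos 2t coefficient are collinear in shape-effect space to first order, so
c₂ is held common), making pairwise species distances uniform to within
~12%.  The scale is set so that the between-species mean shape distance is
roughly three within-species standard deviations at the 50 mm stage and of
the order of the within-species spread at the 20 mm stage — the regime in
which species separate in middle ontogeny but not before hatching.  Within-
species spread is dominated by per-configuration measurement noise rather
than specimen-level parameter drift; coherent drift moves whole specimens
between clusters and is kept small.

**Determinism.**  (species specs, seed) fully determine a dataset: specimen
seeds derive from a `SeedSequence`, every random draw goes through the
specimen's generator, and zero-variance settings still consume the same
draws so that the zero-noise limit is bit-reproducible.

## What the synthetic data do and do not show

The generator reproduces the *structure* of real nautilid data — shared
ontogenetic trajectories with an abrupt hatching discontinuity, species
differences that grow through ontogeny, a diagnostic septal-spacing profile
— but not its *texture*: real sutures have richer lobation, real
cross-sections have dorsal impressions from whorl overlap, real measurement
error includes segmentation bias, and real intraspecific variation is not
multiplicative-Gaussian.  Passing tests therefore demonstrate that the
pipeline recovers known structure from curve data with realistic noise
levels and sample sizes; they do not certify species discrimination rates
for real material, which depend on the true effect sizes.  Per-PC variance
percentages computed on synthetic data characterize the simulated design,
not any particular set of museum specimens.

## Problem sizes

The default study design (9 species specs × 2 specimens, ~33 chambers and
~16 sections per specimen) produces ≈ 590 suture and ≈ 315 section
configurations; a full pipeline run — sliding both characters, GPA, PCA,
and all twelve neighbor-joining trees, including the ≈ 590-tip pooled
trees — completes in about a minute on one CPU, and the simulation-based
checks (200-specimen hatching detection, 2000-replicate ANOVA null
calibration) were sized to keep the whole verification suite comfortably
rerunnable.

## Known limitations

* Tangent-line sliding only; no surface (two-tangent) semi-landmarks and no
  TPS deformation grids.
* Full Procrustes (unit centroid size) only; no partial-Procrustes option.
* No bootstrap support on trees — they are phenetic similarity summaries,
  not phylogenetic inferences.
* The ANOVA pools non-independent chambers within specimens (see above).
* The simulator does not model hydrostatics, whorl-overlap geometry, or CT
  segmentation artifacts.
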