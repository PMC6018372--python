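# Methods

This note records the models, algorithms, numerical choices and known
limitations of the package. Lengths are micrometers unless stated;
voxel grids are indexed `[x, y, z]` with X the nasal–temporal axis, Y the
inferior–superior axis and Z the anterior–posterior (out-of-plane) axis;
physical position is `index × voxel_size`.

## Synthetic LC phantoms

`lcstrain.synthetic` generates volumes that mimic the appearance of an SHG
z-stack of the posterior lamina cribrosa:

* an elliptical LC interior filled with "beam" texture — white noise
  smoothed with a Gaussian of 1.5 voxels, thresholded at the
  `1 − beam_density` quantile, lightly re-smoothed (0.7 voxels) so the
  intensity field is band limited, and scaled to ~25 000 counts over a
  2 000-count background;
* a peripapillary scleral ring saturating at the 16-bit maximum (65 535);
* a dark CRAV disk and a configurable number of dark spherical patches,
  emulating the vessel shadow and non-correlating regions of real stacks;
* additive Gaussian detector noise (default σ = 300 counts), clipped to
  the 16-bit range.

Defaults are 256×256×64 voxels at 2.5 µm in-plane / 3 µm axial spacing
(the in-plane value follows from a strain-grid spacing of 10 µm every four
pixels; the axial value is the slice spacing of the acquisitions being
emulated), a 560×500 µm LC ellipse, a 200 µm CRAV radius, a 30 µm ring and
beam density 0.35. The texture autocorrelation length is 2–4 voxels, which
subset correlation needs; it is a statistical stand-in, not a structural
model of collagen beams — no optical PSF, photon statistics, tile seams or
depth attenuation are simulated. Fixed seeds give bit-identical volumes.

Ground-truth deformations are analytic: rigid translations, uniform
triaxial stretches about an origin, trivariate polynomial displacement
fields, and a Gaussian posterior-bowing profile. Warping uses backward
mapping — each deformed-grid voxel is pulled back through the inverse
mapping (closed form for affine kinds, fixed-point iteration otherwise,
tolerance 10⁻⁴ µm) and sampled with a cubic spline, so scatter artifacts
are avoided and integer translations are exact; out-of-domain voxels are
filled with background and flagged. Mappings whose Jacobian is not
positive on a 7×7×7 probe grid are rejected.

## Digital volume correlation

`run_fidvc` is a coarse-to-fine iterative subset method:

1. Subset schedule 64→32→16 voxels in-plane (half that axially) with 50 %
   overlap, i.e. node spacing `subset × (1 − overlap)`.
2. Each pass warps the deformed volume by the current displacement
   estimate (sampling it at `x + u_est(x)`, which needs no field
   inversion) and correlates reference subsets against the re-warped
   volume; offsets add to the estimate.
3. Subset correlation is a normalized frequency-domain cross-correlation;
   the integer peak is searched within ±¼ subset with exact ties broken
   toward zero lag, and refined per axis by a 3-point Gaussian
   (log-parabolic) fit. The three samples entering the fit are divided by
   the circular-overlap taper `1 − |lag|/N` per axis — left uncorrected
   the taper pulls the fit toward the integer lag by up to ~0.15 voxels
   for this texture. The quality value is the normalized correlation at
   the peak, likewise overlap-corrected.
4. Subsets with (near-)zero variance, or with no resolvable intensity
   gradient along some axis (gradient variance below 2 % of the subset
   variance — e.g. the axially invariant CRAV wall or saturated ring,
   which cannot constrain `U_Z`), are flagged dead. A local 3×3×3 median
   consistency test then discards vectors that disagree with their
   neighborhood median by more than `1 + 0.1|median|` voxels: low-texture
   subsets straddling high-contrast axially invariant structures can
   otherwise lock confidently onto a wrong offset (an aperture problem).
5. The estimate used for warping the next pass has failed nodes filled
   with the nearest valid vector and is smoothed with a Gaussian of 0.8
   node spacings — without this regularization, node-level correlation
   noise feeds back as spurious local strain and grows with iteration
   count.
6. After the final pass one linearized brightness-constancy step (3×3
   normal equations on the subset gradients) polishes the subvoxel part;
   differential estimates are free of the peak-locking bias that pure
   peak fitting carries.
7. The field is resampled onto a regular output grid, by default every
   4 pixels (10 µm) in-plane and every 2 slices (6 µm) axially.
   Displacements are interpolated from the filled field; any output node
   whose linear stencil touches a failed node is invalid. A run fails
   with `CorrelationFailure` when fewer than 25 % of the *correlatable*
   nodes (those with texture) are valid; structurally blank regions are
   excluded from that denominator, mirroring how dark regions are treated
   as exclusions rather than failures.

Iteration stops when the schedule is exhausted and the mean update drops
below 0.02 voxels, or after `max_iterations` (default 6) passes. Recorded
focal-depth adjustments are added back to `U_Z` as the deformed-minus-
reference offset. The quality threshold defaults to 0.25 normalized
correlation and is configurable.

Measured on seeded phantoms (these numbers are computed by the test suite
and the acceptance script, not assumed): a 10-pixel in-plane translation
and a 3-slice axial translation are recovered to ~0.05 px; a 2 % in-plane
stretch and 5 % axial compression to ~0.05 and ~0.2 percentage points at
full scale. Baseline errors from noise-perturbed duplicate stacks are
~0.005 µm displacement and ~10⁻⁴ strain, well below the 10⁻³ strain
resolution such pipelines carry on real tissue, because the synthetic
duplicates share identical structure and suffer no creep, drift or
re-positioning between acquisitions.

## Strain fields

One full trivariate polynomial of total degree 6 (84 coefficients) is
least-squares fitted per displacement component over all valid nodes, on
a domain normalized to [−1, 1]³ for conditioning; a volumetric fit was
chosen over per-slice fits because the strains are subsequently averaged
through depth. The displacement gradient is evaluated analytically
(chain-ruled through the domain map) and the finite-strain Green-Lagrange
tensor formed — the quadratic term matters here because posterior bowing
slopes of ~0.1 contribute ~0.005 to in-plane strain. `Γ_max` is the
tensorial maximum shear (the Mohr radius), not the engineering shear
(twice that value). Out-of-plane components are computed and stored but
not summarized. Component fields are averaged through Z with their signs;
`E_max` and `Γ_max` are averaged as fields rather than recomputed from
averaged components; magnitudes are taken only at the regional-summary
stage, so a region with balanced positive and negative strain does not
appear unstrained.

Before fitting, the displacement field is masked to the LC: nodes outside
the boundary ellipse or within the CRAV disk are dropped, with a boundary
margin of half the finest subset extent (capped at a quarter of the
annulus width so reduced-scale phantoms retain an analysis band), plus an
axial margin of half the axial subset extent (capped at a quarter of the
node range) because subsets reaching into the first and last image slices
see interpolation-degraded content. Subsets that straddle the masked
boundaries still see some ring or vessel content; the resulting
boundary-layer bias is a fixed-width effect, so it grows as the phantom
shrinks relative to the subset — stretch-recovery bounds in the tests are
proportionally wider on the 96-voxel phantoms than at full scale.

For spatially uniform stretches, the reported recovery is the
least-squares slope of `U_X` versus X (or `U_Z` versus Z) over valid
nodes, which is the minimum-variance estimator of a constant gradient;
the polynomial gradient is reported alongside.

## Regional geometry

The LC opening ellipse is fitted to boundary points by the direct
least-squares conic method (via `skimage.measure.EllipseModel`), with
degenerate fits rejected. Segmentation labels every node of the 2D strain
grid: background outside the ellipse; CRAV within 200 µm of the CRAV
center; otherwise central or peripheral according to the mid-radial
boundary, computed per ray as `(crav_radius + ρ_ellipse(θ))/2` with
`ρ_ellipse(θ)` the ray's ellipse-intersection distance (a per-ray
construction rather than a scaled ellipse, matching the definition of the
mid-radial distance literally); quadrants are assigned about the CRAV
center with bisectors at 45° and 135°. Which sector is nasal depends on
eye laterality (nasal = +X for right eyes; configurable). Regional
summaries are means of |strain| over valid nodes; CRAV and background
never contribute, and regions with no valid nodes are omitted rather than
imputed.

## Thickness change and error analyses

Thickness change between same-pressure volumes of the two treatment
states is the per-column difference between mean `U_Z` in the
posterior-most and anterior-most bands of the imaged depth
(`band_fraction` = 0.1 by default; band averages rather than single
slices, for noise robustness). Any rigid axial motion cancels in the
difference. For a uniform axial stretch λ the map equals
`(λ−1) × (posterior-band centroid − anterior-band centroid)` exactly,
which the tests verify.

The baseline error analysis correlates two nominally identical stacks and
reports mean |U| per axis and mean |E| per in-plane component; the
applied-deformation analysis warps an acquired stack by each canonical
case and compares recovered to applied values. Both restrict strain
summaries to the LC interior when the volume metadata records the
boundary, as the main analysis does.

## Statistics

The Wilcoxon signed-rank test is exact: zero differences are dropped,
tied magnitudes mid-ranked, and the null distribution of the positive-rank
sum built by the generating-function recursion over doubled ranks —
identical to enumerating all 2ⁿ sign assignments, which the tests do
directly as an oracle. The two-sided p is twice the smaller tail, capped
at 1. At n = 6 the smallest attainable two-sided p is 2/64 = 0.03125,
which is why the exact test (and not a normal approximation) is required
at this sample size. Enumeration is restricted to n ≤ 20.

Regional comparisons use Gaussian GEE linear models (statsmodels) with an
exchangeable working correlation — all regional measures of one eye share
a single correlation — robust sandwich covariance, and eyes as independent
clusters. Four models are provided per strain measure and pressure pair:
intercept-only on the paired change, change versus baseline magnitude,
change versus central/peripheral location, and change versus age group.
Under an independence working structure the estimates coincide with
ordinary least squares, and the robust errors equal the closed-form
cluster sandwich; both identities are tested. Significance is two-sided
at 0.05 with no multiplicity correction.

## The synthetic benchmark experiment

`run_inflation_analysis` builds a cohort of phantom eyes (default six,
three per age group). Each eye's pressure-induced deformation for the
5→45 mm Hg step combines posterior bowing (a paraboloid cap of 6–12 µm),
anisotropic in-plane stretch (1.2–2.0 % along X, 1.8–2.8 % along Y), a
simple shear of 1.0–2.0 % and a 1–2 % axial compression — magnitudes in
the range such inflation experiments report, with shear and stretch
anisotropy included so the maximum-shear measure carries genuine signal.
The 5→10 mm Hg deformation is the same field at 40 % amplitude. Both
treatment states image the same structure with independent noise; the
enzyme-state deformation is the buffer-state one with every amplitude
reduced by the configured fraction (default 20 %). Boundary points for the
ellipse fit are noisy samples of the true ellipse (σ = 2 µm, 40 points),
emulating manual picking.

The cohort runs at 128×128×32 voxels per eye (320×320×96 µm) with
proportionally scaled geometry (110×95 µm semi-axes, 40 µm CRAV), which
keeps a six-eye, two-state, two-pressure experiment around two minutes on
one CPU; the test suite uses 96- and 64-voxel variants for faster unit
runs. With the default 20 % reduction, all four specimen-averaged strain
measures decrease in all six eyes and every exact signed-rank p equals
0.03125; with no reduction, regional changes sit at the correlation noise
floor (mean |change| below 2×10⁻³ strain). Passing these experiments shows
the chain recovers constructed effects of realistic size under phantom
conditions; it does not certify performance on real SHG tissue, where
creep, bleaching, repositioning error and depth-dependent contrast add
error sources the phantom does not contain.

## Known limitations

* The phantom's beam texture is statistical; morphology-dependent biases
  of real collagen networks are not represented.
* Correlation accuracy along Z is poorer than in-plane (coarser sampling,
  anisotropic voxels); axial-compression recovery carries the widest
  tolerance of the canonical cases.
* The sixth-order volumetric polynomial is a global smoother; it cannot
  follow strain features sharper than the node spacing and oscillates if
  the valid-node hull becomes very thin (hence the capped masking
  margins).
* GEE small-sample behavior at six clusters relies on the usual sandwich
  asymptotics, as is standard practice for this design.
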