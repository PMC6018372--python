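# lcstrain

Displacement and strain analysis for ex vivo inflation imaging of the
human lamina cribrosa (LC) — the porous collagenous plate in the optic
nerve head through which retinal ganglion cell axons exit the eye. The
package is written for ocular biomechanics groups that image the posterior
LC with second-harmonic-generation (SHG) microscopy at several intraocular
pressures (e.g. 5, 10 and 45 mm Hg) and want the full measurement chain in
one tested library:

* **Digital volume correlation (DVC).** A fast-Fourier, iterative,
  coarse-to-fine subset correlation recovers the 3D displacement field
  `U_X, U_Y, U_Z` between a reference z-stack and a deformed z-stack, with
  subvoxel peak refinement, a local median consistency test, quality
  masking of dark non-correlating regions, and a differential
  (brightness-constancy) subvoxel polish.
* **Strain.** Each displacement component is smoothed with a trivariate
  sixth-order polynomial; the Green-Lagrange tensor is evaluated from its
  analytic gradient, `E = ½(∇u + ∇uᵀ + ∇uᵀ∇u)`, and the in-plane measures
  `E_XX`, `E_YY`, `E_XY`, the maximum principal strain
  `E_max = (E_XX+E_YY)/2 + √(((E_XX−E_YY)/2)² + E_XY²)` and the maximum
  shear strain `Γ_max = √(((E_XX−E_YY)/2)² + E_XY²)` are reported, averaged
  through depth at each (X, Y).
* **Regional geometry.** A direct least-squares ellipse fit to manually
  picked LC/sclera boundary points; a 200 µm-radius exclusion disk around
  the central retinal artery and vein (CRAV); central/peripheral bands split
  at the mid-radial distance per ray; superior/inferior/nasal/temporal
  quadrants at the 45°/135° bisectors — eight analysis regions in all.
* **Thickness change and error analyses.** Depth-change maps between
  treatment states (posterior-band minus anterior-band axial motion),
  baseline errors from duplicate acquisitions, and recovery of numerically
  applied deformations (10 px in-plane translation, 3 slices axially,
  2 % in-plane stretch, 5 % axial compression).
* **Statistics.** Exact (fully enumerated) Wilcoxon signed-rank tests for
  paired specimen-level comparisons, and Gaussian GEE linear models with an
  exchangeable (compound-symmetry) working correlation and robust sandwich
  errors for regional comparisons, clustering by eye.
* **Synthetic phantoms.** SHG-like LC volumes (bright saturated
  peripapillary ring, textured elliptical LC, dark CRAV and dark patches)
  warped by analytic deformation fields, so every stage of the pipeline can
  be validated against known ground truth.

## Worked example

```python
import numpy as np
from lcstrain import (
    PhantomSpec, GroundTruthDeformation, generate_phantom, warp_volume,
    run_fidvc, fit_polynomial_field, compute_strain_field, average_through_z,
)

spec = PhantomSpec(grid_shape=(128, 128, 32), semi_axes=(110, 95),
                   crav_radius=40, pps_ring_width=20, seed=3)
vol = generate_phantom(spec)

# stretch the phantom 2% in-plane about its center and correlate
center = tuple((n - 1) * d / 2 for n, d in zip(vol.shape, vol.voxel_size))
stretch = GroundTruthDeformation(kind="uniform_strain",
                                 stretch=(1.02, 1.02, 1.0), origin=center)
field = run_fidvc(vol, warp_volume(vol, stretch))
fit = fit_polynomial_field(field)           # degree-6 smoothing
strain = compute_strain_field(fit, field)
planar = average_through_z(strain)
print("median E_XX:", np.nanmedian(planar.maps["E_XX"]))
```

This prints `median E_XX: 0.0212...` — the finite-strain value for a 2 %
stretch is ½(1.02² − 1) = 0.0202, and the recovered median lands within
the pipeline's ±0.002 strain resolution of it after the whole
correlation + polynomial chain.

A six-eye synthetic before/after-treatment experiment, in which the
post-treatment deformation amplitude is reduced by 20 %:

```python
from lcstrain import RunConfig, run_inflation_analysis

bundle = run_inflation_analysis(RunConfig(seed=17, pressure_pairs=("5-45",)))
print(bundle.wilcoxon["E_max@5-45"].p_value)   # 0.03125
```

All four strain measures decrease in every synthetic eye, and the exact
two-sided signed-rank p at n = 6 is 2/2⁶ = 0.03125 (printed as P = 0.03) —
the smallest value attainable with six pairs.

A command-line interface mirrors the library stages
(`lcstrain phantom | dvc | strain | regions | thickness | errors | stats | all`).

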