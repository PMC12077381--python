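# Methods

This note documents the models, numerical choices and calibrations
behind `eyesim`, and what the test suite does and does not establish.

## The eye model

A pseudophakic eye is a sequential stack along the optical axis z
(millimetres from the anterior corneal vertex):

| element | geometry | following medium (555 nm) |
|---|---|---|
| anterior cornea | conicoid R = 7.8 mm, Q solved (below); optionally + Zernike sag | stroma, n = 1.3771 |
| posterior cornea | sphere R = 6.5 mm, fixed in all conditions | aqueous, n = 1.3374 |
| IOL anterior | conicoid (+ central wavefront-shaping zone for the EDOF lens) | lens, n = 1.55 |
| IOL posterior | conicoid | vitreous, n = 1.3360 |
| retina | plane, position solved per eye | — |

Central corneal thickness is 0.55 mm (thinned after myopic LASIK), the
IOL sits 4.5 mm behind the posterior cornea (anterior chamber depth,
configurable 3.2–4.5 mm), and the aperture stop (iris) is 0.5 mm in
front of the IOL.  Aqueous and vitreous indices are the Le Grand
theoretical-eye values; the lens index (1.55) and central thickness
(0.6 mm) are typical hydrophobic-acrylic figures, configurable.

**Aperture convention.**  The working "pupil diameter" (3.0 or 5.0 mm)
is the entrance beam diameter at the cornea, the usual system-aperture
definition in sequential design software.  The wavefront is sampled on
the entrance grid; the iris diameter is derived from the working pupil
by the paraxial beam scale and is not an independent ray clipper
(surface semi-apertures still vignette).

## Ray tracing and wavefront

Rays from a distant axial object are traced exactly: surface
intersection by damped Newton iteration on the sag equation (tolerance
1e-10 mm, NaN out-of-domain points flagged as vignetted), refraction
by the vector form of Snell's law (residual < 1e-12, tested), and OPL
accumulated as Σ nᵢ·pathᵢ.  Zernike sag terms and their gradients are
evaluated from exact Cartesian power series, which keeps the gradient
finite at the vertex (polar forms are singular there for coma terms).

The OPD map references each ray to the chief ray on a sphere centred
at the chief ray's retinal intersection with vertex at the paraxial
exit pupil; positive OPD = phase advance.  The 256×256 square grid is
masked to the pupil disk, with the pupil centre on a grid sample
(FFT-centred, so index i and 2·(N//2)−i are mirror samples).  A
single-surface model with the stigmatic conic Q = −(n₁/n₂)² reproduces
equal OPLs to machine precision, validating trace and OPD jointly.

**Retinal focus.**  The retina is placed per eye at the plane of
minimum RMS transverse spot radius of a pupil-filling bundle.  Because
each ray's transverse position is linear in z, that RMS is exactly
quadratic in z and the minimiser is closed-form — no iterative search.

## Corneal models

The virgin anterior asphericity is solved (Brent, xtol 1e-5) so the
isolated anterior surface traced into n = 1.3771 carries
c(4,0) = +0.280 μm over a 6.0-mm pupil; this lands at Q ≈ −0.116,
matching the average-eye corneal standard (power ≈ 43 D keratometric).

Post-LASIK corneas change only the anterior surface:

1. radius from the keratometric power change
   (1.3391−1)/R_new = (1.3391−1)/7.8 ∓ M (− myopic, + hyperopic);
2. conic constant re-solved so the single-surface c(4,0)
   (n = 1.3391, 6.5-mm pupil) equals the virgin baseline plus the
   regression delta ΔSA = −0.223 + 0.169·M (myopic) or
   −0.050 − 0.277·M (hyperopic), M the positive correction magnitude —
   the sign reading that reproduces the published per-condition table;
3. myopic thickness loss by the Munnerlyn depth t = S²·M/3
   (12 μm/D at the 6-mm zone); hyperopic thickness unchanged.

The high-myopia solve needs oblate conics (Q up to ≈ +7); the solver
bracket is clamped away from the conic domain boundary
(1+Q)r² < R².  Coma is induced by adding a c(3,1) sag term to the
anterior surface, rescaled by fixed-point iteration (≤10 steps) until
the surface's wavefront coma is 0.5 ± 0.005 μm at 6.5 mm; the initial
guess uses the thin-phase relation sag ≈ W/(n−1).

## IOL models and their calibrations

The commercial lens geometries are proprietary, so both lenses are
parameterized stand-ins pinned to published data:

- **Monofocal:** 22 D equi-biconvex (radii solved for the in-situ
  paraxial power between aqueous and vitreous), anterior conic solved
  for a target isolated SA at a 6-mm aperture.  A catalogue-style
  isolated SA of −0.20 μm leaves the model eye with ≈ +0.09 μm c(4,0)
  at a 5-mm pupil — far more residual aberration than the reported
  near-diffraction-limited virgin-eye performance.  The default is
  therefore the "null-total-eye-SA"-style design: target_sa = −0.411 μm,
  calibrated once so the virgin eye's 5-mm Visual Strehl equals the
  reported 0.89, then frozen.  The virgin 3-mm VS (≈ 1.0) and DOF
  (1.39 D) are untouched by-products, not calibration targets.
- **EDOF:** the monofocal plus a central wavefront-shaping zone on the
  anterior surface, sag A·(1−(r/a)²)^k for r < a = 1.10 mm, zero
  outside, value- and slope-continuous at the edge (no light
  splitting).  A = 2.23 μm and k = 4 are calibrated once so the virgin
  3-mm depth of focus equals the reported 2.50 D, then frozen
  (`DEFAULT_EDOF_PROFILE`).  With k = 3 the through-focus curve
  degrades before reaching 2.50 D; k = 4 reaches it with a contiguous
  super-threshold interval.  Because the zone covers ~88% of the beam
  radius at a 3-mm pupil but only ~53% at 5 mm, the pupil dependence
  of the EDOF effect emerges from geometry alone.

All EDOF-magnitude results are therefore calibrated reproductions, not
independent predictions; only their trends (EDOF vs monofocal, pupil
dependence, LASIK sensitivity) are meaningful comparisons.

## Image quality

Pupil function exp(i2πW/λ) on the masked grid, zero-padded 4× (PSF
sampling λ/(4D) ≈ 0.16′ at 3 mm; field N·λ/D ≥ 30′ enforced, and VS is
converged to < 0.005 between 4× and 8× padding).  MTF = |FFT(PSF)|/DC;
the diffraction-limited MTF matches the closed form
(2/π)(acos ν − ν√(1−ν²)) to < 0.01.

**Visual Strehl** uses a radially symmetric neural contrast
sensitivity S(f) = f^0.8·exp(−0.10·f) (peak 8 c/deg, negligible by
60 c/deg, S(0) = 0).  The exponent/decay pair is a frozen-configuration
calibration: the decay was set so the essentially diffraction-limited
virgin monofocal eye at 3 mm reproduces the reported 1.40 D depth of
focus, since the VS literature's "average neural CSF" is not uniquely
parameterized and the DOF of a well-corrected eye is set almost
entirely by this weighting.  VS-dependent checks carry a ±0.03
tolerance for exactly this freedom.

**Through-focus** curves add Zernike defocus c20 = D·r_p²/(4√3)
analytically to the traced far-focus wavefront, 81 samples over
[−4, +4] D.  **Depth of focus** is the width of the contiguous
VS > 0.12 interval containing the curve maximum, crossings by linear
interpolation (the interval-width convention reproduces the virgin-eye
data best; a rectangular test curve shows the ≤ one-sample-per-side
interpolation bias).

## Halos

The retinal image of a 2-arcmin pinhole is the pinhole disk convolved
with the eye's PSF (FFT convolution, anti-aliased disk edge), and the
halo metric is the diameter about the image centroid enclosing 50% of
the energy — d/√2 ≈ 1.414′ in the point-PSF limit, exact to < 0.5%
here.

The PSF used for halos is the **geometric ray-density PSF** (retinal
ray-intersection histogram in visual-angle units, 0.1′ bins): halos
are a large-scale light-spread phenomenon, and for a well-corrected
eye the geometric PSF collapses to a sub-pixel point so the metric
sits at the bare-pinhole limit — which is where the reported
monofocal values sit at *both* pupils.  A resolved diffraction PSF
cannot produce that: the exact Airy⊛disk value for a 3-mm pupil is
1.57′ (verified against an independent Bessel-function quadrature
oracle).  The Fourier-optics `compute_psf` remains available to
`halo_metric` for diffractive PSFs.  In phase-plate mode no halo is
reported (traced rays do not see the analytic phase screen).

## Phase-plate mode

Instead of rebuilding corneal geometry, the LASIK deltas (ΔSA, coma at
the 6.5-mm definition pupil) can be injected as a Zernike phase screen
at the pupil of the virgin eye.  Coefficients are rescaled to the
working pupil numerically (sample-and-refit aperture scaling, exact
for in-basis wavefronts); the defocus produced by the rescaling is
replaced by the c(2,0) that minimises the mean-square OPD gradient —
the wavefront-side analogue of the min-spot retinal refocus applied to
the full-surface models.  Over the 40 post-LASIK cells the two modes
agree to mean |ΔVS| ≈ 0.02 and mean |ΔDOF| ≈ 0.05 D, well inside the
0.1 / 0.3 D envelope expected of this simplification.

## The condition grid

`run_grid` crosses {virgin + 5 LASIK corrections} × {coma off/on} ×
{monofocal, EDOF} × {3.0, 5.0 mm} = 48 deterministic conditions
(bit-identical on rerun).  Post-LASIK summaries (mean ± SD of DOF and
VS per IOL at 3 mm) aggregate the ten post-LASIK cells; the EDOF-vs-
monofocal DOF comparison uses a paired Wilcoxon signed-rank test over
those cells.  Grid runs default to a 128×128 mesh (the VS convergence
guard shows < 0.005 change vs finer sampling); single-eye headline
metrics use 256×256.

## Analytic fixtures

`eyesim.fixtures` registers seven generators whose expected outputs
are closed-form and computed inside the fixture, never by the
pipeline: pure defocus (c20 = D·r_p²/(4√3)), single Zernike modes,
the Airy pattern (first zero 1.22λ/d), the uniform-disk pinhole image
(50% energy at d/√2), the stigmatic conicoid (equal OPLs), an
aberration-free single-surface eye (Strehl = VS = 1), and random
small-RMS wavefronts in the Maréchal regime
(Strehl ≈ exp(−(2πσ/λ)²), 2%).  Random draws use the fixed seed
20231101.  These cases emulate the pipeline's intermediate products,
not real eyes: passing them shows the numerics are right, not that the
parameterized lens stand-ins equal the proprietary geometries.

## Known limitations

- Monochromatic 555 nm; no chromatic aberration or Stiles–Crawford
  apodization.
- No IOL tilt/decentration, pupil decentration or off-axis fovea.
- The EDOF central zone is a smooth two-parameter bump calibrated to
  one datum; absolute EDOF far-VS and halo magnitudes inherit that
  uncertainty (trend comparisons are the supported use).
- Post-LASIK corneas are aspheric fits, not measured topographies; the
  induced-aberration regressions reflect one early-2000s laser
  platform.
- The neural CSF is a calibrated two-parameter family; absolute VS
  values carry the corresponding ±0.03-level uncertainty.
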