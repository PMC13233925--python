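# Methods

`midgetmosaic` synthesizes image-computable mosaics of linear
spatio-chromatic ON-center midget retinal ganglion cell (mRGC) receptive
fields across the human retina and simulates standard physiology and
psychophysics experiments on them. This note records the model, its
assumptions, the numerical choices, and what the synthetic-data tests do and
do not establish.

## Coordinate conventions and eccentricity

All positions are visual-field degrees of a right eye, origin at the foveal
center, x > 0 temporal. Angular eccentricity maps to linear retinal
eccentricity through a schematic-eye cubic,
`mm = 0.268 r + 3.427e-4 r^2 - 8.3309e-6 r^3` (r in deg), inverted exactly
by Newton iteration. Macaque-equivalent angles assume identical linear
eccentricities across species and a constant 0.221 mm/deg macaque
magnification.

## Density models (stage 1A/1B)

Cell densities are specified along the four principal meridians and
interpolated bilinearly in polar form (radius along the two flanking
meridians, then linearly in polar angle), which is smooth through the fovea.

* **Midget RGC RF density** uses the parametric meridian formula of Watson's
  human-retina synthesis: `d(r) = 29609.2 (1 + r/41.03)^-1 [a (1 + r/r2)^-2 +
  (1-a) exp(-r/re)]` cells/deg^2, with per-meridian `(a, r2, re)` stored in a
  versioned JSON config. The ON-center mosaic is half of the total at every
  point. These constants are a transcription of a published fit; the paper
  this package reimplements does not print them, so the config treats them as
  replaceable parameters.
* **Cone density** uses the same two-term basis expressed against linear
  eccentricity in mm with a foveal peak of 288,000 cones/mm^2 (high end of
  the human range) and coefficients chosen to approximate published human
  profiles (about 17k/mm^2 at 1.75 mm, 9k at 3.4 mm, 6-7k at 5.6 mm
  temporal). This is an explicit approximation: no closed form exists in the
  primary literature.

A consequence of combining a 288k cone peak with the midget formula anchored
at the average cone peak is a foveal cone-to-ON-midget ratio of about 1.4
rather than 1.0, so a minority of foveal RF centers receive two cones rather
than one. Wiring invariants that presume strict single-cone foveal centers
are therefore validated on fixtures with matched densities.

## Lattice synthesis (stage 1C)

Lattices are seeded from a hexagonal grid warped radially about the fovea so
its local density matches the angular average of the target map (random
global phase, 10% positional jitter, both seeded), thinned against the full
2D map where the map is non-radial, and count-adjusted to the rounded map
integral — the returned cell count therefore equals the density integral by
construction. Relaxation is density-weighted Lloyd iteration: each point
moves toward the centroid of its Voronoi cell weighted by the squared target
density (a centroidal tessellation under weight w yields point density
proportional to sqrt(w) in 2D), with the step annealed from 0.5 to 0.05.

We replaced the more common rejection-sampled initialization because Lloyd
relaxation from random seeds freezes grain boundaries at a mean
nearest-neighbor distance about 7% below the hexagonal spacing; the warped
hexagonal seed reaches 1-2%. The default iteration budget is 150: with a
near-crystalline seed, local geometry converges well before that at the
mosaic sizes used here, and counts do not depend on iteration depth at all.
Synthesis runs on the region inflated by three local spacings and is cropped,
so edge rarefaction never reaches the returned points.

Cone types are assigned after synthesis: S cones form a semi-regular sparse
sublattice (greedy with a minimum separation of half the expected S spacing,
7% fraction, none within a 0.15-deg foveal radius); remaining cones are L or
M i.i.d. at a 2:1 ratio. These are conventional values, exposed in the API,
not fitted quantities. Apertures are Gaussian with diameter 0.79 x local
spacing and sigma = 0.204 x diameter.

## Center wiring (stage 2)

* **2A** - nearest-center seeding of L/M cones, BFS chain-shifts to populate
  empty centers (a relocation per hop along the center-neighbor graph), then
  local load balancing: a center donates its most peripheral cone to a
  neighbor at least two cones lighter whenever the move shrinks the total
  within-center spread about cone centroids. Every L/M cone ends in exactly
  one center; every center is non-empty; S cones are never connected.
* **2B** - greedy pairwise swaps of differently-typed cones between
  Delaunay-neighboring centers, accepted when they improve
  `J = phi (-spread) + (1 - phi) purity` (purity = majority-type fraction,
  spread normalized by local spacing squared), at most 20 passes. phi = 1
  maximizes compactness (the default), phi = 0 spectral purity. The greedy
  frontier is approximate: sweeping phi produces no materially dominated
  settings, but purity differences below ~0.01 are not resolved.
* **2C** - weights become `exp[-0.5 (r/sigma_k)^alpha]` about the center
  centroid, with alpha = 10 below 7 deg, 2 beyond 15 deg, and a half-cosine
  ramp between (the endpoints and monotonicity are the constrained
  features). `sigma_k = max(1.19 x max member distance, 0.4 x cone spacing)`:
  the exponent-10 profile passes 0.99 at 0.84 sigma and 0.01 at 1.23 sigma,
  so this keeps all members on the flat top while cones of compact
  neighboring centers stay below 0.01; at exponent 2 the same sigma shares
  cones across neighbors at weight >= 0.1. A fixed additive margin (an
  alternative we tried) leaks the flat top onto neighbors and inflates
  center weight sums severalfold. Weights below 0.001 are pruned and never
  renormalized; the response rule divides by the summed center weight.
  Elongated centers (rare, from irregular partitions) can still overlap
  mildly in the exponent-10 zone.

All tie-breaks go to the lowest cell index; stage 2 is deterministic.

## Front end: display, optics, cone excitations

Stimuli are specified in cone-contrast units on a three-primary display
(smooth CRT-like Gaussian primaries, background chromaticity (0.30, 0.32) at
100 cd/m^2, effectively continuous channel resolution). CIE 1931 color
matching functions come from the standard piecewise-Gaussian analytic fits
and LMS fundamentals from the Hunt-Pointer-Estevez transform, fixed across
eccentricity (foveal 2-deg values; eccentricity-varying inert pigments are
out of scope). Cone-contrast specs are converted to primary modulations by
inverting the primaries-by-fundamentals matrix at the background; requests
that drive a primary past its range raise a gamut error (the maximum
L-minus-M contrast at this background is about 0.086).

The optics model is pluggable with two modes. `diffraction_limited` is the
Airy transfer of a circular pupil (3 mm default). `simplified_physiological`
multiplies that by (a) defocus from a reduced-eye longitudinal chromatic
aberration formula (`1.68524 - 0.63346/(lambda_um - 0.2141)` diopters,
zeroed at 550 nm) plus any refractive offset and residual correction,
applied as the signed thin-lens transfer `2 J1(pi beta f)/(pi beta f)` for a
blur disk `beta = defocus x pupil` — the sign matters: frequencies beyond
its first zero are phase-reversed, which is how chromatic aberration can
invert the retinal phase of one component of a red-green grating; and (b) an
elongated Gaussian whose sigmas grow linearly with eccentricity
(0.004 + 0.0025 e and 0.004 + 0.0010 e deg, major axis radial), standing in
for peripheral aberrations. Every monochromatic PSF integrates to one.
A bracketed search over residual defocus maximizes the Strehl ratio at
550 nm before transfer-function measurements.

Gratings and uniform fields propagate analytically: each wavelength's
sinusoid is scaled by the signed OTF, summed across the spectrum per cone
class, and attenuated by the Gaussian cone-aperture transfer. White-noise
checkerboards use a sparse cone-by-check coupling matrix built from erf
masses of the aperture convolved with a Gaussian equivalent of the PSF
(matched at the half-power frequency). Both paths are validated against
brute-force pixel rendering and per-wavelength FFT convolution in the test
suite (0.5% agreement for gratings).

## Responses and probes

`R(k,t) = [sum_i Pc(i,k) C(i,t) - sum_j Ps(j,k) C(j,t)] / sum_i Pc(i,k)`,
instantaneous and linear; drift is represented as 16 static phase steps per
cycle and response amplitude is the fundamental-frequency sinusoid fit
(exact DFT bin for uniform phases). Transfer functions measured this way on
cells with exact Gaussian center/surround weights reproduce the
Difference-of-Gaussians model
`DoG(w) = Kc Rc^2 exp(-(pi Rc w)^2) - Ks Rs^2 exp(-(pi Rs w)^2)` to 1%.
White-noise receptive-field maps are the frame-by-frame cross-correlation of
responses with the check sequence; the noise floor is estimated by a seeded
temporal shuffle. Gaussian-ellipse fits to the increment-excitatory lobe
report `diameter = 2 sqrt(sigma_minor sigma_major)`.

## Surround wiring (stage 3)

Surround pooling is the H1-like double exponential
`W_s(r) = K_wide exp(-r/R_wide) + K_narrow exp(-r/R_narrow)`, evaluated on
the L/M cones about the center centroid and pruned below 0.005 x the peak
center weight. Its four parameters are optimized per representative cell so
that the forward-simulated transfer function (achromatic drifting gratings
through the chosen optics) is well fit by a DoG whose shape ratios Rs/Rc and
(Ks/Kc)(Rs/Rc)^2 lie within a multiplicative band (default x/1.2) of target
means. Defaults are `Rs/Rc = 6.7`, integrated ratio 0.55 with variance 0.04;
these stand in for population summaries that the primary sources report only
graphically, and every quantitative test constructs self-consistent
synthetic targets instead of leaning on them.

The optimizer is Nelder-Mead in a log-sigmoid transform of the H1 parameter
box (bounds scaled per cell from its spacing, extent and target ratios),
with a deterministic central start, optional caller-provided starts, and
seeded restarts. The inner constrained DoG fit is a bounded least-squares
with warm starting across objective evaluations. Two numerical choices
matter:

* The fit residual alone is degenerate — any profile whose transfer
  function is DoG-shaped with in-band ratios scores near zero — so the
  objective adds a squared-log pull of the fitted ratios toward the target
  means (weight 1.0). This selects, among equally DoG-like solutions, the
  one matching the population trends, and makes self-consistent recovery
  identifiable (2% transfer-function recovery in the tests).
* The norm is RMS over the log-spaced frequency list, normalized by the
  transfer-function peak.
* Because response amplitude is unsigned (no rectification is modeled), a
  surround far stronger than the center can masquerade as a DoG-shaped
  lowpass cell. ON cells keep a net-positive integrated response, so the
  objective penalizes integrated surround/center weight ratios above 0.95;
  the same cap is applied when interpolated profiles overshoot on individual
  cells and inside the variance-matching jitter. This enforces the
  integrated-ratio < 1 invariant everywhere.

Optimized profiles are derived on a sparse eccentricity grid (one node per
2 deg of span, minimum 1), per RF-center cone numerosity and per L/M
dominance, and interpolated to every cell from its 3 nearest nodes with
inverse-distance spatial weights and (L-fraction, M-fraction) spectral
weights; missing numerosities fall back to the nearest available with a
warning. Finally a seeded per-cell scalar on all surround weights matches
the population variance of the integrated surround/center ratio while
preserving its mean (target variance zero returns the input untouched); the
scalar leaves Rs/Rc invariant because it multiplies surround strength only.

The DoG-inference caveat reproduced in the tests: DoG fits to retinal-space
transfer functions of double-exponential-surround cells are good (residual
under 5% of peak) while the inferred Gaussian surround is more diffuse with
a weaker peak-to-integral concentration than the true pooling.

## Computational observer

Responses (cone contrasts or mRGC responses over space and phase) receive
i.i.d. zero-mean Gaussian noise; a two-interval trial is decided by the
larger inner product with the noise-free template difference. The noise
standard deviation is a free scalar, so only relative/qualitative
sensitivity statements are meaningful; observer-level analyses calibrate it
to a fixed fraction of a reference template norm. Threshold is the 80.6%
crossing of a cumulative-Gaussian psychometric function fitted in log
contrast to a seeded constant-stimulus sweep, refined by a second sweep
concentrated (x/1.6) around the first estimate — the log-Gaussian shape is
only locally exact, and the refinement keeps the bias of the recovered
criterion point under ~3% against the analytic matched-filter curve.
Contrast sensitivity is the reciprocal threshold; chromatic threshold
contours sample directions in the L/M cone-contrast plane with a temporally
modulated uniform field, normalize to the M-direction threshold, and fit an
ellipse by linear least squares on the quadratic form.

## What the synthetic tests do and do not show

The generator-based fixtures (hexagonal cone patches with controlled
density ratios, explicit connectivities, exact Gaussian or
double-exponential pooling) establish that every pipeline stage satisfies
its stated contracts and reproduces closed-form oracles. They emulate the
geometry and statistics of the modeled retina, not its biology: there are no
fixational eye movements, phototransduction dynamics, spiking, or
physiological noise, the fundamentals do not vary with eccentricity, and the
optics is a parametric stand-in rather than measured wavefronts. Passing
tests therefore certify the synthesis and simulation machinery, and the
qualitative observer results (low-frequency attenuation at the mRGC stage,
red-green advantage at low frequencies, 45-deg elongation of the foveal
chromatic contour) follow from the wiring, not from fitted psychophysics.

## Known limitations

* The midget and cone density coefficients are transcriptions/approximations
  of published fits; absolute cell counts of synthesized mosaics inherit
  their uncertainty (the foveal-region counts run ~20-30% below the
  reference mosaics of the source material, while peripheral counts and the
  cone peak agree within a few percent).
* The greedy 2B refinement resolves the compactness/purity frontier only to
  ~0.01 in purity.
* Exponent-10 non-overlap is guaranteed for compact centers; irregular
  multi-cone centers can overlap mildly below 7 deg.
* OFF mosaics, S-cone center input, temporal dynamics, and measured
  wavefront optics are out of scope.
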