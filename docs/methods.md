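# Methods

## Model

The renderer solves the radiative transfer equation in a participating
medium extended with a single-inelastic fluorescence term.  A camera-side
path at emission wavelength λ_m undergoes free flights and elastic
scattering events at coefficients evaluated at λ_m; it contributes radiance
only through a fluorescence vertex, where the path couples to the light
source at an excitation wavelength λ_x.  Self-emission of the medium,
secondary fluorescence, quenching, photobleaching and saturation are outside
the model.

Per voxel label the medium carries a scattering spectrum σ_s(λ) (mm⁻¹), a
non-fluorescent absorption spectrum σ_a(λ), a Henyey–Greenstein anisotropy
g, and optionally a dye solution.  The dye adds the fluorescence absorption

    μ_a^f(λ) = ln(10) · ε · C · f̂_x(λ)    [mm⁻¹, ε in cm⁻¹M⁻¹, C in mol/L]

with f̂_x peak-normalized (ε is defined at the excitation maximum, so the
spectrum carries relative shape only).  Total absorption is
μ_a = σ_a + μ_a^f and total extinction σ_t = σ_s + μ_a; the fluorescence
fraction μ_a^f/μ_a therefore never exceeds one.  The fluorescence
probability factorizes into the photon absorption probability
p_x(λ_x) = φ μ_a^f(λ_x)/μ_a(λ_x) and the discrete emission mass
p_m(λ_m) = f_m(λ_m)Δλ / ∫f_m, computed with the rectangle rule on the common
1 nm grid so that Σ p_m = 1 exactly.

Packaged fluorophores are Gaussian stand-ins for the measured Alexa Fluor
350/488/568/633 spectra (60 nm FWHM, truncated at 10⁻⁶ of peak so the
spectra have finite support like measured curves; measured two-column CSVs
can be dropped in instead).  Tabulated constants: λ_x/λ_m maxima
346/442, 495/519, 578/603, 632/647 nm; φ = 0.02, 0.92, 0.69, 0.90;
ε = 19 000, 73 000, 88 000, 159 000 cm⁻¹M⁻¹; molecular weights 410–1200 Da
(recorded for completeness, used in no computation).

## Estimator

Free flights are sampled with woodcock (null-collision) tracking against a
per-wavelength majorant μ̄(λ) = max over materials of σ_t(λ); tentative
collisions are accepted with probability σ_t/μ̄, which is unbiased for
arbitrary label mixtures.  Elastic scattering importance-samples the
Henyey–Greenstein phase function (weight 1); the walk continues with the
single-scattering albedo σ_s/σ_t as survival probability.  Transmittance
along light connections uses unbiased ratio tracking (the public
`transmittance` helper switches to the Beer–Lambert closed form on
homogeneous grids).

Two couplings of the fluorescence source are implemented:

* **`method="nee"` (default).**  At every real collision in a dye-bearing
  voxel the fluorescence source term is gathered deterministically with the
  collision estimator: the contribution is
  `w · φ · p_m(λ_m) · μ_a^f(λ_x) · f_p · L_e · G · τ(λ_x) · A / σ_t(λ_m)`,
  with a light point sampled uniformly on the panel (pdf 1/A), G the
  geometry term (inverse square times the light-side cosine), τ the
  ratio-tracking transmittance at λ_x, and f_p the phase function evaluated
  between the light direction and the camera-side ray.  Each gathered
  contribution is a complete path with exactly one inelastic vertex.
* **`method="analog"`.**  The event taxonomy is sampled literally: a
  collision is elastic with probability σ_s/σ_t, otherwise an absorption
  that is fluorescent with probability μ_a^f(λ_m)/μ_a(λ_m) (only possible
  in dye-bearing voxels); the fluorescence vertex adds the same light
  connection reweighted by the selection probability and terminates the
  path.  This estimator has the same expectation wherever
  f_x(λ_m) > 0, but its selection probability is proportional to the
  excitation spectrum evaluated *in the emission band*: for a dye whose
  Stokes shift exceeds the band overlap (AF350: 346 → 442 nm) it cannot
  reach most of the emission band at all, and where the overlap is small
  its variance grows as 1/f_x(λ_m).  The NEE gather is therefore the
  default; the two modes are cross-checked against each other on an
  overlapping-band dye in the test suite.

For monochromatic sources λ_x is the source line (pdf 1); for broadband
sources λ_x is drawn per event proportional to L_e(λ)·f̂_x(λ) with the pdf
divided out.  Emission wavelengths are stratified per pixel over a sampling
pdf built from the scene's dye emission spectra mixed with a 20% uniform
floor (so any bin with physical radiance has sampling support); the film
accumulator divides by the pdf and the per-pixel path count, so bin λ of the
spectral image estimates the per-bin radiance L(pixel, λ).  The per-pixel
budget is the double sum of the estimator: `spectral_samples` wavelengths ×
`spp` paths each.  A single PCG64 stream derived from the seed drives the
whole render; re-renders with the same seed are bit-identical (tested).
Russian roulette is available beyond a configurable depth but off by
default — survival-by-albedo already terminates walks.

Paths are traced in vectorized batches (bounded by `max_batch` for memory);
positions are micrometres, coefficient tables are converted to μm⁻¹ once per
scene.

## Synthetic tissue

Morphologies are random trees: `n_stems` trunks leave a soma sphere in
uniform random directions and grow in segments of ~`mean_segment_len` with
angular wobble, tapering per level and branching with probability
`branch_prob` up to `max_depth` or an extent sphere.  Defaults (3 stems,
8 μm segments, taper 0.85, depth 4, 40 μm extent, 5 μm soma) give
desk-scale cells of a few tens of segments; the paper-scale circuit and its
morphology database are out of scope, and placement density in a block is a
free parameter.  Populations are placed uniformly in a block with uniform
random orientations.  Morphologies interchange as SWC text; meshes as
Wavefront OBJ.

Meshes are unions of closed components (icosphere soma and joint balls,
closed truncated cones with equal-area polygon rings).  Solid voxelization
casts an axis-aligned ray through every voxel centre and sums *signed*
crossings of the oriented surface — the generalized winding number along the
ray — marking the centre occupied when the count is ≥ 1.  For a single
closed component this is exactly ray-crossing parity; for overlapping
closed components it is exactly their union, which is why no boolean mesh
union is needed.  Rays grazing an edge or vertex are re-cast from an origin
jittered by a fixed sub-voxel epsilon (10⁻⁴ voxels), keeping the result
deterministic.  A conservative flag additionally marks voxels whose box
overlaps a triangle bounding box (a superset of boundary voxels).  Box
clipping is Sutherland–Hodgman halfspace clipping of the triangle soup with
boundary loops chained and ear-clipped into cap faces, so clipped solids
remain watertight; a distance-based rasterizer (centre within soma or
tapered capsule) provides an independent cross-check of the mesh route
(≥ 99% voxel agreement in tests).

## Validation scenes

The emission-profile and excitation-scan validations use a homogeneous
16³-voxel dye block at 0.4 mol/L under a monochromatic diffuse panel in epi
geometry (camera and light on the same side).  Two design constraints set
the scales:

* At 0.4 mol/L the dye reaches μ_a^f ≈ 1.75–14.6 μm⁻¹ at its excitation
  peak, so any block thicker than a few tens of nanometres is optically
  thick in the dye and the recorded SPD acquires a physical inner-filter
  red shift of order 10 nm.  The validation blocks use 0.5 nm voxel
  spacing — the worst-case joint excitation-plus-reabsorption optical depth
  across the block is ≈ 0.2 — so the thin-regime identity SPD ∝ p_m holds
  and the emission maximum is recovered to a few nanometres.  Thicker
  blocks show the (correct) red shift; the package renders them too, they
  are simply not the regime in which spectroscopic constants are measured.
* A flat scattering coefficient (20 μm⁻¹, ~0.15 mean free paths across the
  block, g = 0 so the fluorescence vertex radiates isotropically) gives
  camera paths interactions at every emission wavelength, including bins
  outside the dye's reabsorption band where μ_a^f(λ_m) = 0.

The low/medium/high extinction triplet uses a dilute dye (10⁻⁶ mol/L) in a
millimetre-scale block whose medium is 10/100/1000 × a flat pure-water
extinction baseline (10⁻³ mm⁻¹ by default, overridable with a tabulated
spectrum): across that range the block spans optically thin to thick and
brightness responds monotonically to the multiplier through attenuation
(empirically decreasing — the fluorescence source itself is independent of
the scattering level in the thin regime, since collision rate and the
1/σ_t collision-estimator weight cancel).

What the synthetic scenes do **not** emulate: measured (asymmetric)
dye spectra, refractive-index steps at the block boundary, wavelength-
dependent tissue scattering, spatially varying optical properties from an
atlas, and realistic neuron packing densities.  Passing validations show
that the transport and fluorescence machinery is unbiased and reproduces
prescribed spectroscopy, not that absolute radiances match any particular
microscope.

## Numerical choices

* Off-grid spectrum evaluation: linear interpolation, zero outside the
  grid; spectra are nonnegative by construction and validated.
* Emission pdf normalization: rectangle rule, exact to Σ p_m = 1 (±1e-9
  asserted).
* SPD peak ties break toward the smaller wavelength.
* Profile similarity: Pearson correlation of peak-normalized profiles over
  the union support (threshold 0.95 in the validation tests).
* Degenerate inputs: zero-length morphology segments are skipped with a
  warning; non-watertight meshes are rejected with the offending edges
  reported; zero majorants over a nonzero medium raise; NaN or negative
  path contributions raise.
* Scaled-down problem sizes: validation renders are 32×32 px with 64×64
  (emission) or 32×32 (scan) samples per pixel on 16³ blocks, chosen so the
  full validation suite and the scan script complete in tens of seconds at
  one CPU while keeping SPD argmax noise below the ±5 nm acceptance band.

## Known limitations

* The analog event-classification mode is supported but statistically
  unusable for large-Stokes-shift dyes (see Estimator); it exists as the
  literal taxonomy reference.
* The light connection at the fluorescence vertex attenuates the excitation
  segment with a transmittance estimate rather than a continued random
  walk; multiply-scattered excitation light is therefore not resolved.
* Cap triangulation during clipping assumes simple (hole-free) cut loops,
  which holds for the genus-0 solids the generator emits.
* Extinction and emission are assumed independent of temperature, pH,
  concentration quenching and photobleaching.
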