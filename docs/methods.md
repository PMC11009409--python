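# Methods

This note documents the physics model behind `moirebeam`, the defaults and
why they were chosen, and what the desk-scale simulation can and cannot be
expected to reproduce.

## Geometry and coordinate conventions

The beam travels along +z.  The phantom entrance face sits at the
isocenter plane z = 0; depths are positive into the phantom; x is the
horizontal lateral axis and y vertical.  All lengths are mm, angles
degrees at API boundaries (radians internally), energies MeV.

The dual collimator system (DCS) consists of two 30 mm-thick tungsten
multi-slit collimators: slab 1, a 5 mm gap, slab 2, and a 5 mm gap to the
phantom face.  Slits nominally run along x; in the symmetric construction
the upstream collimator is rotated +θ/2 and the downstream one −θ/2 about
the beam axis, which puts the moiré fringes along x (the y-spacing of the
beamlet lattice is then nearly angle-independent, ~T/cos(θ/2)).  Whether
one collimator rotates by θ or both by ±θ/2 does not change the moiré
period, only the fringe orientation; the symmetric split was chosen so the
fringe axis coincides with a grid axis.  An aperture is centered on the
rotation (beam) axis; lateral phase shifts translate the pattern without
reshaping it.

## Collimator transmission

Each collimator is a perfect binary absorber: a ray is transmitted iff its
straight chord stays within a single aperture, which for planar aperture
walls is equivalent to its entry and exit points lying inside the *same*
aperture interval (convexity).  There is no septal transmission, no
tungsten scatter, and no edge penumbra beyond geometry: 30 mm of tungsten
stops protons of the simulated energies outright, and collimator-scatter
contributions to the valleys are deliberately out of scope (see
Limitations).

## Beam model and treatment plan

Per energy layer and per axis, the (position, angle) phase space at the
isocenter plane is bivariate Gaussian with moments (σ_u, σ_u′, σ_uu′) and
correlation ρ = σ_uu′/(σ_u σ_u′); sampling uses two independent standard
normals per particle and axis:

    u  = σ_u Z_u + μ_u
    u′ = σ_u′ (ρ Z_u + sqrt(1 − ρ²) Z_u′) + μ_u′

x and y are independent.  Spot deflection is modelled as a virtual point
source 2000 mm upstream (μ_u′ = iso_u / SAD), i.e. a diverging scanned
field as cyclotron PBS systems deliver.  This divergence slightly
magnifies the aperture pattern between the collimators and the scoring
plane; it is the reason simulated CTCs read ~1–3% above the closed-form
moiré period.  Particles are generated at the isocenter moments and
drifted upstream to a pre-collimator plane 20 mm before the first slab.

No measured machine model ships with the package.  The synthetic beam
model is a labelled stand-in with machine-plausible magnitudes: spot σ
falling linearly 5 → 3 mm and divergence 4 → 2 mrad across the plan's
energy range, ρ = −0.3 (converging toward the isocenter), and relative
energy spread falling 1.21% → 1.09% with energy — degraded low-energy
cyclotron beams carry the larger momentum spread, and the larger spread at
the shallow layers also helps longitudinal uniformity.  Every simulated
(non-closed-form) result therefore carries trend-level, not
machine-exact, meaning.

The default plan targets a 100 × 25 × 30 mm box (x ∈ [−50, 50],
y ∈ [−12.5, 12.5], z ∈ [55, 85] mm) with spots on a 5 mm grid and eight
energy layers evenly spaced 84.7–107.6 MeV; with the Bragg–Kleeman
constants below, those endpoint ranges land on the 55 and 85 mm target
faces behind the phantom wall.  Layer weights are fitted by nonnegative
least squares so the summed analytic depth-dose is flat over the target
depth window; the residual ripple is <3% in the window interior.  With
only eight fixed layers the first/last peak's falloff leaves ~15%
deviation within ~3 mm of the exact window edges — an intrinsic property
of the layer set, not of the fit — so flatness is asserted over the
interior.

## Transport and scoring

Transport is condensed-history with fixed 1.0 mm geometric steps
(`TransportSettings.step`; halve it to check convergence):

- **Stopping**: Bragg–Kleeman R = αE^p with α = 0.0022 cm·MeV⁻ᵖ,
  p = 1.77 in water.  Each particle draws a Gaussian range perturbation
  with σ_R = 0.012 R_cm^0.935; its per-step energy deposit follows the
  range–energy inverse, rescaled so the summed deposits telescope to
  exactly its sampled kinetic energy.  Energy is conserved to float
  rounding: sampled = deposited + escaped + absorbed-in-collimator.
- **Scattering**: a Gaussian Highland angle per axis and step,
  θ₀ = (13.6 MeV / pv) √(s/X₀), *without* the logarithmic thickness
  correction.  Dropping the log term makes per-step variances exactly
  additive, so the stepping MC and the closed-form Fermi–Eyges integral
  (the independent cross-check, agreeing within 5% down to 90% of range)
  describe the same scattering power; the cost is a few-percent bias in
  absolute spread relative to the full Highland formula.
- **Materials**: the first 10 mm of depth are the PMMA wall, treated as
  water-equivalent with relative stopping power 1.16 (so the wall adds
  1.6 mm excess WET), density 1.19 g/cm³ for the energy-to-dose division,
  and its own radiation length (341 mm) for scattering.
- **Scoring**: voxels of 0.1 × 0.1 × 4.0 mm over a 150 × 100 mm lateral
  field centered on the isocenter, 25 depth slabs from the phantom face;
  dose per voxel is accumulated energy over voxel mass.  The entrance
  window (0–4 mm) lies inside the wall; the SOBP window is 68–72 mm.
- **Analytic Bragg curve**: the depth-dose oracle used for layer-weight
  fitting is the Bragg–Kleeman stopping term (R − z)^(1/p−1) convolved
  with the combined Gaussian range spread (straggling ⊕ p·R·σ_E/E),
  evaluated in closed form with the parabolic-cylinder function and
  normalized to a unit entrance plateau.  The convolved peak sits ~0.9 σ
  proximal of the CSDA range.  There is no nuclear-loss term, so the
  plateau is flat by construction.

Excluded physics: nuclear interactions and secondaries, delta rays,
energy-loss fluctuation beyond the range-spread convolution, collimator
septal/edge scatter, neutrons.

## Randomness and determinism

Phase-space sampling uses one counter-based Philox stream per spot and
transport one stream per energy layer, both keyed by the run seed, so a
run is bit-reproducible and independent of spot iteration order.  (True
per-particle streams would force scalar transport; per-spot/per-layer
streams keep the vectorized stepping while preserving determinism.)

## Metrics

Profiles are depth-window and band averages of the dose grid; an optional
Gaussian smoothing (default 0.3 mm in the summary pipeline) tames
Monte-Carlo noise at 0.1 mm voxel pitch.  Peaks require a prominence of
0.2 × the profile maximum and must lie in the central 80% of the field
(edge beamlets are biased by the scanned-field falloff); positions and
heights get three-point parabolic sub-voxel refinement.  CTC is the mean
consecutive-peak spacing; VPDR the mean valley dose over mean peak dose
(one valley at the minimum between each adjacent peak pair); FWHM is
measured on the *mean beamlet* — the profile folded at the detected peak
positions and averaged — at half height above the local valley baseline.
FWHM_y is taken through the central x-beamlet (±0.5 mm band).  All three
metrics are invariant under positive scaling and translation of the
profile.

The FWHM convention (half height above the valley baseline, on a
band-averaged folded profile) is a package choice; absolute FWHM values
under other conventions (e.g. a thin unaveraged cut through the beamlet
center) differ, while their trends with angle, period, and throughput do
not.

## What the synthetic studies do and do not show

The generator emulates a scanned, diverging, layered proton field with
realistic emittance magnitudes and the printed plan geometry.  It does
not emulate a specific machine's spot-size tables, beamline scatter, or
nuclear halo.  Consequences verified and documented by the test suite:

- Closed-form moiré periods, mask periods, and simulated entrance CTCs
  agree (the latter within 5%, offset by source-divergence
  magnification).
- VPDR *trends* — increasing with angle, decreasing with collimator
  period, decreasing with lower throughput — are reproduced.  *Absolute*
  VPDR is systematically low (e.g. ~0.11 vs ~0.28 for the reference
  2 mm / 50% / 30° case): with no nuclear secondaries and no collimator
  scatter, valleys are filled only by multiple Coulomb scattering and
  beam divergence.
- FWHM_x decreases with angle while FWHM_y stays near 1 mm, insensitive
  to angle.

## Problem sizes

Reduced-statistics study conditions in the test suite use ~3 × 10⁵
sampled primaries each (300 per spot, 1008 spots); the acceptance script
uses ~6 × 10⁵.  These sizes give sub-voxel CTC precision and stable VPDR
estimates at the summary pipeline's 0.3 mm smoothing; they are a
sensible desk-scale operating point, and all stochastic assertions are
made at tolerances appropriate to them.
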