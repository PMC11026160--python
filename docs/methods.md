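# Methods

`vesiquant` quantifies how enzymatically propelled nanoparticles ("nanobots")
distribute through a tumour-bearing bladder, combining four strands of
analysis that in a real study come from different instruments: 3D
scattered-signal light-sheet microscopy of the cleared organ, time-lapse
optical microscopy of swarm motion, diffusion-weighted MRI volumetry, and
PET/dose-calibrator radioactivity readings.  Because raw animal data are
not part of the package, every analysis is exercised on synthetic inputs
with known ground truth; this note describes the models behind both the
generators and the measurements, the defaults and their units, and what
passing tests do and do not demonstrate.

## The bladder phantom

The synthetic organ is a set of concentric ellipsoidal shells around a
lumen — urothelium, lamina propria and detrusor muscle from the cavity
outward — with a tumour modelled as a spherical cap that protrudes from the
wall into the lumen and continues through the wall behind its base.  Region
labels partition the grid; the cavity is the lumen minus the tumour.

Nanobot puncta are sampled voxel-wise from a Poisson law whose mean is

    ρ(d) = ρ₀ · exp(−d / λ) · V_voxel

where `d` is the voxel's anisotropy-aware Euclidean distance to the cavity
surface (the depth), `ρ₀` the surface density of the voxel's region and
`λ` the depth-decay length.  Defaults: `ρ₀ = 0.010 µm⁻³` at the tumour
surface, `0.0025 µm⁻³` in healthy wall tissue (a 4:1 surface ratio) and
`λ = 95 µm`.  With 33 µm analysis layers the expected layer-mean intensity
ratio between the third and first tumour layer is `exp(−66/95) ≈ 0.50`, i.e.
an ≈50 % drop from the first to the third layer — the regime the layer
quantification is designed to recover.

The scattered channel is a flat baseline (20 a.u.) plus puncta whose
brightness is lognormal around 30 000 a.u. (CV 0.2), blurred by a separable
anisotropic Gaussian PSF (σ = FWHM/2.3548; default FWHM 2.4 µm lateral,
5.5 µm axial, the instrument's measured resolutions) and multiplied by
lognormal speckle (σ = 0.2, mean 1) — laser speckle is multiplicative and
survives pivoting only partially.  The autofluorescence channel carries
per-region mean intensities (bright urothelium, dark lamina propria,
intermediate detrusor) with additive Gaussian noise.  Both channels are
quantized to 16 bit.

**Scale.** The default grid is 120 × 256 × 256 voxels at (2.5, 1, 1) µm —
the acquisition pitch of the real instrument — which holds only ≈ 0.3 mm of
tissue, so the anatomy is miniaturized (lumen radius 75 µm, wall 51 µm,
tumour cap with basal radius 65 µm and 60 µm protrusion) while all optical
and layer parameters keep full-scale values.  The tumour cap is deliberately
large enough that tumour depth below the cavity reaches ≈ 96 µm and all
three 33 µm layers have tumour support.  Geometry checks therefore validate
the *method* (distance transforms, layer algebra, intensity normalization)
at reduced organ size; they say nothing about segmenting a real 5 mm
bladder, where annotation quality, clearing artefacts and stitching
dominate.

What the phantom does not emulate: polarization-dependent scattering,
light-sheet shadowing and stripe artefacts, tissue-dependent PSF
degradation with depth, agarose/muscle scatterers outside the organ, and
any propulsion physics — puncta are placed by a density law, not by a
transport simulation.

## Masks and layer algebra

Sparse planar polygon annotations become 3D masks by shape-based
interpolation: each annotated plane is rasterized (even-odd rule, a pixel
belongs iff its centre is inside), converted to a signed Euclidean distance
map (negative inside), and intermediate planes threshold the linear blend
of the two neighbouring maps at zero.  Annotated planes are reproduced
bit-exactly and no extrapolation occurs beyond the first/last annotation.
The default annotation cadence is every 15 planes of a 2.5 µm stack
(37.5 µm).

Morphology is physical: `dilate(M, d)` is the set of voxels whose
anisotropy-aware Euclidean distance to `M` is ≤ d (closed ball, computed
by a sampled distance transform), and erosion is its complement dual.
Using micrometres rather than pixel counts keeps 33 µm layers isotropic in
tissue space on the (2.5, 1, 1) µm grid; dilation with a 3D (not per-plane)
metric was chosen because layer depth is a 3D tissue coordinate.

Layers follow the two-macro bookkeeping: successive cavity masks
BC₁ → BC₂ → … by 33 µm dilations, shells L_k = BC_{k+1} − BC_k, tumour
layers TL_k = L_k minus the healthy annotation, healthy surface layer
HL = L₁ minus the tumour annotation.  Conservation (Σ|L_k| = |BC_{n+1}| −
|BC₁|) holds by construction and is asserted on every run.  In the phantom
pipeline the "healthy annotation" subtracted from TL_k is the complement of
tumour ∪ cavity: that confines tumour layers exactly to tumour tissue, the
synthetic equivalent of an annotator outlining all healthy structures.
Note that repeated 33 µm dilations are composed per step; on a discrete
grid this over-reaches a single 99 µm dilation by a fraction of a voxel per
step, which is immaterial at the default pitch.

The internal-tissue mask thresholds the autofluorescence channel (Otsu by
default, overridable), treats the border-connected background as exterior,
removes the largest enclosed background component as the lumen, and peels a
500 µm rind measured from the exterior-facing boundary only, leaving the
luminal surface untouched.  A collapsed bladder with no enclosed cavity
triggers a warning and keeps the full enclosed volume.

## Scattered-signal quantification

The primary readout is integrated intensity per µm³ of mask — individual
nanobots are not resolved, so particle counting is reserved for the truth
data in tests.  The two headline ratios are TL1/HL (tumour-surface
enrichment over healthy urothelium) and TL3/TL1 (depth attenuation).  The
flat scattered baseline biases both ratios toward 1, which is why the
recovered enrichment (≈ 3.6 on the default phantom against a configured 4)
sits below the configured value; the acceptance band [3, 5] accounts for
this together with Poisson fluctuation.

Histograms span the full 16-bit range, by default in 4096 bins; the
logarithmic variant spaces bins geometrically above intensity 1 with one
leading bin for [0, 1).  Counts always sum to the mask size.

Foreground/background separation inside a mask uses Otsu's threshold on
the masked intensities (recorded in the output); penetration depth of a
foreground voxel is its physical distance to the cavity-surface mask, and
occupancy is the voxel fraction of the region classified foreground.  The
occupancy definition is voxel fraction (not particles per volume), and a
region with no foreground reports its median depth as missing rather than
zero so that summaries are not dragged toward the surface.

Lateral resolution is estimated by least-squares fitting an isotropic 2D
Gaussian with offset to a single-particle image; FWHM = 2√(2 ln 2)·σ.

## Swarm motion

The ROI histogram series samples the pixel-intensity distribution inside a
fixed circle every 15 s (nearest frame at 25 fps defaults) with one bin per
integer intensity level.  The spread of the distribution is reported as
both population SD (headline) and IQR: a passively dispersing bolus's
spread decays toward the background value, while an actively accumulating
swarm keeps the distribution heterogeneous.

Tracer tracks are simulated as 2D Brownian motion (per-axis step variance
2 D dt) with optional advection: a vortex that rotates particles about a
centre by the exact angle ω dt (ω = speed / seeding radius), plus an
optional radial convergence rate that contracts radii by exp(−rate·dt) per
step, standing in for the observed accumulation of tracers inside swarms.
A rigid vortex alone is measure-preserving and cannot change the intensity
histogram; convergence is the minimal ingredient that reproduces the
urea-versus-water contrast in the spread metric.

MSD is time-and-ensemble averaged: squared displacements are pooled over
all start times of all tracks per lag, up to 25 % of the track length by
default (ensemble-only averaging is a trivial restriction but the pooled
estimator is the default because single-track averages are noisy at these
track lengths).  The fit `MSD = 4 D τ^α` is linear least squares in
log-log space; α ≈ 1 marks diffusion, α → 2 ballistic transport.  The
estimator is translation- and rotation-invariant by construction and is
verified as such.

## In vivo arithmetic

Decay correction uses `A₀ = A · 2^(t/T½)` (base-2 form, exact at whole
half-lives; ¹³¹I T½ = 8.01 d as used in the therapy arm, ¹⁸F T½ = 109.77 min
shipped as a constant).  %ID decay-corrects both the VOI and the injected
dose to the common reference before taking the ratio, making the result
independent of readout times; %ID cm⁻³ divides by the MRI-derived tumour
volume.  Radiochemical yield is retained/initial × 100 with a warning (not
an error) above 100 %.

DWI processing divides the diffusion-weighted by the b = 0 acquisition
voxel-wise (zero baselines are zeroed and counted) and smooths with a 3D
Gaussian of σ = 0.7 per axis.  σ is interpreted in voxel units — the
convention of the original ImageJ pipeline on the 0.1 × 0.1 × 0.5 mm MRI
grid — and is overridable.  The synthetic DWI pair places the requested
tumour volume as the n nearest-to-centre voxels (exact to one voxel) with
the b_dw/b0 ratio elevated by the contrast factor, multiplicative Gaussian
noise on both channels; recovery in the pipeline is blind (Otsu on the
smoothed ratio image).

NTV divides each post-treatment volume by the group's mean pre-treatment
volume; group summaries are mean ± s.e.m.  The study-table generator draws
pre-volumes lognormally with the group mean preserved exactly and applies a
group-level fold change, so at zero dispersion the NTV pipeline returns the
configured fold changes identically — the worked-example path for the
six-arm therapy design (2.45, 1.93, 1.66, 0.96, 0.54, 0.27), whose
high-dose-in-urea arm versus non-treated control gives a 89.0 % ≈ 90 %
volume reduction.

Group statistics are deliberately thin wrappers: unpaired two-tailed
Student t-test (pooled variance; Welch by flag — the pooled form is the
default because the source analyses specify only "unpaired") and one-way
ANOVA with Tukey HSD, via scipy.

## Problem sizes and numerical choices

The default pipeline and the acceptance script run the phantom at
120 × 256 × 256 voxels (≈ 7.9 M), 1000 tracer tracks of 200 steps, and a
20 × 160 × 160 DWI grid — sizes chosen so a complete run takes well under a
minute per stage on one CPU while keeping ≥ 10⁴ puncta for stable ratio
statistics.  Distance comparisons use ≤ (closed balls); coordinates are
Z, Y, X, 0-based, with pixel centres at integer positions; 16-bit
quantization rounds and clips.  All randomness flows through explicit
integer seeds on the spec objects; rerunning any generator or the full
pipeline with the same seed is bit-identical (verified via manifest
checksums).

## Known limitations

- Intensity ratios inherit a baseline-induced bias toward 1; no background
  subtraction is applied because the real analysis reports raw integrated
  intensity.
- The internal-tissue mask's 500 µm default erosion assumes a full-scale
  organ; the bundled demo configuration scales it to the miniaturized
  phantom (25 µm).
- Shape-based interpolation blends distance fields linearly and cannot
  represent branching topology between two annotated planes.
- The swarm-motion model reproduces the qualitative histogram contrast but
  is not a hydrodynamic simulation; fitted α for advected mixtures depends
  on the chosen vortex and convergence parameters.
- `percent_id` and friends are plain arithmetic on calibrated inputs; no
  partial-volume or scatter corrections are modelled.
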