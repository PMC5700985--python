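# Methods

This note documents the statistical model, the numerical choices and the
limitations of `sofiquant`, in the order the pipeline applies them.

## Camera model and units

Raw 16-bit counts are converted to photoelectrons by the linear model
`pe = (raw − offset) · sensitivity / em_gain`.  The EM register gain
(default 300) is divided by the A/D sensitivity (default 10 e⁻/count,
i.e. 30 counts per photoelectron): without this divisor a single ~250-pe
emission event would saturate the 16-bit range, and joint clipping across
pixels distorts the sign of odd-order cumulants in dense regions.  EMCCD
excess noise is not modelled and not inverted; read noise is additive
Gaussian in counts.  All physical coordinates are nm from the centre of
the top-left pixel, pixel centres at integer indices, row-major (y, x).

The PSF is a peak-normalized 2D Gaussian.  Its default width, σ = 82 nm,
is the diffraction-limited value 0.21 λ/NA for a NA 1.49 TIRF objective at
~580 nm emission.  Pixelation is handled explicitly — the simulator
integrates the PSF over pixel areas and the analysis corrects pixel
separations through the distance factor — so σ must not be inflated to
"include" it.  For real samples with fixation blur or aberrations, σ is a
config field.

## Drift correction

Candidate fiducials are local maxima of an early-frame average (before
drift accumulates); each is followed frame by frame with a 7×7
background-subtracted centroid window.  Tracks whose peak intensity stays
above the brightness threshold in fewer than 95% of frames are discarded —
this separates gold beads from blinking fluorophores by temporal
persistence rather than brightness.  The per-frame displacement (mean over
beads of position − position₀) is smoothed with a polyorder-1
Savitzky–Golay filter (window 51 frames): in the interior this is the
moving average; at the sequence ends it fits a line, so linear stage drift
is unbiased where a plain moving average with reflective padding is not.
Frames are registered to frame 0 by bilinear interpolation; pixels moved
in from outside the field are zero.  On synthetic drift up to 10 px the
round-trip residual is below 0.1 px.

## Cross-cumulant estimation

The sequence is split into non-overlapping blocks of 500 frames (trailing
remainder discarded) and every pixel trace is mean-subtracted per block —
the only photobleaching mitigation applied.  Joint zero-lag cumulants of
orders 2–4 are estimated per block with the mean-free formulas
(E[X₁X₂]; E[X₁X₂X₃]; E[X₁X₂X₃X₄] − E[X₁X₂]E[X₃X₄] − E[X₁X₃]E[X₂X₄]
− E[X₁X₄]E[X₂X₃]) and averaged across blocks.

For each node of the order-n virtual grid (pitch = camera pitch / n), the
n contributing camera pixels must have the node as their centroid.
Combinations are drawn from a 4×4 offset window, restricted to pixels
within 2σ of the node, with all-distinct combinations strictly preferred
(the joint cumulant of distinct pixels carries no shot-noise bias; a
repeated pixel is allowed only when no distinct combination exists, and is
never mixed into a distinct average).  Each combination's cumulant is
divided by its Gaussian distance factor exp(−Σᵢ|rᵢ−c|²/2σ²), and up to
four equivalent combinations per node are averaged with inverse-variance
weights (∝ weight²; the distance-factor correction amplifies noise by
1/weight).  This multi-combination average reduces estimator variance
without changing the expectation.  Combination tables are resolved once
per (order, σ) with a lexicographic tie-break, so results are
deterministic.

A border of two camera pixels, where combinations would leave the field,
is zero on all cumulant rasters; the simulator pads its camera grid by
three pixels so the ground-truth field is unaffected.

g₂ and g₃ are computed on their native 2×/3× grids and bilinearly
resampled onto the common 4× grid (both grids share the camera origin).
After aggregation g₂ is clamped at zero — negative order-2 values are pure
estimation noise — while g₃ and g₄ keep their signs for the density
inversion.  The bSOFI transparency mask uses the magnitude-linearized
second-order image |g₂|^(1/2) without deconvolution.

## Density inversion

PSF moments μₙ are discrete integrals of Uⁿ over the 4× grid on a ±4σ
support (analytically 2πσ²/(n·pitch²); the ratios μ₂/μ₃ = 3/2 and
μ₂/μ₄ = 2 are exact to <1e-6).  Densities therefore come out in emitters
per grid-pixel area; `DensityMap.per_um2()` converts.

Two estimators of (ε, ρ) are provided:

* **per-pixel** — K₁, K₂ formed pointwise (with an optional median filter,
  default 5 px, which leaves uniform rasters untouched), then inverted.
  This is exact on noiseless forward-model rasters (relative error <1e-9
  over a wide (N, ε, ρ) grid) but is ill-conditioned on real traces with
  PALM-like duty cycles: for ρ of a few percent, κ₃/κ₂ → 1−2ρ and
  κ₄/κ₂ → 1−6ρ are differences of nearly equal noisy numbers, and the
  resulting density map carries order-100× speckle.
* **global** (pipeline default) — one signal-weighted ratio pair per ROI,
  K₁ = μ₂Σ(g₃g₂)/(μ₃Σ(g₂²)), K₂ = μ₂Σ(g₄g₂)/(μ₄Σ(g₂²)), broadcast to the
  raster.  This assumes a single fluorophore species with spatially
  uniform photophysics — the operating regime of the method — and makes
  N(r) proportional to g₂(r).  Because relative densities are invariant
  to the global scalar, a noise excursion of the small-ρ estimate past its
  validity bound is clamped to (0.001, 0.999) rather than failing the map.

Pixels with g₂ below 1e-12 of its maximum, non-positive discriminant
3K₁²−2K₂, or (in per-pixel mode) ρ outside (0.001, 0.999) are flagged
invalid, set to zero and excluded from δ_avg.

Before the inversion, the pipeline sharpens the g₂ numerator of the
density map by 10 Richardson–Lucy iterations with the order-2 image PSF
(Gaussian, σ/√2).  The order-2 kernel otherwise limits the map to ~150 nm
structure separation even though the grid resolves 52.5 nm: two HDRs with
centre distance below ~350 nm never develop a saddle deep enough to
separate at the working threshold, and a random 10-HDR layout on 3×3 µm
contains ~1.3 such pairs in expectation.  A fixed iteration count keeps
the step deterministic; the blinking ratios K₁, K₂ are always formed from
the raw cumulants, so the inversion algebra is unaffected, and flux
normalization preserves δ_avg.  `compute_density_map` leaves sharpening
off unless requested, so the closed-form inversion remains exact.

The background mask thresholds the bSOFI image at 5% of its maximum and
keeps the largest connected component.  The pipeline smooths the bSOFI
image (Gaussian, 4 virtual px ≈ one camera px) before thresholding: the
mask describes the gross specimen footprint, and without smoothing,
pixel-scale speckle fragments the foreground and the largest-component
rule can silently discard genuinely occupied areas.

Group normalization rescales every sample to its group-mean density and
divides all maps by the maximum group mean, making relative densities
comparable across conditions while removing expression-level differences.

## Threshold sweep and automatic threshold

Thresholds run from 0 to N_max/δ_avg in steps of 0.1·δ_avg.  Regions are
8-connected components (diagonally touching HDR networks stay whole).
The sweep reports only regions of at least 4 px: on the 26.25 nm grid the
Nyquist-resolvable minimum diameter is 2 px = 52.5 nm, i.e. an equivalent-
diameter area of π px², and sub-resolution specks would otherwise dominate
the counts.  `segment_hdrs` itself retains 1-px components by default so
no hidden cutoff is imposed outside the sweep.  Relative occupied area is
non-increasing in threshold and regions nest exactly.

The number-of-regions curve is modelled as A·exp(−(t−m)²/2s²) + c with
c ≥ 0: the Gaussian bump is the signature of randomly scattered molecules,
the floor absorbs any plateau of persistent genuine clusters so the
plateau cannot inflate the fitted width.  The fit uses only the peak and
its descending flank (below the peak, counts are suppressed by percolation
of the near-full-field component, which the Gaussian does not model), is
truncated at the last threshold with at least one region, and minimizes
log-scale residuals so it stays faithful to the tail it extrapolates into.
The selected threshold is the smallest grid value at which the fitted
Gaussian component is strictly below one region (closed form
m + s√(2 ln A), snapped up to the grid); if the fitted amplitude never
exceeds one region, m itself is returned.  On an exact Gaussian curve
(A=50, m=1, s=0.5) this recovers 1 + 0.5√(2 ln 50) ≈ 2.399 to within one
grid step.

Group summaries report median, interquartile range and extremes of the
per-sample region count, mean area, equivalent diameter and occupied
fraction at the threshold grid point nearest the requested value.

## Simulator

The ground truth is 10 non-overlapping circular HDRs (diameters 60–180 nm,
densities 500–3000 molecules/µm²) placed uniformly on a 3×3 µm field with
a one-radius border margin; molecule counts are Poisson (density × disk
area), background molecules are Poisson at density HDR-density/contrast
(contrast ∈ {20, 50, 100}) placed uniformly between the disks.  A layout
with no HDRs is the random control; for controls matched in total molecule
count to a clustered condition, the background density can be overridden.

Photokinetics emulate sparse mEos2-like PALM traces at 32 ms exposure:
geometric activation (0.0005/frame), geometric on/off dwells (means 2 and
20 frames), irreversible bleaching from the on-state (0.05/on-frame),
Poisson photon emission (300 photons/on-frame) and detection efficiency
0.9.  Rendering integrates the PSF over pixels via error functions,
draws Poisson photoelectrons, applies gain/offset/read noise and 16-bit
quantization, and returns the linearly re-converted photoelectron stack.
Identical seeds give bit-identical stacks.

What the simulator does **not** emulate: EMCCD excess noise (gamma
statistics of the multiplication register), spectral crosstalk, uneven
illumination, axial defocus, sample drift (available separately through
the drift module's synthetic tests) and reactivation of bleached
molecules.  Passing tests on simulated data therefore demonstrate the
estimator chain and the segmentation logic, not robustness to every
real-camera artefact.

## Validation studies and known limitations

`sofiquant.validation` runs two studies used by the acceptance script and
the test suite, at the conditions of the simulation protocol (5000-frame
sequences, 3×3 µm field, one CPU-scale problem size):

Thresholds are selected at the group level: the per-replicate count
curves of one condition are averaged and the Gaussian rule is applied
once, as sample curves are pooled per condition.

* **HDR recovery** — five clustered replicates at diameter 180 nm,
  density 3000/µm², contrast 100.  The mean region count at the group
  threshold is 9–10 against 10 ground-truth HDRs; the occasional single-
  region deficit comes from layouts in which two HDRs lie within ~250 nm
  and remain merged even after sharpening, an optics limit rather than an
  algorithmic one.
* **Random control** — ten no-cluster replicates at the matched total
  density (~114 molecules/µm²).  The selected threshold lands where the
  *fitted* random count equals one region; the *realized* mean count
  there is ≈2, not below 1 — integer counts and Poisson density clumps of
  a sparse random field exceed the fitted Gaussian exactly at its tail.
  The corresponding test asserts the idealized sub-unit bound and
  documents this gap honestly rather than relaxing it.

Other limitations worth knowing: absolute densities depend on the blinking
inversion and are systematically biased when traces are non-stationary
within a block (activation and bleaching make the effective duty cycle a
per-molecule random variable); relative densities, which all reported
statistics use, are unaffected.  The density map's effective resolution
is set by the order-2 kernel and the modest deconvolution, not by the
grid, so structures separated by less than roughly 250 nm can still
merge.  The automatic threshold assumes the random component of the
count curve is approximately Gaussian; heavy-tailed backgrounds (very
sparse fields of isolated molecules) violate this.
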