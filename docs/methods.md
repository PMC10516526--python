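# Methods

This note documents the models and numerical choices behind `semrestore`:
what each stage computes, which knobs matter, what the synthetic phantoms do
and do not emulate, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A stack is a 3-D float64 array indexed `(z, y, x)` with `z` the
acquisition/milling axis; conversion to and from integer bit depths happens
only at the I/O boundary (multipage TIFF via `tifffile`; MRC2014 read and
written directly, modes 0/1/2/6). Voxel size is carried as metadata only —
no algorithm depends on it. Indices are 0-based, ranges half-open.

## Sharpness and artifactual-slice detection

Per-slice sharpness is the standard deviation of the
Laplacian-of-Gaussian-filtered slice (`log_sigma` = 2 px default, mirror
boundaries so edge response does not dominate the statistic). It is exactly
0 for constant slices and invariant to additive offsets.

Four flagging rules are provided:

* `robust_z` (default of `detect_artifactual_slices`): flag slice *i* when
  `s_i < median(s) − k·MAD(s)`, `k` = 3. Appropriate when clean slices share
  statistics (the planted-blur recovery fixtures).
* `rolling_robust_z`: the same rule on residuals from a running-median
  trend (window 7). Stacks whose content genuinely changes with depth have a
  slowly varying sharpness baseline that inflates the global MAD; a
  defocused slice is an abrupt dip against the local trend.
* `relative` (default of the restoration workflow): flag when
  `s_i < rel_frac ×` running-median trend, `rel_frac` = 0.5. Rationale: a
  strongly defocused slice loses well over half of its LoG response, while
  benign effects cost far less. The specific benign effect that motivates
  this rule: after drift correction, each slice has been resampled at a
  different fractional shift, and spline interpolation attenuates the
  noise-borne part of the LoG response by a shift-dependent amount — on
  processed stacks this produces clean-slice dips tens of MADs deep, which
  defeats any MAD-scaled rule but stays far above a 50 % loss.
* `absolute`: a fixed cutoff, for stacks too short for robust statistics.

## Fourier Ring Correlation

For two equally shaped slices, `FRC(r) = Re(Σ F₁F₂*) / √(Σ|F₁|²·Σ|F₂|²)`
summed over Fourier samples in rings of normalized radius. Numerics:

* Frequencies are normalized per axis to cycles/pixel, so Nyquist is 0.5 on
  both axes for non-square images; samples beyond 0.5 (corners) are not
  binned.
* The DC sample is excluded — it encodes only mean intensity, and excluding
  it makes the metric offset-invariant, consistent with standard EM usage.
* Ring width defaults to one Fourier pixel of the larger axis.
* The global score is the *unweighted* mean over rings; a count-weighted
  mean is available (`FRCCurve.weighted_score`) but is not the default.
* A ring with zero power in either image contributes 0 (logged).

The real part makes each ring value (and hence the mean) real; by
Cauchy–Schwarz every ring lies in [−1, 1].

### Validation protocol

A replaced slice is compared against the slice exactly `plane_range` (= 3)
planes away, before and after inpainting; the replacement is accepted if
the global score does not decrease. Two selection rules:

* the reference must not be flagged itself, and
* a reference that is not even adjacent to a flagged plane is preferred —
  a reference next to a flagged slice shares content with the very donor
  planes the inpainting used, which would bias the comparison upward.

Caveat: with strong per-slice noise the global score saturates low for
*any* pair of distinct slices (high-frequency rings are noise-dominated),
and a smooth inpainted slice can then score above a genuine noisy one.
The protocol is informative when structures persist over the plane range
and per-slice noise is moderate; it does not replace visual inspection.

## Corrections

**Charge (rolling ball).** Background = grayscale opening with a ball
(sphere-cap) structuring element; corrected = image − background, which is
nonnegative because opening is anti-extensive. The ball couples pixel and
intensity units, so the image's dynamic range is internally mapped to 255
gray levels (the classic 8-bit convention) before rolling — without a fixed
convention the "same" radius means a different geometry on differently
scaled data. Default radius 25 px: follows image-scale gradients, passes
under bead/blob-scale structure at that intensity scale. The opening (not
the residual) is idempotent; the oracle test checks the background against
a brute-force min/max implementation.

**Stripes (Fourier wedge + compressed sensing).** Stripes along the milling
direction concentrate spectral energy in a narrow wedge around the
perpendicular frequency axis. Stage 1 zeroes that wedge (half-angle 2°,
keeping DC and the low-frequency disc inside radius 0.08 cycles/px, since
coarse image structure also lives near that axis). Because the wedge carries
object signal too, stage 2 re-estimates it: 100 iterations of Chambolle TV
denoising (weight 0.01 × dynamic range), each followed by exact re-injection
of all kept coefficients, so only the suppressed wedge is free. Defaults
were chosen so that on a stripe-free phantom the full filter is transparent
(> 40 dB) while removing ≥ 90 % of planted stripe-wedge energy; both
properties are asserted in the tests.

**Defocus (PSF estimation + Richardson–Lucy).** The PSF family is an
isotropic Gaussian — the dominant FIB-SEM defocus model and the only
1-parameter family recoverable from a single slice. The estimator fits the
ring-averaged log power spectrum to `a + c·log f − (2πσf)²` (power-law
object spectrum times squared Gaussian MTF), solving the linear part per
candidate σ and refining the best grid point parabolically. Numerics that
matter: the slice is Hann-windowed first (otherwise boundary leakage puts a
1/f² floor under the spectrum and hides the blur attenuation), and rings
more than 50 dB below the spectral peak are excluded (below that the
floor, not the signal, is measured). Flat spectra return the smallest
candidate with a warning.

Richardson–Lucy uses the standard multiplicative update with circular (FFT)
convolution; for a normalized PSF each update then conserves total flux
exactly. Ratio denominators are floored at machine-epsilon scale; negative
inputs are shifted nonnegative and the shift undone afterwards. The
TV-regularized variant divides each update by
`1 − tv_weight · div(∇u/|∇u|)`. The workflow default is 50 iterations,
plain (no TV) — the regularized variant is substantially slower for little
gain on these data.

**Drift (multi-scale cross-correlation).** Coarse-to-fine over a factor-2
block-mean pyramid (3 levels default): full-plane correlation search at the
coarsest level, then peak search within ±3 px of the doubled previous
estimate. The cross spectrum is Hann-windowed (suppresses wrap-around
correlation of non-periodic slices) and *partially* whitened, normalized by
|C|^0.5: full phase correlation over-weights high frequencies where
consecutive slices genuinely differ (structures entering/leaving the
plane) and showed ~1 px peak bias on bead phantoms, while the unwhitened
surface has a broad peak whose quadratic interpolation is biased toward
integers. Subpixel refinement is the argmax of a locally upsampled
(zoomed-DFT, 1/16 px) correlation surface rather than a 3-point quadratic
fit, which removed a ~0.4 px bias near half-integer shifts. Alignment
accumulates sequential pairwise estimates into absolute shifts vs slice 0
and resamples with cubic splines and edge extension (milling stacks are not
periodic); a pair that fails to register inherits the previous pairwise
shift with a warning.

*Identifiability limit:* coherent structural motion (the specimen's own
content drifting across planes) is physically indistinguishable from stage
drift for any registration method; it enters the recovered trajectory as a
slow bias. The phantom therefore keeps blob centroid velocity at
0.15 px/slice by default (exposed as `blob_drift`), and trajectory-recovery
accuracy is quoted as RMS pooled over seeds.

## Structural inpainting

All four methods run natively in 3-D, so a missing slice is constrained by
both z-neighbors; known voxels are returned bit-exact. Convergence is
measured as the maximum relative change on masked voxels. A run of more
than 5 consecutive missing slices warns: structure propagation cannot
recreate objects that fit entirely inside the gap.

* **multiscale** — factor-2 pyramid averaging known voxels only (a coarse
  cell is known if any contributor is); at the first fully known level,
  values propagate back down by trilinear upsampling into unknown voxels.
  The raw pyramid fill carries a half-cell bias where cells straddle known
  and unknown voxels, so a bounded number (25) of neighbor-mean relaxation
  sweeps on the masked voxels completes the propagation; the sweep count is
  deliberately finite so large gaps keep pyramid content instead of
  relaxing to the harmonic solution.
* **dct** — Garcia-style penalized least squares: fixed point of
  `u ← IDCT(Γ_s · DCT(W(y−u)+u))` with gain `Γ_s = 1/(1+sλ²)`, λ the
  type-II DCT Laplacian eigenvalues, annealed over 10 log-spaced s from 10³
  to 10⁻³. The fixed point at each s solves `(W + sL²)u = Wy`, which the
  tests verify against a dense solve.
* **harmonic** — red-black Gauss–Seidel on the 6-neighbor discrete Laplace
  equation with Dirichlet data from known voxels; volume faces use edge
  replication (a replicated neighbor equals the center, reducing the
  stencil). Satisfies the discrete maximum principle; verified against a
  direct sparse solve. Default tolerance 1e-10 on relative change, cap
  2000 sweeps.
* **tv** — alternate one Chambolle TV-denoising step on the whole volume
  (weight 0.05 × dynamic range) with exact re-injection of known voxels.
  Preserves step edges that harmonic diffusion smears. Note that TV is
  *degenerate on monotone fills*: any monotone profile between two boundary
  values has the same total variation, so on a linear-in-z gap the
  converged answer is a few parts in 10³ away from exact interpolation —
  an inherent property, not an iteration artifact.

Method choice: DCT is the workflow default (fast, near-exact on smooth
data); TV when edges dominate; harmonic as the deterministic baseline;
multiscale as the cheap first approximation. No global quality ranking is
asserted — it is data-dependent.

## Restoration workflow

Fixed stage order: charge → destripe → align → deconvolve → detect →
inpaint → FRC-validate. Geometric and intensity corrections precede PSF
estimation because stripes, gradients and drift bias the spectral fit;
detection runs after deconvolution so only slices that deconvolution could
*not* rescue are replaced. The report echoes the full plan, per-stage
status and timings, per-slice sharpness before/after, and per-replaced-
slice FRC pairs; plans round-trip through YAML.

`parallel_map_slices` runs pure per-slice operations (charge, destripe,
deconvolve) over a process pool; results are bitwise independent of the
worker count because each slice is processed by identical code with no
shared state. Stack-level operations (alignment, 3-D inpainting) are
rejected by contract.

## Synthetic data

`make_phantom` emulates a marker-laden biological FIB-SEM sample: a smooth
matrix of 3-D Gaussian blobs whose centroids drift slowly along z (default
≤ 0.15 px/slice, see the identifiability note above) plus bright spheres of
radius 3–5 px (soft supergaussian profile). Bead persistence across ≥ 3
planes is deliberate: the plane-offset FRC validation presupposes
structures that outlive the plane range. Intensities are clipped to [0, 1]
over a 0.1 background. `make_textured_stack` provides i.i.d. textured
slices sharing statistics, for detection and spectral-recovery studies.

`degrade` applies, in order: random-walk drift (cubic-spline resampling),
a smooth planar+quadratic additive charge field (identical on every slice),
oriented stripes (sinusoid + random per-line offsets, per-slice phase),
per-slice Gaussian blur, Poisson then Gaussian noise, and zero-filled
dropped slices — each independently controllable and fully determined by
the spec's seed.

What the phantoms do *not* emulate: detector physics (realistic
noise spectra, saturation), milling physics (correlated curtaining that
drifts across slices, waviness), anisotropic voxels, charging that moves
with the scan, and tissue-like texture. Passing tests demonstrate the
algorithms recover planted parameters under controlled conditions; they do
not certify performance on arbitrary real acquisitions.

Problem sizes used by the tests and the acceptance script (64–128 px
slices, 8–50 slices, 3–20 seeds per property) were chosen so each fixture
isolates one effect at comfortable signal-to-noise; the end-to-end fixture
plants blur of σ = 8 px on 3 consecutive slices — strong enough that
50-iteration deconvolution genuinely cannot rescue them, which is the
regime slice replacement is for (at σ ≈ 4–6 deconvolution partially
recovers the slice and replacement is neither needed nor reliably better).

## Known limitations

* PSF estimation assumes an isotropic Gaussian blur and a roughly power-law
  object spectrum; astigmatism and strongly structured spectra are out of
  scope.
* The stripe wedge geometry is fixed per call; curtaining whose orientation
  varies within a slice needs per-region processing.
* Registration recovers translation only (no rotation/scale), and inherits
  the structural-motion ambiguity above.
* Structural inpainting cannot recreate objects entirely contained in the
  missing region; the 5-slice run warning is a heuristic, not a guarantee.
* FRC validation against noisy references saturates low and can favor any
  smooth replacement; see the caveat above.
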