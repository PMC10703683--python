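# Methods

This note documents the models, numerical choices, and limitations of the
package, in the order data flows through it.

## Grid conventions

Raw frames are T×H×W with pixel pitch `pixel_size` (nm); raw pixel *i* is
centered at (i + 0.5)·Δ. Magnified grids are **sample-aligned**: magnified
pixel *j* sits at raw-pixel coordinate j/M, so `out[::M, ::M]` of an
interpolated frame reproduces the raw samples exactly. All
radial-gradient-convergence (RGC) geometry uses relative distances, so
this convention only matters when relating output indices to physical
coordinates; `esrrf.studies.nm_to_mag_index` does that conversion.

## Band-limited interpolation

Upsampling is spectrum zero-padding (the band-limited interpolant of the
samples), with the Nyquist bin split evenly for even sizes. It is exact at
the original samples, preserves the mean, and commutes with whole-pixel
translations - properties the test suite relies on. The transform is
periodic; instead of pre-padding by default, the edge-affected border of
⌈2RM⌉ magnified pixels is flagged in output metadata (an optional
reflective `pad` parameter exists for inputs with strong edge gradients).
Volumes are interpolated laterally the same way; **axially** a symmetric
(mirror) extension precedes the transform because multiplane stacks have
very few planes (typically 9) and periodic wrap-around rings badly there.

## The RGC transform

Gradients are centered differences on the magnified grid (reflection
borders); interpolation strictly precedes gradient calculation, and
spectral derivatives are deliberately avoided (they amplify ringing on
noisy data). The convergence at output pixel *c* is

    RGC(c) = clamp₀( Σᵢ w(dᵢ)·Dᵢ / Σᵢ w(dᵢ) )^S,

summing magnified pixels within dᵢ ≤ 2R (raw-pixel units), with

* Dᵢ = max(0, 1 − d⊥ᵢ/dᵢ), d⊥ᵢ the perpendicular distance from *c* to the
  gradient line through the neighbor; zero when the gradient points away
  from *c* (∇I·(c−p) ≤ 0) or is negligible (|∇I| < 10⁻⁶·max|∇I|);
* w(d) = [(d/σ_w)·exp(−d²/2σ_w²)]^P, σ_w = R/2.355 (R read as the FWHM of
  the weighting ring), P = 4, truncated at 2R; the ring is zero at d = 0 -
  a pixel cannot vote for itself - and pixels closer than 0.1 magnified
  pixel are excluded to avoid the d⊥/d singularity;
* S ≥ 1 sharpens; optional intensity weighting multiplies the map by the
  (non-negative-clipped) interpolated intensity, default off.

The compiled kernels iterate neighbor offsets outermost for sequential
memory access and reflect indices at borders. An optional
`rel_weight_min` truncates offsets whose ring weight is below that
fraction of the maximum - a support cutoff like a Gaussian filter's
`truncate`; at the 10⁻⁶ used by the long-running studies the discarded
weight mass is < 10⁻⁴ of the total, far below the stochastic noise of any
measurement made on the output. The default (0) keeps the exact 2R
neighborhood, and the brute-force-oracle tests run against that default.

### 3D

The volumetric transform uses the anisotropic distance
d² = dx² + dy² + (δz/ρ)², where ρ ≥ 1 is the axial/lateral PSF elongation
(default 2.5, typical of high-NA objectives). All geometry is evaluated in
the ρ-scaled space in which that metric is Euclidean; gradients transform
accordingly (the axial component is scaled by ρ after conversion to
per-raw-pixel units). The axial magnification Mz defaults to
round(dz/(pixel/M)) capped at 8; the desk-scale studies below use Mz = 3
(130 nm axial voxels for the 390 nm plane spacing), accepting documented
voxel anisotropy in exchange for tractable neighborhood sizes - the
anisotropy check warns rather than errors for this reason.

## Temporal compression

AVG is the mean; VAR the population (1/T) variance - population rather
than sample normalization for scale stability at small T; TAC2 the lag-1
second-order auto-cumulant, mean of δr(t)·δr(t+1), with negative values
clamped to zero (a signed map is not displayable as intensity; the lag is
configurable). AVG is linear in the input; VAR and TAC2 scale
quadratically and ignore per-pixel temporal constants; TAC2 alone is
sensitive to frame order. Rolling-window reconstruction emits
⌊(T−window)/stride⌋+1 images; the default stride is window/10 rounded up,
and the window should come from the tSSIM estimate when the sample moves.

## Quality metrics

**FRC**: ring-averaged normalized cross-spectrum of two statistically
independent reconstructions (even vs odd raw frames, identical settings).
Rings are one FFT bin of the short axis wide; a Hann apodization (default
on) suppresses border leakage and never changes the identical-image case.
Resolution is the inverse frequency of the first crossing below the 1/7
threshold, linearly interpolated between rings, floored at twice the
output pixel (the Nyquist wavelength) and reported at that cap when the
correlation never drops. Blockwise FRC tiles the image (2×2 by default,
tiles at least 64×64 magnified pixels) and reports mean ± s.d.

**RSP/RSE**: the super-resolved image is blurred with a Gaussian
resolution-scaling function whose width is fitted by a bounded 1-D search
(0 to 10 output pixels - the lower bound includes the delta kernel so an
image identical to its reference scores exactly 1), maximizing the Pearson
correlation with the reference (the wide-field temporal mean interpolated
to the magnified grid). Scale and offset are closed-form least squares and
enter only the RMS error.

**QnR** = 2·RSP·nFRC/(RSP+nFRC), with RSP clipped to [0,1] and nFRC the
per-sweep min-max normalization of the FRC resolution (best cell → 1,
worst → 0; a degenerate sweep where all cells tie maps to 1). An
absolute normalization anchored at fixed resolutions was considered and
rejected: the sweep's purpose is ranking within one dataset. The sweep
keeps every cell's reconstruction retrievable for visual inspection -
the score is an aid, not a verdict.

**tSSIM**: SSIM (Gaussian window σ = 1.5 px, K₁ = 0.01, K₂ = 0.03,
dynamic range from the stack's global min/max) of each frame against the
first. The usable window is the longest *initial* run with SSIM at or
above 0.8× the median over the earliest 5% of frames - the first
sustained crossing, not the literal last frame above threshold, because a
transient dip-and-recovery still means motion happened and a window
spanning it would blur.

## Simulators

Two-state telegraph blinking with exponential dwell times (k_on: off→on,
k_off: on→off); the initial state is drawn from the stationary
distribution k_on/(k_on+k_off) to avoid transient bias in short runs. The
photobleaching time is drawn from Exp(k_bleach) on the wall clock but
takes effect only from an on state: a draw landing in an off interval
defers to the next on-state entry, which then emits nothing. Both the
drawn and the realized bleach times are recorded; survival statistics
refer to the drawn exponential. Camera binning integrates on-time over
each exposure window; the read-time gap between exposures contributes
nothing, and transitions mid-frame appear as fractional photon yields.

Rendering places rate·exposure·on-fraction expected photons per emitter as
an analytically pixel-integrated Gaussian (no nearest-pixel stamping),
then applies Poisson photon noise, Gaussian read noise (default σ = 1
count), and a camera offset (default 100 counts). The default photon rate
in `BlinkKinetics` is 15 photons/s; the studies pass 15 000 photons/s
(150 per 10 ms frame, a realistic single-fluorophore budget giving peak
signal-to-noise ≈ 4 over the Poisson floor). Multiplane rendering images
every emitter into every plane through a defocus width-growth model,
σ(δz)² = σ₀²(1+(δz/z_R)²) with z_R = ρσ₀, conserving total flux per plane
(wide-field detection): in-focus planes show tight bright spots, defocused
planes flat haze. Defocus widths are quantized to 0.1 nm so emitters at
similar depths batch into single rendering passes.

What the simulators deliberately do not model: vectorial or aberrated
PSFs, EMCCD gain-register noise, sCMOS pixel-dependent noise maps, sample
drift, background autofluorescence gradients. Tests passing on these
phantoms therefore demonstrate the reconstruction machinery and its
statistical behavior, not robustness to every real-world artifact.

## The phantom studies and their problem sizes

`two_filament_study`: two parallel emitter lines (default 150 nm apart,
1 emitter / 50 nm) with photoswitching kinetics k_on = 2, k_off = 20 s⁻¹
(9% duty cycle, ~2-frame on-dwell - the fluctuation-contrast regime of
photoswitchable labels), 300 frames at 10 ms, reconstructed at M=4,
R=1.5, S=4, VAR. The choice of sparse-ish kinetics is physics, not
tuning: a near-continuously emitting line pair (duty 2/3) carries no
temporal fluctuation for the variance to exploit, and the reconstruction
then merges the pair regardless of frame count. The dip is measured on
the cross-profile averaged along the central half of the filaments.

`woodpile_axial_resolution`: per candidate separation, one pair of
orthogonal filaments (1 emitter / 100 nm) crossing at ±sep/2 around the
center of a 9-plane, 390 nm-spaced multifocal acquisition on a 16×16 px
(100 nm) field; slow photoswitching kinetics k_on = 0.026, k_off = 1.82,
k_bleach = 0.077 s⁻¹; 10 ms exposure + 5 ms read; 2000 frames;
reconstruction with M=4, R=3, S=6, VAR at Mz = 3, ρ = 2.5, restricted to
two one-pixel-wide strips along the filament arms (±600 nm from the
crossing) - the only voxels the measurement needs, which is what makes a
2000-frame 3D study run in minutes on one core. Each arm's axial profile
averages many emitters, so the measurement does not hinge on the few
molecules at the crossing switching on; the per-arm profiles are
normalized to their maxima before combining (the two arms' variance
amplitudes differ by up to an order of magnitude depending on which
molecules blinked), and an arm with no signal above the noise floor
(peak < 10× median) marks the separation unresolved. A separation counts
as resolved when the combined profile shows two maxima at the expected
depths with a ≥ 10% relative dip. Separations are scanned ascending with
early exit: the first resolved separation is the result.

`escalated_density`: independent two-state emitters at a stationary
on-density of 0.121 µm⁻²·frame⁻¹; summing 100-frame windows multiplies
the apparent density by 100 (to 12.1) - the arithmetic of temporal
binning used to escalate sparse data into the high-density regime.

## Registration

Multiplane alignment is translation-only (per the multifocal optics'
residual errors; magnification or rotation differences are out of scope):
phase correlation of each plane against the central plane, band-limited to
half Nyquist before whitening (diffraction-limited images have no
structure near Nyquist, and whitened noise there would dilute the peak),
with 3-point quadratic subpixel refinement per axis. A plane whose
correlation peak does not stand 3× above the off-peak upper envelope
(99th percentile) raises a low-confidence error; the mean residual shift
after applying the registration is reported. Integer shifts relocate
pixels exactly; subpixel shifts are spectral phase ramps, conserving
per-plane flux.

## Known limitations

* The RGC weighting-function family and exponent are one concrete choice
  of ring weighting; other monotone ring shapes change absolute RGC
  values (not peak positions).
* VAR reconstructions have a nonzero noise floor: noise gradients
  occasionally align by chance, so empty regions carry small positive
  variance; quantitative intensity interpretation of the output is not
  supported (fluctuation reconstructions are maps, not photon counts).
* The 3D axial sampling at Mz = 3 quantizes axial profiles to 130 nm;
  sub-voxel peak positions are not refined.
* Periodic lateral interpolation wraps content across edges; the flagged
  edge border should be excluded from measurements.
* tSSIM compares to the first frame; very long acquisitions with slow
  global drift are better served by a sliding reference, which is not
  implemented.
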