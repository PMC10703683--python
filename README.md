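# esrrf

Fluctuation-based live-cell super-resolution reconstruction (eSRRF:
enhanced super-resolution radial fluctuations), in 2D and 3D, with
data-driven reconstruction-parameter optimization and the
blinking-fluorophore simulators needed to test everything without
external data.

## The problem

Live-cell super-resolution has to work with what gentle imaging provides:
a time series of diffraction-limited frames in which fluorophores blink.
Each frame hides emitter positions under a point-spread function (PSF)
hundreds of nanometres wide, but the temporal *fluctuations* of intensity
carry sub-diffraction information. This package reconstructs a
super-resolved image from such a series, for anyone who has a widefield /
TIRF / light-sheet / spinning-disk stack of a blinking or fluctuating
label and wants resolution beyond the diffraction limit without
single-molecule localization hardware.

## The method

Every raw frame is upsampled by band-limited (Fourier) interpolation to a
grid magnified M-fold, intensity gradients *Gx*, *Gy* are computed there,
and each magnified pixel *c* receives a **radial gradient convergence**
(RGC) score - a weighted vote of how precisely the surrounding gradients
point at it:

```
RGC(c) = [ Σᵢ w(dᵢ) · Dᵢ / Σᵢ w(dᵢ) ]^S ,    Dᵢ = max(0, 1 − d⊥ᵢ/dᵢ)
```

where the sum runs over neighbor pixels *pᵢ* within 2*R* of *c*
(*R* in raw pixels, matched to the PSF size), *d⊥ᵢ* is the perpendicular
distance from *c* to the gradient line through *pᵢ*, gradients pointing
away from *c* contribute nothing, and the ring-shaped weight
`w(d) = [(d/σ_w)·exp(−d²/2σ_w²)]⁴` with `σ_w = R/2.355` concentrates the
vote on the PSF flank. The sensitivity exponent *S* sharpens the map.
The per-frame RGC stack is compressed along time into the super-resolved
image: mean (**AVG**), population variance (**VAR**), or lag-1
auto-cumulant (**TAC2**). In 3D, multiplane (multifocus-microscopy)
volumes get the same construction with an anisotropic distance
`d² = dx² + dy² + (δz/ρ)²` that accounts for the axially elongated PSF.

Choosing (R, S) is data-driven: the **QnR** score

```
QnR = 2·RSP·nFRC / (RSP + nFRC)
```

balances reconstruction fidelity (RSP - the resolution-scaled Pearson
correlation against the wide-field mean) against FRC resolution
(Fourier ring correlation of even/odd-frame half reconstructions,
min-max normalized to nFRC ∈ [0,1]); a sweep over the (R, S) grid reports
each cell and the argmax. A temporal structural-similarity trace
(**tSSIM**) bounds the frame window usable before sample motion blurs the
reconstruction.

The `simulate` module generates all test inputs: fan-pattern /
filament-pair / 3D woodpile phantoms, continuous-time two-state blinking
with photobleaching, camera-frame binning with dead time, pixel-integrated
Gaussian PSF rendering with Poisson and read noise, and 9-plane
multifocal acquisition through a defocus-elongated PSF.

## Worked example

```bash
python examples/01_filament_pair_reconstruction.py
```

```
filament separation:        150 nm
reconstruction ridge dip:   0.73
wide-field ridge dip:       -0.01
```

Two emitter lines 150 nm apart (PSF σ = 0.21·580/1.4 = 87 nm, so the pair
is far below the diffraction limit) are simulated with photoswitching
blinking and reconstructed with M=4, R=1.5, S=4, VAR. The cross-profile of
the reconstruction drops 73% between the two ridges - they are cleanly
separated - while the wide-field mean of the same frames shows a single
unresolved ridge (dip ≈ 0). The other scripts in `examples/` demonstrate
the QnR parameter sweep, the tSSIM window estimate, 3D multiplane
reconstruction, and rolling-window time series, each printing the numbers
it computes.

As a library:

```python
from esrrf import ImageStack, ReconstructionSettings, reconstruct
stack = ImageStack(frames, pixel_size=100.0, frame_interval=0.01)
sr = reconstruct(stack, ReconstructionSettings(magnification=4, radius=1.5,
                                               sensitivity=4.0,
                                               temporal_mode="VAR"))
```

A thin CLI covers the same ground from a shell:
`esrrf reconstruct|reconstruct3d|sweep|tssim|register|simulate --help`.

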