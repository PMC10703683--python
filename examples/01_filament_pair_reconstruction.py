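"""Resolve two filaments 150 nm apart - below the diffraction limit.

Simulates two parallel emitter lines separated by 150 nm, blinking with
photoswitching kinetics, imaged through a sigma = 87 nm Gaussian PSF
(0.21 * 580 nm / 1.4 NA) on 100 nm camera pixels, then reconstructs with
the radial-gradient-convergence pipeline (M=4, R=1.5, S=4, VAR) and
compares the cross-profile against the diffraction-limited wide-field mean.
"""

from esrrf.studies import two_filament_study

result = two_filament_study(separation=150.0, seed=0, n_frames=300)

print(f"filament separation:        {result.separation:.0f} nm")
print(f"reconstruction ridge dip:   {result.dip_sr:.2f}")
print(f"wide-field ridge dip:       {result.dip_widefield:.2f}")
print()
print("The reconstruction shows two ridges with a pronounced relative dip")
print("between them (>= 0.2 means clearly separated), while the wide-field")
print("mean shows essentially none (~0): the pair is unresolvable at the")
print("diffraction limit but separated by the fluctuation analysis.")
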