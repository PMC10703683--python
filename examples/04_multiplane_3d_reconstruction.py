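"""3D reconstruction of a multiplane (MFM-style) acquisition.

Simulates a pair of orthogonal filaments crossing at a 400 nm axial
distance, imaged simultaneously on nine focal planes 390 nm apart through
a defocus-elongated Gaussian PSF, with slow photoswitching kinetics
(k_on = 0.026, k_off = 1.82, k_bleach = 0.077 s^-1) and 10 ms exposure /
5 ms read camera timing. The 3D radial-gradient-convergence reconstruction
(M = 4, R = 3, S = 6, VAR) is probed along the axial direction at the
crossing: two distinct maxima mean the axial distance is resolved.

A short run (500 frames) for demonstration; the full-scale study lives in
scripts/acceptance.py.
"""

import numpy as np

from esrrf.studies import woodpile_axial_resolution

result = woodpile_axial_resolution(separations=(400.0,), seed=0, n_frames=500)

sep = result.separations_tested[0]
profile = result.profiles[sep]
dip = result.dips[0]

print(f"axial filament separation:  {sep:.0f} nm")
print(f"axial profile (130 nm voxels, normalized):")
for i, v in enumerate(profile):
    print(f"  z[{i:2d}]  {v:6.3f}  " + "#" * int(40 * v / profile.max()))
print(f"inter-peak dip:             {dip:.2f}")
print()
print("A dip >= 0.10 between two axial maxima means the reconstruction")
print("separates the filament pair along z - inside the classical axial")
print("diffraction limit of this geometry.")
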