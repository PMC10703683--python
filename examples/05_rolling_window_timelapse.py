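"""Super-resolved time series by rolling-window reconstruction.

A reconstruction needs a window of raw frames; overlapping windows turn one
long acquisition into a super-resolved movie at a sampling rate set by the
stride. Here a moving emitter is tracked: each window yields one frame of
the super-resolved time series, and the reconstructed peak follows the
ground-truth path.
"""

import numpy as np

from esrrf import CameraModel, PSFModel, ReconstructionSettings, rolling_reconstruct
from esrrf.simulate import diffusing_particle

camera = CameraModel(exposure=0.010, read_time=0.0, offset=100.0, read_noise=1.0)
stack, path = diffusing_particle(speed=1000.0, direction=(1.0, 0.0),
                                 duration=2.0, psf=PSFModel(), camera=camera,
                                 seed=0, photon_rate=15000.0)

settings = ReconstructionSettings(magnification=4, radius=1.5, sensitivity=4.0,
                                  temporal_mode="AVG")
window, stride = 50, 25
images = rolling_reconstruct(stack, settings, window=window, stride=stride)

print(f"{stack.n_frames} raw frames -> {len(images)} rolling reconstructions "
      f"(window {window}, stride {stride})")
print(f"effective sampling: {1.0 / (stride * camera.frame_interval):.1f} Hz")
for k, img in enumerate(images):
    j = int(np.unravel_index(np.argmax(img.pixels), img.pixels.shape)[1])
    mid = (img.window[0] + img.window[1]) / 2
    true_x = path[int(mid), 0]
    est_x = (j / settings.magnification + 0.5) * camera.pixel_size
    print(f"  window {img.window}: peak x = {est_x:6.0f} nm  "
          f"(truth at mid-window: {true_x:6.0f} nm)")
print()
print("Each rolling window localizes the moving emitter near its mid-window")
print("ground-truth position; the stride sets the output frame rate.")
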