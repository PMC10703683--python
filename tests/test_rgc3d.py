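"""Volumetric RGC, multiplane registration, and 2D/3D consistency."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from esrrf import (
    GroundTruthScene,
    ImageStack,
    CameraModel,
    PSFModel,
    ReconstructionSettings,
    Settings3D,
    VolumeStack,
    apply_registration,
    reconstruct3d,
    register_planes,
    rgc_stack,
)
from esrrf.errors import InvalidInputError, InvalidParameterError, LowConfidenceError
from esrrf.simulate import BlinkTrace, render_mfm

from conftest import always_on_trace


def _bead_plane(rng, n_beads=6, size=64):
    img = np.zeros((size, size))
    for y, x in rng.integers(8, size - 8, (n_beads, 2)):
        img[y, x] = 1000.0
    return gaussian_filter(img, 2.0)


class TestRegistration:
    def test_known_integer_shift_recovered(self, rng):
        base = _bead_plane(rng)
        stack = np.stack([np.roll(base, (3, -2), axis=(0, 1)), base, base])
        reg = register_planes(stack, reference_plane=1)
        assert reg.shifts[0] == pytest.approx((3.0, -2.0), abs=0.1)
        assert reg.shifts[1] == pytest.approx((0.0, 0.0))

    def test_zero_shift_stack(self, rng):
        base = _bead_plane(rng)
        reg = register_planes(np.stack([base, base, base]))
        assert np.abs(reg.shifts).max() < 1e-6
        assert reg.residual_error < 0.05

    def test_featureless_plane_raises_low_confidence(self, rng):
        base = _bead_plane(rng)
        with pytest.raises(LowConfidenceError):
            register_planes(np.stack([base, rng.random((64, 64)), base]),
                            reference_plane=2)

    def test_apply_identity_is_noop(self, rng):
        from esrrf import PlaneRegistration

        vol = rng.random((3, 16, 16))
        reg = PlaneRegistration(shifts=np.zeros((3, 2)), reference_plane=1)
        assert np.allclose(apply_registration(vol, reg), vol)

    def test_apply_shift_roundtrip(self, rng):
        from esrrf import PlaneRegistration

        vol = np.stack([gaussian_filter(rng.random((32, 32)), 1.5, mode="wrap")
                        for _ in range(2)])
        reg = PlaneRegistration(shifts=np.array([[1.2, -0.8], [0.0, 0.0]]),
                                reference_plane=1)
        inv = PlaneRegistration(shifts=-reg.shifts, reference_plane=1)
        out = apply_registration(apply_registration(vol, reg), inv)
        assert np.abs(out - vol).max() < 1e-5

    def test_integer_shift_is_exact_relocation(self, rng):
        from esrrf import PlaneRegistration

        vol = rng.random((2, 16, 16))
        reg = PlaneRegistration(shifts=np.array([[2.0, -3.0], [0.0, 0.0]]),
                                reference_plane=1)
        out = apply_registration(vol, reg)
        assert np.abs(out[0] - np.roll(vol[0], (-2, 3), axis=(0, 1))).max() < 1e-9

    def test_plane_count_mismatch(self, rng):
        from esrrf import PlaneRegistration

        reg = PlaneRegistration(shifts=np.zeros((3, 2)), reference_plane=1)
        with pytest.raises(InvalidInputError):
            apply_registration(rng.random((4, 16, 16)), reg)


class TestReconstruct3D:
    def test_flat_volume_series_is_zero(self):
        vols = VolumeStack(np.full((2, 4, 12, 12), 5.0), pixel_size=100.0,
                           dz=390.0)
        settings = Settings3D(magnification=2, radius=1.5, sensitivity=2.0,
                              temporal_mode="AVG", axial_magnification=2)
        sr = reconstruct3d(vols, settings)
        assert sr.voxels.max() == 0.0

    def test_single_emitter_localized_in_3d(self):
        scene = GroundTruthScene(coords=[[800.0, 800.0, 100.0]],
                                 extent=(1600.0, 1600.0, 3000.0))
        trace = BlinkTrace(on_intervals=[(0.0, 1.0)], bleach_time_drawn=np.inf,
                           bleach_time=np.inf, duration=1.0)
        cam = CameraModel(exposure=0.010, read_time=0.005, offset=0.0,
                          read_noise=0.0)
        psf = PSFModel(wavelength=650.0, na=1.4, rho=2.5)
        vols = render_mfm(scene, [trace], psf, cam, 0, n_planes=9, dz=390.0,
                          n_frames=2, photon_rate=15000.0, poisson=False,
                          read_noise=False)
        settings = Settings3D(magnification=4, radius=2.0, sensitivity=2.0,
                              temporal_mode="AVG", axial_magnification=3,
                              rho=2.5)
        # reconstruct a generous window around the volume center; the peak
        # position within it is what is under test
        roi = (6, 21, 20, 41, 20, 41)
        sr = reconstruct3d(vols, settings, roi=roi)
        k, i, j = np.unravel_index(np.argmax(sr.voxels), sr.voxels.shape)
        k, i, j = k + roi[0], i + roi[2], j + roi[4]
        # raw px (8, 8) -> magnified (30, 30); z = +100 nm above the central
        # plane -> axial voxel 3 * (4 + 100/390) = 12.8
        assert abs(i - 30) <= 1 and abs(j - 30) <= 1
        assert abs(k - 12.8) <= 1.5

    def test_isotropic_spot_axis_permutation_invariance(self):
        # rho = 1 and cubic voxels: the transform must treat all axes alike
        n = 13
        zz, yy, xx = np.mgrid[:n, :n, :n].astype(float)
        c = n // 2
        vol = 50.0 * np.exp(-((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) / (2 * 1.5 ** 2))
        vols = VolumeStack(vol[None], pixel_size=100.0, dz=100.0)
        settings = Settings3D(magnification=1, radius=2.0, sensitivity=2.0,
                              temporal_mode="AVG", axial_magnification=1,
                              rho=1.0)
        sr = reconstruct3d(vols, settings)
        v = sr.voxels
        assert np.abs(v - v.transpose(1, 0, 2)).max() / v.max() < 1e-6
        assert np.abs(v - v.transpose(2, 1, 0)).max() / v.max() < 1e-6

    def test_central_plane_matches_2d_when_axial_terms_vanish(self,
                                                              gaussian_spot_frame):
        # a z-constant volume with rho -> inf: every axial neighbor sees the
        # same lateral geometry, so the 3D sum reduces to the 2D sum plane
        # by plane
        frame = gaussian_spot_frame
        vol = np.repeat(frame[None], 5, axis=0)
        vols = VolumeStack(vol[None], pixel_size=100.0, dz=390.0)
        # native grid (M = Mz = 1): the volume stays exactly z-constant, so
        # the axial gradient is exactly zero and only geometry is under test
        settings3 = Settings3D(magnification=1, radius=1.5, sensitivity=2.0,
                               temporal_mode="AVG", axial_magnification=1,
                               rho=1e8)
        sr3 = reconstruct3d(vols, settings3)
        settings2 = ReconstructionSettings(magnification=1, radius=1.5,
                                           sensitivity=2.0)
        m2 = rgc_stack(ImageStack(frame[None], 100.0), settings2).maps[0]
        central = sr3.voxels[2]
        denom = max(m2.max(), 1e-30)
        assert np.abs(central - m2).max() / denom < 1e-6

    def test_axial_neighborhood_too_small(self):
        vols = VolumeStack(np.random.default_rng(0).random((1, 2, 12, 12)),
                           pixel_size=100.0, dz=390.0)
        settings = Settings3D(magnification=2, radius=1.5, sensitivity=2.0,
                              temporal_mode="AVG", axial_magnification=1)
        with pytest.raises(InvalidParameterError):
            reconstruct3d(vols, settings)

    def test_axial_resolution_gain_over_widefield(self):
        # a single filament imaged through 9 defocus-elongated planes: the
        # reconstruction's axial FWHM must beat the interpolated wide-field
        scene = GroundTruthScene(
            coords=[[x, 800.0, 0.0] for x in np.arange(200.0, 1500.0, 100.0)],
            extent=(1600.0, 1600.0, 3200.0))
        traces = [always_on_trace(1.0)] * scene.n_emitters
        cam = CameraModel(exposure=0.010, read_time=0.005, offset=0.0,
                          read_noise=0.0)
        psf = PSFModel(wavelength=650.0, na=1.4, rho=2.5)
        vols = render_mfm(scene, traces, psf, cam, 0, n_planes=9, dz=390.0,
                          n_frames=1, photon_rate=15000.0, poisson=False,
                          read_noise=False)
        settings = Settings3D(magnification=4, radius=3.0, sensitivity=6.0,
                              temporal_mode="AVG", axial_magnification=3,
                              rho=2.5)
        roi = (3, 24, 30, 31, 20, 41)
        sr = reconstruct3d(vols, settings, roi=roi, rel_weight_min=1e-6)
        prof_sr = sr.voxels.mean(axis=(1, 2))
        from esrrf.interpolation import fourier_interpolate_volume

        wf = fourier_interpolate_volume(vols.frames[0], 4, 3)
        prof_wf = wf[3:24, 30, 20:41].mean(axis=1)

        def fwhm(profile):
            above = np.nonzero(profile >= profile.max() / 2)[0]
            return above[-1] - above[0] + 1

        assert fwhm(prof_sr) < fwhm(prof_wf)

    def test_registration_commutes_with_reconstruction_for_integer_shift(self):
        from esrrf import PlaneRegistration

        rng = np.random.default_rng(2)
        base = gaussian_filter(rng.random((4, 16, 16)), (0, 1.0, 1.0),
                               mode="wrap") * 100
        shift = np.zeros((4, 2))
        shift[1] = (2.0, -1.0)
        reg = PlaneRegistration(shifts=shift, reference_plane=0)
        vols_shifted = VolumeStack(
            np.stack([np.stack([np.roll(base[p], (int(shift[p, 0]),
                                                  int(shift[p, 1])), (0, 1))
                                for p in range(4)])]),
            pixel_size=100.0, dz=200.0)
        settings = Settings3D(magnification=2, radius=1.0, sensitivity=2.0,
                              temporal_mode="AVG", axial_magnification=2)
        sr_reg = reconstruct3d(vols_shifted, settings, registration=reg)
        vols_clean = VolumeStack(base[None], pixel_size=100.0, dz=200.0)
        sr_clean = reconstruct3d(vols_clean, settings)
        b = settings.edge_border + 4
        interior = (slice(None), slice(b, -b), slice(b, -b))
        denom = max(sr_clean.voxels.max(), 1e-30)
        assert (np.abs(sr_reg.voxels[interior] - sr_clean.voxels[interior]).max()
                / denom) < 1e-4
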