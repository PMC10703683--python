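"""Phantom geometry, blinking kinetics, camera binning, and rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from esrrf import (
    BlinkKinetics,
    CameraModel,
    GroundTruthScene,
    ImageStack,
    PSFModel,
    bin_frames,
    bin_trace,
    blink_trace,
    diffusing_particle,
    fan_pattern,
    filament_pair,
    psf_sigma,
    render_frames,
    render_mfm,
    woodpile,
)
from esrrf.errors import InvalidInputError, InvalidParameterError
from esrrf.simulate import BlinkTrace

from conftest import always_on_trace


# --------------------------------------------------------------------------
# PSF

def test_psf_sigma_values():
    assert psf_sigma(580.0, 1.4) == pytest.approx(87.0)
    assert psf_sigma(1160.0, 1.4) == pytest.approx(2 * psf_sigma(580.0, 1.4))
    assert psf_sigma(580.0, 2.8) == pytest.approx(psf_sigma(580.0, 1.4) / 2)
    with pytest.raises(InvalidParameterError):
        psf_sigma(-1.0, 1.4)


# --------------------------------------------------------------------------
# geometries

def test_fan_pattern_ring_geometry():
    scene = fan_pattern()
    center = np.asarray(scene.meta["center"])
    radii = np.hypot(*(scene.coords - center).T)
    unique_radii = np.sort(np.unique(np.round(radii, 6)))
    assert np.allclose(unique_radii, 220.0 * np.arange(1, 7))
    n_inner = int(np.sum(np.isclose(radii, 220.0)))
    arc = 2 * math.pi * 220.0 / n_inner
    # evenly spaced at the requested separation up to count rounding
    assert arc == pytest.approx(57.5, abs=57.5 / n_inner)


def test_fan_pattern_invalid_params():
    with pytest.raises(InvalidParameterError):
        fan_pattern(ring_step=0.0)
    with pytest.raises(InvalidParameterError):
        fan_pattern(separations=[])


def test_filament_pair_geometry():
    scene = filament_pair(separation=150.0, length=1000.0, linear_density=0.02)
    ys = np.unique(scene.coords[:, 1])
    assert len(ys) == 2
    assert ys[1] - ys[0] == pytest.approx(150.0)
    assert scene.n_emitters == 2 * 20


def test_woodpile_geometry_and_density():
    seps = [350.0, 400.0, 450.0, 500.0, 550.0, 600.0]
    scene = woodpile(seps, lateral_spacing=2000.0, emitter_linear_density=0.02,
                     filament_length=1000.0)
    assert len(scene.meta["crossings"]) == 6
    zs = np.unique(scene.coords[:, 2])
    # each pair contributes z = -s/2 and +s/2
    assert np.allclose(sorted(np.unique(np.abs(zs)) * 2), seps)
    # 0.02 nm^-1 on a 1 um filament -> 20 emitters per filament
    assert scene.n_emitters == 6 * 2 * 20


def test_woodpile_invalid_params():
    with pytest.raises(InvalidParameterError):
        woodpile([350.0], emitter_linear_density=0.0)
    with pytest.raises(InvalidParameterError):
        woodpile([50.0])  # below the supported separation range
    with pytest.raises(InvalidParameterError):
        woodpile([350.0], filament_length=0.0)


# --------------------------------------------------------------------------
# kinetics

def test_blink_trace_never_on_when_kon_zero():
    kin = BlinkKinetics(k_on=0.0, k_off=1.0, k_bleach=0.0)
    trace = blink_trace(kin, 10.0, 0)
    assert trace.on_intervals == []


def test_blink_trace_stationary_on_fraction():
    # long-run on-fraction equals k_on / (k_on + k_off)
    kin = BlinkKinetics(k_on=0.026, k_off=1.82, k_bleach=0.0)
    duration = 2000.0
    n = 400
    rng = np.random.default_rng(7)
    fractions = [blink_trace(kin, duration, rng).total_on_time / duration
                 for _ in range(n)]
    duty = kin.duty_cycle
    se = np.std(fractions, ddof=1) / math.sqrt(n)
    assert abs(np.mean(fractions) - duty) < 3 * se + 1e-12


def test_blink_trace_bleach_survival():
    kin = BlinkKinetics(k_on=0.026, k_off=1.82, k_bleach=0.077)
    rng = np.random.default_rng(8)
    n = 2000
    t_ref = 1.0 / kin.k_bleach
    drawn = [blink_trace(kin, 5.0, rng).bleach_time_drawn for _ in range(n)]
    frac = np.mean([t > t_ref for t in drawn])
    p = math.exp(-1.0)
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_blink_trace_reproducible_under_seed():
    kin = BlinkKinetics(k_on=1.0, k_off=5.0, k_bleach=0.1)
    t1 = blink_trace(kin, 20.0, 42)
    t2 = blink_trace(kin, 20.0, 42)
    assert t1.on_intervals == t2.on_intervals
    assert t1.bleach_time_drawn == t2.bleach_time_drawn


def test_blink_intervals_are_ordered_and_within_duration():
    kin = BlinkKinetics(k_on=2.0, k_off=10.0, k_bleach=0.2)
    rng = np.random.default_rng(3)
    for _ in range(50):
        tr = blink_trace(kin, 5.0, rng)
        last = 0.0
        for t0, t1 in tr.on_intervals:
            assert 0.0 <= t0 <= t1 <= 5.0 + 1e-12
            assert t0 >= last
            last = t1
        if math.isfinite(tr.bleach_time):
            assert all(t1 <= tr.bleach_time + 1e-12 for _, t1 in tr.on_intervals)


# --------------------------------------------------------------------------
# camera binning

def test_bin_trace_partial_exposure():
    cam = CameraModel(exposure=0.010, read_time=0.005)
    tr = BlinkTrace(on_intervals=[(0.002, 0.006)], bleach_time_drawn=np.inf,
                    bleach_time=np.inf, duration=0.03)
    fr = bin_trace(tr, cam, 2)
    assert fr[0] == pytest.approx(0.4)
    assert fr[1] == 0.0


def test_bin_trace_always_on_and_read_gap():
    cam = CameraModel(exposure=0.010, read_time=0.005)
    tr = always_on_trace(0.15)
    assert np.allclose(bin_trace(tr, cam, 10), 1.0)
    # an interval falling entirely in the read gap contributes nothing
    tr_gap = BlinkTrace(on_intervals=[(0.011, 0.014)], bleach_time_drawn=np.inf,
                        bleach_time=np.inf, duration=0.03)
    assert np.allclose(bin_trace(tr_gap, cam, 2), 0.0)


def test_bin_trace_transition_at_exposure_boundary():
    cam = CameraModel(exposure=0.010, read_time=0.005)
    # on exactly from the end of exposure 0 through the start of exposure 1
    tr = BlinkTrace(on_intervals=[(0.010, 0.017)], bleach_time_drawn=np.inf,
                    bleach_time=np.inf, duration=0.03)
    fr = bin_trace(tr, cam, 2)
    assert fr[0] == pytest.approx(0.0)
    assert fr[1] == pytest.approx(0.2)  # overlap [0.015, 0.017] of 10 ms


def test_bin_trace_duration_too_short():
    cam = CameraModel(exposure=0.010, read_time=0.005)
    with pytest.raises(InvalidInputError):
        bin_trace(always_on_trace(0.05), cam, 10)


@hyp_settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2 ** 16))
def test_bin_trace_fractions_bounded(seed):
    kin = BlinkKinetics(k_on=5.0, k_off=20.0, k_bleach=1.0)
    cam = CameraModel(exposure=0.010, read_time=0.005)
    tr = blink_trace(kin, 1.0, seed)
    fr = bin_trace(tr, cam, 60)
    assert np.all(fr >= 0.0) and np.all(fr <= 1.0)
    assert fr.sum() * cam.exposure <= tr.total_on_time + 1e-9


# --------------------------------------------------------------------------
# rendering

def test_render_zero_photon_rate_is_background_only(single_emitter_scene, rng):
    cam = CameraModel(exposure=0.010, read_time=0.0, offset=100.0,
                      read_noise=1.0)
    stack = render_frames(single_emitter_scene, [always_on_trace(1.0)],
                          PSFModel(), cam, rng, n_frames=20, photon_rate=0.0)
    assert stack.frames.mean() == pytest.approx(100.0, abs=0.1)


def test_render_flux_conservation(single_emitter_scene, noiseless_camera):
    stack = render_frames(single_emitter_scene, [always_on_trace(1.0)],
                          PSFModel(), noiseless_camera, 0, n_frames=2,
                          photon_rate=15000.0, poisson=False, read_noise=False)
    expected = 15000.0 * noiseless_camera.exposure
    assert stack.frames[0].sum() == pytest.approx(expected, rel=1e-6)


def test_render_poisson_mean_variance(single_emitter_scene):
    cam = CameraModel(exposure=0.010, read_time=0.0, offset=0.0, read_noise=0.0)
    stack = render_frames(single_emitter_scene, [always_on_trace(12.0)],
                          PSFModel(), cam, 123, n_frames=1000,
                          photon_rate=15000.0, read_noise=False)
    mean = stack.frames.mean(axis=0)
    var = stack.frames.var(axis=0)
    bright = mean > 1.0
    ratio = var[bright].sum() / mean[bright].sum()
    assert 0.9 < ratio < 1.1


def test_render_seeded_determinism(single_emitter_scene):
    cam = CameraModel()
    a = render_frames(single_emitter_scene, [always_on_trace(1.0)], PSFModel(),
                      cam, 5, n_frames=3, photon_rate=15000.0)
    b = render_frames(single_emitter_scene, [always_on_trace(1.0)], PSFModel(),
                      cam, 5, n_frames=3, photon_rate=15000.0)
    assert np.array_equal(a.frames, b.frames)


def test_render_out_of_field_warns_and_clips(rng):
    scene = GroundTruthScene(coords=[[2000.0, 800.0]], extent=(1600.0, 1600.0))
    with pytest.warns(UserWarning):
        render_frames(scene, [always_on_trace(1.0)], PSFModel(), CameraModel(),
                      rng, n_frames=1, photon_rate=1000.0)


def test_render_total_photons_track_on_time(noiseless_camera):
    scene = GroundTruthScene(coords=[[800.0, 800.0]], extent=(1600.0, 1600.0))
    kin = BlinkKinetics(k_on=3.0, k_off=10.0, k_bleach=0.0, photon_rate=15000.0)
    rng = np.random.default_rng(11)
    tr = blink_trace(kin, 1.0, rng)
    n_frames = int(1.0 / noiseless_camera.frame_interval)
    stack = render_frames(scene, [tr], PSFModel(), noiseless_camera, rng,
                          n_frames=n_frames, photon_rate=15000.0,
                          poisson=False, read_noise=False)
    rendered = stack.frames.sum()
    on_within_exposures = bin_trace(tr, noiseless_camera, n_frames).sum() \
        * noiseless_camera.exposure
    expected = 15000.0 * on_within_exposures
    assert rendered == pytest.approx(expected, rel=1e-2)


# --------------------------------------------------------------------------
# multiplane rendering

def test_mfm_in_focus_plane_is_brightest(noiseless_camera):
    scene = GroundTruthScene(coords=[[800.0, 800.0, -390.0]],
                             extent=(1600.0, 1600.0, 3200.0))
    vols = render_mfm(scene, [always_on_trace(1.0)], PSFModel(rho=2.5),
                      noiseless_camera, 0, n_planes=9, dz=390.0, n_frames=1,
                      photon_rate=15000.0, poisson=False, read_noise=False)
    peaks = vols.frames[0].max(axis=(1, 2))
    assert peaks.argmax() == 3  # plane 3 focuses at -390 nm


def test_mfm_axial_extent():
    # 9 plane foci at 390 nm spacing span (9-1)*390 = 3120 nm
    n_planes, dz = 9, 390.0
    foci = (np.arange(n_planes) - (n_planes - 1) / 2) * dz
    assert foci.max() - foci.min() == pytest.approx(3120.0)


def test_mfm_defocus_follows_width_growth_model(noiseless_camera):
    # zero-depth scene, rho = 1: neighbor planes see the analytic defocused
    # Gaussian of the width-growth model
    psf = PSFModel(wavelength=580.0, na=1.4, rho=1.0)
    scene = GroundTruthScene(coords=[[800.0, 800.0, 0.0]],
                             extent=(1600.0, 1600.0, 1000.0))
    vols = render_mfm(scene, [always_on_trace(1.0)], psf, noiseless_camera, 0,
                      n_planes=3, dz=100.0, n_frames=1, photon_rate=15000.0,
                      poisson=False, read_noise=False)
    from scipy.special import erf

    def analytic_plane(sigma):
        # pixel-integrated Gaussian, written independently of the renderer
        edges = np.arange(17) * 100.0
        cdf = 0.5 * (1.0 + erf((edges - 800.0) / (np.sqrt(2.0) * sigma)))
        profile = np.diff(cdf)
        return 150.0 * np.outer(profile, profile)

    in_focus = vols.frames[0, 1]
    defocused = vols.frames[0, 0]
    # the renderer quantizes defocus widths to 0.1 nm; allow for that
    tol = 5e-3 * in_focus.max()
    assert np.abs(in_focus - analytic_plane(psf.sigma)).max() < tol
    assert np.abs(defocused - analytic_plane(psf.sigma_at_defocus(100.0))).max() < tol
    # flux is conserved plane to plane (wide-field detection)
    assert defocused.sum() == pytest.approx(in_focus.sum(), rel=1e-3)


def test_mfm_needs_3d_scene_and_two_planes(single_emitter_scene):
    with pytest.raises(InvalidInputError):
        render_mfm(single_emitter_scene, [always_on_trace(1.0)], PSFModel(),
                   CameraModel(), 0, n_frames=1)
    scene3 = GroundTruthScene(coords=[[800.0, 800.0, 0.0]],
                              extent=(1600.0, 1600.0, 1000.0))
    with pytest.raises(InvalidParameterError):
        render_mfm(scene3, [always_on_trace(1.0)], PSFModel(), CameraModel(),
                   0, n_planes=1, n_frames=1)


# --------------------------------------------------------------------------
# moving particle

def test_diffusing_particle_static_and_moving():
    cam = CameraModel(exposure=0.010, read_time=0.0, offset=0.0,
                      read_noise=0.0)
    static, path = diffusing_particle(0.0, (1.0, 0.0), 0.3, PSFModel(), cam, 0)
    assert np.ptp(path, axis=0).max() == 0.0
    speed = 2000.0  # nm/s
    stack, path = diffusing_particle(speed, (1.0, 0.0), 0.5, PSFModel(), cam, 1)
    # centroid displacement per frame matches speed * frame_interval
    disp = np.diff(path[:, 0])
    assert np.allclose(disp, speed * cam.frame_interval)
    cy = [float((f * np.arange(f.shape[1])[None, :]).sum() / f.sum())
          for f in stack.frames[:10]]
    fitted = np.polyfit(np.arange(10), cy, 1)[0] * cam.pixel_size
    assert fitted == pytest.approx(speed * cam.frame_interval, rel=0.1)


def test_diffusing_particle_truncates_at_field_edge():
    cam = CameraModel(exposure=0.010, read_time=0.0)
    with pytest.warns(UserWarning):
        stack, path = diffusing_particle(50000.0, (1.0, 0.0), 10.0, PSFModel(),
                                         cam, 0)
    assert stack.n_frames == len(path)
    assert path[:, 0].max() <= 3200.0


def test_diffusing_particle_short_duration_single_frame():
    cam = CameraModel(exposure=0.010, read_time=0.0)
    stack, path = diffusing_particle(100.0, (1.0, 0.0), 0.005, PSFModel(), cam, 0)
    assert stack.n_frames == 1


# --------------------------------------------------------------------------
# temporal binning (density escalation)

def test_bin_frames_mean_and_sum(rng):
    frames = rng.random((10, 8, 8))
    stack = ImageStack(frames, 100.0)
    binned = bin_frames(stack, 5)
    assert binned.n_frames == 2
    assert np.allclose(binned.frames[0], frames[:5].mean(axis=0))
    summed = bin_frames(stack, 5, reduce="sum")
    assert np.allclose(summed.frames[0], frames[:5].sum(axis=0))
    assert binned.frame_interval == pytest.approx(stack.frame_interval * 5)
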