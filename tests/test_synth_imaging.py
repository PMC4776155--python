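import numpy as np
import pytest

from micskit.stack_io import AcquisitionMeta
from micskit.synth_imaging import (
    MotionModel,
    SceneConfig,
    frame_times,
    line_times,
    mics_acquisition,
    render_frames,
    render_raster,
    simulate_trajectories,
)


@pytest.fixture
def small_cfg():
    meta = AcquisitionMeta(pixel_size=0.1, pixel_dwell=1e-6, line_time=1e-4,
                           frame_interval=0.05, beam_waist=0.25, axial_waist=0.75)
    return SceneConfig(n_particles=5, brightness=20.0, frame_geometry=meta,
                       height=16, width=16, n_frames=10, seed=11, poisson=False)


class TestTrajectories:
    def test_zero_diffusion_is_static(self, small_cfg):
        pos = simulate_trajectories(MotionModel(mode="bound"), small_cfg)
        assert np.all(pos == pos[0])

    def test_diffusion_step_variance(self):
        """Empirical per-axis step variance equals 2 D dt within 5%."""
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=200, brightness=1.0, frame_geometry=meta,
                          height=32, width=256, n_frames=60, seed=5, poisson=False)
        D, dt = 1.0, 1e-3
        times = np.arange(10001) * dt
        pos = simulate_trajectories(MotionModel(mode="diffusion", D=D), cfg, times)
        steps = np.diff(pos, axis=0)
        # exclude wrap jumps (periodic re-entry)
        steps = steps[np.all(np.abs(steps) < 1.0, axis=2)]
        assert steps.var() == pytest.approx(2 * D * dt, rel=0.05)

    def test_directed_mean_displacement(self):
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=2000, brightness=1.0, frame_geometry=meta,
                          height=32, width=256, n_frames=2, seed=6, poisson=False)
        times = np.array([0.0, 1.0])
        model = MotionModel(mode="directed", velocity=(1.0, 0.0), D=0.01)
        pos = simulate_trajectories(model, cfg, times)
        disp = pos[1] - pos[0]
        keep = np.all(np.abs(disp) < 5.0, axis=1)  # drop wrapped particles
        dx, dy = disp[keep, 0], disp[keep, 1]
        assert dx.mean() == pytest.approx(1.0, abs=3 * dx.std() / np.sqrt(keep.sum()))
        assert abs(dy.mean()) < 3 * dy.std() / np.sqrt(keep.sum())

    def test_confined_particles_stay_in_box(self):
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=50, brightness=1.0, frame_geometry=meta,
                          height=32, width=256, n_frames=200, seed=7, poisson=False)
        model = MotionModel(mode="confined_oscillating", D=0.5, box_half_width=0.4,
                            osc_amplitude=0.1, osc_period=2.0)
        pos = simulate_trajectories(model, cfg)
        spread = pos.max(axis=0) - pos.min(axis=0)
        assert np.all(spread[:, 0] <= 2 * 0.4 + 2 * 0.1 + 1e-9)
        assert np.all(spread[:, 1] <= 2 * 0.4 + 1e-9)

    def test_bound_with_residence_relocates(self):
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=100, brightness=1.0, frame_geometry=meta,
                          height=32, width=256, n_frames=200, seed=8, poisson=False)
        pos = simulate_trajectories(MotionModel(mode="bound", residence_time=2.0), cfg)
        moved = np.any(pos[-1] != pos[0], axis=1)
        # 200 frames ~ 10 s >> 2 s residence: nearly every emitter has hopped
        assert moved.mean() > 0.9

    def test_filament_oscillates_perpendicular(self):
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=10, brightness=1.0, frame_geometry=meta,
                          height=32, width=256, n_frames=100, seed=9, poisson=False)
        th = np.deg2rad(30)
        model = MotionModel(mode="filament_oscillating", filament_orientation=th,
                            filament_length=2.0, osc_amplitude=0.3, osc_period=2.0)
        pos = simulate_trajectories(model, cfg)
        # rigid: pairwise distances constant over time
        d01 = np.linalg.norm(pos[:, 0] - pos[:, 1], axis=1)
        np.testing.assert_allclose(d01, d01[0], atol=1e-9)
        # displacement from t=0 is along the perpendicular of the axis
        disp = pos[:, 0] - pos[0, 0]
        along = disp @ np.array([np.cos(th), np.sin(th)])
        np.testing.assert_allclose(along, 0.0, atol=1e-9)
        assert np.abs(disp).max() > 0.1


class TestRendering:
    def test_static_particle_at_pixel_center_gives_psf_profile(self, small_cfg):
        cfg = small_cfg
        px, w0 = cfg.frame_geometry.pixel_size, cfg.waist
        pos = np.full((cfg.n_frames, cfg.n_particles, 2), -50.0)  # park off-field
        pos[:, 0] = (8 * px, 8 * px)  # one emitter at pixel (8, 8) center
        stack = render_frames(pos, cfg)
        frame = stack.frames[0]
        assert frame[8, 8] == pytest.approx(cfg.brightness, rel=1e-9)
        xs = np.arange(cfg.width) * px
        expected = cfg.brightness * np.exp(-2 * (xs - 8 * px) ** 2 / w0 ** 2)
        np.testing.assert_allclose(frame[8, :], expected, atol=1e-9)

    def test_seeded_determinism_bit_identical(self):
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=30, brightness=25.0, frame_geometry=meta,
                          height=32, width=64, n_frames=20, seed=123)
        model = MotionModel(mode="diffusion", D=0.1)
        s1 = render_frames(simulate_trajectories(model, cfg), cfg)
        s2 = render_frames(simulate_trajectories(model, cfg), cfg)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_static_scene_raster_equals_frames(self):
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=20, brightness=25.0, frame_geometry=meta,
                          height=32, width=64, n_frames=10, seed=4)
        model = MotionModel(mode="bound")
        sf = render_frames(simulate_trajectories(model, cfg, frame_times(cfg)), cfg)
        sr = render_raster(simulate_trajectories(model, cfg, line_times(cfg)), cfg)
        np.testing.assert_array_equal(sf.frames, sr.frames)

    def test_photon_conservation_for_confined_motion(self):
        """Without noise, total intensity is constant when emitters stay well
        inside the frame (a centered oscillating filament never approaches
        the edges, so PSF leakage is negligible)."""
        meta = mics_acquisition()
        cfg = SceneConfig(n_particles=30, brightness=10.0, frame_geometry=meta,
                          height=32, width=64, n_frames=50, seed=2, poisson=False)
        model = MotionModel(mode="filament_oscillating", filament_orientation=0.0,
                            filament_length=2.0, osc_amplitude=0.05, osc_period=1.0)
        stack = render_frames(simulate_trajectories(model, cfg), cfg)
        totals = stack.frames.sum(axis=(1, 2))
        assert totals.std() / totals.mean() < 0.01

    def test_wrong_time_base_rejected(self, small_cfg):
        pos = np.zeros((3, small_cfg.n_particles, 2))
        with pytest.raises(ValueError):
            render_frames(pos, small_cfg)
        with pytest.raises(ValueError):
            render_raster(pos, small_cfg)

    def test_fast_diffusion_broadens_raster_correlation(self):
        """The fast-axis correlation of a D=10 stack decays more slowly than
        the static PSF correlation (motion during the scan)."""
        from micskit.rics import spatial_autocorrelation

        meta = AcquisitionMeta(pixel_size=0.08, pixel_dwell=6.3e-6,
                               line_time=1.2 * 64 * 6.3e-6,
                               frame_interval=64 * 1.2 * 64 * 6.3e-6,
                               beam_waist=0.25, axial_waist=0.75)
        profiles = {}
        for D, mode in ((0.0, "bound"), (10.0, "diffusion")):
            cfg = SceneConfig(n_particles=40, brightness=25.0, frame_geometry=meta,
                              height=64, width=64, n_frames=30, seed=3, poisson=False)
            model = MotionModel(mode=mode, D=D)
            stack = render_raster(simulate_trajectories(model, cfg, line_times(cfg)), cfg)
            acc = np.zeros(17)
            for t in range(stack.n_frames):
                g = spatial_autocorrelation(stack.frames[t], 8, 0)
                acc += g[0] / g[0, 8]
            profiles[mode] = acc / stack.n_frames
        # at a few-pixel shift the moving-emitter correlation sits higher
        assert profiles["diffusion"][8 + 4] > profiles["bound"][8 + 4]
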