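import dataclasses
import math

import numpy as np
import pytest

from echophase import (
    PipelineConfig,
    SimulationConfig,
    fit_model,
    normalized_correlation,
    reconstruct,
    render_cycle,
    run_pipeline,
    simulate,
    single_cycle,
)
from echophase.evaluate import _best_circular_offset
from echophase.reconstruct import circular_distance


def brute_force_nadaraya_watson(model, phi):
    """Direct per-frame evaluation of the kernel-weighted average."""
    num = np.zeros_like(model.frames[0])
    den = 0.0
    for t in range(model.n_frames):
        d = abs(phi - model.cardiac_phase[t])
        d = min(d, 1.0 - d)
        w = math.exp(-(d**2) / (2.0 * model.sigma_phi**2))
        if model.kernel == "bivariate":
            dl = model.lowess_model(float(phi)) - model.u_hat[t]
            w *= math.exp(-(dl**2) / (2.0 * model.sigma_L**2))
        if model.include is not None:
            w *= model.include[t]
        num += w * model.frames[t]
        den += w
    return num / den


class TestFitModel:
    def test_sigma_phi_from_median_phase_step(self, pipeline_result):
        fpc = 27.27
        phases = (np.arange(100) / fpc) % 1.0
        track = dataclasses.replace(
            pipeline_result.phase_track,
            cardiac_phase=phases,
            resp_phase=np.zeros(100),
            unwrapped_cardiac=np.arange(100) / fpc,
        )
        from echophase import VideoSequence
        video = VideoSequence(np.random.default_rng(0).random((100, 8, 8)), fps=233.0)
        model = fit_model(
            video, track, pipeline_result.gating,
            u_hat=np.random.default_rng(1).random(100),
        )
        assert model.sigma_phi == pytest.approx(0.4 / fpc, rel=1e-6)

    def test_sigma_phi_close_to_ground_truth_step(self, pipeline_result, default_config):
        expected = 0.4 * default_config.heart_rate / (60.0 * default_config.fps)
        assert pipeline_result.model.sigma_phi == pytest.approx(expected, rel=0.1)

    def test_zero_residuals_trigger_sigma_floor(self, pipeline_result, default_video):
        g = pipeline_result.gating
        phi = pipeline_result.phase_track.cardiac_phase
        u = g.lowess_model(phi)  # residuals identically zero
        model = fit_model(default_video, pipeline_result.phase_track, g, u_hat=u)
        assert model.sigma_L > 0.0

    def test_frozen_video_raises(self, pipeline_result, default_video):
        track = dataclasses.replace(
            pipeline_result.phase_track,
            cardiac_phase=np.full(default_video.n_frames, 0.25),
        )
        with pytest.raises(ValueError, match="frozen"):
            fit_model(default_video, track, pipeline_result.gating,
                      u_hat=np.ones(default_video.n_frames))

    def test_unknown_kernel_rejected(self, pipeline_result, default_video):
        with pytest.raises(ValueError, match="kernel"):
            fit_model(default_video, pipeline_result.phase_track,
                      pipeline_result.gating,
                      u_hat=np.ones(default_video.n_frames), kernel="cubic")


class TestReconstruct:
    def test_identical_frames_reproduced_exactly(self, pipeline_result):
        from echophase import VideoSequence
        frame = np.random.default_rng(3).random((16, 16))
        video = VideoSequence(np.tile(frame, (50, 1, 1)), fps=100.0)
        track = dataclasses.replace(
            pipeline_result.phase_track,
            cardiac_phase=(np.arange(50) * 0.13) % 1.0,
        )
        model = fit_model(video, track, pipeline_result.gating, u_hat=np.ones(50))
        for phi in (0.0, 0.31, 0.77):
            np.testing.assert_allclose(reconstruct(model, phi), frame, atol=1e-12)

    def test_tiny_bandwidth_converges_to_nearest_frame(self, pipeline_result, default_video):
        model = dataclasses.replace(
            pipeline_result.model, sigma_phi=1e-4, kernel="phase-only"
        )
        # pick the frame whose phase is best isolated from every other frame's
        phases = model.cardiac_phase
        gaps = circular_distance(phases[:, None], phases[None, :])
        np.fill_diagonal(gaps, np.inf)
        target = int(gaps.min(axis=1).argmax())
        phi = float(model.cardiac_phase[target])
        np.testing.assert_allclose(
            reconstruct(model, phi), default_video.frames[target], atol=1e-8
        )

    def test_matches_brute_force_definition(self, pipeline_result):
        model = pipeline_result.model
        for phi in (0.0, 0.123, 0.5, 0.987):
            expected = brute_force_nadaraya_watson(model, phi)
            np.testing.assert_allclose(reconstruct(model, phi), expected, atol=1e-10)

    def test_convex_combination_bounds(self, pipeline_result, default_video):
        lo, hi = default_video.frames.min(), default_video.frames.max()
        for phi in np.linspace(0, 1, 7, endpoint=False):
            image = reconstruct(pipeline_result.model, float(phi))
            assert image.min() >= lo - 1e-12
            assert image.max() <= hi + 1e-12

    def test_weights_normalized(self, pipeline_result):
        w = pipeline_result.model.weights(0.4)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0.0)

    def test_continuity_in_phase(self, pipeline_result):
        base = reconstruct(pipeline_result.model, 0.3)
        deltas = [1e-2, 1e-3, 1e-4]
        sups = [
            np.abs(reconstruct(pipeline_result.model, 0.3 + d) - base).max()
            for d in deltas
        ]
        assert sups[0] > sups[1] > sups[2]
        assert sups[2] < 1e-3

    def test_vanishing_total_weight_raises(self, pipeline_result):
        model = dataclasses.replace(pipeline_result.model, sigma_phi=1e-6, sigma_L=1e-9)
        # a phase between two frames' phases is unreachable at these bandwidths
        with pytest.raises(ValueError, match="bandwidth"):
            reconstruct(model, 0.517351)

    def test_out_of_range_phase_rejected(self, pipeline_result):
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            reconstruct(pipeline_result.model, 1.2)


class TestSingleCycle:
    def test_native_magnification_frame_count(self, pipeline_result):
        model = dataclasses.replace(pipeline_result.model, frames_per_cycle=27.27)
        cycle = single_cycle(model, magnification=1.0)
        assert cycle.frames.shape[0] == 27
        assert cycle.phase_grid[0] == 0.0
        assert np.all(np.diff(cycle.phase_grid) > 0)

    def test_magnification_scales_frame_count(self, pipeline_result):
        model = dataclasses.replace(pipeline_result.model, frames_per_cycle=27.27)
        for mag in (2.0, 4.0, 8.0):
            cycle = single_cycle(model, magnification=mag)
            assert cycle.frames.shape[0] == round(mag * 27.27)

    def test_nonpositive_magnification_raises(self, pipeline_result):
        with pytest.raises(ValueError, match="magnification"):
            single_cycle(pipeline_result.model, magnification=0.0)

    def test_pixel_values_within_input_range(self, pipeline_result, default_video):
        cycle = single_cycle(pipeline_result.model, magnification=1.0)
        assert cycle.frames.min() >= default_video.frames.min() - 1e-12
        assert cycle.frames.max() <= default_video.frames.max() + 1e-12


class TestKernelComparison:
    def test_bivariate_beats_phase_only(self, default_config, default_truth, pipeline_result):
        grid = np.arange(27) / 27
        reference = render_cycle(default_config, grid)
        offset = _best_circular_offset(
            pipeline_result.phase_track.cardiac_phase, default_truth.cardiac_phase
        )
        scores = {}
        for kernel in ("bivariate", "phase-only"):
            model = dataclasses.replace(pipeline_result.model, kernel=kernel)
            frames = np.stack(
                [reconstruct(model, float((g + (1.0 - offset)) % 1.0)) for g in grid]
            )
            scores[kernel] = normalized_correlation(frames, reference)
        assert scores["bivariate"] > scores["phase-only"]
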