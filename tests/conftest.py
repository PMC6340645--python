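"""Shared fixtures: the default synthetic video and its pipeline run are
expensive enough to share across the whole session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from echophase import PipelineConfig, SimulationConfig, run_pipeline, simulate

settings.register_profile("repro", database=None, deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_video_truth(default_config):
    return simulate(default_config)


@pytest.fixture(scope="session")
def default_video(default_video_truth):
    return default_video_truth[0]


@pytest.fixture(scope="session")
def default_truth(default_video_truth):
    return default_video_truth[1]


@pytest.fixture(scope="session")
def pipeline_result(default_video):
    return run_pipeline(default_video, PipelineConfig(fps=default_video.fps))


@pytest.fixture(scope="session")
def cardiac_only_config(default_config) -> SimulationConfig:
    """Noiseless, respiration-free: motion from the cardiac source only."""
    return dataclasses.replace(default_config, speckle_level=0.0, resp_amplitude=0.0)


@pytest.fixture(scope="session")
def cardiac_only_video_truth(cardiac_only_config):
    return simulate(cardiac_only_config)


@pytest.fixture(scope="session")
def cardiac_only_result(cardiac_only_video_truth):
    video, _ = cardiac_only_video_truth
    return run_pipeline(video, PipelineConfig(fps=video.fps))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
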