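"""End-to-end pipeline: similarity -> decomposition -> phases -> gating -> model."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

from .config import PipelineConfig
from .decompose import BandSpec, SignalDecomposition, bandlimit, periodogram_entropy, select_row
from .gating import GatingResult, gate
from .phases import PhaseTrack, estimate_phases
from .reconstruct import ReconstructionModel, fit_model
from .similarity import SimilarityMatrix, similarity_matrix
from .video import VideoSequence

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("echophase")


@dataclass(frozen=True)
class PipelineResult:
    """Every intermediate of a full pipeline run."""

    similarity: SimilarityMatrix
    decomposition: SignalDecomposition
    phase_track: PhaseTrack
    gating: GatingResult
    model: ReconstructionModel


def run_pipeline(video: VideoSequence, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage in order on one video.

    Raises at the first failing stage with the stage name and the cause.
    """
    config = config or PipelineConfig(fps=video.fps)
    stages: list[tuple[str, float]] = []

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except ValueError as err:
            raise ValueError(f"pipeline stage {stage!r} failed: {err}") from err
        stages.append((stage, time.perf_counter() - t0))
        logger.info("stage %-14s %.3fs", stage, stages[-1][1])
        return out

    sim = _run("similarity", lambda: similarity_matrix(video))
    decomp = _run(
        "decomposition",
        lambda: select_row(sim, lambda_=config.lambda_, fps=video.fps),
    )
    logger.info(
        "selected row %d (entropy %.4f)",
        decomp.row_index, decomp.entropy_per_row[decomp.row_index],
    )
    bands = BandSpec(
        resp_lowpass_bpm=config.resp_lowpass_bpm,
        heart_band_bpm=tuple(config.heart_band_bpm),
    )
    decomp = _run("bandlimit", lambda: bandlimit(decomp, bands, fps=video.fps))
    track = _run("phases", lambda: estimate_phases(decomp, fps=video.fps))
    gating = _run(
        "gating",
        lambda: gate(
            decomp.u_hat, track,
            c=config.c, k=config.k, one_sided=config.one_sided,
            lowess_fraction=config.lowess_fraction,
            lowess_iterations=config.lowess_iterations,
        ),
    )
    # native cycle length from the cleaned cardiac signal's dominant frequency
    pgram, _ = periodogram_entropy(decomp.r_heart, video.fps)
    f_dom = pgram.dominant_frequency
    fpc = video.fps / f_dom if f_dom > 0 else None
    model = _run(
        "model_fit",
        lambda: fit_model(
            video, track, gating, decomp.u_hat,
            k_phi=config.k_phi, k_L=config.k_L, frames_per_cycle=fpc,
        ),
    )
    return PipelineResult(
        similarity=sim, decomposition=decomp, phase_track=track,
        gating=gating, model=model,
    )
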