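"""Validation protocols: reference phase, error statistics, LOOCV and
downsample-reconstruct experiments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .phases import wrap_events
from .pipeline import run_pipeline
from .reconstruct import circular_distance, reconstruct, single_cycle
from .similarity import normalized_correlation
from .video import VideoSequence

__all__ = [
    "ReferencePhase",
    "PhaseErrorStats",
    "DownsampleResult",
    "ecg_reference_phase",
    "phase_error",
    "r_peak_frame_error",
    "loocv_reconstruction",
    "downsample_experiment",
]


@dataclass(frozen=True)
class ReferencePhase:
    """Reference cardiac phase: linear ramps between consecutive R-peak frames."""

    r_peak_frames: np.ndarray
    phase: np.ndarray
    in_support: np.ndarray  # False before the first / after the last peak


@dataclass(frozen=True)
class PhaseErrorStats:
    """Summary statistics of per-frame circular phase errors."""

    mean: float
    stddev: float
    median: float
    iqr: float
    range: tuple[float, float]
    offset: float = 0.0
    errors: np.ndarray = field(default=None, repr=False)


def ecg_reference_phase(r_peak_frames: np.ndarray, n_frames: int) -> ReferencePhase:
    """Per-frame reference phase by linear interpolation between R-peaks.

    Phase is 0 at each peak frame and ramps linearly to 1 at the next peak;
    frames before the first or after the last peak are flagged out-of-support.
    """
    peaks = np.asarray(r_peak_frames, dtype=float)
    if peaks.size < 2:
        raise ValueError(f"need at least 2 R-peak frames, got {peaks.size}")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("R-peak frames must be strictly increasing")
    t = np.arange(n_frames, dtype=float)
    cycle = np.searchsorted(peaks, t, side="right") - 1
    in_support = (cycle >= 0) & (t < peaks[-1]) | (t == peaks[-1])
    phase = np.zeros(n_frames)
    interior = (cycle >= 0) & (cycle < peaks.size - 1)
    c = cycle[interior]
    phase[interior] = (t[interior] - peaks[c]) / (peaks[c + 1] - peaks[c])
    phase[t == peaks[-1]] = 0.0  # last peak wraps back to 0
    return ReferencePhase(
        r_peak_frames=np.asarray(r_peak_frames, dtype=int),
        phase=phase,
        in_support=in_support,
    )


def _best_circular_offset(estimated: np.ndarray, reference: np.ndarray,
                          n_grid: int = 2048) -> float:
    offsets = np.arange(n_grid) / n_grid
    # mean circular distance for every candidate offset, vectorized
    diff = (estimated[None, :] + offsets[:, None] - reference[None, :]) % 1.0
    errs = np.minimum(diff, 1.0 - diff).mean(axis=1)
    return float(offsets[int(np.argmin(errs))])


def phase_error(
    estimated: np.ndarray,
    reference: ReferencePhase | np.ndarray,
    allow_offset: bool = True,
) -> PhaseErrorStats:
    """Circular distance statistics between estimated and reference phases.

    With ``allow_offset`` a single constant circular offset minimizing the
    mean error is removed first (the estimator carries no absolute phase
    anchor).  Out-of-support frames of a :class:`ReferencePhase` are excluded.
    """
    estimated = np.asarray(estimated, dtype=float)
    if isinstance(reference, ReferencePhase):
        mask = reference.in_support
        ref = reference.phase
    else:
        ref = np.asarray(reference, dtype=float)
        mask = np.ones(ref.size, dtype=bool)
    if estimated.size != ref.size:
        raise ValueError("estimated and reference phase series differ in length")
    if not mask.any():
        raise ValueError("all frames are out of the reference's support")
    est, ref = estimated[mask], ref[mask]
    offset = _best_circular_offset(est, ref) if allow_offset else 0.0
    errors = circular_distance((est + offset) % 1.0, ref)
    q25, q75 = np.percentile(errors, [25, 75])
    return PhaseErrorStats(
        mean=float(errors.mean()),
        stddev=float(errors.std()),
        median=float(np.median(errors)),
        iqr=float(q75 - q25),
        range=(float(errors.min()), float(errors.max())),
        offset=offset,
        errors=errors,
    )


def r_peak_frame_error(
    estimated_cardiac_phase: np.ndarray,
    r_peak_frames: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Frame-localization error of cardiac-cycle onsets.

    Estimated events are the wrap points (local minima) of the estimated
    phase signal.  Each reference R-peak is matched greedily (smallest
    distance first) to an unused estimated event; unmatched reference peaks
    are dropped.  Returns ``(mean, stddev, per-peak absolute errors)``.
    """
    peaks = np.asarray(r_peak_frames, dtype=int)
    if peaks.size < 2:
        raise ValueError(f"need at least 2 reference peaks, got {peaks.size}")
    events = wrap_events(estimated_cardiac_phase)
    if events.size == 0:
        raise ValueError("estimated phase signal contains no wrap events")

    dist = np.abs(peaks[:, None] - events[None, :]).astype(float)
    order = np.argsort(dist, axis=None, kind="stable")
    used_peak = np.zeros(peaks.size, dtype=bool)
    used_event = np.zeros(events.size, dtype=bool)
    errors = []
    for flat in order:
        i, j = divmod(int(flat), events.size)
        if used_peak[i] or used_event[j]:
            continue
        used_peak[i] = used_event[j] = True
        errors.append(dist[i, j])
        if used_peak.all() or used_event.all():
            break
    errors = np.asarray(errors, dtype=float)
    return float(errors.mean()), float(errors.std()), errors


def loocv_reconstruction(
    video: VideoSequence,
    config: PipelineConfig | None = None,
    n_rounds: int = 50,
    seed: int = 0,
    r_peak_frames: np.ndarray | None = None,
) -> dict:
    """Leave-one-out cross-validation of the reconstruction model.

    Each round picks a random non-respiratory frame, holds it out together
    with the frame closest in cardiac phase within every cycle, reconstructs
    the image at the held-out phase from the remaining frames, and scores it
    against the original with normalized correlation.  If reference R-peak
    frames are given, the mean pairwise ncorr among those frames is reported
    as a baseline.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    config = config or PipelineConfig(fps=video.fps)
    result = run_pipeline(video, config)
    phi = result.phase_track.cardiac_phase

    events = wrap_events(phi)
    boundaries = np.concatenate([[0], events, [video.n_frames]])
    cycles = [np.arange(boundaries[i], boundaries[i + 1])
              for i in range(boundaries.size - 1)
              if boundaries[i + 1] > boundaries[i]]
    if len(cycles) < 3:
        raise ValueError(f"too few cardiac cycles for LOOCV ({len(cycles)} < 3)")

    retained = result.gating.retained
    if retained.size == 0:
        raise ValueError("no non-respiratory frames available")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_rounds)
    held_frames = np.empty(n_rounds, dtype=int)
    for r in range(n_rounds):
        t0 = int(rng.choice(retained))
        target = phi[t0]
        holdout = [int(cyc[np.argmin(circular_distance(phi[cyc], target))])
                   for cyc in cycles]
        sub = result.model.excluding(np.asarray(holdout))
        image = reconstruct(sub, float(target))
        scores[r] = normalized_correlation(image, video.frames[t0])
        held_frames[r] = t0

    out = {
        "mean_ncorr": float(scores.mean()),
        "stddev_ncorr": float(scores.std()),
        "scores": scores,
        "held_frames": held_frames,
    }
    if r_peak_frames is not None:
        peaks = np.asarray(r_peak_frames, dtype=int)
        pair_scores = [
            normalized_correlation(video.frames[a], video.frames[b])
            for idx, a in enumerate(peaks)
            for b in peaks[idx + 1:]
        ]
        out["baseline_mean_ncorr"] = float(np.mean(pair_scores))
        out["baseline_stddev_ncorr"] = float(np.std(pair_scores))
    return out


@dataclass(frozen=True)
class DownsampleResult:
    """Scores of the decimate-then-reconstruct experiment for one factor."""

    factor: int
    fps: float
    mean_ncorr: float
    stddev_ncorr: float
    scores: np.ndarray = field(repr=False)
    flagged: bool = False  # fewer than 4 frames per cardiac cycle


def downsample_experiment(
    video: VideoSequence,
    reference_cycle: np.ndarray,
    true_cardiac_phase: np.ndarray,
    config: PipelineConfig | None = None,
    factors: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_starts: int = 7,
    start_window: int = 14,
    seed: int = 0,
) -> list[DownsampleResult]:
    """Decimate, re-run the pipeline, reconstruct the cycle, score vs truth.

    ``reference_cycle`` holds ground-truth frames at evenly spaced phases
    covering [0, 1); ``true_cardiac_phase`` gives the true phase of every
    original frame (used only to align the estimated phase's arbitrary
    constant offset before scoring).  For each factor the decimation is
    repeated from ``n_starts`` random offsets within the first
    ``start_window`` frames.
    """
    if min(factors) < 1:
        raise ValueError("factors must be >= 1")
    config = config or PipelineConfig(fps=video.fps)
    reference_cycle = np.asarray(reference_cycle, dtype=float)
    n_ref = reference_cycle.shape[0]
    grid = np.arange(n_ref) / n_ref
    truth = np.asarray(true_cardiac_phase, dtype=float)

    rng = np.random.default_rng(seed)
    results = []
    for factor in factors:
        window = min(start_window, video.n_frames - 1)
        starts = rng.choice(window, size=min(n_starts, window), replace=False)
        scores, flagged = [], False
        for start in sorted(int(s) for s in starts):
            dec = video.decimate(factor, start=start)
            res = run_pipeline(dec, config.replace(fps=dec.fps))
            if res.model.frames_per_cycle < 4:
                flagged = True
            offset = _best_circular_offset(
                res.phase_track.cardiac_phase, truth[start::factor]
            )
            recon = np.stack([
                reconstruct(res.model, float((g + (1.0 - offset)) % 1.0)) for g in grid
            ])
            scores.append(normalized_correlation(recon, reference_cycle))
        scores = np.asarray(scores)
        results.append(DownsampleResult(
            factor=int(factor), fps=video.fps / factor,
            mean_ncorr=float(scores.mean()), stddev_ncorr=float(scores.std()),
            scores=scores, flagged=flagged,
        ))
    return results
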