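"""Kernel-regression reconstruction of the image at any cardiac phase.

A Nadaraya-Watson estimator whose weight for each frame is the product of a
circular RBF kernel in cardiac phase and an RBF kernel comparing the frame's
similarity value with the LOWESS prediction at the target phase; the second
factor is what suppresses frames with heavy respiratory motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gating import GatingResult, LowessModel, robust_sigma
from .phases import PhaseTrack
from .video import VideoSequence

__all__ = [
    "ReconstructionModel",
    "SingleCycleVideo",
    "circular_distance",
    "fit_model",
    "reconstruct",
    "single_cycle",
]

DEFAULT_K_PHI = 0.4
DEFAULT_K_L = 2.0
_MIN_TOTAL_WEIGHT = 1e-12


def circular_distance(a, b):
    """Distance on the unit phase circle: min(|a-b|, 1-|a-b|)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.minimum(d, 1.0 - d)


@dataclass(frozen=True)
class ReconstructionModel:
    """Fitted Nadaraya-Watson model over the frames of one video."""

    frames: np.ndarray = field(repr=False)
    cardiac_phase: np.ndarray = field(repr=False)
    u_hat: np.ndarray = field(repr=False)
    lowess_model: LowessModel
    sigma_phi: float
    sigma_L: float
    k_phi: float = DEFAULT_K_PHI
    k_L: float = DEFAULT_K_L
    frames_per_cycle: float = 0.0
    kernel: str = "bivariate"          # "bivariate" or "phase-only"
    include: np.ndarray | None = field(default=None, repr=False)  # frame mask

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def weights(self, phi: float) -> np.ndarray:
        """Normalized kernel weights of every frame for a target phase."""
        d_phi = circular_distance(phi, self.cardiac_phase)
        w = np.exp(-(d_phi**2) / (2.0 * self.sigma_phi**2))
        if self.kernel == "bivariate":
            d_l = self.lowess_model(float(phi)) - self.u_hat
            w = w * np.exp(-(d_l**2) / (2.0 * self.sigma_L**2))
        if self.include is not None:
            w = w * self.include
        total = w.sum()
        if total < _MIN_TOTAL_WEIGHT:
            raise ValueError(
                f"total kernel weight {total:.3e} at phase {phi:.4f} is below "
                f"{_MIN_TOTAL_WEIGHT}; increase the bandwidths (k_phi/k_L)"
            )
        return w / total

    def excluding(self, frame_indices: np.ndarray) -> "ReconstructionModel":
        """A copy of the model with the given frames removed from the average."""
        mask = np.ones(self.n_frames) if self.include is None else self.include.copy()
        mask = np.asarray(mask, dtype=float)
        mask[np.asarray(frame_indices, dtype=int)] = 0.0
        return replace(self, include=mask)


@dataclass(frozen=True)
class SingleCycleVideo:
    """One reconstructed cardiac cycle at a chosen temporal magnification."""

    frames: np.ndarray = field(repr=False)
    magnification: float = 1.0
    phase_grid: np.ndarray = field(default=None, repr=False)


def fit_model(
    video: VideoSequence,
    phase_track: PhaseTrack,
    gating_result: GatingResult,
    u_hat: np.ndarray,
    k_phi: float = DEFAULT_K_PHI,
    k_L: float = DEFAULT_K_L,
    frames_per_cycle: float | None = None,
    kernel: str = "bivariate",
    restrict_to_retained: bool = False,
) -> ReconstructionModel:
    """Set the two kernel bandwidths and bundle the model state.

    ``sigma_phi`` is ``k_phi`` times the median circular phase step between
    consecutive frames.  ``sigma_L`` is ``k_L`` times the robust residual
    scale recomputed on the non-respiratory frames only.  By default the
    weighted average runs over all frames (the similarity kernel is what
    down-weights the respiratory ones); ``restrict_to_retained`` excludes the
    gated frames from the sum instead.

    ``frames_per_cycle`` (native temporal resolution of one cardiac cycle)
    defaults to the reciprocal of the median phase step.
    """
    if kernel not in ("bivariate", "phase-only"):
        raise ValueError(f"kernel must be 'bivariate' or 'phase-only', got {kernel!r}")
    u_hat = np.asarray(u_hat, dtype=float)
    phi = phase_track.cardiac_phase
    if not (video.n_frames == phi.size == u_hat.size):
        raise ValueError("video, phase track and similarity signal disagree in length")

    steps = circular_distance(phi[1:], phi[:-1])
    median_step = float(np.median(steps))
    if median_step == 0.0:
        raise ValueError("median consecutive phase step is zero (frozen video)")
    sigma_phi = k_phi * median_step

    model_l = gating_result.lowess_model
    non_resp = np.setdiff1d(np.arange(video.n_frames), gating_result.f_resp)
    sigma_l_raw = robust_sigma(u_hat[non_resp] - model_l(phi[non_resp]))
    # degeneracy floor: noiseless data would otherwise collapse the kernel
    floor = 1e-6 * max(float(np.ptp(u_hat)), 1e-30)
    sigma_l = max(k_L * sigma_l_raw, floor)

    include = None
    if restrict_to_retained:
        include = np.zeros(video.n_frames)
        include[gating_result.retained] = 1.0

    return ReconstructionModel(
        frames=video.frames,
        cardiac_phase=phi,
        u_hat=u_hat,
        lowess_model=model_l,
        sigma_phi=sigma_phi,
        sigma_L=sigma_l,
        k_phi=k_phi,
        k_L=k_L,
        frames_per_cycle=(1.0 / median_step if frames_per_cycle is None else frames_per_cycle),
        kernel=kernel,
        include=include,
    )


def reconstruct(model: ReconstructionModel, phi: float) -> np.ndarray:
    """Kernel-weighted average image at cardiac phase ``phi`` in [0, 1)."""
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"target phase must lie in [0, 1), got {phi}")
    w = model.weights(phi)
    return np.tensordot(w, model.frames, axes=1)


def single_cycle(model: ReconstructionModel, magnification: float = 1.0) -> SingleCycleVideo:
    """Reconstruct one full cardiac cycle on an evenly spaced phase grid.

    The grid has ``round(magnification * frames_per_cycle)`` phases starting
    at 0.
    """
    if magnification <= 0:
        raise ValueError(f"magnification must be positive, got {magnification}")
    if model.frames_per_cycle <= 0:
        raise ValueError("model has no native frames-per-cycle estimate")
    n = int(round(magnification * model.frames_per_cycle))
    if n < 1:
        raise ValueError("magnification too small: empty phase grid")
    grid = np.arange(n) / n
    frames = np.stack([reconstruct(model, p) for p in grid])
    return SingleCycleVideo(frames=frames, magnification=magnification, phase_grid=grid)
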