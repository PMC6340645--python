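"""Instantaneous phase of near-sinusoidal signals via the analytic signal."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .decompose import SignalDecomposition

__all__ = ["PhaseTrack", "hilbert_phase", "estimate_phases", "wrap_events"]


@dataclass(frozen=True)
class PhaseTrack:
    """Per-frame cardiac and respiratory phases in [0, 1)."""

    cardiac_phase: np.ndarray
    resp_phase: np.ndarray
    unwrapped_cardiac: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.cardiac_phase.size


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a near-sinusoidal series, mapped to [0, 1).

    The signal mean is removed, the analytic signal ``x + i H(x)`` is formed,
    and its quadrant-aware angle in [-pi, pi) is affinely mapped through
    ``(angle + pi) / (2 pi)`` so that local minima of the input land near
    phase 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("hilbert_phase needs a univariate series of length >= 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    x = x - x.mean()
    if np.ptp(x) == 0.0:
        raise ValueError("constant series: instantaneous phase undefined")
    angle = np.angle(hilbert(x))
    phase = (angle + np.pi) / (2.0 * np.pi)
    # guard against angle == pi rounding onto 1.0
    phase[phase >= 1.0] -= 1.0
    return phase


def unwrap_phase(phase: np.ndarray) -> np.ndarray:
    """Cumulative (non-modular) phase from a wrapped [0, 1) phase series."""
    return np.unwrap(np.asarray(phase, dtype=float), period=1.0)


def wrap_events(phase: np.ndarray) -> np.ndarray:
    """Frame indices where a wrapped [0, 1) phase series wraps through 0.

    These are the local minima of the sawtooth-like phase signal: the first
    frame of each new cycle (a backward jump of more than half a cycle).
    """
    phase = np.asarray(phase, dtype=float)
    jumps = np.flatnonzero(np.diff(phase) < -0.5)
    return jumps + 1


def estimate_phases(decomp: SignalDecomposition, fps: float | None = None) -> PhaseTrack:
    """Cardiac phase from the heart-beat residual, respiratory phase from the
    respiratory trend, both via :func:`hilbert_phase`."""
    try:
        cardiac = hilbert_phase(decomp.r_heart)
    except ValueError as err:
        raise ValueError(f"heart-beat signal: {err}") from err
    try:
        resp = hilbert_phase(decomp.tau_resp)
    except ValueError as err:
        raise ValueError(f"respiration signal: {err}") from err
    return PhaseTrack(
        cardiac_phase=cardiac,
        resp_phase=resp,
        unwrapped_cardiac=unwrap_phase(cardiac),
    )
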