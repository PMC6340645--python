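"""Two-step respiratory gating.

Step 1 discards frames whose respiratory phase lies within a cutoff of the
heavy-motion point (phase 0).  Step 2 fits a robust LOWESS curve of frame
similarity vs cardiac phase on the surviving frames and gates frames that
fall too far below the fit, measured in robust (MAD-based) standard
deviations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import median_abs_deviation
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .phases import PhaseTrack

__all__ = [
    "LowessModel",
    "GatingResult",
    "cutoff_gate",
    "lowess_fit",
    "robust_sigma",
    "gate_respiratory",
    "gate",
]

DEFAULT_CUTOFF = 0.2
DEFAULT_K = 2.0
DEFAULT_LOWESS_FRACTION = 0.3
DEFAULT_LOWESS_ITERATIONS = 3
_GRID_SIZE = 512


@dataclass(frozen=True)
class LowessModel:
    """Periodic LOWESS predictor of frame similarity at any cardiac phase.

    The fitted curve is tabulated on a dense phase grid over [0, 1) and
    evaluated by periodic linear interpolation.
    """

    grid_phase: np.ndarray = field(repr=False)
    grid_value: np.ndarray = field(repr=False)
    fraction: float = DEFAULT_LOWESS_FRACTION
    iterations: int = DEFAULT_LOWESS_ITERATIONS

    def __call__(self, phase: np.ndarray | float) -> np.ndarray | float:
        phi = np.mod(np.asarray(phase, dtype=float), 1.0)
        # periodic interpolation: close the grid with the wrapped first point
        xp = np.concatenate([self.grid_phase, [self.grid_phase[0] + 1.0]])
        fp = np.concatenate([self.grid_value, [self.grid_value[0]]])
        out = np.interp(phi, xp, fp)
        return float(out) if np.isscalar(phase) else out


def cutoff_gate(resp_phase: np.ndarray, c: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Frames whose respiratory phase is within ``c`` of phase 0 (circularly).

    Returns the sorted array of gated frame indices
    ``{t | resp_phase(t) < c or resp_phase(t) > 1 - c}``.
    """
    resp_phase = np.asarray(resp_phase, dtype=float)
    if not 0.0 <= c < 0.5:
        raise ValueError(f"cutoff c must lie in [0, 0.5), got {c}")
    return np.flatnonzero((resp_phase < c) | (resp_phase > 1.0 - c))


def lowess_fit(
    cardiac_phase: np.ndarray,
    u_hat: np.ndarray,
    fraction: float = DEFAULT_LOWESS_FRACTION,
    iterations: int = DEFAULT_LOWESS_ITERATIONS,
) -> LowessModel:
    """Robust periodic LOWESS fit of similarity values against cardiac phase.

    Training pairs are replicated at phase - 1 and phase + 1 before fitting so
    the curve is continuous across the phase wrap; the neighborhood fraction
    refers to the original (un-replicated) sample.
    """
    phi = np.mod(np.asarray(cardiac_phase, dtype=float), 1.0)
    val = np.asarray(u_hat, dtype=float)
    if phi.shape != val.shape or phi.ndim != 1:
        raise ValueError("phase and value arrays must be 1-D and equal-length")
    if phi.size < 10:
        raise ValueError(f"need at least 10 training pairs, got {phi.size}")
    srt = np.sort(phi)
    gaps = np.diff(np.concatenate([srt, [srt[0] + 1.0]]))
    worst = float(gaps.max())
    if worst > 0.25:
        at = srt[int(np.argmax(gaps))]
        raise ValueError(
            f"cardiac phases leave a gap of {worst:.3f} (> 0.25) starting at phase {at:.3f}"
        )

    x3 = np.concatenate([phi - 1.0, phi, phi + 1.0])
    y3 = np.tile(val, 3)
    fitted = _sm_lowess(y3, x3, frac=fraction / 3.0, it=iterations, return_sorted=True)
    grid = np.arange(_GRID_SIZE) / _GRID_SIZE
    grid_value = np.interp(grid, fitted[:, 0], fitted[:, 1])
    return LowessModel(grid_phase=grid, grid_value=grid_value,
                       fraction=fraction, iterations=iterations)


def robust_sigma(residuals: np.ndarray) -> float:
    """MAD-based robust standard deviation (scale factor 1.4826)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 3:
        raise ValueError(f"need at least 3 residuals, got {residuals.size}")
    return float(median_abs_deviation(residuals, scale="normal"))


def gate_respiratory(
    u_hat: np.ndarray,
    cardiac_phase: np.ndarray,
    lowess_model: LowessModel,
    sigma_L: float,
    k: float = DEFAULT_K,
    one_sided: bool = True,
) -> np.ndarray:
    """Frames whose similarity deviates from the LOWESS fit by more than
    ``k * sigma_L`` — below the fit only (default) or on either side."""
    if k <= 0:
        raise ValueError(f"gate multiple k must be positive, got {k}")
    u_hat = np.asarray(u_hat, dtype=float)
    predicted = lowess_model(np.asarray(cardiac_phase, dtype=float))
    if one_sided:
        excess = predicted - u_hat
    else:
        excess = np.abs(u_hat - predicted)
    return np.flatnonzero(excess > k * sigma_L)


@dataclass(frozen=True)
class GatingResult:
    """Output of the two-step respiratory gating."""

    f_cutoff: np.ndarray
    f_resp: np.ndarray
    lowess_model: LowessModel
    sigma_L: float
    c: float = DEFAULT_CUTOFF
    k: float = DEFAULT_K
    one_sided: bool = True
    n_frames: int = 0

    @property
    def gated(self) -> np.ndarray:
        """Union of the two discarded sets."""
        return np.union1d(self.f_cutoff, self.f_resp)

    @property
    def retained(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_frames), self.gated)

    def to_dict(self) -> dict:
        return {
            "f_cutoff": self.f_cutoff.tolist(),
            "f_resp": self.f_resp.tolist(),
            "sigma_L": self.sigma_L,
            "c": self.c,
            "k": self.k,
            "one_sided": self.one_sided,
            "n_frames": self.n_frames,
            "lowess": {
                "grid_phase": self.lowess_model.grid_phase.tolist(),
                "grid_value": self.lowess_model.grid_value.tolist(),
                "fraction": self.lowess_model.fraction,
                "iterations": self.lowess_model.iterations,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "GatingResult":
        lw = d["lowess"]
        model = LowessModel(
            grid_phase=np.asarray(lw["grid_phase"], dtype=float),
            grid_value=np.asarray(lw["grid_value"], dtype=float),
            fraction=lw["fraction"],
            iterations=lw["iterations"],
        )
        return cls(
            f_cutoff=np.asarray(d["f_cutoff"], dtype=int),
            f_resp=np.asarray(d["f_resp"], dtype=int),
            lowess_model=model,
            sigma_L=d["sigma_L"],
            c=d["c"],
            k=d["k"],
            one_sided=d["one_sided"],
            n_frames=d["n_frames"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GatingResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def gate(
    u_hat: np.ndarray,
    phase_track: PhaseTrack,
    c: float = DEFAULT_CUTOFF,
    k: float = DEFAULT_K,
    one_sided: bool = True,
    lowess_fraction: float = DEFAULT_LOWESS_FRACTION,
    lowess_iterations: int = DEFAULT_LOWESS_ITERATIONS,
    sigma_from_all_frames: bool = True,
) -> GatingResult:
    """Run both gating steps and bundle the results.

    The LOWESS curve is trained on frames surviving step 1; the robust scale
    is computed from the residuals of all frames (flag to restrict it to the
    step-1 survivors instead).
    """
    u_hat = np.asarray(u_hat, dtype=float)
    n = u_hat.size
    f_cutoff = cutoff_gate(phase_track.resp_phase, c)
    train = np.setdiff1d(np.arange(n), f_cutoff)
    model = lowess_fit(
        phase_track.cardiac_phase[train], u_hat[train],
        fraction=lowess_fraction, iterations=lowess_iterations,
    )
    resid_frames = np.arange(n) if sigma_from_all_frames else train
    residuals = u_hat[resid_frames] - model(phase_track.cardiac_phase[resid_frames])
    sigma_l = robust_sigma(residuals)
    f_resp = gate_respiratory(
        u_hat, phase_track.cardiac_phase, model, sigma_l, k=k, one_sided=one_sided
    )
    return GatingResult(
        f_cutoff=f_cutoff, f_resp=f_resp, lowess_model=model, sigma_L=sigma_l,
        c=c, k=k, one_sided=one_sided, n_frames=n,
    )
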