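"""Synthetic quasi-periodic ultrasound-like video generator.

Renders a pulsating bright ring (a stand-in for a heart chamber wall) whose
radius follows a skewed periodic waveform (fast contraction, slower
relaxation), plus respiratory motion concentrated in a short burst of each
respiratory cycle: a global vertical displacement and a partial out-of-plane
excursion in which the chamber is progressively replaced by frame-specific
tissue texture.  Multiplicative speckle-like noise is applied last.
Ground-truth per-frame cardiac/respiratory phases and R-peak frame indices
are returned alongside the rendered video, so every downstream stage can be
validated without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .video import VideoSequence

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "render_cycle"]

# exactly 2 respiratory cycles per 300 frames at 233 FPS
_DEFAULT_RESP_RATE = 2.0 * 60.0 * 233.0 / 300.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic video generator.

    Defaults mimic a high-frame-rate mouse echocardiography acquisition:
    233 FPS, 300 frames, a heart rate of 512 BPM (~11 cardiac cycles) and a
    respiratory rate giving exactly 2 respiratory cycles per video.
    Setting ``resp_amplitude`` to 0 disables the respiratory model entirely
    (no displacement and no out-of-plane excursion).
    """

    n_frames: int = 300
    fps: float = 233.0
    heart_rate: float = 512.0       # beats per minute
    resp_rate: float = _DEFAULT_RESP_RATE   # breaths per minute (93.2)
    image_shape: tuple[int, int] = (64, 64)
    speckle_level: float = 0.15     # multiplicative noise scale (0 disables)
    resp_amplitude: float = 3.0     # peak vertical displacement in pixels
    cardiac_asymmetry: float = 0.2  # waveform skew; > 0 = contraction faster
    seed: int = 0

    # geometry and respiratory-burst shape; rarely need tuning
    ring_radius: float = 18.0       # diastolic (maximum) ring radius, pixels
    contraction_depth: float = 5.0  # radius reduction at peak contraction
    ring_sigma: float = 2.5         # Gaussian thickness of the ring profile
    resp_width: float = 0.1         # phase-width of the respiratory burst
    resp_smooth: float = 0.25       # fraction of displacement in a smooth breathing term
    resp_occlusion: float = 0.9     # peak out-of-plane texture replacement in [0, 1]
    cardiac_phase0: float = 0.5     # cardiac phase of frame 0
    resp_phase0: float = 0.3        # respiratory phase of frame 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not self.heart_rate > 0 or not self.resp_rate > 0:
            raise ValueError("heart_rate and resp_rate must be strictly positive")
        if self.heart_rate <= self.resp_rate:
            raise ValueError(
                f"heart_rate ({self.heart_rate}) must exceed resp_rate ({self.resp_rate})"
            )
        if not 0 <= abs(self.cardiac_asymmetry) < 1:
            raise ValueError("cardiac_asymmetry must lie in (-1, 1)")
        if not self.resp_width > 0:
            raise ValueError("resp_width must be strictly positive")
        if not 0.0 <= self.resp_smooth <= 1.0:
            raise ValueError("resp_smooth must lie in [0, 1]")
        if not 0.0 <= self.resp_occlusion <= 1.0:
            raise ValueError("resp_occlusion must lie in [0, 1]")
        if self.speckle_level < 0:
            raise ValueError("speckle_level must be non-negative")
        needed = self.ring_radius + 3.0 * self.ring_sigma + abs(self.resp_amplitude)
        if needed >= min(self.image_shape) / 2:
            raise ValueError(
                f"image_shape {self.image_shape} too small to contain the ring "
                f"(needs half-size > {needed:.1f} px)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame ground truth emitted with each simulated video."""

    cardiac_phase: np.ndarray   # in [0, 1), phase 0 = peak contraction
    resp_phase: np.ndarray      # in [0, 1), phase 0 = peak displacement
    r_peak_frames: np.ndarray   # frames nearest each cardiac wrap through 0
    resp_displacement: np.ndarray = field(default=None, repr=False)


def _signed_circular_distance(phase: np.ndarray) -> np.ndarray:
    """Signed distance of each phase to 0, wrapped into (-0.5, 0.5]."""
    phase = np.asarray(phase, dtype=float)
    return phase - np.round(phase)


def _radius(phase: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Skewed raised-cosine radius waveform with its minimum at phase 0.

    The time warp ``h`` compresses the approach to peak contraction and
    stretches the relaxation, so systole and diastole are distinguishable
    and the direction of time is testable.
    """
    phase = np.asarray(phase, dtype=float)
    a = config.cardiac_asymmetry
    h = phase - a * (1.0 - np.cos(2.0 * np.pi * phase)) / (2.0 * np.pi)
    return config.ring_radius - config.contraction_depth * (1.0 + np.cos(2.0 * np.pi * h)) / 2.0


def _resp_burst(resp_phase: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Unit burst profile concentrating heavy motion near respiratory phase 0."""
    d = _signed_circular_distance(resp_phase)
    return np.exp(-((d / config.resp_width) ** 2))


def _resp_displacement(resp_phase: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.resp_amplitude == 0:
        return np.zeros_like(np.asarray(resp_phase, dtype=float))
    burst = _resp_burst(resp_phase, config)
    smooth = (1.0 + np.cos(2.0 * np.pi * np.asarray(resp_phase, dtype=float))) / 2.0
    return config.resp_amplitude * (
        (1.0 - config.resp_smooth) * burst + config.resp_smooth * smooth
    )


def _render_ring(radius: float, dy: float, config: SimulationConfig) -> np.ndarray:
    rows, cols = config.image_shape
    y = np.arange(rows, dtype=float)[:, None] - (rows - 1) / 2.0 - dy
    x = np.arange(cols, dtype=float)[None, :] - (cols - 1) / 2.0
    rho = np.hypot(y, x)
    return np.exp(-((rho - radius) ** 2) / (2.0 * config.ring_sigma**2))


def _r_peak_frames(config: SimulationConfig) -> np.ndarray:
    """Frames nearest each instant where cardiac phase wraps through 0."""
    step = config.heart_rate / (60.0 * config.fps)
    # event times (in frame units) solve cardiac_phase0 + t*step = integer k
    k_min = int(np.ceil(config.cardiac_phase0))
    k_max = int(np.floor(config.cardiac_phase0 + (config.n_frames - 1) * step))
    events = (np.arange(k_min, k_max + 1) - config.cardiac_phase0) / step
    peaks = np.unique(np.rint(events).astype(int))
    return peaks[(peaks >= 0) & (peaks < config.n_frames)]


def simulate(config: SimulationConfig) -> tuple[VideoSequence, GroundTruth]:
    """Render a synthetic video together with its ground truth.

    The same seed always yields a bit-identical video.
    """
    t = np.arange(config.n_frames)
    cardiac_phase = (config.cardiac_phase0 + t * config.heart_rate / (60.0 * config.fps)) % 1.0
    resp_phase = (config.resp_phase0 + t * config.resp_rate / (60.0 * config.fps)) % 1.0

    radii = _radius(cardiac_phase, config)
    displacement = _resp_displacement(resp_phase, config)
    resp_on = config.resp_amplitude != 0
    burst = _resp_burst(resp_phase, config) if resp_on else np.zeros(config.n_frames)

    rng = np.random.default_rng(config.seed)
    frames = np.empty((config.n_frames,) + tuple(config.image_shape), dtype=np.float64)
    for i in range(config.n_frames):
        scene = _render_ring(radii[i], displacement[i], config)
        occ = config.resp_occlusion * burst[i]
        if occ > 1e-3:
            # out-of-plane excursion: the plane sweeps through different
            # anatomy on every heavy-motion frame, so each such frame gets
            # its own smooth random texture
            tex = gaussian_filter(rng.standard_normal(config.image_shape), 2.0)
            tex = (tex - tex.min()) / (tex.max() - tex.min())
            scene = (1.0 - occ) * scene + occ * tex
        frames[i] = scene

    if config.speckle_level > 0:
        g = rng.standard_normal(frames.shape)
        frames *= 1.0 + config.speckle_level * (g**2 - 1.0)  # unit-mean multiplier

    np.clip(frames, 0.0, 1.0, out=frames)

    truth = GroundTruth(
        cardiac_phase=cardiac_phase,
        resp_phase=resp_phase,
        r_peak_frames=_r_peak_frames(config),
        resp_displacement=displacement,
    )
    return VideoSequence(frames, config.fps), truth


def render_cycle(config: SimulationConfig, phases: np.ndarray) -> np.ndarray:
    """Noise-free, respiration-free frames at the given cardiac phases.

    Serves as the ground-truth single-cycle video for reconstruction scoring.
    """
    phases = np.asarray(phases, dtype=float)
    radii = _radius(phases, config)
    return np.stack([_render_ring(r, 0.0, config) for r in radii])
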