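"""Core video container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VideoSequence:
    """An ordered stack of equal-shape 2-D grayscale frames at a fixed frame rate.

    Parameters
    ----------
    frames : ndarray, shape (N, rows, cols)
        Pixel intensities, stored as float64.
    fps : float
        Acquisition frame rate in frames per second.
    """

    frames: np.ndarray = field(repr=False)
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (N, rows, cols) array, got ndim={frames.ndim}"
            )
        if frames.shape[0] < 2:
            raise ValueError(f"a video needs at least 2 frames, got {frames.shape[0]}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def n_pixels(self) -> int:
        return self.frames.shape[1] * self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Video duration in seconds."""
        return self.n_frames / self.fps

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, index):
        return self.frames[index]

    def decimate(self, factor: int, start: int = 0) -> "VideoSequence":
        """Temporally down-sample: keep every ``factor``-th frame from ``start``."""
        if factor < 1 or int(factor) != factor:
            raise ValueError(f"decimation factor must be a positive integer, got {factor}")
        if not 0 <= start < self.n_frames:
            raise ValueError(f"start index {start} out of range")
        return VideoSequence(self.frames[start::int(factor)], self.fps / factor)
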