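"""Readers and writers for videos, phase tracks and ground-truth tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth
from .video import VideoSequence

__all__ = [
    "read_video",
    "write_video",
    "write_truth",
    "read_truth",
    "write_r_peaks",
    "read_r_peaks",
    "write_phase_track",
    "write_decomposition",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def _to_unit_float(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if np.issubdtype(frames.dtype, np.integer):
        info = np.iinfo(frames.dtype)
        return frames.astype(np.float64) / float(info.max)
    return frames.astype(np.float64)


def write_video(video: VideoSequence, path: str | Path) -> None:
    """Write a video as a multi-page float32 TIFF; fps goes in the description."""
    tifffile.imwrite(
        str(path),
        video.frames.astype(np.float32),
        photometric="minisblack",
        description=json.dumps({"fps": video.fps}),
    )


def _read_tiff(path: Path, fps: float | None) -> VideoSequence:
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        if fps is None:
            desc = tif.pages[0].description or ""
            try:
                fps = float(json.loads(desc).get("fps"))
            except (json.JSONDecodeError, TypeError, ValueError):
                fps = None
    if frames.ndim == 2:
        frames = frames[None]
    if fps is None:
        raise ValueError(
            f"{path}: no frame rate in TIFF metadata; pass fps explicitly"
        )
    return VideoSequence(_to_unit_float(frames), fps)


def _read_nifti(path: Path, fps: float | None) -> VideoSequence:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D NIfTI stack, got ndim={data.ndim}")
    frames = np.moveaxis(data, -1, 0)  # time is the last axis by convention
    if fps is None:
        zooms = img.header.get_zooms()
        dt = float(zooms[-1]) if len(zooms) >= 3 else 0.0
        fps = 1.0 / dt if dt > 0 else None
    if fps is None:
        raise ValueError(f"{path}: no frame rate in NIfTI header; pass fps explicitly")
    return VideoSequence(_to_unit_float(frames), fps)


def _read_directory(path: Path, fps: float | None) -> VideoSequence:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise ValueError(f"{path}: no image files found")
    frames = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse RGB(A) to grayscale
            img = img[..., :3].mean(axis=-1)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"{f.name}: frame shape {img.shape} differs from {files[0].name}'s {shape}"
            )
        frames.append(img)
    if fps is None:
        raise ValueError(f"{path}: frame rate unknown for an image directory; pass fps")
    return VideoSequence(_to_unit_float(np.stack(frames)), fps)


def read_video(path: str | Path, fps: float | None = None) -> VideoSequence:
    """Load a video from a multi-page TIFF, a NIfTI stack, or a directory of
    per-frame images (lexicographic order).  Intensities are scaled to [0, 1]
    for integer inputs.  An explicit ``fps`` overrides any file metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video path does not exist: {path}")
    if path.is_dir():
        return _read_directory(path, fps)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(path, fps)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path, fps)
    raise ValueError(f"unsupported video format: {path}")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    pd.DataFrame({
        "frame_index": np.arange(truth.cardiac_phase.size),
        "cardiac_phase": truth.cardiac_phase,
        "resp_phase": truth.resp_phase,
    }).to_csv(path, index=False, float_format="%.9f")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_r_peaks(r_peak_frames: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"frame_index": np.asarray(r_peak_frames, dtype=int)}).to_csv(
        path, index=False
    )


def read_r_peaks(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["frame_index"].to_numpy(dtype=int)


def write_phase_track(phase_track, path: str | Path) -> None:
    pd.DataFrame({
        "frame_index": np.arange(phase_track.n_frames),
        "cardiac_phase": phase_track.cardiac_phase,
        "resp_phase": phase_track.resp_phase,
    }).to_csv(path, index=False, float_format="%.9f")


def write_decomposition(decomp, path: str | Path) -> None:
    pd.DataFrame({
        "t": np.arange(decomp.u_hat.size),
        "u_hat": decomp.u_hat,
        "tau_resp": decomp.tau_resp,
        "r_heart": decomp.r_heart,
    }).to_csv(path, index=False, float_format="%.9f")
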