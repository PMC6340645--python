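"""Trend/residual decomposition of similarity signals.

Each row of the inter-frame similarity matrix is split into a slow
respiratory trend and a fast cardiac residual with a Hodrick-Prescott (HP)
filter; the best row is picked by the spectral entropy of its residual, and
the two signals are then cleaned with zero-phase Butterworth filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import signal as sps

from .similarity import SimilarityMatrix

__all__ = [
    "Periodogram",
    "BandSpec",
    "SignalDecomposition",
    "hp_filter",
    "spectral_entropy",
    "periodogram_entropy",
    "select_row",
    "bandlimit",
]

DEFAULT_LAMBDA = 6400.0


@dataclass(frozen=True)
class Periodogram:
    """FFT periodogram of a mean-removed signal on a fixed frequency grid."""

    freqs: np.ndarray            # Hz
    power: np.ndarray
    normalized_power: np.ndarray

    @property
    def freqs_bpm(self) -> np.ndarray:
        return self.freqs * 60.0

    @property
    def dominant_frequency(self) -> float:
        """Frequency (Hz) of the highest power bin."""
        return float(self.freqs[int(np.argmax(self.power))])


@dataclass(frozen=True)
class BandSpec:
    """Physiological frequency bands used to clean the two signals."""

    resp_lowpass_bpm: float = 230.0
    heart_band_bpm: tuple[float, float] = (310.0, 840.0)

    def __post_init__(self) -> None:
        lo, hi = self.heart_band_bpm
        if not 0 < self.resp_lowpass_bpm < lo < hi:
            raise ValueError(
                f"bands must satisfy 0 < resp lowpass ({self.resp_lowpass_bpm}) "
                f"< heart band low ({lo}) < heart band high ({hi})"
            )


@dataclass(frozen=True)
class SignalDecomposition:
    """The selected similarity row and its trend/residual split."""

    row_index: int
    u_hat: np.ndarray
    tau_resp: np.ndarray
    r_heart: np.ndarray
    lambda_: float
    entropy_per_row: np.ndarray
    bandlimited: bool = False
    trend_matrix: np.ndarray | None = field(default=None, repr=False)
    residual_matrix: np.ndarray | None = field(default=None, repr=False)


def _second_difference(n: int) -> sp.csc_matrix:
    """The (n-2) x n second-order difference operator."""
    return sp.diags(
        [np.ones(n - 2), -2.0 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
        format="csc",
    )


def hp_filter(u: np.ndarray, lambda_: float = DEFAULT_LAMBDA) -> tuple[np.ndarray, np.ndarray]:
    """Hodrick-Prescott decomposition of ``u`` into (trend, residual).

    The trend solves the sparse SPD system ``(I + lambda_ * D'D) tau = u``
    with ``D`` the second-difference operator over the interior points; the
    residual is defined by subtraction, so ``trend + residual == u`` exactly.
    """
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 1:
        raise ValueError("hp_filter expects a univariate series")
    n = u.size
    if n < 3:
        raise ValueError(f"hp_filter needs at least 3 samples, got {n}")
    if lambda_ < 0:
        raise ValueError(f"lambda_ must be non-negative, got {lambda_}")
    if lambda_ == 0:
        return u.copy(), np.zeros_like(u)
    d = _second_difference(n)
    a = sp.eye(n, format="csc") + lambda_ * (d.T @ d)
    trend = spla.spsolve(a, u)
    return trend, u - trend


def spectral_entropy(normalized_power: np.ndarray) -> float:
    """Shannon entropy (natural log) of a normalized power distribution."""
    p = np.asarray(normalized_power, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("normalized power must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("normalized power sums to zero; entropy undefined")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def periodogram_entropy(x: np.ndarray, fps: float) -> tuple[Periodogram, float]:
    """Mean-removed, zero-padded FFT periodogram and its spectral entropy.

    Zero padding to the next power of two >= 4N stabilizes the entropy
    comparison across rows.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("periodogram needs a univariate series of length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    x = x - x.mean()
    if not np.any(x):
        raise ValueError("all-zero (constant) series: periodogram normalization undefined")
    nfft = 1 << int(np.ceil(np.log2(4 * x.size)))
    spectrum = np.fft.rfft(x, n=nfft)
    power = np.abs(spectrum) ** 2 / (x.size * fps)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    pgram = Periodogram(freqs=freqs, power=power, normalized_power=power / power.sum())
    return pgram, spectral_entropy(pgram.normalized_power)


def select_row(
    S: SimilarityMatrix,
    lambda_: float = DEFAULT_LAMBDA,
    fps: float = 1.0,
    keep_matrices: bool = False,
) -> SignalDecomposition:
    """HP-filter every similarity row and keep the one whose cardiac residual
    has the smallest periodogram entropy (ties broken by lowest row index)."""
    values = S.values
    n = values.shape[0]
    entropies = np.empty(n)
    trends = np.empty_like(values)
    for i in range(n):
        try:
            trends[i], residual = hp_filter(values[i], lambda_)
            _, entropies[i] = periodogram_entropy(residual, fps)
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from err
    best = int(np.argmin(entropies))
    residuals = values - trends
    return SignalDecomposition(
        row_index=best,
        u_hat=values[best].copy(),
        tau_resp=trends[best],
        r_heart=residuals[best],
        lambda_=lambda_,
        entropy_per_row=entropies,
        trend_matrix=trends if keep_matrices else None,
        residual_matrix=residuals if keep_matrices else None,
    )


def _check_edge(edge_bpm: float, fps: float) -> float:
    nyquist_bpm = fps * 60.0 / 2.0
    if edge_bpm >= nyquist_bpm:
        raise ValueError(
            f"band edge {edge_bpm} BPM is at or above Nyquist ({nyquist_bpm:.1f} BPM) "
            f"for a {fps} FPS video"
        )
    return edge_bpm / nyquist_bpm  # normalized frequency for filter design


def bandlimit(
    decomp: SignalDecomposition,
    bands: BandSpec = BandSpec(),
    fps: float = 1.0,
    order: int = 4,
) -> SignalDecomposition:
    """Zero-phase Butterworth cleanup of the two component signals.

    Low-pass on the respiratory trend, band-pass on the cardiac residual.
    Filtering is forward-backward (no group delay) so downstream Hilbert
    phases are not shifted in time.  After this step the trend and residual
    no longer sum to ``u_hat`` exactly.
    """
    wn_resp = _check_edge(bands.resp_lowpass_bpm, fps)
    wn_heart = (_check_edge(bands.heart_band_bpm[0], fps),
                _check_edge(bands.heart_band_bpm[1], fps))

    sos_lp = sps.butter(order, wn_resp, btype="lowpass", output="sos")
    sos_bp = sps.butter(order, wn_heart, btype="bandpass", output="sos")

    # low-pass the trend around its mean so the DC level is preserved exactly
    mean = decomp.tau_resp.mean()
    tau = sps.sosfiltfilt(sos_lp, decomp.tau_resp - mean) + mean
    r = sps.sosfiltfilt(sos_bp, decomp.r_heart)
    return replace(decomp, tau_resp=tau, r_heart=r, bandlimited=True)
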