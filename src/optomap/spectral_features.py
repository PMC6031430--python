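"""Normalized mode-frequency spectra via the Morlet continuous wavelet transform.

Each posture-mode time series is transformed with a bank of 25 Morlet
wavelets whose center frequencies are dyadically (log2-uniformly) spaced
between 1 and 50 Hz; only the amplitudes of the complex coefficients are
kept. Per frame, the mode x channel amplitude matrix is flattened, floored
and normalized to a probability vector — the object whose pairwise KL
divergences drive the behavior-space embedding.

Channel normalization convention: amplitudes are scaled so that a
unit-amplitude sinusoid at a channel's center frequency produces a peak
amplitude of 1 on that channel, making channels directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default Morlet nondimensional frequency
OMEGA0 = 5.0


@dataclass(frozen=True)
class ChannelGrid:
    """Dyadically spaced wavelet center frequencies (Hz)."""

    frequencies: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.frequencies)

    @property
    def f_min(self) -> float:
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])


def channel_grid(f_min: float = 1.0, f_max: float = 50.0, n: int = 25) -> ChannelGrid:
    """Log2-equally spaced frequencies f_i = f_min * 2^((i-1) log2(f_max/f_min)/(n-1))."""
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    if n < 2:
        raise ValueError("need at least two channels")
    exponents = np.arange(n) * (np.log2(f_max / f_min) / (n - 1))
    return ChannelGrid(frequencies=f_min * 2.0 ** exponents)


def morlet_scale(frequency_hz: float, omega0: float = OMEGA0) -> float:
    """Scale (seconds) whose Morlet center frequency equals ``frequency_hz``.

    Uses the exact relation s = (omega0 + sqrt(2 + omega0^2)) / (4 pi f).
    """
    return (omega0 + np.sqrt(2.0 + omega0 ** 2)) / (4 * np.pi * frequency_hz)


def morlet_cwt(modes: np.ndarray, grid: ChannelGrid, fps: float,
               omega0: float = OMEGA0) -> np.ndarray:
    """Amplitude spectrogram, shape (T, n_modes, n_channels).

    FFT-based convolution with analytic Morlet wavelets. Per channel the
    amplitude is divided by the closed-form response of the wavelet to a
    unit sinusoid at the channel's own center frequency, so every channel
    reports an amplitude of ~1 for a matched unit oscillation; the wavelet's
    own pi^{-1/4} sqrt(2 pi s) prefactor cancels in this ratio.
    """
    modes = np.asarray(modes)
    if not np.issubdtype(modes.dtype, np.floating):
        modes = modes.astype(np.float64)
    if modes.ndim == 1:
        modes = modes[:, None]
    if modes.ndim != 2:
        raise ValueError("modes must be a (T, n_modes) array")
    T, M = modes.shape
    if grid.f_max > fps / 2 + 1e-9:
        raise ValueError(
            f"maximum channel frequency {grid.f_max} Hz exceeds the Nyquist "
            f"frequency {fps / 2} Hz"
        )
    if T < fps / grid.f_min:
        raise ValueError(
            f"series of {T} frames is shorter than one period of the lowest "
            f"channel ({grid.f_min} Hz at {fps} fps)"
        )
    if not np.all(np.isfinite(modes)):
        raise ValueError("modes must be finite (zero-fill invalid frames first)")

    from scipy import fft as spfft

    work_dtype = np.float32 if modes.dtype == np.float32 else np.float64
    omega = 2 * np.pi * np.fft.fftfreq(T, d=1.0 / fps)
    X = spfft.fft(modes.astype(work_dtype), axis=0)  # (T, M)

    out = np.empty((T, M, grid.n_channels), dtype=work_dtype)
    for c, f in enumerate(grid.frequencies):
        s = morlet_scale(f, omega0)
        # exp(-(s w - w0)^2 / 2) transfer normalized by the matched-sinusoid
        # response 0.5 * exp(-(s*2 pi f - w0)^2 / 2)
        matched = np.exp(-0.5 * (s * 2 * np.pi * f - omega0) ** 2) / 2.0
        g = (np.exp(-0.5 * (s * omega - omega0) ** 2) / matched)
        g[omega <= 0] = 0.0
        W = spfft.ifft(X * g[:, None].astype(X.dtype), axis=0)
        out[:, :, c] = np.abs(W)
    return out


def normalize_spectra(spectrogram: np.ndarray, eps: float = 1e-12):
    """Flatten mode x channel amplitudes into probability rows.

    Returns ``(features, low_power)``: rows are floored at ``eps`` and
    normalized to sum to 1; all-zero frames become uniform rows and are
    flagged in ``low_power``.
    """
    spec = np.asarray(spectrogram)
    if np.any(spec < 0):
        raise ValueError("amplitudes must be non-negative")
    T = spec.shape[0]
    flat = spec.reshape(T, -1).astype(spec.dtype, copy=True)
    raw_sums = flat.sum(axis=1, dtype=np.float64)
    low_power = raw_sums <= 0
    flat += spec.dtype.type(eps) if np.issubdtype(spec.dtype, np.floating) else eps
    flat /= (raw_sums + eps * flat.shape[1])[:, None].astype(flat.dtype)
    return flat, low_power
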