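"""Shared spectral engine: Morlet wavelet envelopes and FFT amplitude spectra.

One normalization convention is used throughout the package: a stationary
unit-amplitude sinusoid at an analysis frequency yields an envelope (or a
single-sided FFT amplitude) of 1.0 uV. Wavelet cycle counts scale with
frequency (``n_cycles = freq / 2``), so time resolution is constant across
the analysis band and amplitudes are directly comparable between the two
tag frequencies.

Finite epochs attenuate the convolution near their edges. The envelope is
divided by the local Gaussian "coverage" (the fraction of wavelet mass
falling inside the epoch), which makes the stationary-tone gain exact at
every sample; samples within three Gaussian widths of an edge are still
flagged so downstream windows can avoid them.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import fftconvolve

#: Morlet analysis grid: 10 log-spaced frequencies spanning 1-40 Hz.
LOG_FREQS = np.geomspace(1.0, 40.0, 10)


def analysis_freqs(extra: tuple[float, ...] = (12.0, 15.0)) -> np.ndarray:
    """Log-spaced 1-40 Hz grid with the tag frequencies appended.

    The log grid does not land on the flicker frequencies, so they are
    added explicitly and the union is returned sorted.
    """
    return np.unique(np.concatenate([LOG_FREQS, np.asarray(extra, float)]))


def morlet_wavelet(freq: float, fs: float, n_cycles: float | None = None):
    """Complex Morlet wavelet and its Gaussian envelope, sampled at ``fs``."""
    if n_cycles is None:
        n_cycles = freq / 2.0
    if n_cycles < 1:
        raise ValueError("wavelet needs at least one cycle")
    if freq >= fs / 2:
        raise ValueError(f"analysis frequency {freq} Hz at or above Nyquist")
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = max(int(round(5.0 * sigma_t * fs)), 1)
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    wavelet = gauss * np.exp(2j * np.pi * freq * t)
    return wavelet, gauss, sigma_t


def morlet_envelope(
    data: np.ndarray,
    fs: float,
    freqs,
    n_cycles=None,
    edge_correction: bool = True,
):
    """Amplitude envelope of ``data`` at each analysis frequency.

    Parameters
    ----------
    data : array (..., n_samples)
        Signal in uV; the transform runs along the last axis.
    fs : float
        Sample rate in Hz.
    freqs : sequence of float
        Analysis frequencies in Hz.
    n_cycles : None, scalar or sequence
        Cycles per wavelet; default ``freq / 2``.
    edge_correction : bool
        Divide by local Gaussian coverage so stationary-tone gain is exact
        up to the epoch edges.

    Returns
    -------
    env : array (n_freqs, ..., n_samples)
        Nonnegative amplitude envelope, unit-sinusoid gain 1.0.
    edge_mask : array (n_freqs, n_samples) of bool
        True where the sample lies within three Gaussian widths of an
        epoch edge (estimates there lean on extrapolated signal).
    """
    data = np.asarray(data, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if n_cycles is None:
        cycles = freqs / 2.0
    else:
        cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)
    n = data.shape[-1]
    env = np.empty(freqs.shape + data.shape, dtype=float)
    edge_mask = np.zeros((len(freqs), n), dtype=bool)
    for i, (f, c) in enumerate(zip(freqs, cycles)):
        wavelet, gauss, sigma_t = morlet_wavelet(f, fs, c)
        gain = gauss.sum()
        conv = fftconvolve(data, wavelet.reshape((1,) * (data.ndim - 1) + (-1,)),
                           mode="same", axes=-1)
        e = 2.0 * np.abs(conv) / gain
        if edge_correction:
            coverage = fftconvolve(np.ones(n), gauss, mode="same") / gain
            e = e / coverage
        env[i] = e
        margin = int(np.ceil(3.0 * sigma_t * fs))
        if margin > 0:
            edge_mask[i, : min(margin, n)] = True
            edge_mask[i, max(n - margin, 0):] = True
    return env, edge_mask


def single_sided_amplitude(x: np.ndarray, fs: float):
    """Single-sided FFT amplitude spectrum along the last axis.

    A unit-amplitude sinusoid exactly on a frequency bin reads 1.0.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    spec = np.abs(np.fft.rfft(x, axis=-1)) / n
    spec *= 2.0
    spec[..., 0] /= 2.0
    if n % 2 == 0:
        spec[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def amplitude_at(x: np.ndarray, fs: float, freq: float, warn_leakage: bool = True):
    """Single-sided amplitude at the bin nearest ``freq``.

    Warns when the window does not hold an integer number of cycles at
    ``freq`` (spectral leakage smears the tone across bins).
    """
    n = x.shape[-1]
    cycles = freq * n / fs
    if warn_leakage and abs(cycles - round(cycles)) > 1e-6:
        warnings.warn(
            f"window holds {cycles:.2f} cycles at {freq} Hz "
            "(non-integer: expect spectral leakage)",
            stacklevel=2,
        )
    freqs, spec = single_sided_amplitude(x, fs)
    idx = int(np.argmin(np.abs(freqs - freq)))
    return spec[..., idx]
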