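"""Adaptive directed transfer function from time-varying MVAR coefficients.

With A_k(t) the lag-k coefficient matrices, the spectral coefficient matrix
is

    Abar(f, t) = I - sum_{k=1..p} A_k(t) exp(-i 2 pi f k / fs)

(the lag-0 term carries the minus-identity under the standard MVAR spectral
convention). Its inverse H(f, t) = Abar^-1 is the time-varying transfer
matrix; the normalized ADTF is the row-normalized squared magnitude

    iota2_ij(f, t) = |H_ij(f, t)|^2 / sum_k |H_ik(f, t)|^2   in [0, 1],

quantifying directed flow j -> i, and the integrated ADTF upsilon2_ij(t) is
the mean of iota2 over the grid frequencies inside the analysis band. Using
the in-band grid count as the denominator (rather than the band width in Hz)
keeps upsilon2 in [0, 1] independent of the grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tvar import TVARModel

DEFAULT_FREQS = np.arange(1.0, 31.0)  # 1 Hz grid over the analysis band
DEFAULT_BAND = (1.0, 30.0)


@dataclass
class TransferSpectrum:
    H: np.ndarray       # (n, n, F, T) complex
    freqs: np.ndarray   # Hz


@dataclass
class ADTFResult:
    iota2: np.ndarray     # (n, n, F, T), rows sum to 1 over sources
    upsilon2: np.ndarray  # (n, n, T), band-integrated flow
    freqs: np.ndarray
    band: tuple[float, float]


def coeffs_to_spectrum(
    coeffs: np.ndarray, freqs: np.ndarray, sampling_rate: float
) -> np.ndarray:
    """Evaluate Abar(f, t) = I - sum_k A_k(t) e^{-i 2 pi f k / fs}.

    ``coeffs`` is (n, n, p, T); returns (n, n, F, T) complex.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if freqs.min() < 0 or freqs.max() > sampling_rate / 2:
        raise ValueError(
            f"frequencies must lie in [0, {sampling_rate / 2}] Hz, got "
            f"[{freqs.min()}, {freqs.max()}]"
        )
    n, _, p, T = coeffs.shape
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / sampling_rate)  # (F, p)
    omega = -np.einsum("ijkt,fk->ijft", coeffs, phase, optimize=True)
    omega[np.arange(n), np.arange(n)] += 1.0
    return omega


def compute_H(omega: np.ndarray, freqs: np.ndarray | None = None) -> TransferSpectrum:
    """Invert the spectral coefficient matrix per (frequency, time)."""
    n = omega.shape[0]
    stacked = np.ascontiguousarray(np.moveaxis(omega, (0, 1), (2, 3)))  # (F, T, n, n)
    try:
        Hs = np.linalg.inv(stacked)
    except np.linalg.LinAlgError:
        dets = np.abs(np.linalg.det(stacked))
        f_idx, t_idx = np.unravel_index(int(np.argmin(dets)), dets.shape)
        raise np.linalg.LinAlgError(
            f"spectral coefficient matrix singular near (freq index {f_idx}, "
            f"time index {t_idx})"
        ) from None
    H = np.moveaxis(Hs, (2, 3), (0, 1))
    if freqs is None:
        freqs = np.arange(omega.shape[2], dtype=float)
    return TransferSpectrum(H=np.ascontiguousarray(H), freqs=np.asarray(freqs, dtype=float))


def normalize_adtf(H: TransferSpectrum | np.ndarray) -> np.ndarray:
    """Row-normalized squared transfer magnitudes, iota2 in [0, 1]."""
    arr = H.H if isinstance(H, TransferSpectrum) else H
    power = arr.real**2 + arr.imag**2
    denom = power.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("zero row in the transfer matrix; ADTF undefined")
    return power / denom


def integrate_adtf(
    iota2: np.ndarray, freqs: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Mean of iota2 over the grid frequencies inside [f1, f2] (inclusive)."""
    f1, f2 = band
    if f2 <= f1:
        raise ValueError("band must satisfy f1 < f2")
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= f1) & (freqs <= f2)
    if not mask.any():
        raise ValueError(f"band {band} contains no grid frequency")
    return iota2[:, :, mask, :].mean(axis=2)


def adtf(
    model: TVARModel,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    time_indices: np.ndarray | None = None,
) -> ADTFResult:
    """Full ADTF computation for a fitted time-varying model.

    ``time_indices`` restricts the (costly) spectral evaluation to a subset
    of time points, e.g. the network reporting window.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    coeffs = model.coeffs if time_indices is None else model.coeffs[:, :, :, time_indices]
    omega = coeffs_to_spectrum(coeffs, freqs, model.sampling_rate)
    spectrum = compute_H(omega, freqs)
    iota2 = normalize_adtf(spectrum)
    upsilon2 = integrate_adtf(iota2, freqs, band)
    return ADTFResult(iota2=iota2, upsilon2=upsilon2, freqs=freqs, band=band)
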