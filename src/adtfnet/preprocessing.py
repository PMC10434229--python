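"""Epoch conditioning for stimulus-locked multichannel recordings.

The conditioning chain is baseline correction -> amplitude-based artifact
rejection -> zero-phase band-pass filtering, applied to epoched data
(channels x samples x epochs). All operations are pure: they return new
:class:`EpochedRecording` objects and never mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class EpochedRecording:
    """Stimulus-locked epoched multichannel time series.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples, n_epochs)`` in microvolt.
    sampling_rate:
        Sampling frequency in Hz.
    tmin:
        Time of the first sample relative to stimulus onset, in seconds.
        The epoch time axis is ``tmin + arange(n_samples) / sampling_rate``
        (half-open interval: the nominal end time is not itself sampled).
    channel_names:
        Optional channel labels; generated as ``ch00 ...`` when omitted.
    """

    data: np.ndarray
    sampling_rate: float
    tmin: float = -0.2
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (channels, samples, epochs), got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_times(self) -> np.ndarray:
        """Per-sample time axis in seconds, strictly increasing."""
        return self.tmin + np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "EpochedRecording":
        return replace(self, data=data, channel_names=list(self.channel_names))


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    Defaults: 200 ms pre-stimulus baseline, +/-75 microvolt rejection
    threshold, 0.1-30 Hz pass band.
    """

    baseline_window: tuple[float, float] = (-0.2, 0.0)
    reject_threshold: float = 75.0
    band: tuple[float, float] = (0.1, 30.0)
    common_average: bool = False

    def validate(self, sampling_rate: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < sampling_rate / 2):
            raise ValueError(f"band {self.band} invalid for fs={sampling_rate}")
        if self.reject_threshold <= 0:
            raise ValueError("reject_threshold must be positive")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ValueError("baseline_window must be an increasing interval")


def _window_mask(rec: EpochedRecording, window: tuple[float, float]) -> np.ndarray:
    t = rec.epoch_times
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError(f"window {window} selects no samples in [{t[0]}, {t[-1]}]")
    return mask


def baseline_correct(
    rec: EpochedRecording, window: tuple[float, float] = (-0.2, 0.0)
) -> EpochedRecording:
    """Subtract the per-channel, per-epoch mean over ``window``.

    After correction the mean of every channel/epoch over the baseline
    window is zero (to round-off).
    """
    mask = _window_mask(rec, window)
    baseline = rec.data[:, mask, :].mean(axis=1, keepdims=True)
    return rec.copy_with(rec.data - baseline)


def reject_artifacts(
    rec: EpochedRecording, threshold: float = 75.0
) -> tuple[EpochedRecording, np.ndarray]:
    """Drop epochs whose absolute amplitude strictly exceeds ``threshold`` (microvolt).

    An epoch survives when every sample on every channel satisfies
    ``|x| <= threshold``; samples exactly at the threshold are kept.
    Surviving epochs are returned unmodified and in their original order,
    together with the indices of the rejected epochs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(rec.data).max(axis=(0, 1))
    rejected = np.flatnonzero(peak > threshold)
    if rejected.size == rec.n_epochs:
        raise ValueError(
            f"all {rec.n_epochs} epochs exceed +/-{threshold} microvolt; nothing left to analyze"
        )
    keep = np.setdiff1d(np.arange(rec.n_epochs), rejected)
    return rec.copy_with(rec.data[:, :, keep]), rejected


def bandpass(
    rec: EpochedRecording, band: tuple[float, float] = (0.1, 30.0), order: int = 4
) -> EpochedRecording:
    """Zero-phase Butterworth band-pass along the sample axis.

    A forward-backward pass of an ``order``-th Butterworth filter (no group
    delay, squared magnitude response). Each epoch is demeaned first: over a
    short epoch an IIR high-pass with a cut-off well below 1 Hz cannot settle,
    so the DC component is removed exactly rather than asymptotically.

    When the epoch is shorter than two periods of the low cut-off, the IIR
    high-pass section is dropped entirely: its impulse response outlasts the
    epoch, so it contributes only edge transients (which distort in-band
    amplitudes), while the sub-cut-off content it would remove is exactly the
    per-epoch mean already subtracted.
    """
    lo, hi = band
    if not (0 < lo < hi < rec.sampling_rate / 2):
        raise ValueError(f"band {band} invalid for fs={rec.sampling_rate}")
    if rec.n_samples < 2 * rec.sampling_rate / lo:
        sos = signal.butter(order, hi, btype="lowpass", fs=rec.sampling_rate, output="sos")
    else:
        sos = signal.butter(order, band, btype="bandpass", fs=rec.sampling_rate, output="sos")
    # pad length sosfiltfilt would use; epochs shorter than this cannot be filtered
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"epoch of {rec.n_samples} samples is shorter than the filter warm-up ({padlen})"
        )
    centered = rec.data - rec.data.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, centered, axis=1)
    return rec.copy_with(filtered)


def common_average_reference(rec: EpochedRecording) -> EpochedRecording:
    """Re-reference to the instantaneous mean over channels.

    Stands in for reference standardization when no head model is available.
    """
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def preprocess(
    rec: EpochedRecording, config: PreprocessConfig | None = None
) -> tuple[EpochedRecording, np.ndarray]:
    """Full conditioning chain: baseline -> reject -> band-pass [-> reference].

    Returns the conditioned recording and the indices of rejected epochs.
    """
    config = config or PreprocessConfig()
    config.validate(rec.sampling_rate)
    out = baseline_correct(rec, config.baseline_window)
    out, rejected = reject_artifacts(out, config.reject_threshold)
    out = bandpass(out, config.band)
    if config.common_average:
        out = common_average_reference(out)
    return out, rejected
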