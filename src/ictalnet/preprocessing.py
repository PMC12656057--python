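"""Filtering and montage standardization for raw EEG recordings.

Pipeline order: Butterworth bandpass (0.5-40 Hz, 4th order) -> 60 Hz
notch -> 20-channel average-reference montage.  Both filters are applied
zero-phase (forward-backward), so the magnitude response is squared and
no phase delay is introduced; sampling rates of 250 and 400 Hz are
handled natively, never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError
from .recording import Recording

DEFAULT_BANDPASS = (0.5, 40.0)
DEFAULT_ORDER = 4
DEFAULT_NOTCH_HZ = 60.0
DEFAULT_NOTCH_Q = 30.0
MONTAGE_CHANNELS = 20


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filtering stage."""

    kind: str  # 'bandpass' | 'notch'
    order: int = DEFAULT_ORDER
    low_hz: float | None = None
    high_hz: float | None = None
    center_hz: float | None = None
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if self.kind == "bandpass":
            if self.low_hz is None or self.high_hz is None:
                raise ValueError("bandpass requires low_hz and high_hz")
            if not (0 < self.low_hz < self.high_hz < nyq):
                raise ValueError("bandpass needs 0 < low < high < Nyquist")
        elif self.kind == "notch":
            if self.center_hz is None or not (0 < self.center_hz < nyq):
                raise ValueError("notch needs 0 < center < Nyquist")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


def _check_length(recording: Recording, order: int) -> None:
    # sosfiltfilt needs more samples than its padding (~3x filter order);
    # anything shorter cannot be filtered meaningfully.
    padlen = 3 * (2 * order + 1)
    if recording.n_samples <= padlen:
        raise ValueError(
            f"recording of {recording.n_samples} samples is shorter than the "
            f"filter warm-up ({padlen} samples)"
        )


def bandpass(
    recording: Recording,
    low: float = DEFAULT_BANDPASS[0],
    high: float = DEFAULT_BANDPASS[1],
    order: int = DEFAULT_ORDER,
) -> Recording:
    """Zero-phase Butterworth bandpass; returns a new recording."""
    nyq = recording.sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    _check_length(recording, order)
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=recording.sampling_rate, output="sos")
    return recording.copy_with(data=sps.sosfiltfilt(sos, recording.data, axis=1))


def notch(
    recording: Recording,
    center: float = DEFAULT_NOTCH_HZ,
    q: float = DEFAULT_NOTCH_Q,
) -> Recording:
    """Zero-phase second-order IIR notch (quality factor 30 by default)."""
    nyq = recording.sampling_rate / 2.0
    if not (0 < center < nyq):
        raise ValueError(f"notch center {center} Hz must lie below Nyquist {nyq} Hz")
    _check_length(recording, 1)
    b, a = sps.iirnotch(center, q, fs=recording.sampling_rate)
    return recording.copy_with(data=sps.filtfilt(b, a, recording.data, axis=1))


def standardize_montage(recording: Recording, n_channels: int = MONTAGE_CHANNELS) -> Recording:
    """Select the first ``n_channels`` channels and re-apply the average reference.

    After selection the mean across retained channels is exactly zero at
    every time point, which also makes the output invariant to any
    common-mode signal added to all input channels.
    """
    if recording.n_channels < n_channels:
        raise DataError(
            f"recording (patient {recording.patient_id!r}) has "
            f"{recording.n_channels} channels; {n_channels} required"
        )
    data = recording.data[:n_channels].copy()
    data -= data.mean(axis=0, keepdims=True)
    return recording.copy_with(
        data=data, channel_labels=recording.channel_labels[:n_channels]
    )


def preprocess(recording: Recording) -> Recording:
    """Full pipeline: bandpass -> notch -> montage."""
    return standardize_montage(notch(bandpass(recording)))
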