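"""Dual-domain feature extraction: 14 features per channel, 280 per segment.

Per channel: nine time-domain statistics (mean, SD, max, min, IQR,
median, variance, mean absolute amplitude, line length) and the mean
Welch power spectral density over five clinical bands (delta 0.5-4,
theta 4-8, alpha 8-13, beta 13-30, high beta 30-40 Hz).  The Welch
window is ~1.024 s (256 samples at 250 Hz, 410 at 400 Hz) with a Hann
taper and 50% overlap.  Features are computed from filtered but
unnormalized µV signals; no scaling is applied before the classifier,
whose first batch-normalization layer absorbs the scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError
from .recording import Segment


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low_hz, high_hz); ``closed_high`` includes the upper edge."""

    name: str
    low_hz: float
    high_hz: float
    closed_high: bool = False


#: The five clinical bands, ordered; edges half-open so 4/8/13/30 Hz are
#: counted once, with the final band closed at the 40 Hz passband edge.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("highbeta", 30.0, 40.0, closed_high=True),
)

TEMPORAL_NAMES: tuple[str, ...] = (
    "mean", "sd", "max", "min", "iqr", "median", "variance",
    "mean_abs_amplitude", "line_length",
)
FEATURE_NAMES: tuple[str, ...] = TEMPORAL_NAMES + tuple(f"power_{b.name}" for b in BANDS)

N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)  # 14
N_CHANNELS = 20
N_FEATURES = N_CHANNELS * N_FEATURES_PER_CHANNEL  # 280


def temporal_features(channel_signal: np.ndarray) -> np.ndarray:
    """The nine time-domain statistics, in canonical column order.

    IQR uses linear-interpolation percentiles; line length is the sum of
    absolute first differences.
    """
    x = np.asarray(channel_signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D signal with at least 2 samples")
    q75, q25 = np.percentile(x, [75, 25])
    return np.array(
        [
            x.mean(),
            x.std(),
            x.max(),
            x.min(),
            q75 - q25,
            np.median(x),
            x.var(),
            np.abs(x).mean(),
            np.abs(np.diff(x)).sum(),
        ]
    )


def welch_window_length(sampling_rate: float) -> int:
    """Welch segment length: ~1.024 s of signal (256 @ 250 Hz, 410 @ 400 Hz)."""
    return int(round(1.024 * sampling_rate))


def welch_psd(channel_signal: np.ndarray, sampling_rate: float):
    """One-sided Welch PSD (density scaling), Hann window, 50% overlap."""
    x = np.asarray(channel_signal, dtype=float)
    nperseg = welch_window_length(sampling_rate)
    if x.size < nperseg:
        raise ValueError(
            f"signal of {x.size} samples shorter than one Welch window ({nperseg})"
        )
    freqs, psd = sps.welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def band_power(frequencies: np.ndarray, psd: np.ndarray, band: BandDefinition) -> float:
    """Mean PSD over the band's frequency bins."""
    frequencies = np.asarray(frequencies)
    if band.closed_high:
        mask = (frequencies >= band.low_hz) & (frequencies <= band.high_hz)
    else:
        mask = (frequencies >= band.low_hz) & (frequencies < band.high_hz)
    if not mask.any():
        raise ValueError(
            f"no frequency bins fall inside band {band.name} "
            f"[{band.low_hz}, {band.high_hz}) - spectral resolution too coarse"
        )
    return float(np.asarray(psd)[mask].mean())


@dataclass
class FeatureMatrix:
    """20 x 14 feature matrix; rows follow channel order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CHANNELS, N_FEATURES_PER_CHANNEL):
            raise ValueError(f"feature matrix must be {N_CHANNELS} x {N_FEATURES_PER_CHANNEL}")

    def flatten(self) -> np.ndarray:
        """Row-major (channel-major) 280-vector."""
        return self.values.ravel()

    @property
    def column_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES


def extract(segment: Segment) -> FeatureMatrix:
    """Compute the full 20 x 14 feature matrix of a segment.

    Vectorized across channels; numerically identical to applying
    :func:`temporal_features`, :func:`welch_psd` and :func:`band_power`
    channel by channel.
    """
    if segment.data.shape[0] != N_CHANNELS:
        raise ValueError("segment must have exactly 20 channels")
    x = segment.data
    fs = segment.sampling_rate
    rows = np.empty((N_CHANNELS, N_FEATURES_PER_CHANNEL))
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    rows[:, 0] = x.mean(axis=1)
    rows[:, 1] = x.std(axis=1)
    rows[:, 2] = x.max(axis=1)
    rows[:, 3] = x.min(axis=1)
    rows[:, 4] = q75 - q25
    rows[:, 5] = np.median(x, axis=1)
    rows[:, 6] = x.var(axis=1)
    rows[:, 7] = np.abs(x).mean(axis=1)
    rows[:, 8] = np.abs(np.diff(x, axis=1)).sum(axis=1)

    nperseg = welch_window_length(fs)
    if x.shape[1] < nperseg:
        raise ValueError(
            f"segment of {x.shape[1]} samples shorter than one Welch window ({nperseg})"
        )
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", scaling="density", axis=1,
    )
    for j, b in enumerate(BANDS):
        if b.closed_high:
            mask = (freqs >= b.low_hz) & (freqs <= b.high_hz)
        else:
            mask = (freqs >= b.low_hz) & (freqs < b.high_hz)
        rows[:, 9 + j] = psd[:, mask].mean(axis=1)
    return FeatureMatrix(rows)


class FeatureExtractor:
    """scikit-learn style transformer: list of segments -> (n, 280) array.

    Stateless (``fit`` is a no-op); provided so feature extraction can
    sit inside sklearn pipelines next to the classifier.
    """

    def __init__(self, flatten: bool = True):
        self.flatten = flatten

    def get_params(self, deep: bool = True) -> dict:
        return {"flatten": self.flatten}

    def set_params(self, **params) -> "FeatureExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "FeatureExtractor":
        return self

    def transform(self, X: "list[Segment]") -> np.ndarray:
        mats = [extract(seg).values for seg in X]
        out = np.stack(mats) if mats else np.empty((0, N_CHANNELS, N_FEATURES_PER_CHANNEL))
        return out.reshape(len(mats), -1) if self.flatten else out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)


def labels_of(segments: "list[Segment]") -> np.ndarray:
    """Integer class labels of a segment list."""
    return np.array([int(s.label) for s in segments], dtype=int)


def patients_of(segments: "list[Segment]") -> np.ndarray:
    return np.array([s.patient_id for s in segments])
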