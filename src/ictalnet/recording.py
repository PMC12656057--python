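"""In-memory containers for multi-channel EEG recordings and fixed windows."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import DataError
from .seizures import SeizureClass

#: First 20 electrode names of the extended 10-20 layout used by default.
DEFAULT_CHANNEL_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "Oz",
)

#: Sampling rates handled natively (no resampling is ever performed).
SUPPORTED_RATES: tuple[float, ...] = (250.0, 400.0)

#: Analysis window length in seconds.
WINDOW_SECONDS: float = 10.0


@dataclass
class Recording:
    """A multi-channel EEG recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_labels : sequence of str
        Electrode names in row order.
    patient_id : str
        Subject identifier; all windows cut from this recording inherit it.
    events : list of (start_s, end_s, SeizureClass)
        Annotated seizure events in seconds from recording onset.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = ()
    patient_id: str = ""
    events: list[tuple[float, float, SeizureClass]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise DataError("recording data must be a 2-D channels x samples array")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"CH{i:02d}" for i in range(self.data.shape[0])
            )
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise DataError("one label per channel required")
        dur = self.duration_s
        norm_events = []
        for start, end, klass in self.events:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise DataError(
                    f"event ({start}, {end}) outside recording of {dur:.3f} s "
                    f"(patient {self.patient_id!r})"
                )
            norm_events.append((float(start), float(end), SeizureClass.from_label(klass)))
        self.events = norm_events

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with selected fields replaced (data is copied)."""
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)

    # -- array-bundle round trip ------------------------------------------
    def to_npz(self, path: "str | Path") -> None:
        """Save as an .npz array bundle."""
        events = self.events or []
        np.savez(
            path,
            data=self.data,
            sampling_rate=self.sampling_rate,
            channel_labels=np.asarray(self.channel_labels),
            patient_id=self.patient_id,
            event_start=np.asarray([e[0] for e in events], dtype=float),
            event_end=np.asarray([e[1] for e in events], dtype=float),
            event_class=np.asarray([int(e[2]) for e in events], dtype=int),
        )

    @classmethod
    def from_npz(cls, path: "str | Path") -> "Recording":
        with np.load(path, allow_pickle=False) as z:
            events = [
                (float(s), float(e), SeizureClass(int(k)))
                for s, e, k in zip(z["event_start"], z["event_end"], z["event_class"])
            ]
            return cls(
                data=z["data"],
                sampling_rate=float(z["sampling_rate"]),
                channel_labels=tuple(str(c) for c in z["channel_labels"]),
                patient_id=str(z["patient_id"]),
                events=events,
            )


@dataclass
class Segment:
    """A fixed 10-second, 20-channel labelled window.

    ``padded`` marks windows cut from events shorter than 10 s that were
    zero-padded at the end; ``synthetic`` marks noise-augmented copies.
    """

    data: np.ndarray
    sampling_rate: float
    label: SeizureClass
    patient_id: str = ""
    padded: bool = False
    synthetic: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 20:
            raise DataError("segment must have exactly 20 channels")
        expected = int(round(WINDOW_SECONDS * self.sampling_rate))
        if self.data.shape[1] != expected:
            raise DataError(
                f"segment length {self.data.shape[1]} != 10 s at "
                f"{self.sampling_rate} Hz ({expected} samples)"
            )
        self.label = SeizureClass.from_label(self.label)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
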