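"""EDF (European Data Format) input/output.

Reading delegates the heavy lifting to :mod:`mne` after a light header
pre-parse that enforces the dialect this package supports (one common
sampling rate across channels) and reports malformed headers with the
byte offset of the offending field.  Writing is a minimal 16-bit EDF
encoder (1-second data records, per-channel physical scaling), enough
for lossless-to-quantization round trips of synthetic recordings.

Seizure annotations travel in a CSV sidecar ``<stem>.events.csv`` with
columns ``start_s, end_s, class``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .recording import Recording
from .seizures import CLASS_LABELS, SeizureClass

_HDR_FIXED = 256


def events_sidecar(path: "str | Path") -> Path:
    path = Path(path)
    return path.with_suffix(".events.csv")


def _ascii_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: "str | Path", *, annotations: bool = True) -> Path:
    """Write a recording as 16-bit EDF (and its events sidecar CSV).

    The signal is padded with zeros to a whole number of 1-second data
    records.  Per-channel physical min/max are symmetric around zero, so
    amplitudes survive the 16-bit quantization to within one digitizer
    step.
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))
    data = np.zeros((n_ch, n_records * spr))
    data[:, : recording.n_samples] = recording.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    dig_max, dig_min = 32767, -32768
    # exact EDF affine map: [-p, p] onto [dig_min, dig_max]
    slope = (dig_max - dig_min) / (2 * phys_max)
    offset = dig_min + phys_max * slope
    digital = np.round(
        np.clip(data * slope[:, None] + offset[:, None], dig_min, dig_max)
    ).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(recording.patient_id or "X", 80),
            _ascii_field("ictalnet synthetic", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(str(_HDR_FIXED * (1 + n_ch)), 8),
            _ascii_field("", 44),
            _ascii_field(str(n_records), 8),
            _ascii_field("1", 8),
            _ascii_field(str(n_ch), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_ascii_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_ascii_field("EEG", 80) for _ in range(n_ch)),
            b"".join(_ascii_field("uV", 8) for _ in range(n_ch)),
            b"".join(_ascii_field(f"{-p:.6g}"[:8], 8) for p in phys_max),
            b"".join(_ascii_field(f"{p:.6g}"[:8], 8) for p in phys_max),
            b"".join(_ascii_field(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(_ascii_field(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_ascii_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + per_sig)
        # records: per record, all samples of ch0, then ch1, ...
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())

    if annotations and recording.events:
        import pandas as pd

        pd.DataFrame(
            [
                dict(start_s=s, end_s=e, **{"class": CLASS_LABELS[int(k)]})
                for s, e, k in recording.events
            ]
        ).to_csv(events_sidecar(path), index=False)
    return path


def _parse_header(path: Path) -> dict:
    """Validate the fixed + per-signal header, raising FormatError with offsets."""
    raw = path.read_bytes()
    if len(raw) < _HDR_FIXED:
        raise FormatError(f"{path}: truncated EDF header (need 256 bytes, got {len(raw)})")

    def intfield(offset: int, width: int, name: str) -> int:
        txt = raw[offset : offset + width].decode("ascii", errors="replace").strip()
        try:
            return int(txt)
        except ValueError:
            raise FormatError(
                f"{path}: malformed {name} field at byte offset {offset}: {txt!r}"
            ) from None

    version = raw[0:8].decode("ascii", errors="replace").strip()
    if version != "0":
        raise FormatError(f"{path}: malformed version field at byte offset 0: {version!r}")
    n_records = intfield(236, 8, "number-of-records")
    n_ch = intfield(252, 4, "number-of-signals")
    need = _HDR_FIXED * (1 + n_ch)
    if len(raw) < need:
        raise FormatError(f"{path}: truncated signal headers (need {need} bytes)")
    spr_off = _HDR_FIXED + n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [intfield(spr_off + 8 * i, 8, "samples-per-record") for i in range(n_ch)]
    if len(set(spr)) > 1:
        raise FormatError(
            f"{path}: heterogeneous per-channel sampling rates {sorted(set(spr))} "
            "are not supported"
        )
    return dict(n_records=n_records, n_channels=n_ch, samples_per_record=spr[0])


def read_edf(path: "str | Path", *, annotations: bool = True) -> Recording:
    """Read an EDF file into a :class:`Recording` (data in µV).

    Events are attached from the ``<stem>.events.csv`` sidecar when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _parse_header(path)

    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns Volts
    patient = (raw.info.get("subject_info") or {}).get("his_id", "") or ""

    events: list[tuple[float, float, SeizureClass]] = []
    sidecar = events_sidecar(path)
    if annotations and sidecar.exists():
        import pandas as pd

        tab = pd.read_csv(sidecar)
        for _, row in tab.iterrows():
            events.append(
                (float(row["start_s"]), float(row["end_s"]),
                 SeizureClass.from_label(row["class"]))
            )
    return Recording(
        data=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        patient_id=str(patient),
        events=events,
    )
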