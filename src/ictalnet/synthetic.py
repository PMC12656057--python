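"""Synthetic multi-channel seizure-EEG cohorts.

Generates inter-ictal background (pink noise plus a posterior-dominant
alpha rhythm) and superposes class-specific ictal signatures:

* ABSZ — generalized ~3 Hz spike-and-wave trains on all channels;
* FNSZ — beta / high-beta power elevation on a contiguous focal subset;
* SPSZ — intermittent theta bursts on a small focal subset;
* TCSZ — global amplitude surge with a rhythm evolving from sustained
  fast activity into ~3-5 Hz bursting;
* TNSZ — sustained global high-beta elevation without bursting.

The cohort generator draws event durations log-uniformly so both
zero-padded (<10 s) and multi-window events occur, and reproduces a
heavily imbalanced class mix (the default proportions follow the event
distribution of a large clinical seizure corpus, where focal
non-specific events outnumber absence events by more than 100:1).
Everything is deterministic for a fixed config seed: one root seed
sequence per cohort, split per event by counter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DataError
from .recording import DEFAULT_CHANNEL_LABELS, Recording
from .seizures import CLASS_LABELS, N_CLASSES, SeizureClass

#: Event-count mix of a large clinical corpus (ABSZ, FNSZ, SPSZ, TCSZ, TNSZ).
CORPUS_EVENT_COUNTS: tuple[int, ...] = (43, 6924, 942, 247, 380)
_TOTAL = sum(CORPUS_EVENT_COUNTS)
DEFAULT_PROPORTIONS: tuple[float, ...] = tuple(c / _TOTAL for c in CORPUS_EVENT_COUNTS)

#: Contiguous focal block width for FNSZ/SPSZ signatures (channels).
FOCAL_WIDTH = 4


@dataclass
class SynthConfig:
    """Cohort-level generation parameters.

    Amplitudes are in tens of µV, the scale of scalp EEG;
    ``amplitude_scale`` multiplies every signal component uniformly.
    """

    sampling_rate: float = 250.0
    n_channels: int = 20
    n_patients: int = 10
    n_events: int = 100
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    duration_range: tuple[float, float] = (4.0, 120.0)
    amplitude_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate not in (250, 400):
            raise ValueError("sampling_rate must be 250 or 400 Hz")
        if self.n_channels < 20:
            raise ValueError("n_channels must be >= 20")
        if self.n_patients < 1 or self.n_events < 1:
            raise ValueError("n_patients and n_events must be positive")
        props = tuple(float(p) for p in self.class_proportions)
        if len(props) != N_CLASSES:
            raise ValueError(f"need {N_CLASSES} class proportions")
        if any(p < 0 for p in props):
            raise ValueError("class proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        self.class_proportions = props
        lo, hi = self.duration_range
        if lo <= 0 or hi < lo:
            raise ValueError("duration_range must satisfy 0 < min <= max")


@dataclass
class SynthCohort:
    """A generated cohort: one recording per annotated seizure event."""

    recordings: list[Recording]
    labels: list[SeizureClass]
    patient_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.recordings)


# ----------------------------------------------------------------------
# background
# ----------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, fs: float) -> np.ndarray:
    """1/f-power broadband noise, unit SD per channel, via spectral shaping."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])  # amplitude ~ f^-1/2 -> power ~ 1/f
    shape[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * shape, n=n, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def generate_background(
    config: SynthConfig, duration_s: float, seed: "int | np.random.SeedSequence"
) -> Recording:
    """Inter-ictal background: pink noise (SD ~20 µV) + ~10 Hz alpha (~10 µV).

    Deterministic for a fixed seed; the alpha rhythm has a random phase
    and a slightly jittered frequency per channel so channels are not
    perfectly coherent.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fs = config.sampling_rate
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    amp = config.amplitude_scale
    t = np.arange(n) / fs

    data = 20.0 * amp * _pink_noise(rng, config.n_channels, n, fs)
    alpha_f = rng.uniform(9.5, 10.5, size=config.n_channels)
    alpha_phase = rng.uniform(0, 2 * np.pi, size=config.n_channels)
    alpha_amp = 10.0 * amp * rng.uniform(0.8, 1.2, size=config.n_channels)
    data += alpha_amp[:, None] * np.sin(
        2 * np.pi * alpha_f[:, None] * t[None, :] + alpha_phase[:, None]
    )

    labels = tuple(DEFAULT_CHANNEL_LABELS) + tuple(
        f"EX{i}" for i in range(20, config.n_channels)
    )
    return Recording(
        data=data,
        sampling_rate=fs,
        channel_labels=labels[: config.n_channels],
    )


# ----------------------------------------------------------------------
# ictal signatures
# ----------------------------------------------------------------------

def _spike_wave(t: np.ndarray, rate_hz: float, spike_amp: float, wave_amp: float,
                rng: np.random.Generator, n_channels: int) -> np.ndarray:
    """Generalized spike-and-wave train: a sharp transient riding each slow wave."""
    phase = (t * rate_hz) % 1.0
    # sharp transient near the start of each cycle (~25 ms wide gaussian)
    spike = np.exp(-0.5 * ((phase - 0.12) / (0.025 * rate_hz)) ** 2)
    slow = np.sin(2 * np.pi * rate_hz * t)
    template = spike_amp * spike + wave_amp * slow
    gains = rng.uniform(0.8, 1.2, size=n_channels)
    return gains[:, None] * template[None, :]


def _band_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                low: float, high: float) -> np.ndarray:
    """Band-limited gaussian noise, unit SD per channel."""
    x = rng.standard_normal(shape)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=1)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _burst_envelope(t: np.ndarray, rng: np.random.Generator,
                    on_s: float = 1.0, off_s: float = 1.0) -> np.ndarray:
    """Smooth on/off envelope with jittered burst timing."""
    env = np.zeros_like(t)
    pos = float(rng.uniform(0, off_s))
    t_end = t[-1] if len(t) else 0.0
    while pos < t_end:
        dur = on_s * rng.uniform(0.7, 1.3)
        mask = (t >= pos) & (t < pos + dur)
        # raised-cosine edges
        local = (t[mask] - pos) / max(dur, 1e-9)
        env[mask] = np.maximum(env[mask], np.sin(np.pi * local) ** 2)
        pos += dur + off_s * rng.uniform(0.7, 1.3)
    return env


def generate_seizure(
    klass: "SeizureClass | str | int",
    config: SynthConfig,
    duration_s: float,
    seed: "int | np.random.SeedSequence",
) -> Recording:
    """Generate a recording whose whole extent is one ictal event of ``klass``.

    The signature is superposed on (or, for tonic-clonic events, scales)
    the pink-noise + alpha background produced by the same seed stream.
    """
    klass = SeizureClass.from_label(klass)
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    bg_ss, sig_ss = ss.spawn(2)
    rec = generate_background(config, duration_s, bg_ss)
    rng = np.random.default_rng(sig_ss)

    fs = config.sampling_rate
    n = rec.n_samples
    n_ch = config.n_channels
    t = np.arange(n) / fs
    amp = config.amplitude_scale
    data = rec.data

    if klass is SeizureClass.ABSZ:
        # ~3 Hz generalized spike-and-wave on every channel
        rate = rng.uniform(2.9, 3.1)
        data += _spike_wave(t, rate, spike_amp=120.0 * amp, wave_amp=70.0 * amp,
                            rng=rng, n_channels=n_ch)
    elif klass is SeizureClass.FNSZ:
        # focal beta / high-beta elevation on a contiguous 4-channel block
        start = int(rng.integers(0, 20 - FOCAL_WIDTH + 1))
        focal = slice(start, start + FOCAL_WIDTH)
        n_focal = FOCAL_WIDTH
        beta = 35.0 * amp * _band_noise(rng, (n_focal, n), fs, 13.0, 35.0)
        tone = 15.0 * amp * np.sin(
            2 * np.pi * rng.uniform(20, 28) * t + rng.uniform(0, 2 * np.pi)
        )
        data[focal] += beta + tone[None, :]
    elif klass is SeizureClass.SPSZ:
        # intermittent focal theta bursts
        start = int(rng.integers(0, 20 - FOCAL_WIDTH + 1))
        focal = slice(start, start + FOCAL_WIDTH)
        env = _burst_envelope(t, rng, on_s=1.2, off_s=1.0)
        theta_f = rng.uniform(5.0, 7.0)
        burst = 60.0 * amp * env * np.sin(2 * np.pi * theta_f * t + rng.uniform(0, 2 * np.pi))
        gains = rng.uniform(0.8, 1.2, size=FOCAL_WIDTH)
        data[focal] += gains[:, None] * burst[None, :]
    elif klass is SeizureClass.TCSZ:
        # global surge: sustained fast (tonic) phase evolving into 3-5 Hz bursting
        data *= 2.5
        split = int(0.4 * n)
        tonic = np.zeros(n)
        tonic[:split] = 90.0 * amp * np.sin(2 * np.pi * 10.0 * t[:split])
        clonic = np.zeros(n)
        if n > split:
            tc = t[split:]
            burst_rate = rng.uniform(3.0, 5.0)
            mod = np.sin(2 * np.pi * 1.0 * tc) ** 2  # ~1 Hz burst modulation
            clonic[split:] = 150.0 * amp * mod * np.sin(2 * np.pi * burst_rate * tc)
        gains = rng.uniform(0.8, 1.2, size=n_ch)
        data += gains[:, None] * (tonic + clonic)[None, :]
    elif klass is SeizureClass.TNSZ:
        # sustained global high-beta elevation, constant envelope
        hb_f = rng.uniform(31.0, 38.0)
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        gains = rng.uniform(0.9, 1.1, size=n_ch)
        data += 40.0 * amp * gains[:, None] * np.sin(
            2 * np.pi * hb_f * t[None, :] + phases[:, None]
        )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown seizure class: {klass!r}")

    rec.events = [(0.0, duration_s, klass)]
    return rec


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

def _apportion(proportions: tuple[float, ...], total: int) -> list[int]:
    """Largest-remainder rounding of proportions*total to integers summing to total."""
    raw = [p * total for p in proportions]
    counts = [math.floor(r) for r in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a cohort of single-event recordings.

    Each event sits inside its own recording with 2 s of pre-ictal and
    1 s of post-ictal background.  Per-class event counts follow the
    configured proportions to within one event (largest-remainder
    rounding); patients partition the events, each patient receiving at
    least one recording.  One root seed stream per cohort is split per
    event by counter, so regeneration is reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    counts = _apportion(config.class_proportions, config.n_events)
    labels = [SeizureClass(i) for i, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(labels)

    lo, hi = config.duration_range
    durations = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_events))

    # every patient gets >=1 event; remaining events assigned uniformly
    patients = [f"P{i:03d}" for i in range(config.n_patients)]
    if config.n_events < config.n_patients:
        raise ValueError("n_events must be >= n_patients")
    assignment = list(range(config.n_patients)) + list(
        rng.integers(0, config.n_patients, size=config.n_events - config.n_patients)
    )
    rng.shuffle(assignment)

    pre_s, post_s = 2.0, 1.0
    recordings: list[Recording] = []
    patient_ids: list[str] = []
    for idx, (label, dur) in enumerate(zip(labels, durations)):
        ev_ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1, idx))
        bg_ss, sz_ss = ev_ss.spawn(2)
        dur = float(dur)
        total = pre_s + dur + post_s
        rec = generate_background(config, total, bg_ss)
        ictal = generate_seizure(label, config, dur, sz_ss)
        i0 = int(round(pre_s * config.sampling_rate))
        i1 = i0 + ictal.n_samples
        rec.data[:, i0:i1] = ictal.data
        rec.events = [(pre_s, pre_s + dur, label)]
        rec.patient_id = patients[assignment[idx]]
        recordings.append(rec)
        patient_ids.append(rec.patient_id)

    return SynthCohort(recordings=recordings, labels=list(labels), patient_ids=patient_ids)


def cohort_manifest(cohort: SynthCohort):
    """Return a pandas DataFrame manifest (patient_id, event bounds, class)."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(cohort.recordings):
        for start, end, klass in rec.events:
            rows.append(
                dict(
                    recording=i,
                    patient_id=rec.patient_id,
                    event_start_s=start,
                    event_end_s=end,
                    label=CLASS_LABELS[int(klass)],
                )
            )
    return pd.DataFrame(rows)
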