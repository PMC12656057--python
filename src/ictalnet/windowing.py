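"""Event segmentation into fixed 10-s windows and noise-augmentation balancing.

Each annotated seizure event is cut into non-overlapping 10-second
windows.  Events shorter than 10 s yield one end-zero-padded window;
for longer events, a trailing partial window (<10 s) is discarded.
Class balancing creates noisy copies of existing minority-class windows
(additive Gaussian noise, SD = 1% of each channel's SD, ~40 dB SNR)
until each minority class reaches a target fraction of the majority
class size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .recording import WINDOW_SECONDS, Recording, Segment
from .seizures import SeizureClass

DEFAULT_NOISE_FRACTION = 0.01
DEFAULT_TARGET_FRACTION = 0.2


@dataclass(frozen=True)
class BalancePlan:
    """Per-class synthetic-sample counts needed to reach the balance target."""

    needed: dict[SeizureClass, int]

    def __getitem__(self, klass) -> int:
        return self.needed[SeizureClass.from_label(klass)]

    def total(self) -> int:
        return sum(self.needed.values())


def segment_events(recording: Recording) -> list[Segment]:
    """Cut every annotated event into labelled 10-s windows.

    For an event of duration ``d``: ``floor(d/10)`` full windows; if
    ``d < 10`` instead one window zero-padded at the end.  Windows
    inherit the event label and the recording's patient id.
    """
    if recording.n_channels != 20:
        raise DataError("recording must be standardized to 20 channels first")
    fs = recording.sampling_rate
    win = int(round(WINDOW_SECONDS * fs))
    segments: list[Segment] = []
    for start_s, end_s, klass in recording.events:
        i0 = int(round(start_s * fs))
        i1 = int(round(end_s * fs))
        if i0 < 0 or i1 > recording.n_samples or i0 >= i1:
            raise DataError(
                f"event ({start_s}, {end_s}) exceeds recording bounds "
                f"(patient {recording.patient_id!r})"
            )
        n_samples = i1 - i0
        if n_samples < win:
            block = np.zeros((20, win))
            block[:, :n_samples] = recording.data[:, i0:i1]
            segments.append(
                Segment(block, fs, klass, recording.patient_id, padded=True)
            )
        else:
            for w in range(n_samples // win):
                a = i0 + w * win
                segments.append(
                    Segment(
                        recording.data[:, a : a + win].copy(),
                        fs,
                        klass,
                        recording.patient_id,
                    )
                )
    return segments


def augment_noise(
    segment: Segment,
    fraction: float = DEFAULT_NOISE_FRACTION,
    seed: "int | np.random.SeedSequence" = 0,
) -> Segment:
    """Return a synthetic copy with per-channel Gaussian noise added.

    Noise SD on channel ``c`` is ``fraction * SD_c``; at the default 1%
    this corresponds to ~40 dB SNR.  Zero-variance channels receive no
    noise.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    rng = np.random.default_rng(seed)
    sd = segment.data.std(axis=1, keepdims=True)
    noise = rng.standard_normal(segment.data.shape) * (fraction * sd)
    return Segment(
        segment.data + noise,
        segment.sampling_rate,
        segment.label,
        segment.patient_id,
        padded=segment.padded,
        synthetic=True,
    )


def balance_plan(
    class_counts: "dict[SeizureClass, int] | Counter",
    target_fraction: float = DEFAULT_TARGET_FRACTION,
) -> BalancePlan:
    """Synthetic samples needed to lift each class to ``target_fraction`` of the majority.

    ``needed_c = max(0, round(target_fraction * max_count) - count_c)``.
    """
    counts = {SeizureClass.from_label(k): int(v) for k, v in class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("class counts must be non-negative")
    max_count = max(counts.values(), default=0)
    if max_count == 0:
        raise ValueError("at least one class must have samples")
    target = int(np.rint(target_fraction * max_count))
    return BalancePlan(
        needed={k: max(0, target - v) for k, v in counts.items()}
    )


def augment_to_balance(
    segments: list[Segment],
    target_fraction: float = DEFAULT_TARGET_FRACTION,
    seed: int = 0,
) -> list[Segment]:
    """Append noisy copies of minority-class segments per the balance plan.

    Source segments are drawn with replacement from the existing real
    segments of each deficient class, each copy with a fresh noise seed.
    """
    counts = Counter(s.label for s in segments)
    plan = balance_plan(counts, target_fraction)
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    out = list(segments)
    by_class: dict[SeizureClass, list[Segment]] = {}
    for s in segments:
        by_class.setdefault(s.label, []).append(s)
    for klass, n_needed in sorted(plan.needed.items()):
        if n_needed == 0 or klass not in by_class:
            continue
        pool = by_class[klass]
        picks = rng.integers(0, len(pool), size=n_needed)
        seeds = root.spawn(n_needed)
        for pick, s_seed in zip(picks, seeds):
            out.append(augment_noise(pool[pick], seed=s_seed))
    return out
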