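"""Seizure-type taxonomy.

Five clinically distinct seizure classes are modelled, with a stable
integer encoding (alphabetical order) used everywhere a class index is
needed: ABSZ=0, FNSZ=1, SPSZ=2, TCSZ=3, TNSZ=4.
"""

from __future__ import annotations

import enum


class SeizureClass(enum.IntEnum):
    """Seizure type labels.

    ABSZ
        Absence seizure: brief lapse of consciousness, classically a
        ~3 Hz generalized spike-and-wave discharge.
    FNSZ
        Focal non-specific seizure: originates in a localized region
        without a more specific focal sub-classification; typically
        shows localized beta / high-beta power changes.
    SPSZ
        Simple partial seizure: focal, consciousness preserved.
    TCSZ
        Tonic-clonic seizure: generalized, with a stiffening (tonic)
        phase evolving into rhythmic jerking (clonic) with large
        amplitude excursions.
    TNSZ
        Tonic seizure: sustained muscle stiffening without a clonic
        component.
    """

    ABSZ = 0
    FNSZ = 1
    SPSZ = 2
    TCSZ = 3
    TNSZ = 4

    @classmethod
    def from_label(cls, label: "str | int | SeizureClass") -> "SeizureClass":
        """Coerce a string label, integer code or enum member to the enum."""
        if isinstance(label, cls):
            return label
        if isinstance(label, str):
            try:
                return cls[label.strip().upper()]
            except KeyError:
                raise ValueError(f"unknown seizure class label: {label!r}") from None
        try:
            return cls(int(label))
        except (ValueError, TypeError):
            raise ValueError(f"unknown seizure class label: {label!r}") from None


#: Class labels in encoding order.
CLASS_LABELS: tuple[str, ...] = tuple(c.name for c in SeizureClass)

N_CLASSES: int = len(SeizureClass)
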