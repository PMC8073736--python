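"""Activity label vocabulary.

Eight daily physical activities, six recorded with periodic body motion and
two static postures. The integer encoding (declaration order) is fixed: it
defines the row/column order of every confusion matrix and the output order
of every softmax classifier in this package.
"""

from __future__ import annotations

from enum import IntEnum


class ActivityLabel(IntEnum):
    """The eight activity classes, with a stable 0-7 integer encoding."""

    WALKING = 0
    JOGGING = 1
    JUMPING = 2
    UPSTAIRS = 3
    DOWNSTAIRS = 4
    STILL = 5
    LYING = 6
    CYCLING = 7

    @classmethod
    def from_name(cls, name: str) -> "ActivityLabel":
        """Parse a label from a case-insensitive name, e.g. ``"walking"``."""
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown activity label {name!r}; expected one of "
                f"{[m.name.lower() for m in cls]}"
            ) from None


N_CLASSES = len(ActivityLabel)

#: Static postures: gravity offset plus sensor noise, no periodic motion.
STATIC_LABELS = frozenset({ActivityLabel.STILL, ActivityLabel.LYING})

#: Periodic activities driven by a class-specific fundamental frequency.
DYNAMIC_LABELS = frozenset(set(ActivityLabel) - STATIC_LABELS)
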