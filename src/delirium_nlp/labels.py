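"""Sentence label classes and provenance tags.

Every sentence containing a delirium keyword is assigned one of three
classes: POSITIVE (the note asserts the patient is delirious / has the
symptom), NEGATIVE (the note explicitly denies it), or NEITHER (the
keyword is used in an unrelated sense, e.g. "family confused about the
schedule").  The fixed class order below is used everywhere scores,
confusion matrices, and tie-breaks need an ordering.
"""

from __future__ import annotations

import enum


class Label(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NEITHER = "NEITHER"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: Fixed class order: POSITIVE < NEGATIVE < NEITHER (argmax ties resolve this way).
CLASS_ORDER: tuple[Label, Label, Label] = (Label.POSITIVE, Label.NEGATIVE, Label.NEITHER)

CLASS_INDEX: dict[Label, int] = {lab: i for i, lab in enumerate(CLASS_ORDER)}


class Provenance(str, enum.Enum):
    """How a sentence label was obtained."""

    HUMAN = "human"
    PATTERN = "pattern"
    MODEL = "model"

    def __str__(self) -> str:
        return self.value


def as_label(value: "str | Label") -> Label:
    """Coerce a string (any case) to a :class:`Label`."""
    if isinstance(value, Label):
        return value
    try:
        return Label[value.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown label {value!r}; expected one of "
                         f"{[l.value for l in CLASS_ORDER]}") from None
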