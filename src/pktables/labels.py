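"""The three-class label set and the canonical class order."""
from __future__ import annotations

from enum import Enum


class Label(str, Enum):
    """Gold / predicted table category."""

    PK = "PK"
    DEMOGRAPHICS = "DEMOGRAPHICS"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Global class order used for probability vectors, tie-breaks and serialization.
CLASS_ORDER: tuple[Label, Label, Label] = (Label.PK, Label.DEMOGRAPHICS, Label.OTHER)

_ALLOWED = {label.value for label in Label}


def normalize_label(value: "str | Label") -> Label:
    """Case-insensitively map a string onto the label enum.

    Raises ``ValueError`` listing the allowed labels for anything outside the
    three-class set.
    """
    if isinstance(value, Label):
        return value
    key = str(value).strip().upper()
    if key not in _ALLOWED:
        raise ValueError(
            f"unknown label {value!r}; allowed labels are "
            f"{', '.join(sorted(_ALLOWED))} (case-insensitive)"
        )
    return Label(key)
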