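"""Core record types: protein sequences and hierarchical enzyme-class labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residue codes that are syntactically legal in many databases but outside
#: the 20-letter standard alphabet the feature definitions require.
AMBIGUOUS_RESIDUES = frozenset("BZXUOJ*")

NON_ENZYME = "non_enzyme"


class LabelError(ValueError):
    """Raised for malformed or out-of-range class labels."""


@dataclass(frozen=True)
class ECLabel:
    """Enzyme label at sub-class resolution: main class 1-6, optional "X.Y"."""

    main_class: int
    sub_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.main_class not in range(1, 7):
            raise LabelError(f"main class must be in 1..6, got {self.main_class}")
        if self.sub_class is not None:
            parts = self.sub_class.split(".")
            if len(parts) != 2 or not all(p.isdigit() for p in parts):
                raise LabelError(f"sub-class must look like 'X.Y', got {self.sub_class!r}")
            if int(parts[0]) != self.main_class:
                raise LabelError(
                    f"sub-class {self.sub_class!r} does not belong to main class {self.main_class}"
                )

    def __str__(self) -> str:
        return self.sub_class if self.sub_class is not None else str(self.main_class)

    @classmethod
    def parse(cls, text: str) -> "ECLabel":
        text = text.strip()
        if "." in text:
            main = text.split(".", 1)[0]
            if not main.isdigit():
                raise LabelError(f"cannot parse label {text!r}")
            return cls(int(main), text)
        if not text.isdigit():
            raise LabelError(f"cannot parse label {text!r}")
        return cls(int(text))


@dataclass
class ProteinRecord:
    """A validated protein sequence with an optional hierarchical label.

    ``label`` is an :class:`ECLabel`, the string ``"non_enzyme"``, or ``None``
    when unlabeled.
    """

    id: str
    residues: str
    description: str = ""
    label: object = field(default=None)

    def validate(self) -> "ProteinRecord":
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )
        return self

    @property
    def is_enzyme(self) -> Optional[bool]:
        if self.label is None:
            return None
        return isinstance(self.label, ECLabel)
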