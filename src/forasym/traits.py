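"""Core data model for inter-foramina distance cohorts.

The measurement design consists of nine distances per subject, taken
between the supraorbital (SOF), infraorbital (IOF) and mental (MFO)
foramina on CBCT reconstructions:

* three *paired* vertical distances, measured on the right and left
  side independently (SOF-IOF, IOF-MFO, SOF-MFO) — these carry the
  asymmetry signal;
* three *horizontal* inter-foramina distances crossing the midline
  (SOF-SOF, IOF-IOF, MFO-MFO) — unpaired, purely descriptive.

All lengths are in centimeters and must be strictly positive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping


class PairedTrait(enum.Enum):
    """A bilateral vertical distance measured on both sides."""

    SOF_IOF = "SOF-IOF"
    IOF_MFO = "IOF-MFO"
    SOF_MFO = "SOF-MFO"


class HorizontalTrait(enum.Enum):
    """An unpaired horizontal distance crossing the facial midline."""

    SOF_SOF = "SOF-SOF"
    IOF_IOF = "IOF-IOF"
    MFO_MFO = "MFO-MFO"


class Sex(enum.Enum):
    F = "F"
    M = "M"


class Group(enum.Enum):
    """Diagnostic group: healthy control, hemimandibular elongation (HE)
    or condylar hyperplasia (CH, the screening target)."""

    CONTROL = "CONTROL"
    HE = "HE"
    CH = "CH"


def _is_valid_length(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x) and x > 0


@dataclass(frozen=True)
class BilateralPair:
    """Right/left measurements of one paired trait, in cm."""

    right: float
    left: float

    def validate(self) -> list[str]:
        problems = []
        if not _is_valid_length(self.right):
            problems.append(f"right side must be a finite positive length, got {self.right!r}")
        if not _is_valid_length(self.left):
            problems.append(f"left side must be a finite positive length, got {self.left!r}")
        return problems


@dataclass
class SubjectRecord:
    """One individual's sex, diagnostic group and nine distances.

    A paired or horizontal trait absent from the maps is treated as
    explicitly missing: it contributes nothing to asymmetry indices or
    composites but the subject still participates through its other
    traits.
    """

    subject_id: str
    sex: Sex
    group: Group
    paired: dict[PairedTrait, BilateralPair] = field(default_factory=dict)
    horizontal: dict[HorizontalTrait, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        for trait, pair in self.paired.items():
            for p in pair.validate():
                problems.append(f"{trait.value}: {p}")
        for trait, value in self.horizontal.items():
            if not _is_valid_length(value):
                problems.append(
                    f"{trait.value}: must be a finite positive length, got {value!r}"
                )
        return problems


@dataclass
class Cohort:
    """Ordered collection of subject records with unique ids."""

    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def by_group(self) -> Mapping[Group, list[SubjectRecord]]:
        out: dict[Group, list[SubjectRecord]] = {g: [] for g in Group}
        for r in self.records:
            out[r.group].append(r)
        return out
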