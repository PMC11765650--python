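"""Reading, writing and validating cohort tables.

The on-disk format is a UTF-8 comma-separated table with a fixed
header::

    subject_id,sex,group,sof_iof_r,sof_iof_l,iof_mfo_r,iof_mfo_l,
    sof_mfo_r,sof_mfo_l,sof_sof,iof_iof,mfo_mfo

Sex codes are F/M, group codes CONTROL/HE/CH, all measurements in cm.
An empty cell marks a missing trait; for paired traits both sides must
be present for the pair to be usable, so a half-present pair is
demoted to missing (strict mode rejects it instead).
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path

from .traits import (
    BilateralPair,
    Cohort,
    Group,
    HorizontalTrait,
    PairedTrait,
    Sex,
    SubjectRecord,
)

logger = logging.getLogger(__name__)

PAIRED_COLUMNS: dict[PairedTrait, tuple[str, str]] = {
    PairedTrait.SOF_IOF: ("sof_iof_r", "sof_iof_l"),
    PairedTrait.IOF_MFO: ("iof_mfo_r", "iof_mfo_l"),
    PairedTrait.SOF_MFO: ("sof_mfo_r", "sof_mfo_l"),
}
HORIZONTAL_COLUMNS: dict[HorizontalTrait, str] = {
    HorizontalTrait.SOF_SOF: "sof_sof",
    HorizontalTrait.IOF_IOF: "iof_iof",
    HorizontalTrait.MFO_MFO: "mfo_mfo",
}
HEADER: list[str] = (
    ["subject_id", "sex", "group"]
    + [c for pair in PAIRED_COLUMNS.values() for c in pair]
    + list(HORIZONTAL_COLUMNS.values())
)


class SchemaError(ValueError):
    """The file header does not match the documented column set."""


class ValidationError(ValueError):
    """A row violates the record invariants in strict mode."""


def _parse_length(raw: str, subject: str, column: str, strict: bool) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        if strict:
            raise ValidationError(
                f"subject {subject!r}, column {column}: non-numeric value {raw!r}"
            ) from None
        logger.warning("subject %r, column %s: dropping non-numeric value %r", subject, column, raw)
        return None
    if not (math.isfinite(value) and value > 0):
        if strict:
            raise ValidationError(
                f"subject {subject!r}, column {column}: measurement must be positive, got {value}"
            )
        logger.warning("subject %r, column %s: dropping non-positive value %r", subject, column, value)
        return None
    return value


def read_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    In strict mode any invalid cell aborts with :class:`ValidationError`
    naming the subject and column; in lenient mode invalid cells become
    missing traits and are logged at warning level.  Unknown sex/group
    codes are always errors, as is a malformed header.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header {HEADER}")
        missing_cols = [c for c in HEADER if c not in reader.fieldnames]
        if missing_cols:
            raise SchemaError(f"{path}: missing required columns {missing_cols}")
        records: list[SubjectRecord] = []
        for row in reader:
            subject = (row["subject_id"] or "").strip()
            if not subject:
                raise ValidationError(f"{path}: row with empty subject_id")
            try:
                sex = Sex(row["sex"].strip().upper())
            except ValueError:
                raise ValidationError(
                    f"subject {subject!r}: unknown sex code {row['sex']!r}"
                ) from None
            try:
                group = Group(row["group"].strip().upper())
            except ValueError:
                raise ValidationError(
                    f"subject {subject!r}: unknown group code {row['group']!r}"
                ) from None
            paired: dict[PairedTrait, BilateralPair] = {}
            for trait, (col_r, col_l) in PAIRED_COLUMNS.items():
                r = _parse_length(row[col_r], subject, col_r, strict)
                l = _parse_length(row[col_l], subject, col_l, strict)
                if r is not None and l is not None:
                    paired[trait] = BilateralPair(right=r, left=l)
                elif r is not None or l is not None:
                    logger.warning(
                        "subject %r: trait %s has only one side, treated as missing",
                        subject, trait.value,
                    )
            horizontal: dict[HorizontalTrait, float] = {}
            for trait, col in HORIZONTAL_COLUMNS.items():
                v = _parse_length(row[col], subject, col, strict)
                if v is not None:
                    horizontal[trait] = v
            records.append(SubjectRecord(subject, sex, group, paired, horizontal))
    cohort = Cohort(records=records, provenance=str(path))
    dup = _duplicate_ids(cohort)
    if dup:
        raise ValidationError(f"{path}: duplicate subject ids {sorted(dup)}")
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the documented CSV format; missing traits become empty cells.

    ``read_cohort(write_cohort(c))`` reproduces every retained
    measurement exactly (values are rendered with ``repr`` round-trip
    precision).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for rec in cohort:
            row: list[str] = [rec.subject_id, rec.sex.value, rec.group.value]
            for trait in PAIRED_COLUMNS:
                pair = rec.paired.get(trait)
                row += ["", ""] if pair is None else [_fmt(pair.right), _fmt(pair.left)]
            for trait in HORIZONTAL_COLUMNS:
                v = rec.horizontal.get(trait)
                row.append("" if v is None else _fmt(v))
            writer.writerow(row)


def _fmt(x: float) -> str:
    return repr(float(x))


def _duplicate_ids(cohort: Cohort) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for r in cohort:
        if r.subject_id in seen:
            dup.add(r.subject_id)
        seen.add(r.subject_id)
    return dup


def validate_cohort(cohort: Cohort) -> list[str]:
    """Return one finding per invariant violation (empty list if valid)."""
    findings: list[str] = []
    for sid in sorted(_duplicate_ids(cohort)):
        findings.append(f"duplicate subject_id {sid!r}")
    for rec in cohort:
        for problem in rec.validate():
            findings.append(f"subject {rec.subject_id!r}: {problem}")
    return findings
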