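"""Palmer-style fluctuating-asymmetry indices.

For a bilateral trait measured as R (right) and L (left):

* ``FA1 = |R - L|`` — absolute asymmetry, in the trait's units (cm);
* ``FA2 = |R - L| / ((R + L) / 2)`` — asymmetry relative to the
  individual's bilateral mean, dimensionless and scale-invariant,
  which removes between-subject size variation.

Composite predictors ``Total FA1`` / ``Total FA2`` sum the per-trait
index over the three paired vertical distances (SOF-IOF, IOF-MFO,
SOF-MFO).  Horizontal distances have no left/right pairing and hence
no FA index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .traits import BilateralPair, Cohort, PairedTrait, SubjectRecord


class EmptyIndexError(ValueError):
    """All paired traits of a subject are missing; no FA index exists."""


def _check_pair(pair: BilateralPair) -> None:
    problems = pair.validate()
    if problems:
        raise ValueError("; ".join(problems))


def compute_fa1(pair: BilateralPair) -> float:
    """``|R - L|`` in cm; symmetric in its arguments."""
    _check_pair(pair)
    return abs(pair.right - pair.left)


def compute_fa2(pair: BilateralPair) -> float:
    """``|R - L| / ((R + L) / 2)``; lies in [0, 2) for positive sides."""
    _check_pair(pair)
    return abs(pair.right - pair.left) / ((pair.right + pair.left) / 2.0)


@dataclass
class FAIndexSet:
    """Per-trait FA1/FA2 of one subject plus composite sums.

    ``traits_used`` records which paired traits entered the composites;
    a missing trait is simply excluded from the sums.
    """

    fa1: dict[PairedTrait, float] = field(default_factory=dict)
    fa2: dict[PairedTrait, float] = field(default_factory=dict)
    traits_used: tuple[PairedTrait, ...] = ()

    @property
    def total_fa1(self) -> float:
        return sum(self.fa1[t] for t in self.traits_used)

    @property
    def total_fa2(self) -> float:
        return sum(self.fa2[t] for t in self.traits_used)


def compute_fa_set(record: SubjectRecord) -> FAIndexSet:
    """FA1/FA2 for every non-missing paired trait of one subject."""
    out = FAIndexSet()
    used = []
    for trait in PairedTrait:
        pair = record.paired.get(trait)
        if pair is None:
            continue
        out.fa1[trait] = compute_fa1(pair)
        out.fa2[trait] = compute_fa2(pair)
        used.append(trait)
    if not used:
        raise EmptyIndexError(
            f"subject {record.subject_id!r}: all paired traits missing, no FA index defined"
        )
    out.traits_used = tuple(used)
    return out


def cohort_fa_table(cohort: Cohort, strict: bool = True) -> pd.DataFrame:
    """One row per subject with per-trait fa1/fa2 and the totals.

    Columns: ``<trait>_fa1`` / ``<trait>_fa2`` for the three paired
    traits (NaN where missing), ``total_fa1``, ``total_fa2`` and
    ``n_traits_used``.  Row order follows cohort order; the index is
    the subject id.  In lenient mode a subject with no usable paired
    trait gets an all-NaN row instead of raising.
    """
    rows = []
    index = []
    for rec in cohort:
        index.append(rec.subject_id)
        try:
            fa = compute_fa_set(rec)
        except EmptyIndexError:
            if strict:
                raise
            rows.append({})
            continue
        row: dict[str, float] = {}
        for trait in fa.traits_used:
            key = trait.name.lower()
            row[f"{key}_fa1"] = fa.fa1[trait]
            row[f"{key}_fa2"] = fa.fa2[trait]
        row["total_fa1"] = fa.total_fa1
        row["total_fa2"] = fa.total_fa2
        row["n_traits_used"] = len(fa.traits_used)
        rows.append(row)
    columns = (
        [f"{t.name.lower()}_fa1" for t in PairedTrait]
        + [f"{t.name.lower()}_fa2" for t in PairedTrait]
        + ["total_fa1", "total_fa2", "n_traits_used"]
    )
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"), columns=columns)
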