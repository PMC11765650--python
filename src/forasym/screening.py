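"""ROC and cutpoint analysis for FA indices as CH screening predictors.

The classification convention throughout is *higher score = more
likely positive* and the decision rule at a threshold t is
``score >= t -> positive``; condylar hyperplasia (CH) is the positive
class by default and every other diagnostic group is negative.

AUC is computed by pair counting (the Mann-Whitney formulation): the
fraction of (positive, negative) score pairs with the positive score
higher, counting ties as one half.  This is algebraically identical to
the trapezoidal area under the empirical ROC step curve; the test
suite verifies the equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import cohort_fa_table
from .traits import Cohort, Group, PairedTrait


@dataclass(frozen=True)
class LabeledScores:
    """One predictor's value per subject, with binary class labels."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = positive class
    positive_class: str = Group.CH.value

    @staticmethod
    def from_arrays(scores, labels, positive_class: str = Group.CH.value) -> "LabeledScores":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be parallel 1-D arrays")
        if scores.size < 2:
            raise ValueError("need at least two subjects")
        if not labels.any():
            raise ValueError("no positive subjects")
        if labels.all():
            raise ValueError("no negative subjects")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        return LabeledScores(scores, labels, positive_class)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class RocCurve:
    """(threshold, sensitivity, specificity) triples plus the AUC.

    Thresholds run from -inf (everything positive: sens 1, spec 0) up
    through each observed score to +inf above the maximum (nothing
    positive: sens 0, spec 1).
    """

    points: tuple[tuple[float, float, float], ...]
    auc: float


@dataclass(frozen=True)
class CutpointReport:
    """One predictor's optimal-cutpoint row: the screening metrics."""

    predictor: str
    cutpoint: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float
    auc: float


def pair_count_auc(data: LabeledScores) -> float:
    """P(positive score > negative score) + 0.5 P(tie)."""
    pos = data.scores[data.labels]
    neg = data.scores[~data.labels]
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (pos.size * neg.size))


def confusion_at(data: LabeledScores, cutpoint: float) -> ConfusionCounts:
    """Counts under the rule ``score >= cutpoint -> positive``."""
    pred = data.scores >= cutpoint
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & data.labels)),
        fp=int(np.count_nonzero(pred & ~data.labels)),
        tn=int(np.count_nonzero(~pred & ~data.labels)),
        fn=int(np.count_nonzero(~pred & data.labels)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and Youden's index.

    PPV/NPV are NaN when their denominator is zero (no predicted
    positives / negatives); an empty truth class is a domain error.
    """
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics require at least one true positive-class "
                         "and one true negative-class subject")
    sens = counts.tp / n_pos
    spec = counts.tn / n_neg
    ppv = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else float("nan")
    npv = counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "youden": sens + spec - 1.0,
    }


def build_roc(data: LabeledScores) -> RocCurve:
    """Empirical ROC over thresholds at every observed score plus sentinels."""
    thresholds = np.concatenate(
        [[-np.inf], np.unique(data.scores), [np.inf]]
    )
    n_pos = int(np.count_nonzero(data.labels))
    n_neg = data.labels.size - n_pos
    points = []
    for t in thresholds:
        c = confusion_at(data, t)
        points.append((float(t), c.tp / n_pos, c.tn / n_neg))
    return RocCurve(points=tuple(points), auc=pair_count_auc(data))


def trapezoid_auc(curve: RocCurve) -> float:
    """Trapezoidal area under the step curve, in (FPR, TPR) space."""
    # points run threshold-ascending, i.e. FPR-descending; reverse to
    # traverse the curve from (0,0) to (1,1)
    fpr = np.array([1.0 - spec for _, _, spec in curve.points])[::-1]
    tpr = np.array([sens for _, sens, _ in curve.points])[::-1]
    return float(np.trapezoid(tpr, fpr))


def optimal_cutpoint(data: LabeledScores, predictor: str = "") -> CutpointReport:
    """Scan observed score values for the Youden-optimal cutpoint.

    Ties on Youden's index are broken toward higher sensitivity, then
    toward the lower cutpoint — a screening test favors catching
    positives over parsimony of referrals.
    """
    best = None
    for t in np.unique(data.scores):
        m = metrics(confusion_at(data, float(t)))
        key = (m["youden"], m["sensitivity"], -t)
        if best is None or key > best[0]:
            best = (key, float(t), m)
    _, cut, m = best
    return CutpointReport(
        predictor=predictor,
        cutpoint=cut,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        ppv=m["ppv"],
        npv=m["npv"],
        youden=m["youden"],
        auc=pair_count_auc(data),
    )


#: Predictor columns of the FA table, in report order: the six
#: single-trait indices ordered by discriminative focus, then the
#: composites (Total FA1 goes beyond the customary seven-row layout).
PREDICTOR_ORDER: list[tuple[str, str]] = [
    ("IOF-MFO FA1", "iof_mfo_fa1"),
    ("IOF-MFO FA2", "iof_mfo_fa2"),
    ("SOF-MFO FA1", "sof_mfo_fa1"),
    ("SOF-MFO FA2", "sof_mfo_fa2"),
    ("SOF-IOF FA2", "sof_iof_fa2"),
    ("SOF-IOF FA1", "sof_iof_fa1"),
    ("Total FA2", "total_fa2"),
    ("Total FA1", "total_fa1"),
]


def labeled_scores_from(fa_table: pd.DataFrame, cohort: Cohort, column: str,
                        positive_class: str = Group.CH.value) -> LabeledScores:
    """Extract one predictor column with CH-vs-rest labels, dropping NaNs."""
    groups = pd.Series([r.group.value for r in cohort], index=cohort.subject_ids())
    scores = fa_table[column]
    mask = scores.notna()
    return LabeledScores.from_arrays(
        scores[mask].to_numpy(),
        (groups[mask] == positive_class).to_numpy(),
        positive_class,
    )


def screening_report(fa_table: pd.DataFrame, cohort: Cohort,
                     positive_class: str = Group.CH.value) -> pd.DataFrame:
    """Optimal-cutpoint report for all eight FA predictors.

    One row per predictor (FA1 and FA2 of each paired trait plus the
    two composite sums) with cutpoint, sensitivity/specificity, PPV,
    NPV, Youden's index and AUC.
    """
    if positive_class not in {g.value for g in Group}:
        raise ValueError(f"unknown positive class {positive_class!r}")
    rows = []
    for name, column in PREDICTOR_ORDER:
        data = labeled_scores_from(fa_table, cohort, column, positive_class)
        rep = optimal_cutpoint(data, predictor=name)
        rows.append({
            "predictor": rep.predictor,
            "cutpoint": rep.cutpoint,
            "sensitivity_pct": 100.0 * rep.sensitivity,
            "specificity_pct": 100.0 * rep.specificity,
            "ppv_pct": 100.0 * rep.ppv,
            "npv_pct": 100.0 * rep.npv,
            "youden": rep.youden,
            "auc": rep.auc,
        })
    return pd.DataFrame(rows)


def screening_report_for_cohort(cohort: Cohort,
                                positive_class: str = Group.CH.value) -> pd.DataFrame:
    """Convenience wrapper: FA table + screening report in one call."""
    return screening_report(cohort_fa_table(cohort), cohort, positive_class)
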