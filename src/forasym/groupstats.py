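"""Descriptive and nonparametric inferential comparisons.

Two report layers sit on top of the cohort and its FA table:

* sex comparison — per-sex mean/median/SD and a two-sided
  Mann–Whitney U p-value for each of the 15 analysis variables
  (six side-specific paired measurements, six per-trait FA1/FA2
  indices, three horizontal distances);
* diagnostic-group comparison — Kruskal–Wallis across
  CONTROL/HE/CH for the same variables, with pairwise post-hoc
  p-values (Dwass–Steel–Critchlow–Fligner by default, Dunn with
  Holm adjustment selectable).

Mann–Whitney p-values are exact for small tie-free samples (both
n <= 8) and otherwise use the tie-corrected normal approximation
with continuity correction.  No multiplicity correction is applied
across variables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .traits import Cohort, Group, HorizontalTrait, PairedTrait, Sex


@dataclass(frozen=True)
class DescriptiveSummary:
    variable: str
    stratum: str
    mean: float
    median: float
    sd: float
    n: int


@dataclass(frozen=True)
class TwoGroupTestResult:
    variable: str
    u_statistic: float
    p_value: float
    groups: tuple[str, str]


@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    chi2: float
    df: int
    p_value: float
    posthoc: dict[tuple[str, str], float]


def summarize(values: Sequence[float], variable: str = "", stratum: str = "",
              strict: bool = False) -> DescriptiveSummary:
    """Arithmetic mean, sample median and n-1 SD of one stratum.

    For a single observation the SD is reported as 0.0 unless
    ``strict`` is set, in which case it is a domain error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("summarize requires at least one value")
    if arr.size == 1:
        if strict:
            raise ValueError("sample SD undefined for n = 1 in strict mode")
        sd = 0.0
    else:
        sd = float(np.std(arr, ddof=1))
    return DescriptiveSummary(
        variable=variable,
        stratum=stratum,
        mean=float(np.mean(arr)),
        median=float(np.median(arr)),
        sd=sd,
        n=int(arr.size),
    )


def _has_ties(combined: np.ndarray) -> bool:
    return np.unique(combined).size < combined.size


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 variable: str = "", groups: tuple[str, str] = ("a", "b")
                 ) -> TwoGroupTestResult:
    """Two-sided Mann–Whitney U test; U is reported for the first group.

    Exact enumeration when both samples have n <= 8 and the pooled data
    are tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction.  Pooled constant data give
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return TwoGroupTestResult(variable, a.size * b.size / 2.0, 1.0, groups)
    exact = a.size <= 8 and b.size <= 8 and not _has_ties(combined)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return TwoGroupTestResult(variable, float(res.statistic),
                              float(min(res.pvalue, 1.0)), groups)


def kruskal_wallis(groups: Sequence[Sequence[float]], variable: str = "",
                   labels: Sequence[str] | None = None) -> GroupTestResult:
    """Kruskal–Wallis H with midranks and tie correction; p from chi2.

    All-constant pooled data are a defined degenerate case (H = 0,
    p = 1), not an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("kruskal_wallis requires non-empty groups")
    if sum(g.size for g in arrays) < 3:
        raise ValueError("kruskal_wallis requires total n >= 3")
    df = len(arrays) - 1
    combined = np.concatenate(arrays)
    if np.all(combined == combined[0]):
        return GroupTestResult(variable, 0.0, df, 1.0, {})
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(variable, float(h), df, float(p), {})


def _tie_term(combined: np.ndarray) -> float:
    _, counts = np.unique(combined, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _dscf_pair_p(x: np.ndarray, y: np.ndarray, k: int) -> float:
    # studentized-range p for one pair, following the DSCF construction:
    # the pair is re-ranked in isolation and its Mann-Whitney U compared
    # against the q distribution with k groups.
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(combined) / (n * (n - 1)))
    if var <= 0:
        return 1.0
    q = math.sqrt(2.0) * abs(u - mu) / math.sqrt(var)
    return float(stats.studentized_range.sf(q, k, np.inf))


def _dunn_pairwise(arrays: list[np.ndarray], labels: list[str]) -> dict[tuple[str, str], float]:
    combined = np.concatenate(arrays)
    n = combined.size
    ranks = stats.rankdata(combined)
    mean_ranks = []
    i = 0
    for g in arrays:
        mean_ranks.append(ranks[i:i + g.size].mean())
        i += g.size
    tie_corr = _tie_term(combined) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_corr
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    raw = []
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    # Holm step-down adjustment over the C(k,2) pairs
    order = np.argsort(raw)
    m = len(raw)
    adj = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(1.0, running)
    return {(labels[i], labels[j]): adj[t] for t, (i, j) in enumerate(pairs)}


def posthoc_pairwise(groups: Sequence[Sequence[float]],
                     labels: Sequence[str] | None = None,
                     method: str = "dscf") -> dict[tuple[str, str], float]:
    """All-pairs post-hoc p-values after Kruskal–Wallis.

    ``method='dscf'`` — Dwass–Steel–Critchlow–Fligner pairwise rank
    tests against the studentized-range distribution (the default of
    common menu-driven statistics software); ``method='dunn'`` — Dunn's
    z-tests on the joint ranking with Holm adjustment.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("posthoc requires non-empty groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(arrays))]
    labels = list(labels)
    if method == "dscf":
        k = len(arrays)
        return {
            (labels[i], labels[j]): _dscf_pair_p(arrays[i], arrays[j], k)
            for i, j in itertools.combinations(range(k), 2)
        }
    if method == "dunn":
        return _dunn_pairwise(arrays, labels)
    raise ValueError(f"unknown post-hoc method {method!r} (expected 'dscf' or 'dunn')")


# ---------------------------------------------------------------------------
# Analysis-variable extraction and the two report tables
# ---------------------------------------------------------------------------

#: Row order of the report tables: per paired trait right, left, FA1, FA2,
#: then the three horizontal distances.
VARIABLE_ORDER: list[str] = [
    name
    for t in PairedTrait
    for name in (f"{t.value} right", f"{t.value} left", f"{t.value} FA1", f"{t.value} FA2")
] + [t.value for t in HorizontalTrait]


def variable_table(cohort: Cohort, fa_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject table of the 15 analysis variables plus sex/group."""
    rows = []
    for rec in cohort:
        row: dict[str, object] = {"sex": rec.sex.value, "group": rec.group.value}
        for t in PairedTrait:
            pair = rec.paired.get(t)
            key = t.name.lower()
            row[f"{t.value} right"] = pair.right if pair else np.nan
            row[f"{t.value} left"] = pair.left if pair else np.nan
            row[f"{t.value} FA1"] = fa_table.loc[rec.subject_id, f"{key}_fa1"]
            row[f"{t.value} FA2"] = fa_table.loc[rec.subject_id, f"{key}_fa2"]
        for t in HorizontalTrait:
            row[t.value] = rec.horizontal.get(t, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(cohort.subject_ids(), name="subject_id"),
                        columns=["sex", "group"] + VARIABLE_ORDER)


def sex_comparison_report(cohort: Cohort, fa_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sex descriptives and Mann–Whitney p for each analysis variable.

    Two rows (Female then Male) per variable, mirroring the layout of a
    stratified descriptive table; the p-value is repeated on both rows.
    """
    table = variable_table(cohort, fa_table)
    present = set(table["sex"])
    if not {"F", "M"} <= present:
        raise ValueError(f"sex comparison requires both sexes, found {sorted(present)}")
    out = []
    for var in VARIABLE_ORDER:
        f_vals = table.loc[table["sex"] == "F", var].dropna().to_numpy()
        m_vals = table.loc[table["sex"] == "M", var].dropna().to_numpy()
        test = mann_whitney(f_vals, m_vals, variable=var, groups=("Female", "Male"))
        for label, vals in (("Female", f_vals), ("Male", m_vals)):
            s = summarize(vals, variable=var, stratum=label)
            out.append({
                "variable": var, "stratum": label, "mean": s.mean,
                "median": s.median, "sd": s.sd, "n": s.n,
                "u_statistic": test.u_statistic, "p_value": test.p_value,
                "significant": test.p_value <= 0.05,
            })
    return pd.DataFrame(out)


def group_comparison_report(cohort: Cohort, fa_table: pd.DataFrame,
                            posthoc: str = "dscf") -> pd.DataFrame:
    """Kruskal–Wallis across CONTROL/HE/CH plus pairwise post-hoc p-values.

    One row per analysis variable with chi2, df (= 2 for three groups),
    the omnibus p and the three pairwise p's.
    """
    table = variable_table(cohort, fa_table)
    labels = [g.value for g in Group]
    missing = [g for g in labels if g not in set(table["group"])]
    if missing:
        raise ValueError(f"group comparison requires all three groups, missing {missing}")
    out = []
    for var in VARIABLE_ORDER:
        arrays = [table.loc[table["group"] == g, var].dropna().to_numpy() for g in labels]
        kw = kruskal_wallis(arrays, variable=var, labels=labels)
        ph = posthoc_pairwise(arrays, labels=labels, method=posthoc)
        row = {
            "variable": var, "chi2": kw.chi2, "df": kw.df, "p_value": kw.p_value,
            "significant": kw.p_value <= 0.05,
        }
        for (g1, g2), p in ph.items():
            row[f"p_{g1}_{g2}"] = p
        out.append(row)
    return pd.DataFrame(out)
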