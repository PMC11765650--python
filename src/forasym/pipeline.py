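"""End-to-end analysis orchestration: validate -> FA -> sex table ->
group table -> screening report, with a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .groupstats import group_comparison_report, sex_comparison_report
from .indices import cohort_fa_table
from .io import read_cohort
from .screening import screening_report
from .traits import Cohort, Group

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str
    out_dir: str
    positive_class: str = Group.CH.value
    posthoc: str = "dscf"
    alpha: float = 0.05
    strict: bool = True
    formats: tuple[str, ...] = ("csv", "json")

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.positive_class not in {g.value for g in Group}:
            raise ValueError(f"unknown positive class {self.positive_class!r}")
        if self.posthoc not in {"dscf", "dunn"}:
            raise ValueError(f"unknown post-hoc method {self.posthoc!r}")


@dataclass
class RunManifest:
    version: str
    config: dict
    input_sha256: str
    row_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _emit(df: pd.DataFrame, out_dir: Path, stem: str, formats: tuple[str, ...],
          manifest: RunManifest) -> None:
    if "csv" in formats:
        p = out_dir / f"{stem}.csv"
        df.to_csv(p, index=df.index.name is not None)
        manifest.outputs[str(p)] = _sha256(p)
    if "json" in formats:
        p = out_dir / f"{stem}.json"
        df.reset_index().to_json(p, orient="records", indent=2)
        manifest.outputs[str(p)] = _sha256(p)


def run_all(config: RunConfig) -> RunManifest:
    """Run every analysis stage and write all reports plus a manifest.

    Stage failures after the FA table (e.g. a missing sex or group) are
    recorded as warnings and the remaining stages still run, so a
    partial cohort still yields the reports it supports.
    """
    config.validate()
    in_path = Path(config.input_path)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config={k: list(v) if isinstance(v, tuple) else v
                for k, v in config.__dict__.items()},
        input_sha256=_sha256(in_path),
    )

    cohort = read_cohort(in_path, strict=config.strict)
    manifest.row_counts["subjects"] = len(cohort)

    fa = cohort_fa_table(cohort, strict=config.strict)
    manifest.row_counts["fa_table"] = len(fa)
    _emit(fa, out_dir, "fa_table", config.formats, manifest)

    for stem, fn in [
        ("sex_report", lambda: sex_comparison_report(cohort, fa)),
        ("group_report", lambda: group_comparison_report(cohort, fa, posthoc=config.posthoc)),
        ("screening_report", lambda: screening_report(fa, cohort, config.positive_class)),
    ]:
        try:
            df = fn()
        except ValueError as exc:
            msg = f"stage {stem} skipped: {exc}"
            logger.warning(msg)
            manifest.warnings.append(msg)
            continue
        manifest.row_counts[stem] = len(df)
        _emit(df, out_dir, stem, config.formats, manifest)

    mpath = out_dir / "manifest.json"
    mpath.write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# Plain-text rendering
# ---------------------------------------------------------------------------

def _mark(p: float, alpha: float) -> str:
    return " *" if p <= alpha else ""


def render_sex_table(report: pd.DataFrame, alpha: float = 0.05) -> str:
    """Stratified descriptives table; '*' marks p <= alpha (inclusive)."""
    lines = [f"{'Variable':<16}{'Group':<8}{'Mean':>9}{'Median':>9}{'SD':>9}  p-value"]
    for _, row in report.iterrows():
        p = f"{row['p_value']:.3f}{_mark(row['p_value'], alpha)}" if row["stratum"] == "Female" else ""
        lines.append(
            f"{row['variable']:<16}{row['stratum']:<8}"
            f"{row['mean']:>9.4f}{row['median']:>9.4f}{row['sd']:>9.4f}  {p}"
        )
    return "\n".join(lines)


def render_group_table(report: pd.DataFrame, alpha: float = 0.05) -> str:
    lines = [f"{'Variable':<16}{'chi2':>8}{'df':>4}  p-value"]
    for _, row in report.iterrows():
        lines.append(
            f"{row['variable']:<16}{row['chi2']:>8.3f}{row['df']:>4}  "
            f"{row['p_value']:.3f}{_mark(row['p_value'], alpha)}"
        )
    return "\n".join(lines)


def render_screening_table(report: pd.DataFrame) -> str:
    header = (f"{'Predictor':<14}{'Cutpoint':>9}{'Sensitivity (%)':>17}"
              f"{'Specificity (%)':>17}{'PPV (%)':>9}{'NPV (%)':>9}"
              f"{'Youden':>8}{'AUC':>7}")
    lines = [header]
    for _, row in report.iterrows():
        lines.append(
            f"{row['predictor']:<14}{row['cutpoint']:>9.3f}"
            f"{row['sensitivity_pct']:>17.2f}{row['specificity_pct']:>17.2f}"
            f"{row['ppv_pct']:>9.2f}{row['npv_pct']:>9.2f}"
            f"{row['youden']:>8.3f}{row['auc']:>7.3f}"
        )
    return "\n".join(lines)
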