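"""Synthetic inter-foramina cohort generator.

The generator emulates the statistical structure the analysis
assumes rather than any imaging physics:

* per-sex trait baselines (cm) for all nine distances, scaled by a
  per-subject size factor ``s ~ Normal(1, between_subject_cv)``;
* a signed bilateral deviate ``d ~ Normal(0, fa_scale(trait, group))``
  split evenly across sides, so ``FA1 = |R - L|`` is half-normal with
  scale ``fa_scale`` when measurement noise is off (mean
  ``fa_scale * sqrt(2/pi)``);
* optional directional asymmetry (a constant signed R-L offset);
* independent per-side measurement noise ``Normal(0, measurement_sd)``.

Group structure: condylar hyperplasia (CH) carries a 5x elevated
asymmetry scale on every paired trait; hemimandibular elongation (HE)
matches controls except on SOF-MFO, where it is doubled.  Sex affects
baselines only, never the asymmetry scales.

Each subject draws from its own counter-derived random stream, so a
cohort is reproducible from ``(config, seed)`` alone and insensitive
to generation order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cohort_io
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

Trait = PairedTrait | HorizontalTrait

#: Per-sex baseline means (cm).  Paired-trait baselines are right-side
#: reference values; the same baseline feeds both sides.
DEFAULT_BASELINES: dict[tuple[str, str], float] = {
    ("SOF_IOF", "F"): 4.5473, ("SOF_IOF", "M"): 4.7300,
    ("IOF_MFO", "F"): 6.1920, ("IOF_MFO", "M"): 6.7920,
    ("SOF_MFO", "F"): 10.5927, ("SOF_MFO", "M"): 11.3607,
    ("SOF_SOF", "F"): 5.1813, ("SOF_SOF", "M"): 5.6933,
    ("IOF_IOF", "F"): 5.2087, ("IOF_IOF", "M"): 5.5587,
    ("MFO_MFO", "F"): 4.7807, ("MFO_MFO", "M"): 4.9480,
}

#: Control-group asymmetry scales (cm), chosen so the half-normal FA1
#: mean sigma*sqrt(2/pi) lands near typical observed per-trait FA1
#: means (~0.14, 0.40, 0.50 cm respectively).
DEFAULT_CONTROL_FA_SCALE: dict[str, float] = {
    "SOF_IOF": 0.17,
    "IOF_MFO": 0.50,
    "SOF_MFO": 0.63,
}

CH_RATIO = 5.0          # CH asymmetry scale vs control, every paired trait
HE_SOF_MFO_RATIO = 2.0  # HE elevation, SOF-MFO only


@dataclass
class SyntheticConfig:
    """Complete parameterization of one synthetic cohort."""

    n_per_cell: int = 5  # subjects per (group x sex) cell; 5 -> 30 total
    trait_baseline: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    between_subject_cv: float = 0.05
    measurement_sd: float = 0.03
    directional_asymmetry: dict[str, float] = field(
        default_factory=lambda: {t.name: 0.0 for t in PairedTrait})
    fa_scale: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if any(v <= 0 for v in self.trait_baseline.values()):
            raise ValueError("all trait baselines must be positive")
        if any(v < 0 for v in self.fa_scale.values()):
            raise ValueError("fa_scale values must be non-negative")
        if self.between_subject_cv < 0 or self.measurement_sd < 0:
            raise ValueError("noise scales must be non-negative")
        for t in PairedTrait:
            for g in Group:
                if (t.name, g.value) not in self.fa_scale:
                    raise ValueError(f"fa_scale missing entry for ({t.name}, {g.value})")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["trait_baseline"] = {f"{t}|{s}": v for (t, s), v in self.trait_baseline.items()}
        d["fa_scale"] = {f"{t}|{g}": v for (t, g), v in self.fa_scale.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "SyntheticConfig":
        d = json.loads(text)
        d["trait_baseline"] = {
            tuple(k.split("|")): v for k, v in d["trait_baseline"].items()}
        d["fa_scale"] = {tuple(k.split("|")): v for k, v in d["fa_scale"].items()}
        return SyntheticConfig(**d)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The reference cohort design: 30 subjects, 10 per diagnostic group,
    sex-balanced, with the CH 5x / HE SOF-MFO 2x asymmetry structure."""
    fa_scale: dict[tuple[str, str], float] = {}
    for t in PairedTrait:
        base = DEFAULT_CONTROL_FA_SCALE[t.name]
        fa_scale[(t.name, Group.CONTROL.value)] = base
        fa_scale[(t.name, Group.CH.value)] = CH_RATIO * base
        fa_scale[(t.name, Group.HE.value)] = (
            HE_SOF_MFO_RATIO * base if t is PairedTrait.SOF_MFO else base)
    return SyntheticConfig(fa_scale=fa_scale, seed=seed)


def null_config(seed: int = 0) -> SyntheticConfig:
    """All three groups share the control asymmetry scales (no group
    effect anywhere) — the type-I-error design."""
    cfg = default_config(seed)
    for t in PairedTrait:
        base = DEFAULT_CONTROL_FA_SCALE[t.name]
        for g in Group:
            cfg.fa_scale[(t.name, g.value)] = base
    return cfg


def strong_ch_config(seed: int = 0, n_per_cell: int = 50) -> SyntheticConfig:
    """The high-power design: 100 subjects per diagnostic group with the
    default CH 5x asymmetry elevation."""
    cfg = default_config(seed)
    cfg.n_per_cell = n_per_cell
    return cfg


@dataclass
class GeneratorReceipt:
    """Echo of the generating configuration plus realized FA summaries."""

    config_json: str
    seed: int
    realized_mean_fa1: dict[tuple[str, str], float]  # (trait, group) -> mean |R-L|

    def to_json(self) -> str:
        return json.dumps({
            "config": json.loads(self.config_json),
            "seed": self.seed,
            "realized_mean_fa1": {
                f"{t}|{g}": v for (t, g), v in self.realized_mean_fa1.items()},
        }, indent=2, sort_keys=True)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     what: str) -> float:
    """One Normal(mean, sd) draw, redrawing any non-positive value."""
    if sd == 0:
        if mean <= 0:
            raise ValueError(f"{what}: degenerate non-positive value {mean}")
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
        logger.warning("rejected non-positive draw for %s, redrawing", what)
    raise RuntimeError(f"{what}: could not draw a positive value")


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, GeneratorReceipt]:
    """Generate one cohort deterministically from (config, seed)."""
    config.validate()
    records: list[SubjectRecord] = []
    fa1_acc: dict[tuple[str, str], list[float]] = {
        (t.name, g.value): [] for t in PairedTrait for g in Group}
    counter = 0
    for group in Group:
        for sex in Sex:
            for i in range(config.n_per_cell):
                # documented counter scheme: stream = SeedSequence((seed, counter))
                rng = np.random.default_rng(np.random.SeedSequence((config.seed, counter)))
                sid = f"SYN-{group.value}-{sex.value}-{i + 1:03d}"
                s = rng.normal(1.0, config.between_subject_cv)
                while s <= 0:
                    s = rng.normal(1.0, config.between_subject_cv)
                paired: dict[PairedTrait, BilateralPair] = {}
                for t in PairedTrait:
                    b = s * config.trait_baseline[(t.name, sex.value)]
                    d = rng.normal(0.0, config.fa_scale[(t.name, group.value)])
                    da = config.directional_asymmetry.get(t.name, 0.0)
                    right = _positive_normal(
                        rng, b + da / 2.0 + d / 2.0, config.measurement_sd,
                        f"{sid}/{t.value} right")
                    left = _positive_normal(
                        rng, b - da / 2.0 - d / 2.0, config.measurement_sd,
                        f"{sid}/{t.value} left")
                    paired[t] = BilateralPair(right=right, left=left)
                    fa1_acc[(t.name, group.value)].append(abs(right - left))
                horizontal: dict[HorizontalTrait, float] = {}
                for t in HorizontalTrait:
                    b = s * config.trait_baseline[(t.name, sex.value)]
                    horizontal[t] = _positive_normal(
                        rng, b, config.measurement_sd, f"{sid}/{t.value}")
                records.append(SubjectRecord(sid, sex, group, paired, horizontal))
                counter += 1
    receipt = GeneratorReceipt(
        config_json=config.to_json(),
        seed=config.seed,
        realized_mean_fa1={k: float(np.mean(v)) for k, v in fa1_acc.items()},
    )
    return Cohort(records=records, provenance=f"synthetic seed={config.seed}"), receipt


def fixture_suite(outdir: str | Path, seed: int = 20220412) -> dict[str, Path]:
    """Write the named test cohorts and return their paths.

    * ``null`` — identical group distributions (type-I-error design);
    * ``study_like`` — the 30-subject reference design;
    * ``strong_ch`` — 100 subjects per group, for power/AUC checks;
    * ``degenerate`` — single-sex with missing cells, for error paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    for name, cfg in [
        ("null", null_config(seed)),
        ("study_like", default_config(seed)),
        ("strong_ch", strong_ch_config(seed)),
    ]:
        cohort, receipt = generate_cohort(cfg)
        path = outdir / f"{name}.csv"
        cohort_io.write_cohort(cohort, path)
        (outdir / f"{name}.receipt.json").write_text(receipt.to_json())
        out[name] = path

    degen_cfg = default_config(seed)
    degen_cfg.n_per_cell = 2
    cohort, _ = generate_cohort(degen_cfg)
    females = [r for r in cohort if r.sex is Sex.F]
    del females[0].paired[PairedTrait.SOF_MFO]
    degen = Cohort(records=females, provenance="degenerate fixture")
    path = outdir / "degenerate.csv"
    cohort_io.write_cohort(degen, path)
    out["degenerate"] = path
    return out
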