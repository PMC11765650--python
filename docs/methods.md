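# Methods

## Measurement model and data format

A cohort is a flat CSV with one row per subject: id, sex (F/M),
diagnostic group (CONTROL/HE/CH), right and left values of the three
paired vertical distances (SOF-IOF, IOF-MFO, SOF-MFO) and the three
horizontal distances (SOF-SOF, IOF-IOF, MFO-MFO).  All lengths are in
centimeters — the magnitudes involved (e.g. IOF-IOF ≈ 5.2) sit on the
cm scale — and must be strictly positive.  An empty cell marks a
missing trait; a paired trait with only one side present is demoted to
missing, because every asymmetry quantity needs both sides.  A subject
missing a paired trait is excluded from that trait's statistics and
from any composite containing it, but contributes everywhere else;
this deterministic rule is what makes reuse on incomplete data
well-defined.

## Asymmetry indices

FA1 = |R − L| and FA2 = |R − L| / ((R + L)/2).  FA2's denominator is
the subject's own bilateral mean, so it is invariant under a common
rescaling of both sides and bounded in [0, 2) — the property tests
quantify both.  The composites Total FA1/FA2 sum the per-trait index
over exactly the three paired vertical traits, the only bilateral
measurements in the design.  No decomposition into directional
asymmetry versus antisymmetry is attempted; the indices are used as
plain per-subject scores.

## Group comparisons

All inference is rank-based: the measured traits are small positive
distances with skewed asymmetry indices, so no normality is assumed.

* Mann–Whitney U (sexes): exact enumeration when both groups have
  n ≤ 8 and the pooled sample is tie-free; otherwise the normal
  approximation with midrank tie correction and continuity correction
  (the regime any 15-vs-15 comparison with ties lands in).  A pooled
  constant sample yields p = 1 by convention.
* Kruskal–Wallis (three diagnostic groups): midranks with tie
  correction, χ² reference with df = k − 1 = 2.  All-identical data
  give H = 0, p = 1 — a defined degenerate case, not an error.
* Post-hoc pairs: Dwass–Steel–Critchlow–Fligner by default — each
  pair re-ranked in isolation, its Mann–Whitney statistic referred to
  the studentized-range distribution with k = 3 groups — matching the
  behavior of common menu-driven statistics software.  Dunn's z-tests
  on the joint ranking with Holm adjustment are available via
  `posthoc="dunn"`.  No package in the installed stack provides DSCF,
  so it is implemented here directly and exercised by property tests
  (identical groups → p = 1; a far-shifted group owns the two smallest
  pairwise p's).

No multiplicity correction is applied across the 15 report variables;
the report marks p ≤ 0.05 (inclusive at the boundary) and leaves
family-wise control to the reader.  Reproducing any particular
published table's p-values is out of reach without the underlying raw
measurements; the suite verifies the *procedure* on synthetic data
with known structure instead.

## Screening analysis

CH is the positive class; everything else (controls and HE pooled) is
negative, giving the 10/20 split at the reference cohort size.  The
classification rule is score ≥ cutpoint → positive, because elevated
FA indicates CH.  Design choices:

* AUC by pair counting (ties ½).  The test suite proves equality with
  the trapezoidal area under the empirical step curve to 1e-12 and
  cross-checks against an independent library implementation.
* Candidate cutpoints are the observed score values.  Midpoints
  between adjacent values reach identical confusion matrices, so the
  attainable Youden maximum is the same either way (oracle-tested);
  observed values keep reported cutpoints interpretable as actual
  subject scores.
* Youden ties break toward higher sensitivity, then lower cutpoint:
  in an initial screen, missing a CH case costs more than a false
  referral.
* PPV/NPV are reported as NaN when no subject is predicted
  positive/negative rather than silently 0 or 1.
* The report covers 8 predictors — FA1 and FA2 of each paired trait
  plus both composites.  Total FA1 goes beyond the customary
  seven-predictor layout and is flagged only by its position at the
  end of the table.

No smoothed ROC, no cross-validation (evaluation is in-sample by
design), no AUC confidence intervals.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis
assumes, not imaging physics.  Per subject: a size factor
s ~ N(1, cv) (default cv = 0.05) scales all nine sex-specific
baselines; each paired trait draws a signed asymmetry deviate
d ~ N(0, fa_scale(trait, group)) split evenly across sides
(R = b + d/2, L = b − d/2), optionally plus a constant directional
offset (default 0: pure fluctuating asymmetry); each side and each
horizontal trait adds independent measurement noise N(0, 0.03 cm).
Non-positive draws are rejected and redrawn.  With noise off, FA1 is
exactly half-normal with scale fa_scale, giving the closed-form mean
fa_scale·√(2/π) used for calibration tests.

Defaults are the reference study design: 5 subjects per group × sex
cell (30 total, 10 per group, sexes 1:1); per-sex baselines set to
published per-sex right-side means (e.g. female SOF-MFO 10.5927 cm,
male SOF-IOF 4.7300 cm); control asymmetry scales 0.17 / 0.50 /
0.63 cm for SOF-IOF / IOF-MFO / SOF-MFO, chosen so the implied mean
FA1 matches typical observed per-trait values (≈ 0.14 / 0.40 /
0.50 cm); CH scale 5× control on every paired trait; HE equal to
control except SOF-MFO at 2× — the pattern of a CH group with
markedly elevated asymmetry and an HE group that differs from
controls on SOF-MFO only.  The 5× ratio is a modeling default, chosen
so the Total FA2 composite attains AUC > 0.9 against controls at
realistic noise; it is a config knob, not a constant.  Sex offsets
apply to baselines only, never to asymmetry scales, so FA indices are
sex-neutral by construction.

Each subject draws from a stream seeded by (root seed, subject
counter), so cohorts are byte-reproducible and insensitive to
generation order.  The high-power design (`strong_ch_config`) uses 50
subjects per cell → 100 per group.

What the generator does *not* emulate: heavy-tailed or skewed
measurement error, correlated asymmetry across traits beyond the
shared size factor, antisymmetry, observer effects, or any 3-D
geometry.  Passing tests on synthetic cohorts therefore demonstrate
that the pipeline recovers known structure under its own model
assumptions, not that real CBCT data satisfy those assumptions.

A side effect of the deterministic 5F/5M-per-group layout is worth
knowing: variables whose distribution depends on sex are *stratified*
across groups, which makes rank tests on them mildly conservative,
while rows of the group report are mutually dependent through the
shared size factor — a single null cohort can occasionally show
several correlated false-positive rows at once.  Null-calibration
checks therefore assert rates over many replicates, not counts in one
cohort.

## Problem sizes and runtimes

The test suite and acceptance script scale their simulations as: 100
replicate cohorts of 200 subjects for the composite-AUC check, 1,000
replicate 30-subject cohorts for type-I calibration, 200 random small
instances for ROC oracle equivalence, and n = 1,200 for the
half-normal calibration (3-SE tolerance).  The whole suite runs in
well under a minute on one core.

## Known limitations

* Cutpoint selection is in-sample; reported sensitivities are
  optimistic for prospective use.
* PPV/NPV inherit the synthetic prevalence (1/3 CH) and do not
  transfer to populations with different prevalence.
* The DSCF implementation assumes the asymptotic studentized-range
  reference; very small groups (n < 5) push it outside its comfort
  zone, where the Dunn option with Holm correction is preferable.
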