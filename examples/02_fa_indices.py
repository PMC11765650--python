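"""Compute FA1/FA2 asymmetry indices for a handmade subject.

FA1 = |R - L| keeps the trait's units (cm); FA2 = |R - L| / ((R+L)/2)
is dimensionless and comparable across traits of different size, which
is what makes the Total FA2 sum a meaningful composite.
"""

from forasym import (
    BilateralPair,
    Group,
    PairedTrait,
    Sex,
    SubjectRecord,
    compute_fa_set,
)

subject = SubjectRecord(
    subject_id="S01", sex=Sex.F, group=Group.CH,
    paired={
        PairedTrait.SOF_IOF: BilateralPair(right=4.72, left=4.67),
        PairedTrait.IOF_MFO: BilateralPair(right=6.22, left=6.52),
        PairedTrait.SOF_MFO: BilateralPair(right=10.57, left=10.83),
    },
)

fa = compute_fa_set(subject)
print(f"{'trait':<10}{'FA1 (cm)':>10}{'FA2':>10}")
for trait in fa.traits_used:
    print(f"{trait.value:<10}{fa.fa1[trait]:>10.3f}{fa.fa2[trait]:>10.4f}")
print(f"{'Total':<10}{fa.total_fa1:>10.3f}{fa.total_fa2:>10.4f}")
print("\nTotal FA2 is the composite screening predictor: higher values"
      "\nmean more relative left-right imbalance across all three traits.")
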