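import pytest

from forasym import (
    BilateralPair,
    Cohort,
    Group,
    HorizontalTrait,
    PairedTrait,
    Sex,
    SubjectRecord,
    cohort_fa_table,
    default_config,
    generate_cohort,
)


def make_record(sid="S01", sex=Sex.F, group=Group.CONTROL,
                pairs=((4.72, 4.67), (6.22, 6.52), (10.57, 10.83)),
                horizontal=(5.22, 5.20, 4.76)):
    """Handmade subject with explicit measurement values (cm)."""
    paired = {t: BilateralPair(*p) for t, p in zip(PairedTrait, pairs)}
    horiz = {t: v for t, v in zip(HorizontalTrait, horizontal)}
    return SubjectRecord(sid, sex, group, paired, horiz)


@pytest.fixture
def small_cohort():
    return Cohort(records=[
        make_record("S01", Sex.F, Group.CH),
        make_record("S02", Sex.M, Group.CONTROL, pairs=((5.0, 5.0), (6.0, 4.0), (8.0, 8.0))),
        make_record("S03", Sex.F, Group.HE, pairs=((4.5, 4.6), (6.1, 6.0), (10.2, 10.4))),
    ])


@pytest.fixture(scope="session")
def study_like_cohort():
    """30 subjects, 10 per group, sex-balanced, seeded."""
    cohort, _ = generate_cohort(default_config(seed=20220412))
    return cohort


@pytest.fixture(scope="session")
def study_like_fa(study_like_cohort):
    return cohort_fa_table(study_like_cohort)
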