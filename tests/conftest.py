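import datetime as dt

import pytest

from reaim.model import (
    CohortDataset,
    EligibilityModel,
    MeasurementSet,
    ParticipantRecord,
    SiteRecord,
    Timepoint,
)

COLLECTION = dt.date(2008, 1, 15)


def make_participant(pid="P1", site="S1", sex="female", age=45.0,
                     days_before=400, w0=220.0, w1=None, w2=None,
                     done1=False, done2=False, height=64.0):
    ms = {Timepoint.BASELINE: MeasurementSet(weight_lb=w0, height_in=height)}
    if w1 is not None:
        ms[Timepoint.END_PHASE1] = MeasurementSet(weight_lb=w1)
    if w2 is not None:
        ms[Timepoint.END_PHASE2] = MeasurementSet(weight_lb=w2)
    return ParticipantRecord(
        participant_id=pid, site_id=site, sex=sex, age_years=age,
        enrollment_date=COLLECTION - dt.timedelta(days=days_before),
        measurements=ms, completed_phase1=done1, completed_phase2=done2,
    )


def make_site(sid="S1", site_type="fitness_center", days_before=800,
              n_components=14, still_accepting=True):
    comps = tuple([True] * n_components + [False] * (14 - n_components))
    return SiteRecord(
        site_id=sid, site_type=site_type,
        approval_date=COLLECTION - dt.timedelta(days=days_before),
        components_implemented=comps, still_accepting=still_accepting,
    )


@pytest.fixture
def eligibility():
    return EligibilityModel(
        n_adult_members=60041, p_obese=0.31, p_overweight=0.36,
        p_comorbid_overweight=0.66, eligible_sex_split=0.541,
        eligible_age_distribution=(0.10, 0.17, 0.19, 0.20, 0.16, 0.18))


@pytest.fixture
def tiny_cohort(eligibility):
    participants = [
        make_participant("P1", sex="female", w1=205.0, done1=True),
        make_participant("P2", sex="male", w0=270.0, w1=250.0, w2=245.0,
                         done1=True, done2=True),
        make_participant("P3", sex="female", days_before=30),
    ]
    sites = [make_site("S1")]
    return CohortDataset(
        participants=participants, sites=sites,
        data_collection_date=COLLECTION, eligibility=eligibility,
        n_potential_sites=352,
    )


@pytest.fixture(scope="session")
def big_default_cohort():
    """One large calibrated cohort shared by convergence-style tests."""
    from reaim.simulate import default_paper_config, generate_cohort

    return generate_cohort(default_paper_config(seed=20080115,
                                                n_participants=20000))
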