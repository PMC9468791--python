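import datetime as dt

import pytest

from bleeddiary.diary_core import (
    AgeGroup,
    BleedRecord,
    Cohort,
    Diary,
    MedicationRecord,
    Participant,
    Regimen,
    StudyPhase,
)

START = dt.date(2020, 1, 1)


def day(d: int, hour: int = 0, minute: int = 0) -> dt.datetime:
    return dt.datetime.combine(START, dt.time(hour, minute)) + dt.timedelta(days=d)


def make_participant(
    pid="p1",
    cohort=Cohort.A,
    regimen=Regimen.EPISODIC,
    study_phase=StudyPhase.NIS,
    efficacy_days=366,
    prior_iti=None,
) -> Participant:
    cohort = Cohort(cohort)
    return Participant(
        participant_id=pid,
        cohort=cohort,
        age_group=AgeGroup.PEDIATRIC if cohort is Cohort.B else AgeGroup.ADULT_ADOLESCENT,
        inhibitor_status=cohort in (Cohort.A, Cohort.B),
        regimen=regimen,
        study_phase=study_phase,
        efficacy_start=START,
        efficacy_end=START + dt.timedelta(days=efficacy_days),
        prior_iti=prior_iti,
    )


def bleed(pid="p1", onset=0, location="knee", cause="spontaneous",
          symptoms=(), joint_flag=None) -> BleedRecord:
    onset_ts = day(onset) if isinstance(onset, int) else onset
    return BleedRecord(
        participant_id=pid,
        onset=onset_ts,
        location=location,
        cause=cause,
        symptoms=frozenset(symptoms),
        reported_joint_location=(
            location in {"knee", "elbow", "ankle", "wrist", "fingers_thumb",
                         "shoulder", "hip", "toes"}
            if joint_flag is None else joint_flag
        ),
    )


def dose(pid="p1", time=0, purpose="treat_bleed", agent="bypassing_agent",
         amount=50.0) -> MedicationRecord:
    time_ts = day(time) if isinstance(time, int) else time
    return MedicationRecord(
        participant_id=pid, time=time_ts, agent=agent, dose=amount,
        dose_unit="IU/kg", purpose=purpose,
    )


def make_diary(bleeds=(), medications=(), participants=None) -> Diary:
    if participants is None:
        pids = {b.participant_id for b in bleeds} | {m.participant_id for m in medications}
        participants = [make_participant(pid) for pid in sorted(pids or {"p1"})]
    return Diary(participants=list(participants), bleeds=list(bleeds),
                 medications=list(medications))


@pytest.fixture
def single_participant_diary():
    return make_diary(bleeds=[bleed(onset=5)], medications=[dose(time=9)])
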