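"""Domain types, vocabularies, and readers/writers for bleed/medication diaries.

The data model mirrors a Bleed and Medication Questionnaire (BMQ)-style diary:
participants report perceived bleeds and coagulation-factor / emicizumab doses
*independently* of each other, which is what makes untreated bleeds observable
at all.  Three record types are carried:

* :class:`Participant` — roster entry with cohort, regimen, inhibitor status and
  the efficacy (follow-up) period whose day count is the ABR denominator.
* :class:`BleedRecord` — one perceived bleed (onset, location, cause, symptoms).
* :class:`MedicationRecord` — one dose (time, agent, dose, participant-stated
  purpose).

Cohorts carry different location vocabularies: adults/adolescents with FVIII
inhibitors (cohort A) could record soft-tissue, bruise/hematoma and
miscellaneous bleeds, whereas the pediatric inhibitor cohort (B) and the
non-inhibitor cohort (C) used a single "other" category.  The vocabulary is
enforced per cohort and a coarse normalization (joint / muscle / other_nonjoint)
is provided for cross-cohort summaries.

Timestamps are ISO-8601 with day resolution as the floor; finer-than-day times
are honored when present and preserved losslessly on round trip.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Cohort",
    "AgeGroup",
    "Regimen",
    "StudyPhase",
    "Cause",
    "Agent",
    "Purpose",
    "Symptom",
    "JOINT_SITES",
    "location_vocabulary",
    "coarse_location",
    "Participant",
    "BleedRecord",
    "MedicationRecord",
    "Diary",
    "DiaryValidationError",
    "parse_timestamp",
    "format_timestamp",
    "is_day_resolution",
    "within_window",
    "read_diary",
    "write_diary",
    "read_diary_json",
    "write_diary_json",
]


class Cohort(str, enum.Enum):
    A = "A"  # adults/adolescents with FVIII inhibitors
    B = "B"  # children (<12 y) with FVIII inhibitors
    C = "C"  # adults/adolescents without FVIII inhibitors


class AgeGroup(str, enum.Enum):
    ADULT_ADOLESCENT = "adult_adolescent"
    PEDIATRIC = "pediatric"


class Regimen(str, enum.Enum):
    EPISODIC = "episodic"
    PROPHYLACTIC = "prophylactic"


class StudyPhase(str, enum.Enum):
    NIS = "NIS"
    HAVEN = "HAVEN"


class Cause(str, enum.Enum):
    SPONTANEOUS = "spontaneous"
    TRAUMATIC = "traumatic"
    SURGERY_PROCEDURE = "surgery_procedure"


class Agent(str, enum.Enum):
    FVIII = "FVIII"
    BYPASSING_AGENT = "bypassing_agent"
    EMICIZUMAB = "emicizumab"


class Purpose(str, enum.Enum):
    TREAT_BLEED = "treat_bleed"
    PROPHYLAXIS = "prophylaxis"
    PROCEDURE = "procedure"
    OTHER = "other"


class Symptom(str, enum.Enum):
    AURA = "aura"
    PAIN = "pain"
    SWELLING = "swelling"
    REDUCED_MOTION = "reduced_motion"
    WARMTH = "warmth"


#: Anatomic sites counted as joints (knee/elbow/ankle printed individually in
#: summaries; the rest are pooled as "other joint").
JOINT_SITES = frozenset(
    {"knee", "elbow", "ankle", "wrist", "fingers_thumb", "shoulder", "hip", "toes"}
)

_SHARED_LOCATIONS = JOINT_SITES | {"muscle"}
_COHORT_EXTRAS: Mapping[Cohort, frozenset[str]] = {
    Cohort.A: frozenset({"soft_tissue", "bruise_hematoma", "miscellaneous"}),
    Cohort.B: frozenset({"other"}),
    Cohort.C: frozenset({"other"}),
}


def location_vocabulary(cohort: Cohort) -> frozenset[str]:
    """Allowed bleed locations for a cohort (joint sites + muscle + dialect extras)."""
    return _SHARED_LOCATIONS | _COHORT_EXTRAS[Cohort(cohort)]


def coarse_location(location: str) -> str:
    """Normalize a location token to the shared taxonomy joint/muscle/other_nonjoint."""
    if location in JOINT_SITES:
        return "joint"
    if location == "muscle":
        return "muscle"
    return "other_nonjoint"


# ---------------------------------------------------------------------------
# timestamps
# ---------------------------------------------------------------------------

def parse_timestamp(token: str) -> _dt.datetime:
    """Parse an ISO-8601 date or datetime; date-only tokens map to midnight."""
    try:
        return _dt.datetime.fromisoformat(str(token))
    except ValueError as exc:
        raise ValueError(f"unparseable ISO-8601 timestamp: {token!r}") from exc


def format_timestamp(ts: _dt.datetime) -> str:
    """Serialize a timestamp; midnight timestamps are written date-only."""
    if ts.time() == _dt.time(0, 0):
        return ts.date().isoformat()
    return ts.isoformat()


def is_day_resolution(ts: _dt.datetime) -> bool:
    return ts.time() == _dt.time(0, 0)


def within_window(reference: _dt.datetime, later: _dt.datetime, hours: float) -> bool:
    """True when ``later`` falls within ``hours`` after ``reference``.

    With day-resolution data (both stamps at midnight) the window is evaluated
    on calendar-day differences: 72 h means <= 3 days, 24 h means <= 1 day.
    Exact timedelta arithmetic is used as soon as either stamp carries a
    time of day.
    """
    if later < reference:
        return False
    if is_day_resolution(reference) and is_day_resolution(later):
        return (later.date() - reference.date()).days <= hours / 24.0
    return later - reference <= _dt.timedelta(hours=hours)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class Participant:
    participant_id: str
    cohort: Cohort
    age_group: AgeGroup
    inhibitor_status: bool
    regimen: Regimen
    study_phase: StudyPhase
    efficacy_start: _dt.date
    efficacy_end: _dt.date
    prior_iti: bool | None = None

    def __post_init__(self) -> None:
        self.cohort = Cohort(self.cohort)
        self.age_group = AgeGroup(self.age_group)
        self.regimen = Regimen(self.regimen)
        self.study_phase = StudyPhase(self.study_phase)
        if isinstance(self.efficacy_start, _dt.datetime):
            self.efficacy_start = self.efficacy_start.date()
        if isinstance(self.efficacy_end, _dt.datetime):
            self.efficacy_end = self.efficacy_end.date()
        if self.efficacy_start >= self.efficacy_end:
            raise ValueError(
                f"participant {self.participant_id}: efficacy_start must precede efficacy_end"
            )
        expected_age = AgeGroup.PEDIATRIC if self.cohort is Cohort.B else AgeGroup.ADULT_ADOLESCENT
        if self.age_group is not expected_age:
            raise ValueError(
                f"participant {self.participant_id}: cohort {self.cohort.value} implies "
                f"age_group {expected_age.value}"
            )
        expected_inh = self.cohort in (Cohort.A, Cohort.B)
        if self.inhibitor_status != expected_inh:
            raise ValueError(
                f"participant {self.participant_id}: cohort {self.cohort.value} implies "
                f"inhibitor_status {expected_inh}"
            )

    @property
    def efficacy_days(self) -> int:
        """Length of the half-open efficacy period [start, end) in days."""
        return (self.efficacy_end - self.efficacy_start).days

    def in_efficacy(self, ts: _dt.datetime) -> bool:
        return self.efficacy_start <= ts.date() < self.efficacy_end


@dataclass
class BleedRecord:
    participant_id: str
    onset: _dt.datetime
    location: str
    cause: Cause
    symptoms: frozenset[Symptom] = frozenset()
    reported_joint_location: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.onset, str):
            self.onset = parse_timestamp(self.onset)
        self.cause = Cause(self.cause)
        self.symptoms = frozenset(Symptom(s) for s in self.symptoms)

    def validate_location(self, cohort: Cohort) -> None:
        vocab = location_vocabulary(cohort)
        if self.location not in vocab:
            raise ValueError(
                f"location {self.location!r} is not in the cohort {Cohort(cohort).value} "
                f"vocabulary ({', '.join(sorted(vocab))})"
            )


@dataclass
class MedicationRecord:
    participant_id: str
    time: _dt.datetime
    agent: Agent
    dose: float
    dose_unit: str
    purpose: Purpose

    def __post_init__(self) -> None:
        if isinstance(self.time, str):
            self.time = parse_timestamp(self.time)
        self.agent = Agent(self.agent)
        self.purpose = Purpose(self.purpose)
        self.dose = float(self.dose)
        if self.dose < 0:
            raise ValueError(f"dose must be nonnegative, got {self.dose}")


class DiaryValidationError(ValueError):
    """Raised when diary inputs violate the schema; carries per-row diagnostics."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        super().__init__("\n".join(self.diagnostics))


@dataclass
class Diary:
    """A validated bundle of roster + bleed + medication records.

    Events outside their owner's efficacy period are retained but flagged; the
    ``*_in_efficacy`` accessors give the default analysis population.
    """

    participants: list[Participant]
    bleeds: list[BleedRecord] = field(default_factory=list)
    medications: list[MedicationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._roster = {p.participant_id: p for p in self.participants}
        if len(self._roster) != len(self.participants):
            raise DiaryValidationError(["duplicate participant_id in roster"])
        problems: list[str] = []
        for i, b in enumerate(self.bleeds):
            if b.participant_id not in self._roster:
                problems.append(f"bleed row {i}: unknown participant {b.participant_id!r}")
                continue
            try:
                b.validate_location(self._roster[b.participant_id].cohort)
            except ValueError as exc:
                problems.append(f"bleed row {i}: {exc}")
        for i, m in enumerate(self.medications):
            if m.participant_id not in self._roster:
                problems.append(f"medication row {i}: unknown participant {m.participant_id!r}")
        if problems:
            raise DiaryValidationError(problems)

    def participant(self, participant_id: str) -> Participant:
        return self._roster[participant_id]

    @property
    def roster(self) -> Mapping[str, Participant]:
        return dict(self._roster)

    def event_in_efficacy(self, record: BleedRecord | MedicationRecord) -> bool:
        owner = self._roster[record.participant_id]
        ts = record.onset if isinstance(record, BleedRecord) else record.time
        return owner.in_efficacy(ts)

    def bleeds_in_efficacy(self) -> list[BleedRecord]:
        return [b for b in self.bleeds if self.event_in_efficacy(b)]

    def medications_in_efficacy(self) -> list[MedicationRecord]:
        return [m for m in self.medications if self.event_in_efficacy(m)]

    def flagged_outside_efficacy(self) -> tuple[list[BleedRecord], list[MedicationRecord]]:
        return (
            [b for b in self.bleeds if not self.event_in_efficacy(b)],
            [m for m in self.medications if not self.event_in_efficacy(m)],
        )

    def without_participant(self, participant_id: str) -> "Diary":
        if participant_id not in self._roster:
            raise KeyError(f"unknown participant {participant_id!r}")
        return Diary(
            participants=[p for p in self.participants if p.participant_id != participant_id],
            bleeds=[b for b in self.bleeds if b.participant_id != participant_id],
            medications=[m for m in self.medications if m.participant_id != participant_id],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diary):
            return NotImplemented
        return (
            self.participants == other.participants
            and self.bleeds == other.bleeds
            and self.medications == other.medications
        )


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

ROSTER_COLUMNS = [
    "participant_id", "cohort", "age_group", "inhibitor_status", "regimen",
    "study_phase", "efficacy_start", "efficacy_end", "prior_iti",
]
BLEED_COLUMNS = [
    "participant_id", "onset", "location", "cause", "symptoms", "reported_joint_location",
]
MEDICATION_COLUMNS = [
    "participant_id", "time", "agent", "dose", "dose_unit", "purpose",
]

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(token: str, *, allow_empty: bool = False) -> bool | None:
    token = str(token).strip().lower()
    if token == "" and allow_empty:
        return None
    if token not in _BOOL_TOKENS:
        raise ValueError(f"expected boolean token, got {token!r}")
    return _BOOL_TOKENS[token]


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"missing diary file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DiaryValidationError(
            [f"{path}: missing column(s) {', '.join(missing)}"]
        )
    return df


def read_diary(bleeds_path, medications_path, roster_path) -> Diary:
    """Load and validate a diary from three CSV files.

    Every malformed row produces a located diagnostic; all diagnostics are
    collected and raised together as :class:`DiaryValidationError` (no silent
    drops).  Events outside the efficacy period are retained and flagged.
    """
    roster_df = _read_table(Path(roster_path), ROSTER_COLUMNS)
    bleeds_df = _read_table(Path(bleeds_path), BLEED_COLUMNS)
    meds_df = _read_table(Path(medications_path), MEDICATION_COLUMNS)

    problems: list[str] = []
    participants: list[Participant] = []
    for i, row in roster_df.iterrows():
        try:
            participants.append(
                Participant(
                    participant_id=row["participant_id"],
                    cohort=row["cohort"],
                    age_group=row["age_group"],
                    inhibitor_status=_parse_bool(row["inhibitor_status"]),
                    regimen=row["regimen"],
                    study_phase=row["study_phase"],
                    efficacy_start=_dt.date.fromisoformat(row["efficacy_start"]),
                    efficacy_end=_dt.date.fromisoformat(row["efficacy_end"]),
                    prior_iti=_parse_bool(row["prior_iti"], allow_empty=True),
                )
            )
        except ValueError as exc:
            problems.append(f"{roster_path} row {i}: {exc}")

    bleeds: list[BleedRecord] = []
    for i, row in bleeds_df.iterrows():
        try:
            symptoms = [s for s in str(row["symptoms"]).split(";") if s.strip()]
            bleeds.append(
                BleedRecord(
                    participant_id=row["participant_id"],
                    onset=parse_timestamp(row["onset"]),
                    location=row["location"],
                    cause=row["cause"],
                    symptoms=frozenset(symptoms),
                    reported_joint_location=_parse_bool(row["reported_joint_location"]),
                )
            )
        except ValueError as exc:
            problems.append(f"{bleeds_path} row {i}: {exc}")

    medications: list[MedicationRecord] = []
    for i, row in meds_df.iterrows():
        try:
            medications.append(
                MedicationRecord(
                    participant_id=row["participant_id"],
                    time=parse_timestamp(row["time"]),
                    agent=row["agent"],
                    dose=row["dose"],
                    dose_unit=row["dose_unit"],
                    purpose=row["purpose"],
                )
            )
        except ValueError as exc:
            problems.append(f"{medications_path} row {i}: {exc}")

    if problems:
        raise DiaryValidationError(problems)
    try:
        return Diary(participants=participants, bleeds=bleeds, medications=medications)
    except DiaryValidationError:
        raise


def write_diary(diary: Diary, bleeds_path, medications_path, roster_path) -> None:
    """Write a diary to three CSVs; ``read_diary`` of the output round-trips."""
    roster_rows = []
    for p in diary.participants:
        roster_rows.append(
            {
                "participant_id": p.participant_id,
                "cohort": p.cohort.value,
                "age_group": p.age_group.value,
                "inhibitor_status": str(p.inhibitor_status).lower(),
                "regimen": p.regimen.value,
                "study_phase": p.study_phase.value,
                "efficacy_start": p.efficacy_start.isoformat(),
                "efficacy_end": p.efficacy_end.isoformat(),
                "prior_iti": "" if p.prior_iti is None else str(p.prior_iti).lower(),
            }
        )
    bleed_rows = []
    for b in diary.bleeds:
        bleed_rows.append(
            {
                "participant_id": b.participant_id,
                "onset": format_timestamp(b.onset),
                "location": b.location,
                "cause": b.cause.value,
                "symptoms": ";".join(sorted(s.value for s in b.symptoms)),
                "reported_joint_location": str(b.reported_joint_location).lower(),
            }
        )
    med_rows = []
    for m in diary.medications:
        med_rows.append(
            {
                "participant_id": m.participant_id,
                "time": format_timestamp(m.time),
                "agent": m.agent.value,
                "dose": repr(m.dose),
                "dose_unit": m.dose_unit,
                "purpose": m.purpose.value,
            }
        )
    pd.DataFrame(roster_rows, columns=ROSTER_COLUMNS).to_csv(roster_path, index=False)
    pd.DataFrame(bleed_rows, columns=BLEED_COLUMNS).to_csv(bleeds_path, index=False)
    pd.DataFrame(med_rows, columns=MEDICATION_COLUMNS).to_csv(medications_path, index=False)


def write_diary_json(diary: Diary, path) -> None:
    """Lossless typed JSON mirror of the three-table diary."""
    payload = {
        "participants": [
            {
                **{k: (v.value if isinstance(v, enum.Enum) else v)
                   for k, v in dataclasses.asdict(p).items()
                   if k not in ("efficacy_start", "efficacy_end")},
                "efficacy_start": p.efficacy_start.isoformat(),
                "efficacy_end": p.efficacy_end.isoformat(),
            }
            for p in diary.participants
        ],
        "bleeds": [
            {
                "participant_id": b.participant_id,
                "onset": b.onset.isoformat(),
                "location": b.location,
                "cause": b.cause.value,
                "symptoms": sorted(s.value for s in b.symptoms),
                "reported_joint_location": b.reported_joint_location,
            }
            for b in diary.bleeds
        ],
        "medications": [
            {
                "participant_id": m.participant_id,
                "time": m.time.isoformat(),
                "agent": m.agent.value,
                "dose": m.dose,
                "dose_unit": m.dose_unit,
                "purpose": m.purpose.value,
            }
            for m in diary.medications
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_diary_json(path) -> Diary:
    payload = json.loads(Path(path).read_text())
    participants = [
        Participant(
            participant_id=p["participant_id"],
            cohort=p["cohort"],
            age_group=p["age_group"],
            inhibitor_status=p["inhibitor_status"],
            regimen=p["regimen"],
            study_phase=p["study_phase"],
            efficacy_start=_dt.date.fromisoformat(p["efficacy_start"]),
            efficacy_end=_dt.date.fromisoformat(p["efficacy_end"]),
            prior_iti=p.get("prior_iti"),
        )
        for p in payload["participants"]
    ]
    bleeds = [
        BleedRecord(
            participant_id=b["participant_id"],
            onset=parse_timestamp(b["onset"]),
            location=b["location"],
            cause=b["cause"],
            symptoms=frozenset(b["symptoms"]),
            reported_joint_location=b["reported_joint_location"],
        )
        for b in payload["bleeds"]
    ]
    medications = [
        MedicationRecord(
            participant_id=m["participant_id"],
            time=parse_timestamp(m["time"]),
            agent=m["agent"],
            dose=m["dose"],
            dose_unit=m["dose_unit"],
            purpose=m["purpose"],
        )
        for m in payload["medications"]
    ]
    return Diary(participants=participants, bleeds=bleeds, medications=medications)
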