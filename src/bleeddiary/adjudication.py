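"""Bleed–treatment linkage and bleed classification.

Implements the adjudication conventions used when analysing self-reported
hemophilia diaries in which bleeds and doses are recorded independently:

* A bleed and the first treat-purpose dose thereafter are linked — one
  treatment belongs to one bleed only — irrespective of the gap between bleed
  and treatment.  Exception: when multiple bleeds occur on the same calendar
  day, the subsequent treatment applies to each of them.
* A bleed at a different location is always a separate bleed, regardless of
  time from the last treatment; linkage itself never merges bleeds.
* The ISTH SSC "72-hour rule" (a second bleed of the same type and anatomic
  location within 72 h after stopping treatment for the first counts as the
  same bleed) is available but OFF by default: with untreated bleeds in scope
  the rule would have to run relative to the previous bleed rather than the
  previous treatment, so the headline analysis counts every bleed
  individually.  Both reference conventions are implemented.
* Joint-bleed status is cohort-specific: cohort A requires an aura plus
  another joint symptom, cohort C a joint symptom with no aura requirement,
  and cohort B goes by the reported joint location (children are not expected
  to identify symptoms).
* Untreated bleeds followed within 24 h by a dose recorded as prophylaxis are
  flagged (a possible "schedule-shift" treatment response).

Only doses whose participant-stated purpose is ``treat_bleed`` participate in
linkage; prophylaxis doses never convert a bleed to treated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .diary_core import (
    BleedRecord,
    Cause,
    Cohort,
    Diary,
    JOINT_SITES,
    MedicationRecord,
    Purpose,
    Symptom,
    within_window,
)

__all__ = [
    "CollapseReference",
    "AdjudicationConfig",
    "AdjudicatedBleed",
    "AdjudicationResult",
    "Counts",
    "link_treatments",
    "classify_treated_untreated",
    "collapse_72h",
    "classify_joint",
    "flag_prophylaxis_followup",
    "adjudicate",
]


class CollapseReference(str, enum.Enum):
    #: window measured from the previous bleed's treatment time (ISTH reading)
    AFTER_TREATMENT_STOP = "after_treatment_stop"
    #: window measured from the previous bleed's onset (untreated chains)
    AFTER_PREVIOUS_BLEED = "after_previous_bleed"


@dataclass
class AdjudicationConfig:
    apply_72h_rule: bool = False
    collapse_reference: CollapseReference = CollapseReference.AFTER_TREATMENT_STOP
    same_type_required: bool = True
    prophylaxis_window_hours: float = 24.0
    collapse_window_hours: float = 72.0
    include_surgery_bleeds: bool = True

    def __post_init__(self) -> None:
        self.collapse_reference = CollapseReference(self.collapse_reference)
        if self.prophylaxis_window_hours <= 0 or self.collapse_window_hours <= 0:
            raise ValueError("window lengths must be positive")


@dataclass
class AdjudicatedBleed:
    bleed: BleedRecord
    treated: bool
    linked_medication: MedicationRecord | None
    joint_bleed: bool = False
    collapse_group_id: int = -1
    prophylaxis_followup_within_24h: bool = False

    def __post_init__(self) -> None:
        if self.treated != (self.linked_medication is not None):
            raise ValueError("treated flag must mirror presence of a linked medication")
        if self.linked_medication is not None:
            if self.linked_medication.purpose is not Purpose.TREAT_BLEED:
                raise ValueError("linked medication must have purpose=treat_bleed")


@dataclass
class AdjudicationResult:
    bleeds: list[AdjudicatedBleed]
    orphan_medications: list[MedicationRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.bleeds)

    def __len__(self) -> int:
        return len(self.bleeds)


@dataclass(frozen=True)
class Counts:
    treated: int
    untreated: int

    @property
    def all(self) -> int:
        return self.treated + self.untreated


def _dose_eligible(bleed: BleedRecord, med: MedicationRecord) -> bool:
    # "thereafter" at day resolution: a dose on the bleed's calendar day counts
    # even if its (unreported) clock time was earlier
    return med.time >= bleed.onset or med.time.date() == bleed.onset.date()


def link_treatments(diary: Diary, config: AdjudicationConfig | None = None) -> AdjudicationResult:
    """Greedy chronological bleed→treatment linkage per participant.

    Scanning a participant's bleeds in onset order, each bleed links to the
    earliest treat-purpose dose at or after its onset that is either unconsumed
    or consumed only by bleeds sharing this bleed's calendar day (the same-day
    exception).  Bleeds with no such dose are untreated.  Treat-purpose doses
    never linked to any bleed are returned as ``orphan_medications``.
    """
    config = config or AdjudicationConfig()
    out: list[AdjudicatedBleed] = []
    orphans: list[MedicationRecord] = []

    by_participant: dict[str, list[BleedRecord]] = {}
    for b in diary.bleeds_in_efficacy():
        if not config.include_surgery_bleeds and b.cause is Cause.SURGERY_PROCEDURE:
            continue
        by_participant.setdefault(b.participant_id, []).append(b)

    meds_by_participant: dict[str, list[MedicationRecord]] = {}
    for m in diary.medications_in_efficacy():
        if m.purpose is Purpose.TREAT_BLEED:
            meds_by_participant.setdefault(m.participant_id, []).append(m)

    for pid in sorted(set(by_participant) | set(meds_by_participant)):
        bleeds = sorted(
            by_participant.get(pid, []), key=lambda b: (b.onset, b.location)
        )
        meds = sorted(meds_by_participant.get(pid, []), key=lambda m: m.time)
        # consumed_by[j] = calendar days of the bleeds linked to dose j
        consumed_by: list[set] = [set() for _ in meds]
        for b in bleeds:
            linked = None
            for j, m in enumerate(meds):
                if not _dose_eligible(b, m):
                    continue
                if not consumed_by[j] or consumed_by[j] == {b.onset.date()}:
                    linked = m
                    consumed_by[j].add(b.onset.date())
                    break
            out.append(
                AdjudicatedBleed(
                    bleed=b,
                    treated=linked is not None,
                    linked_medication=linked,
                )
            )
        orphans.extend(m for j, m in enumerate(meds) if not consumed_by[j])

    return AdjudicationResult(bleeds=out, orphan_medications=orphans)


def classify_treated_untreated(adjudicated: Iterable[AdjudicatedBleed]) -> Counts:
    """Partition into treated / untreated; ``all`` is their sum by construction."""
    treated = untreated = 0
    for ab in adjudicated:
        if ab.treated:
            treated += 1
        else:
            untreated += 1
    return Counts(treated=treated, untreated=untreated)


def collapse_72h(
    adjudicated: Sequence[AdjudicatedBleed], config: AdjudicationConfig | None = None
) -> list[AdjudicatedBleed]:
    """Assign collapse group ids under the (optional) 72-hour rule.

    With the rule off every bleed gets a unique group id, i.e. each bleed is
    counted individually.  With the rule on, bleeds of the same participant,
    cause category (when ``same_type_required``) and anatomic location merge
    transitively into the previous group member when the later onset falls
    within the collapse window after the reference point: the previous member's
    linked treatment time (``after_treatment_stop``; its onset when untreated)
    or the previous member's onset (``after_previous_bleed``).
    """
    config = config or AdjudicationConfig()
    adjudicated = list(adjudicated)
    if not config.apply_72h_rule:
        return [replace(ab, collapse_group_id=i) for i, ab in enumerate(adjudicated)]

    order = sorted(
        range(len(adjudicated)),
        key=lambda i: (
            adjudicated[i].bleed.participant_id,
            adjudicated[i].bleed.onset,
            adjudicated[i].bleed.location,
        ),
    )
    group_of = [-1] * len(adjudicated)
    next_group = 0
    # open chain state per (participant, type-key, location): (group, reference time)
    chains: dict[tuple, tuple[int, object]] = {}
    for i in order:
        ab = adjudicated[i]
        b = ab.bleed
        type_key = b.cause if config.same_type_required else None
        key = (b.participant_id, type_key, b.location)
        if key in chains:
            group, ref = chains[key]
            if within_window(ref, b.onset, config.collapse_window_hours):
                group_of[i] = group
                chains[key] = (group, _reference_time(ab, config))
                continue
        group_of[i] = next_group
        chains[key] = (next_group, _reference_time(ab, config))
        next_group += 1
    return [replace(ab, collapse_group_id=g) for ab, g in zip(adjudicated, group_of)]


def _reference_time(ab: AdjudicatedBleed, config: AdjudicationConfig):
    if config.collapse_reference is CollapseReference.AFTER_TREATMENT_STOP and ab.treated:
        return ab.linked_medication.time
    return ab.bleed.onset


_JOINT_SYMPTOMS = frozenset(
    {Symptom.PAIN, Symptom.SWELLING, Symptom.REDUCED_MOTION, Symptom.WARMTH}
)


def classify_joint(bleed: BleedRecord, cohort: Cohort) -> bool:
    """Cohort-specific joint-bleed definition."""
    cohort = Cohort(cohort)
    at_joint = bleed.location in JOINT_SITES
    if cohort is Cohort.A:
        return (
            at_joint
            and Symptom.AURA in bleed.symptoms
            and bool(bleed.symptoms & _JOINT_SYMPTOMS)
        )
    if cohort is Cohort.C:
        return at_joint and bool(bleed.symptoms & _JOINT_SYMPTOMS)
    # cohort B: by reported location only
    return bleed.reported_joint_location or at_joint


def flag_prophylaxis_followup(
    adjudicated: Sequence[AdjudicatedBleed],
    medications: Iterable[MedicationRecord],
    config: AdjudicationConfig | None = None,
) -> list[AdjudicatedBleed]:
    """Flag untreated bleeds followed within the window by a prophylaxis dose.

    Treated bleeds are never flagged.  At day resolution "within 24 h" means
    the dose date is the bleed date or the next day.
    """
    config = config or AdjudicationConfig()
    prophy: dict[str, list[MedicationRecord]] = {}
    for m in medications:
        if m.purpose is Purpose.PROPHYLAXIS:
            prophy.setdefault(m.participant_id, []).append(m)
    out = []
    for ab in adjudicated:
        flagged = False
        if not ab.treated:
            flagged = any(
                within_window(ab.bleed.onset, m.time, config.prophylaxis_window_hours)
                for m in prophy.get(ab.bleed.participant_id, [])
            )
        out.append(replace(ab, prophylaxis_followup_within_24h=flagged))
    return out


def adjudicate(diary: Diary, config: AdjudicationConfig | None = None) -> AdjudicationResult:
    """Full adjudication: linkage, joint classification, collapse ids, 24-h flags."""
    config = config or AdjudicationConfig()
    result = link_treatments(diary, config)
    bleeds = [
        replace(ab, joint_bleed=classify_joint(ab.bleed, diary.participant(ab.bleed.participant_id).cohort))
        for ab in result.bleeds
    ]
    bleeds = collapse_72h(bleeds, config)
    bleeds = flag_prophylaxis_followup(bleeds, diary.medications_in_efficacy(), config)
    return AdjudicationResult(bleeds=bleeds, orphan_medications=result.orphan_medications)
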