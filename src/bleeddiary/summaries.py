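"""Descriptive result tables over adjudicated diaries.

Every function returns a tidy :class:`pandas.DataFrame` with numerator ``n``,
denominator ``N``, the raw fraction, and ``pct`` — the percentage rounded to
one decimal with half-up rounding (matching how clinical tables are printed).
Empty strata report an undefined (NaN) percentage, never 0.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adjudication import (
    AdjudicatedBleed,
    AdjudicationConfig,
    adjudicate,
)
from .diary_core import Cause, Cohort, Diary, JOINT_SITES, Regimen

__all__ = [
    "round_half_up",
    "proportion_untreated",
    "reporter_percentages",
    "location_table",
    "cause_table",
    "prophylaxis_follow_summary",
    "build_all_tables",
    "sensitivity_exclude",
]

#: joint sites printed individually; the rest pool into the other-joint sub-row
_NAMED_JOINTS = ("knee", "elbow", "ankle")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as clinical tables print."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: int, den: int) -> float:
    if den == 0:
        return float("nan")
    return round_half_up(100.0 * n / den)


def _frac(n: int, den: int) -> float:
    return float("nan") if den == 0 else n / den


def _row(n: int, den: int, **labels) -> dict:
    return {**labels, "n": n, "N": den, "fraction": _frac(n, den), "pct": _pct(n, den)}


def proportion_untreated(
    adjudicated: Iterable[AdjudicatedBleed], diary: Diary
) -> pd.DataFrame:
    """Share of untreated bleeds among all bleeds, per cohort."""
    rows = []
    adjudicated = list(adjudicated)
    for cohort in Cohort:
        strat = [
            ab for ab in adjudicated
            if diary.participant(ab.bleed.participant_id).cohort is cohort
        ]
        if not strat and not any(p.cohort is cohort for p in diary.participants):
            continue
        untreated = sum(not ab.treated for ab in strat)
        rows.append(_row(untreated, len(strat), cohort=cohort.value, label="untreated"))
    return pd.DataFrame(rows)


def reporter_percentages(
    adjudicated: Iterable[AdjudicatedBleed], diary: Diary
) -> pd.DataFrame:
    """Share of participants reporting at least one untreated bleed, per cohort.

    The denominator is every analyzed participant in the cohort, including
    those with no bleed at all.
    """
    reporters: set[str] = {
        ab.bleed.participant_id for ab in adjudicated if not ab.treated
    }
    rows = []
    for cohort in Cohort:
        members = [p for p in diary.participants if p.cohort is cohort]
        if not members:
            continue
        n = sum(p.participant_id in reporters for p in members)
        rows.append(
            _row(n, len(members), cohort=cohort.value, label="untreated_reporters")
        )
    return pd.DataFrame(rows)


def location_table(
    adjudicated: Iterable[AdjudicatedBleed], diary: Diary
) -> pd.DataFrame:
    """Bleed locations per cohort x treated stratum.

    Row percentages are of the stratum's total bleeds, except the joint
    sub-rows (knee / elbow / ankle / other_joint) which are percentages of the
    stratum's *joint* bleeds.  Cohort-dialect extras (soft tissue,
    bruise/hematoma, miscellaneous for cohort A; "other" for B and C) appear as
    their own rows.
    """
    adjudicated = list(adjudicated)
    rows = []
    for cohort in Cohort:
        extras = (
            ("soft_tissue", "bruise_hematoma", "miscellaneous")
            if cohort is Cohort.A
            else ("other",)
        )
        for treated in (True, False):
            strat = [
                ab for ab in adjudicated
                if ab.treated == treated
                and diary.participant(ab.bleed.participant_id).cohort is cohort
            ]
            if not strat:
                continue
            total = len(strat)
            arm = "treated" if treated else "untreated"
            joint = [ab for ab in strat if ab.bleed.location in JOINT_SITES]
            rows.append(_row(len(joint), total, cohort=cohort.value, arm=arm,
                             row="joint", parent="total"))
            for site in _NAMED_JOINTS:
                k = sum(ab.bleed.location == site for ab in joint)
                rows.append(_row(k, len(joint), cohort=cohort.value, arm=arm,
                                 row=site, parent="joint"))
            other_joint = sum(
                ab.bleed.location not in _NAMED_JOINTS for ab in joint
            )
            rows.append(_row(other_joint, len(joint), cohort=cohort.value, arm=arm,
                             row="other_joint", parent="joint"))
            muscle = sum(ab.bleed.location == "muscle" for ab in strat)
            rows.append(_row(muscle, total, cohort=cohort.value, arm=arm,
                             row="muscle", parent="total"))
            for extra in extras:
                k = sum(ab.bleed.location == extra for ab in strat)
                rows.append(_row(k, total, cohort=cohort.value, arm=arm,
                                 row=extra, parent="total"))
    return pd.DataFrame(rows)


def cause_table(
    adjudicated: Iterable[AdjudicatedBleed],
    diary: Diary,
    by_regimen: bool = False,
) -> pd.DataFrame:
    """Spontaneous / traumatic / surgery shares per cohort x treated (x regimen)."""
    adjudicated = list(adjudicated)
    rows = []
    regimens: tuple = (None,) if not by_regimen else tuple(Regimen)
    for cohort in Cohort:
        for regimen in regimens:
            for treated in (True, False):
                strat = []
                for ab in adjudicated:
                    p = diary.participant(ab.bleed.participant_id)
                    if p.cohort is not cohort or ab.treated != treated:
                        continue
                    if regimen is not None and p.regimen is not regimen:
                        continue
                    strat.append(ab)
                if not strat:
                    continue
                total = len(strat)
                arm = "treated" if treated else "untreated"
                labels = {"cohort": cohort.value, "arm": arm}
                if regimen is not None:
                    labels["regimen"] = regimen.value
                for cause in Cause:
                    k = sum(ab.bleed.cause is cause for ab in strat)
                    rows.append(_row(k, total, **labels, row=cause.value))
    return pd.DataFrame(rows)


def prophylaxis_follow_summary(
    adjudicated: Iterable[AdjudicatedBleed], diary: Diary
) -> pd.DataFrame:
    """Among untreated bleeds of prophylaxis-regimen participants, the share
    followed within the window by a dose recorded as prophylaxis."""
    rows = []
    adjudicated = list(adjudicated)
    for cohort in Cohort:
        strat = [
            ab for ab in adjudicated
            if not ab.treated
            and diary.participant(ab.bleed.participant_id).cohort is cohort
            and diary.participant(ab.bleed.participant_id).regimen is Regimen.PROPHYLACTIC
        ]
        if not any(
            p.cohort is cohort and p.regimen is Regimen.PROPHYLACTIC
            for p in diary.participants
        ):
            continue
        flagged = sum(ab.prophylaxis_followup_within_24h for ab in strat)
        rows.append(
            _row(flagged, len(strat), cohort=cohort.value,
                 label="untreated_followed_by_prophylaxis_24h")
        )
    return pd.DataFrame(rows)


def build_all_tables(
    diary: Diary, config: AdjudicationConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Run adjudication and build every summary table for a diary."""
    config = config or AdjudicationConfig()
    result = adjudicate(diary, config)
    bleeds = result.bleeds
    return {
        "proportion_untreated": proportion_untreated(bleeds, diary),
        "reporter_percentages": reporter_percentages(bleeds, diary),
        "location_table": location_table(bleeds, diary),
        "cause_table": cause_table(bleeds, diary),
        "cause_table_by_regimen": cause_table(bleeds, diary, by_regimen=True),
        "prophylaxis_follow_summary": prophylaxis_follow_summary(bleeds, diary),
    }


def sensitivity_exclude(
    diary: Diary,
    participant_id: str,
    config: AdjudicationConfig | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Recompute every summary with one participant excluded.

    Returns ``{"included": tables, "excluded": tables}`` where ``excluded`` is
    the identical pipeline run on the diary minus the named participant, so
    the result is exactly what a from-scratch run on the filtered diary gives.
    """
    if participant_id not in diary.roster:
        raise KeyError(f"unknown participant {participant_id!r}")
    return {
        "included": build_all_tables(diary, config),
        "excluded": build_all_tables(diary.without_participant(participant_id), config),
    }
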