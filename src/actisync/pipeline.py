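"""End-to-end cohort analysis: registration → scoring → wear screening →
bout validation → agreement tables.

`analyze_cohort` is the one-call surface mirroring the full study pipeline
on a list of participants (each a pair of device streams plus an exercise
journal).  Participants without valid days and journal entries that fail
bout matching are excluded with logged, queryable reasons — never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import agreement, bouts, intensity, wear
from .device_io import DeviceMinuteSeries, RegisteredStream, register
from .intensity import CutPointScheme, FREEDSON_ADULT_VM, MetModel
from .wear import WearCriteria

logger = logging.getLogger(__name__)


@dataclass
class ParticipantData:
    """One participant's raw inputs: the two device exports and the journal."""

    participant_id: str
    research: DeviceMinuteSeries
    consumer: DeviceMinuteSeries
    journal: pd.DataFrame


@dataclass
class ParticipantResult:
    participant_id: str
    registered: RegisteredStream
    day_summaries: pd.DataFrame
    bout_summaries: list = field(default_factory=list)
    rejections: list = field(default_factory=list)


@dataclass
class CohortResult:
    """Cohort-level outputs: agreement tables plus per-participant detail."""

    tables: dict
    participant_summaries: pd.DataFrame
    bout_summaries: list
    participants: list
    excluded: dict  # participant_id -> reason


def analyze_participant(
    pdata: ParticipantData,
    criteria: WearCriteria = WearCriteria(),
    scheme: CutPointScheme = CutPointScheme(),
    met_model: MetModel = FREEDSON_ADULT_VM,
    bout_tolerance: int = 5,
    sedentary_rule: str = "steps_aware",
) -> ParticipantResult:
    """Run the single-participant pipeline.

    Steps: register the raw streams onto their common grid, score the
    research stream (codes, METs, sedentary flag), detect nonwear per device
    and intersect, screen valid days, summarise valid days, then validate
    and summarise journal bouts (overlapping validated bouts are merged).
    """
    reg = register(pdata.research, pdata.consumer)
    reg.research = intensity.score_research(reg.research, scheme, met_model)
    reg = wear.apply_joint_exclusion(reg, criteria)
    reg.valid_days = wear.screen_valid_days(reg, criteria)

    day_summaries = agreement.summarize_days(reg, sedentary_rule=sedentary_rule)

    accepted, rejected = [], []
    for entry in bouts.journal_entries(pdata.journal):
        result = bouts.validate_bout(
            entry,
            reg.research,
            joint_wear=reg.joint_wear,
            tolerance=bout_tolerance,
            participant=pdata.participant_id,
        )
        if isinstance(result, bouts.BoutRejection):
            logger.info("bout rejected (%s, %s): %s", pdata.participant_id, entry.date, result.reason)
            rejected.append(result)
        else:
            accepted.append(result)
    merged = bouts.merge_overlapping(accepted)
    summaries = [bouts.summarize_bout(reg, b) for b in merged]

    return ParticipantResult(
        participant_id=pdata.participant_id,
        registered=reg,
        day_summaries=day_summaries,
        bout_summaries=summaries,
        rejections=rejected,
    )


def analyze_cohort(
    participants: list,
    criteria: WearCriteria = WearCriteria(),
    scheme: CutPointScheme = CutPointScheme(),
    met_model: MetModel = FREEDSON_ADULT_VM,
    bout_tolerance: int = 5,
    sedentary_rule: str = "steps_aware",
) -> CohortResult:
    """Run the pipeline for every participant and build the agreement tables.

    Day-level comparisons use participants (mean over their valid days) as
    units; bout-level comparisons pool validated bouts.
    """
    results, rows, all_bouts, excluded = [], {}, [], {}
    for pdata in participants:
        res = analyze_participant(
            pdata,
            criteria=criteria,
            scheme=scheme,
            met_model=met_model,
            bout_tolerance=bout_tolerance,
            sedentary_rule=sedentary_rule,
        )
        results.append(res)
        if len(res.day_summaries) == 0:
            excluded[pdata.participant_id] = "no valid days"
            logger.warning("participant %s excluded: no valid days", pdata.participant_id)
        else:
            rows[pdata.participant_id] = agreement.participant_mean_summary(res.day_summaries)
        all_bouts.extend(res.bout_summaries)

    participant_summaries = pd.DataFrame.from_dict(rows, orient="index")
    participant_summaries.index.name = "participant"
    tables = agreement.build_tables(participant_summaries, all_bouts)
    return CohortResult(
        tables=tables,
        participant_summaries=participant_summaries,
        bout_summaries=all_bouts,
        participants=results,
        excluded=excluded,
    )
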