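"""Paired device-agreement statistics and day/bout-level summary tables.

The analysis mirrors a simple paired design: for each unit (a participant's
valid-day average, or a validated exercise bout) the consumer and research
values form a pair, and agreement is reported as the paired *t* test, the
paired Cohen's d (mean of within-pair differences over the SD of those
differences), and the Pearson correlation across pairs.  The sign convention
is fixed throughout: a positive mean difference means the consumer device
exceeds the research device.

Day-level summaries are computed on the joint-wear minutes of valid days and
averaged within participant, so participants are the analysis units; bout
summaries use the bout as the unit.  Intensity shares are percentages of
joint-wear time and always partition 100%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bouts import BoutSummary
from .device_io import RegisteredStream
from .errors import DomainError

logger = logging.getLogger(__name__)

SEDENTARY_RULES = ("steps_aware", "code_only")

DAY_VARIABLES = ("met_rate", "sedentary_pct", "light_pct", "moderate_pct", "vigorous_pct", "steps")
BOUT_VARIABLES = ("mets", "intensity", "steps")
#: the three most homogeneous journal categories get per-type tables
TYPED_CATEGORIES = ("walk", "run_or_sports", "cardio_machine")


@dataclass(frozen=True)
class PairedComparison:
    """Full paired-statistics record for one variable."""

    n: int
    mean_research: float
    mean_consumer: float
    sd_research: float
    sd_consumer: float
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_value: float
    r: float
    d: float
    d_undefined: bool = False


def paired_compare(values_research, values_consumer) -> PairedComparison:
    """Paired t test, Pearson r and paired Cohen's d on elementwise pairs.

    Differences are consumer − research.  ``sd_diff`` uses the n−1
    denominator; t has n−1 degrees of freedom with a two-sided p.  When the
    differences are constant, d is undefined (flagged) and t is reported
    with infinite magnitude unless the constant is zero.
    """
    a = np.asarray(values_research, dtype=float)
    b = np.asarray(values_consumer, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"length mismatch: {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise DomainError("paired comparison needs at least 2 pairs")
    diff = b - a
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))

    if sd_diff == 0.0:
        if mean_diff == 0.0:
            t, p, d, flag = 0.0, 1.0, 0.0, False
        else:
            t = math.copysign(math.inf, mean_diff)
            p, d, flag = 0.0, math.nan, True
    else:
        t = mean_diff / (sd_diff / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), n - 1))
        d = mean_diff / sd_diff
        flag = False

    if a.std() == 0.0 or b.std() == 0.0:
        r = math.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])

    return PairedComparison(
        n=n,
        mean_research=float(a.mean()),
        mean_consumer=float(b.mean()),
        sd_research=float(a.std(ddof=1)),
        sd_consumer=float(b.std(ddof=1)),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        t_statistic=t,
        p_value=p,
        r=r,
        d=d,
        d_undefined=flag,
    )


def cohen_d_from_summary(mean_a: float, sd_a: float, mean_b: float, sd_b: float, r: float) -> float:
    """Paired Cohen's d reconstructed from per-group moments.

    d = (mean_b − mean_a) / sqrt(sd_a² + sd_b² − 2·r·sd_a·sd_b), the SD of
    paired differences implied by the two SDs and their correlation.
    Matches :func:`paired_compare`'s d exactly on moment-matched data.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise DomainError("summary SDs must be positive")
    if abs(r) > 1:
        raise DomainError("|r| must be <= 1")
    radicand = sd_a**2 + sd_b**2 - 2.0 * r * sd_a * sd_b
    if radicand <= 0:
        raise DomainError(f"nonpositive difference variance ({radicand})")
    return (mean_b - mean_a) / math.sqrt(radicand)


def _day_shares(codes: np.ndarray, sedentary: np.ndarray) -> tuple:
    """Intensity shares (%) partitioning the day's joint-wear minutes.

    ``sedentary`` marks minutes counted as the sedentary share; code-0
    minutes it excludes (steps during sub-threshold counts) are assigned to
    the light share so the four shares remain a partition.
    """
    n = len(codes)
    sed = sedentary.sum()
    light = ((codes == 1) | ((codes == 0) & ~sedentary)).sum()
    moderate = (codes == 2).sum()
    vigorous = (codes == 3).sum()
    return tuple(100.0 * x / n for x in (sed, light, moderate, vigorous))


def summarize_days(reg: RegisteredStream, sedentary_rule: str = "steps_aware") -> pd.DataFrame:
    """Per-valid-day device summaries over joint-wear minutes.

    Columns per device: total steps, MET rate (mean METs/min), and the four
    intensity shares (% of joint-wear time).  The research sedentary share
    follows ``sedentary_rule``: ``steps_aware`` (counts < 200 and no steps;
    stepping code-0 minutes count as light) or ``code_only``.  The consumer
    stream has no counts, so its sedentary share is always code-based.
    """
    if sedentary_rule not in SEDENTARY_RULES:
        raise DomainError(f"sedentary_rule must be one of {SEDENTARY_RULES}")
    rows = {}
    dates = pd.Index(reg.minutes.date)
    for day in sorted(reg.valid_days):
        sel = np.asarray(dates == day) & reg.joint_wear.to_numpy()
        res = reg.research.data.loc[sel]
        con = reg.consumer.data.loc[sel]
        res_codes = res["intensity_code"].to_numpy()
        if sedentary_rule == "steps_aware" and "sedentary_flag" in res.columns:
            res_sed = res["sedentary_flag"].to_numpy().astype(bool)
        else:
            res_sed = res_codes == 0
        con_codes = con["intensity_code"].to_numpy()
        r_shares = _day_shares(res_codes, res_sed)
        c_shares = _day_shares(con_codes, con_codes == 0)
        rows[day] = {
            "research_steps": float(res["steps"].sum()),
            "research_met_rate": float(res["mets"].mean()),
            "research_sedentary_pct": r_shares[0],
            "research_light_pct": r_shares[1],
            "research_moderate_pct": r_shares[2],
            "research_vigorous_pct": r_shares[3],
            "consumer_steps": float(con["steps"].sum()),
            "consumer_met_rate": float(con["mets"].mean()),
            "consumer_sedentary_pct": c_shares[0],
            "consumer_light_pct": c_shares[1],
            "consumer_moderate_pct": c_shares[2],
            "consumer_vigorous_pct": c_shares[3],
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "date"
    return out


def participant_mean_summary(day_summaries: pd.DataFrame) -> pd.Series:
    """Average the per-day summaries within a participant (the day-level
    analysis unit)."""
    if len(day_summaries) == 0:
        raise DomainError("participant has no valid days")
    return day_summaries.mean()


def _comparison_row(variable: str, comp: PairedComparison) -> dict:
    return {"variable": variable, **comp.__dict__}


def day_level_table(participant_summaries: pd.DataFrame) -> pd.DataFrame:
    """Day-level agreement table: one paired comparison per activity variable,
    participants as units."""
    pairs = {
        "met_rate": ("research_met_rate", "consumer_met_rate"),
        "sedentary_pct": ("research_sedentary_pct", "consumer_sedentary_pct"),
        "light_pct": ("research_light_pct", "consumer_light_pct"),
        "moderate_pct": ("research_moderate_pct", "consumer_moderate_pct"),
        "vigorous_pct": ("research_vigorous_pct", "consumer_vigorous_pct"),
        "steps": ("research_steps", "consumer_steps"),
    }
    rows = []
    for variable, (ra, ca) in pairs.items():
        if len(participant_summaries) < 2:
            logger.warning("day-level row %s omitted: fewer than 2 participants", variable)
            continue
        comp = paired_compare(participant_summaries[ra], participant_summaries[ca])
        rows.append(_comparison_row(variable, comp))
    return pd.DataFrame(rows)


def _bout_frame(bout_summaries: list[BoutSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [s.bout.category for s in bout_summaries],
            "research_mets": [s.research_mets for s in bout_summaries],
            "consumer_mets": [s.consumer_mets for s in bout_summaries],
            "research_intensity": [s.research_intensity for s in bout_summaries],
            "consumer_intensity": [s.consumer_intensity for s in bout_summaries],
            "research_steps": [s.research_steps for s in bout_summaries],
            "consumer_steps": [s.consumer_steps for s in bout_summaries],
        }
    )


def bout_level_table(bout_summaries: list[BoutSummary]) -> pd.DataFrame:
    """Pooled bout-level agreement: METs/min, intensity score/min, steps/min
    with bouts as units."""
    frame = _bout_frame(bout_summaries)
    rows = []
    for variable in BOUT_VARIABLES:
        if len(frame) < 2:
            logger.warning("bout-level row %s omitted: fewer than 2 bouts", variable)
            continue
        comp = paired_compare(frame[f"research_{variable}"], frame[f"consumer_{variable}"])
        rows.append(_comparison_row(variable, comp))
    return pd.DataFrame(rows)


def bout_category_table(bout_summaries: list[BoutSummary]) -> pd.DataFrame:
    """Per-category bout agreement for walk, run-or-sports, and cardio
    machine (the three most homogeneous categories); categories with fewer
    than 2 bouts are omitted with a logged reason."""
    frame = _bout_frame(bout_summaries)
    rows = []
    for category in TYPED_CATEGORIES:
        sub = frame[frame["category"] == category]
        if len(sub) < 2:
            logger.warning("category %s omitted: %d bout(s)", category, len(sub))
            continue
        for variable in BOUT_VARIABLES:
            comp = paired_compare(sub[f"research_{variable}"], sub[f"consumer_{variable}"])
            row = _comparison_row(variable, comp)
            row["category"] = category
            rows.append(row)
    return pd.DataFrame(rows)


def build_tables(participant_summaries: pd.DataFrame, bout_summaries: list[BoutSummary]) -> dict:
    """All three agreement tables: day-level, pooled bouts, bouts by type."""
    return {
        "day_level": day_level_table(participant_summaries),
        "bouts_overall": bout_level_table(bout_summaries),
        "bouts_by_type": bout_category_table(bout_summaries),
    }
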