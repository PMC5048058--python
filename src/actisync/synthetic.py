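"""Synthetic paired two-device cohort generator with recoverable injected
device bias.

The generator states a concrete free-living world so every downstream stage
is testable without any download:

* A day has a wake window (default 16 h from 07:00); sleep minutes are zero
  on both devices.  Within wake, minute activity states follow a discrete
  semi-Markov chain over {nonwear, sedentary, light, moderate, vigorous}
  with geometric dwell times — the exposure of transition and dwell
  parameters, rather than a hard-coded behaviour model, is deliberate since
  free-living structure is unknown.
* Vector-magnitude counts per worn minute are lognormal, truncated exactly
  to the state's cut-point band, so count-based classification of the truth
  is exact by construction.  Steps are Poisson with mean proportional to
  counts, clipped at a physiological cap.
* True METs follow the research-device linear count model, so the research
  pipeline reproduces truth exactly and any consumer/research discrepancy
  is attributable to the injected :class:`DeviceBiasModel`: a MET
  multiplier, a 4x4 intensity confusion matrix, per-minute step noise, and
  a probability that a worn minute reads zero on one device only.
* Participants report purposeful-exercise bouts (default rate 6.34 per 14
  days); journals carry the true windows shifted by integer jitter of at
  most 5 minutes and are truncated to 4 entries per day (shortest dropped
  first, earliest among ties).

One root seed; per-participant child streams are derived by fixed spawn
key, so adding a participant never perturbs earlier ones.  Identical
(config, bias, seed) reproduce identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .device_io import CONSUMER, RESEARCH, DeviceMinuteSeries, _finalize_frame
from .errors import ConfigurationError
from .intensity import FREEDSON_ADULT_VM, estimate_mets
from .pipeline import ParticipantData

STATES = ("nonwear", "sedentary", "light", "moderate", "vigorous")
NONWEAR = 0  # state index; worn states 1..4 map to intensity codes 0..3

BOUT_CATEGORIES = ("walk", "run_or_sports", "bike", "cardio_dance", "cardio_machine", "weights")

#: journal label vocabularies per category (drawn uniformly)
LABEL_VOCAB = {
    "walk": ("walk", "morning walk", "dog walk", "hike"),
    "run_or_sports": ("running", "jogging", "basketball", "soccer", "ultimate frisbee", "football"),
    "bike": ("bike ride", "cycling"),
    "cardio_dance": ("zumba", "dance class", "aerobics"),
    "cardio_machine": ("treadmill running", "elliptical trainer", "stair-climber", "stationary bike"),
    "weights": ("weight lifting", "strength training"),
}

#: per-category minute state distribution over (sedentary, light, moderate,
#: vigorous) during a bout; kept >= 95% non-sedentary so journalled bouts
#: are matchable under the 0.8 activity-fraction rule
BOUT_STATE_PROBS = {
    "walk": (0.02, 0.68, 0.28, 0.02),
    "run_or_sports": (0.02, 0.08, 0.50, 0.40),
    "bike": (0.02, 0.18, 0.65, 0.15),
    "cardio_dance": (0.02, 0.18, 0.60, 0.20),
    "cardio_machine": (0.02, 0.13, 0.70, 0.15),
    "weights": (0.05, 0.50, 0.40, 0.05),
}


@dataclass(frozen=True)
class CountBand:
    """Truncated-lognormal count distribution for one worn state.

    Samples are floored to integers on [lo, hi]; the default bands coincide
    with the cut-point bands so classifying a generated minute recovers its
    state exactly.
    """

    lo: int
    hi: int
    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ConfigurationError("count band requires 0 <= lo <= hi")
        if self.log_sd <= 0:
            raise ConfigurationError("log_sd must be positive")

    def mean(self) -> float:
        """Analytic mean of the continuous truncated lognormal (before the
        integer floor)."""
        mu, s = self.log_mean, self.log_sd
        a = math.log(max(self.lo, 1e-12))
        b = math.log(self.hi + 1)
        z = sps.norm.cdf((b - mu) / s) - sps.norm.cdf((a - mu) / s) if self.lo > 0 else sps.norm.cdf((b - mu) / s)
        num = sps.norm.cdf((b - mu - s**2) / s) - (sps.norm.cdf((a - mu - s**2) / s) if self.lo > 0 else 0.0)
        return math.exp(mu + s**2 / 2) * num / z


def _default_bands() -> dict:
    return {
        "sedentary": CountBand(0, 199, math.log(40.0), 1.2),
        "light": CountBand(200, 2690, math.log(700.0), 0.9),
        "moderate": CountBand(2691, 6166, math.log(3900.0), 0.45),
        "vigorous": CountBand(6167, 20000, math.log(7800.0), 0.35),
    }


def _default_transition() -> np.ndarray:
    # Jump-chain rows over (nonwear, sedentary, light, moderate, vigorous).
    # With the default dwell means the dwell-weighted stationary worn shares
    # are ~68/27/4/1 %, matching a mostly sedentary young-adult cohort.
    return np.array(
        [
            [0.00, 0.80, 0.15, 0.04, 0.01],
            [0.04, 0.00, 0.82, 0.11, 0.03],
            [0.02, 0.83, 0.00, 0.13, 0.02],
            [0.02, 0.45, 0.38, 0.00, 0.15],
            [0.02, 0.25, 0.38, 0.35, 0.00],
        ]
    )


@dataclass(frozen=True)
class StepsPerCount:
    """Linear link between counts and steps: Poisson mean = slope * counts,
    optional Gaussian jitter, clipped at a physiological cap.

    Minutes below the ambulation threshold (sub-200 counts: fidgeting, not
    stepping) record zero steps, which keeps the steps-aware sedentary rule
    consistent with count-only classification on generated truth.
    """

    slope: float = 0.02
    noise_sd: float = 0.0
    cap: int = 220
    ambulation_threshold: int = 200


@dataclass
class SimulationConfig:
    n_participants: int = 19
    n_days: int = 14
    wake_minutes_per_day: int = 960
    wake_start_minute: int = 420  # 07:00
    state_transition: np.ndarray = field(default_factory=_default_transition)
    state_dwell: tuple = (90.0, 30.0, 12.0, 7.0, 3.5)
    count_band_params: dict = field(default_factory=_default_bands)
    steps_per_count: StepsPerCount = StepsPerCount()
    bout_rate: float = 6.34 / 14  # reported bouts per participant-day
    bout_duration_mean: float = 55.0
    bout_duration_sd: float = 25.0
    bout_jitter_minutes: int = 2
    category_weights: tuple = (0.15, 0.35, 0.10, 0.10, 0.20, 0.10)
    start_date: str = "2024-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        t = np.asarray(self.state_transition, dtype=float)
        if t.shape != (5, 5) or (t < 0).any():
            raise ConfigurationError("state_transition must be a nonnegative 5x5 matrix")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ConfigurationError("state_transition rows must sum to 1 within 1e-12")
        self.state_transition = t
        if len(self.state_dwell) != 5 or any(d <= 0 for d in self.state_dwell):
            raise ConfigurationError("all dwell means must be positive")
        if not 0 <= self.bout_jitter_minutes <= 5:
            raise ConfigurationError("bout_jitter_minutes must lie in [0, 5]")
        if not 0 <= self.wake_start_minute:
            raise ConfigurationError("wake_start_minute must be nonnegative")
        if self.wake_start_minute + self.wake_minutes_per_day > 1440:
            raise ConfigurationError("wake window must fit within the day")
        if abs(sum(self.category_weights) - 1.0) > 1e-9:
            raise ConfigurationError("category_weights must sum to 1")


def _identity_confusion() -> np.ndarray:
    return np.eye(4)


def _default_confusion() -> np.ndarray:
    # Consumer cut points misread research intensity: genuinely light wear is
    # often reported sedentary, active codes smear upward — the direction of
    # the day-level discrepancies the analysis is built to expose.
    return np.array(
        [
            [0.95, 0.03, 0.01, 0.01],
            [0.55, 0.30, 0.10, 0.05],
            [0.05, 0.15, 0.60, 0.20],
            [0.02, 0.05, 0.13, 0.80],
        ]
    )


@dataclass
class DeviceBiasModel:
    """Parametric surrogate for the consumer device's undisclosed algorithms."""

    met_multiplier: float = 1.44
    intensity_confusion: np.ndarray = field(default_factory=_default_confusion)
    step_noise_sd: float = 8.0
    nonwear_disagreement_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.met_multiplier <= 0:
            raise ConfigurationError("met_multiplier must be positive")
        c = np.asarray(self.intensity_confusion, dtype=float)
        if c.shape != (4, 4) or (c < 0).any() or not np.allclose(c.sum(axis=1), 1.0, atol=1e-9, rtol=0):
            raise ConfigurationError("intensity_confusion must be 4x4 row-stochastic")
        self.intensity_confusion = c
        if self.step_noise_sd < 0:
            raise ConfigurationError("step_noise_sd must be nonnegative")
        if not 0 <= self.nonwear_disagreement_prob <= 1:
            raise ConfigurationError("nonwear_disagreement_prob must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "DeviceBiasModel":
        """A consumer device that reports the truth exactly."""
        return cls(
            met_multiplier=1.0,
            intensity_confusion=_identity_confusion(),
            step_noise_sd=0.0,
            nonwear_disagreement_prob=0.0,
        )


@dataclass
class ParticipantTruth:
    participant_id: str
    minutes: pd.DataFrame  # index minute; columns true_state, true_counts, true_mets
    bouts: pd.DataFrame  # columns date, category, start, end (end exclusive), n_minutes


@dataclass
class GroundTruth:
    participants: list
    bias: DeviceBiasModel
    config: SimulationConfig


def _participant_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))


def _sample_band(rng: np.random.Generator, band: CountBand, size: int) -> np.ndarray:
    """Integer counts from the lognormal truncated exactly to [lo, hi]."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    dist = sps.lognorm(s=band.log_sd, scale=math.exp(band.log_mean))
    lo_cdf = dist.cdf(band.lo) if band.lo > 0 else 0.0
    hi_cdf = dist.cdf(band.hi + 1)
    u = rng.uniform(lo_cdf, hi_cdf, size)
    x = np.floor(dist.ppf(u))
    return np.clip(x, band.lo, band.hi).astype(np.int64)


def _semi_markov(rng: np.random.Generator, n: int, transition: np.ndarray, dwell: tuple, start_state: int = 1) -> np.ndarray:
    seq = np.empty(n, dtype=np.int8)
    state = start_state
    i = 0
    while i < n:
        d = int(rng.geometric(1.0 / dwell[state]))
        seq[i : i + d] = state
        i += d
        state = int(rng.choice(5, p=transition[state]))
    return seq


def _place_bouts(rng, config: SimulationConfig, day: int) -> list:
    """Non-overlapping (category, start_minute, duration) bouts inside wake."""
    n = rng.poisson(config.bout_rate)
    wake_lo = config.wake_start_minute
    wake_hi = config.wake_start_minute + config.wake_minutes_per_day
    placed = []
    for _ in range(n):
        dur = int(np.clip(round(rng.normal(config.bout_duration_mean, config.bout_duration_sd)), 15, 130))
        if dur > config.wake_minutes_per_day:
            continue
        category = BOUT_CATEGORIES[rng.choice(len(BOUT_CATEGORIES), p=np.asarray(config.category_weights))]
        for _attempt in range(25):
            start = int(rng.integers(wake_lo, wake_hi - dur + 1))
            # 15-min buffer keeps jittered reports and validated windows distinct
            if all(start + dur + 15 <= s or e + 15 <= start for _, s, e in placed):
                placed.append((category, start, start + dur))
                break
    return sorted(placed, key=lambda b: b[1])


def _generate_participant(rng, config: SimulationConfig, bias: DeviceBiasModel, pid: str):
    n_minutes = config.n_days * 1440
    start = pd.Timestamp(config.start_date)
    index = pd.date_range(start, periods=n_minutes, freq="min")

    state = np.full(n_minutes, NONWEAR, dtype=np.int8)
    bout_rows = []
    for day in range(config.n_days):
        off = day * 1440
        w0 = off + config.wake_start_minute
        w1 = w0 + config.wake_minutes_per_day
        state[w0:w1] = _semi_markov(
            rng, config.wake_minutes_per_day, config.state_transition, config.state_dwell
        )
        for category, s, e in _place_bouts(rng, config, day):
            probs = np.asarray(BOUT_STATE_PROBS[category])
            state[off + s : off + e] = rng.choice(4, size=e - s, p=probs) + 1
            bout_rows.append(
                {
                    "date": (start + pd.Timedelta(days=day)).date(),
                    "category": category,
                    "start": index[off + s],
                    "end": index[off + e] if off + e < n_minutes else index[-1] + pd.Timedelta(minutes=1),
                    "n_minutes": e - s,
                }
            )

    # counts per state (order fixed for determinism)
    counts = np.zeros(n_minutes, dtype=np.int64)
    for k, name in enumerate(STATES[1:], start=1):
        sel = np.flatnonzero(state == k)
        counts[sel] = _sample_band(rng, config.count_band_params[name], len(sel))

    spc = config.steps_per_count
    ambulatory = counts >= spc.ambulation_threshold
    steps = rng.poisson(spc.slope * counts * ambulatory).astype(float)
    if spc.noise_sd > 0:
        steps += np.round(rng.normal(0.0, spc.noise_sd, n_minutes))
    steps = np.clip(steps, 0, spc.cap).astype(np.int64)
    steps[(state == NONWEAR) | ~ambulatory] = 0

    true_mets = estimate_mets(counts, FREEDSON_ADULT_VM)
    true_mets = np.where(state == NONWEAR, 1.0, true_mets)
    true_code = np.maximum(state - 1, 0)  # worn-state intensity code; 0 when nonwear

    # consumer distortion
    worn = state != NONWEAR
    consumer_code = np.zeros(n_minutes, dtype=np.int64)
    u = rng.random(n_minutes)
    cum = np.cumsum(bias.intensity_confusion, axis=1)
    for k in range(4):
        sel = worn & (true_code == k)
        consumer_code[sel] = np.searchsorted(cum[k], u[sel], side="right")
    consumer_code = np.minimum(consumer_code, 3)

    consumer_steps = steps.astype(float)
    if bias.step_noise_sd > 0:
        consumer_steps = consumer_steps + np.round(rng.normal(0.0, bias.step_noise_sd, n_minutes))
    consumer_steps = np.clip(consumer_steps, 0, None).astype(np.int64)
    consumer_steps[~worn] = 0

    consumer_mets = np.where(worn, bias.met_multiplier * true_mets, 1.0)

    research_counts = counts.copy()
    research_steps = steps.copy()
    if bias.nonwear_disagreement_prob > 0:
        flip = rng.random(n_minutes) < bias.nonwear_disagreement_prob
        side = rng.random(n_minutes) < 0.5
        res_flip = worn & flip & side
        con_flip = worn & flip & ~side
        research_counts[res_flip] = 0
        research_steps[res_flip] = 0
        consumer_steps[con_flip] = 0
        consumer_code[con_flip] = 0
        consumer_mets[con_flip] = 1.0

    research = DeviceMinuteSeries(
        device=RESEARCH,
        data=_finalize_frame(
            pd.DataFrame(
                {"counts": research_counts.astype(float), "steps": research_steps, "wear": True},
                index=index,
            )
        ),
    )
    consumer = DeviceMinuteSeries(
        device=CONSUMER,
        data=_finalize_frame(
            pd.DataFrame(
                {
                    "steps": consumer_steps,
                    "mets": consumer_mets,
                    "intensity_code": consumer_code.astype(float),
                    "wear": True,
                },
                index=index,
            )
        ),
    )
    truth = ParticipantTruth(
        participant_id=pid,
        minutes=pd.DataFrame(
            {"true_state": state, "true_counts": counts, "true_mets": true_mets}, index=index
        ),
        bouts=pd.DataFrame(bout_rows, columns=["date", "category", "start", "end", "n_minutes"]),
    )
    return research, consumer, truth


def generate_journal(truth: GroundTruth, jitter: int, seed: int) -> pd.DataFrame:
    """Journal table (participant, date, type, start, end; HH:MM) from true
    bouts: boundaries shifted by integer minutes uniform on [−jitter, +jitter],
    at most 4 rows per participant-day (shortest dropped first, earliest among
    equal lengths), labels drawn from the category vocabularies."""
    if not 0 <= jitter <= 5:
        raise ConfigurationError("jitter must lie in [0, 5] minutes")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1_000_003,)))
    rows = []
    for pt in truth.participants:
        for _, b in pt.bouts.iterrows():
            ds = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            de = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            rep_start = b["start"] + pd.Timedelta(minutes=ds)
            rep_end = b["end"] + pd.Timedelta(minutes=de)
            label = LABEL_VOCAB[b["category"]][rng.integers(len(LABEL_VOCAB[b["category"]]))]
            rows.append(
                {
                    "participant": pt.participant_id,
                    "date": b["date"],
                    "type": label,
                    "start": rep_start.strftime("%H:%M"),
                    "end": rep_end.strftime("%H:%M"),
                    "_duration": int((rep_end - rep_start) / pd.Timedelta(minutes=1)),
                    "_start_ts": rep_start,
                }
            )
    journal = pd.DataFrame(
        rows, columns=["participant", "date", "type", "start", "end", "_duration", "_start_ts"]
    )
    if len(journal) == 0:
        return journal.drop(columns=["_duration", "_start_ts"])

    kept = []
    for _, group in journal.groupby(["participant", "date"], sort=False):
        if len(group) > 4:
            group = group.sort_values(["_duration", "_start_ts"]).iloc[len(group) - 4 :]
        kept.append(group.sort_values("_start_ts"))
    out = pd.concat(kept).sort_values(["participant", "_start_ts"])
    return out.drop(columns=["_duration", "_start_ts"]).reset_index(drop=True)


def generate_cohort(config: SimulationConfig, bias: DeviceBiasModel | None = None):
    """Generate the full synthetic cohort.

    Returns ``(participants, truth)`` where each participant dataset holds
    two device series on an identical minute grid plus that participant's
    journal slice, and ``truth`` records the per-minute states, true METs,
    true bout windows and the bias model used.
    """
    bias = bias if bias is not None else DeviceBiasModel()
    participants, truths = [], []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        rng = _participant_rng(config.seed, i)
        research, consumer, truth = _generate_participant(rng, config, bias, pid)
        participants.append((pid, research, consumer))
        truths.append(truth)

    truth = GroundTruth(participants=truths, bias=bias, config=config)
    journal = generate_journal(truth, config.bout_jitter_minutes, config.seed)
    out = []
    for pid, research, consumer in participants:
        pj = journal[journal["participant"] == pid].drop(columns=["participant"]).reset_index(drop=True)
        out.append(ParticipantData(participant_id=pid, research=research, consumer=consumer, journal=pj))
    return out, truth


# ---------------------------------------------------------------------------
# provenance output

def _config_dict(config: SimulationConfig, bias: DeviceBiasModel) -> dict:
    cfg = dataclasses.asdict(config)
    cfg["state_transition"] = np.asarray(config.state_transition).tolist()
    cfg["count_band_params"] = {k: dataclasses.asdict(v) for k, v in config.count_band_params.items()}
    b = dataclasses.asdict(bias)
    b["intensity_confusion"] = np.asarray(bias.intensity_confusion).tolist()
    return {"simulation": cfg, "bias": b}


def write_cohort(participants: list, truth: GroundTruth, outdir) -> None:
    """Write the cohort in the same CSV dialects the readers consume, plus a
    ground-truth sidecar per participant and a JSON config echo."""
    from pathlib import Path

    from .device_io import write_consumer_export, write_research_export

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pdata, pt in zip(participants, truth.participants):
        stem = outdir / pdata.participant_id
        write_research_export(pdata.research, f"{stem}_research.csv")
        write_consumer_export(pdata.consumer, f"{stem}_consumer.csv")
        pdata.journal.to_csv(f"{stem}_journal.csv", index=False)
        sidecar = pd.DataFrame(
            {
                "minute": pt.minutes.index,
                "true_state": [STATES[s] for s in pt.minutes["true_state"]],
                "true_mets": pt.minutes["true_mets"],
            }
        )
        sidecar.to_csv(f"{stem}_truth.csv", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(_config_dict(truth.config, truth.bias), fh, indent=2, default=str)
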