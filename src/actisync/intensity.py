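"""Count-based intensity classification and MET estimation for the research
stream.

Intensity codes use the adult vector-magnitude cut points: sedentary
(0: 0–199 counts/min), light (1: 200–2690), moderate (2: 2691–6166) and
vigorous (3: >= 6167); the device's separate very-vigorous category is folded
into vigorous so both streams share one 0–3 scale.  Sedentary *behaviour*
additionally requires that no steps were recorded in the minute (< 200
counts/min AND steps == 0) — the steps rule only ever tightens code 0.

METs come from a linear count model clipped at a resting floor,
``max(floor, intercept + slope * counts)``; the default coefficients are the
published adult vector-magnitude regression (METs = 0.000863·VM + 0.668876,
floor 1.0).  Coefficients live in :class:`MetModel`, never in logic, so any
linear count→MET model can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device_io import DeviceMinuteSeries
from .errors import ConfigurationError, DomainError

INTENSITY_LABELS = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class CutPointScheme:
    """Ordered lower bounds (counts/min) of the light, moderate and vigorous
    bands; sedentary is everything below ``boundaries[0]``."""

    boundaries: tuple = (200, 2691, 6167)
    labels: tuple = INTENSITY_LABELS

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != 3 or list(b) != sorted(b) or len(set(b)) != 3:
            raise ConfigurationError("boundaries must be three strictly increasing thresholds")
        if b[0] <= 0:
            raise ConfigurationError("the first boundary must be positive")

    def band(self, code: int) -> tuple:
        """Closed [lo, hi] count band for a code; hi is None for vigorous."""
        lows = (0,) + self.boundaries
        highs = tuple(x - 1 for x in self.boundaries) + (None,)
        return lows[code], highs[code]


@dataclass(frozen=True)
class MetModel:
    """Linear counts→METs model with a resting floor."""

    intercept: float = 0.668876
    slope: float = 0.000863
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.slope < 0 or self.floor < 0:
            raise ConfigurationError("slope and floor must be nonnegative")


#: the published adult vector-magnitude regression, the package default
FREEDSON_ADULT_VM = MetModel()


def classify_intensity(counts, scheme: CutPointScheme = CutPointScheme()):
    """Intensity code(s) in {0,1,2,3} for nonnegative counts/min.

    Vectorised; scalar in, scalar out.
    """
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise DomainError("counts must be nonnegative")
    codes = np.searchsorted(np.asarray(scheme.boundaries), arr, side="right")
    if np.isscalar(counts) or arr.ndim == 0:
        return int(codes)
    return codes


def is_sedentary_behavior(counts, steps):
    """Sedentary behaviour: under 200 counts/min with no steps recorded."""
    arr_c = np.asarray(counts)
    arr_s = np.asarray(steps)
    if (arr_c < 0).any() or (arr_s < 0).any():
        raise DomainError("counts and steps must be nonnegative")
    out = (arr_c < 200) & (arr_s == 0)
    if np.isscalar(counts) or arr_c.ndim == 0:
        return bool(out)
    return out


def estimate_mets(counts, model: MetModel = FREEDSON_ADULT_VM):
    """METs from counts: ``max(floor, intercept + slope * counts)``."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise DomainError("counts must be nonnegative")
    mets = np.maximum(model.floor, model.intercept + model.slope * arr)
    if np.isscalar(counts) or arr.ndim == 0:
        return float(mets)
    return mets


def combine_vigorous(code):
    """Fold the very-vigorous category (4) into vigorous (3)."""
    arr = np.asarray(code)
    if ((arr < 0) | (arr > 4)).any():
        raise DomainError("intensity code must lie in 0-4")
    out = np.minimum(arr, 3)
    if np.isscalar(code) or arr.ndim == 0:
        return int(out)
    return out


def score_research(
    series: DeviceMinuteSeries,
    scheme: CutPointScheme = CutPointScheme(),
    model: MetModel = FREEDSON_ADULT_VM,
) -> DeviceMinuteSeries:
    """Fill the research stream's intensity codes, METs, and sedentary flag."""
    counts = series.data["counts"].to_numpy()
    codes = classify_intensity(counts, scheme).astype(float)
    mets = estimate_mets(counts, model)
    scored = series.with_data(intensity_code=codes, mets=mets)
    scored.data["sedentary_flag"] = is_sedentary_behavior(counts, series.data["steps"].to_numpy())
    return scored


def scored_minutes_frame(series: DeviceMinuteSeries) -> pd.DataFrame:
    """Per-minute scored table (minute, counts, steps, code, sedentary flag,
    METs) for export."""
    df = series.data
    out = pd.DataFrame(
        {
            "minute": df.index,
            "counts": df["counts"],
            "steps": df["steps"],
            "code": df["intensity_code"],
            "sedentary_flag": df.get("sedentary_flag", pd.Series(np.nan, index=df.index)),
            "mets": df["mets"],
        }
    )
    return out.reset_index(drop=True)
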