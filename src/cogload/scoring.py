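"""Composite scores: PACC5, cognitive reserve, affective state, allostatic
load (7 subdomains) and sleep-wake quality.

All composites follow the same z-score aggregation: each constituent measure
is standardized against a reference (by default the analysis cohort itself,
sample-SD convention, n-1), multiplied by a direction sign, averaged within
participant, and the per-participant averages are re-standardized over the
cohort — so every global composite has cohort mean 0 and SD 1. PACC5 is the
exception: it is the plain *sum* of the five test z-scores.

Direction conventions: higher reserve = better; higher allostatic load =
worse (the protective measures HDL, DHEA-S, SDANN and RMSSD enter with sign
-1); higher affective and sleep composites = worse state. Urinary cortisol,
adrenaline and noradrenaline are divided by serum creatinine before scoring
to adjust for lean body mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import (
    DegenerateMeasureError,
    DomainError,
    InsufficientDataError,
    MissingDataError,
    SchemaError,
)
from .synthetic import CR_SUBSCORES, PACC5_TESTS, LifestyleHistory, RRSeries

__all__ = [
    "ZReference",
    "zscore_composite",
    "pacc5",
    "occupation_score",
    "physical_activity_score",
    "leisure_score",
    "cognitive_reserve",
    "affective_state",
    "creatinine_correct",
    "rmssd",
    "sdnn",
    "sdann",
    "allostatic_load",
    "sleep_quality",
    "score_cohort",
    "AL_DOMAINS",
]

# allostatic-load subdomains: constituent column -> direction sign
AL_DOMAINS: dict[str, dict[str, int]] = {
    "al_cardio": {"sbp": 1, "heart_rate": 1, "pulse_pressure": 1},
    "al_parasymp": {"sdann": -1, "rmssd": -1},
    "al_lipid": {"bmi": 1, "whr": 1, "ldl": 1, "hdl": -1, "triglycerides": 1},
    "al_glucose": {"hba1c": 1, "glucose": 1},
    "al_inflam": {"crp": 1, "il6": 1},
    "al_hpa": {"dheas": -1, "cortisol_corrected": 1},
    "al_symp": {"adrenaline_corrected": 1, "noradrenaline_corrected": 1},
}

_CREATININE_CORRECTED = ("cortisol", "adrenaline", "noradrenaline")

QUESTIONNAIRE_RANGES = {"bdi": (0, 63), "bai": (0, 63), "psqi": (0, 21), "ess": (0, 24)}


@dataclass(frozen=True)
class ZReference:
    """Per-measure (mean, SD) used for standardization.

    By default estimated on the analysis cohort (``source='cohort'``); an
    externally normed reference can be supplied instead.
    """

    means: Mapping[str, float]
    sds: Mapping[str, float]
    source: str = "user"

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise DegenerateMeasureError(f"zero or negative SD for measure {name!r}")

    @classmethod
    def from_cohort(cls, table: pd.DataFrame, measures: Sequence[str]) -> "ZReference":
        if len(table) < 2:
            raise InsufficientDataError("cohort-estimated reference needs >= 2 participants")
        means, sds = {}, {}
        for name in measures:
            col = table[name]
            sd = float(col.std(ddof=1, skipna=True))
            if not sd > 0:
                raise DegenerateMeasureError(f"measure {name!r} has zero spread in the cohort")
            means[name] = float(col.mean(skipna=True))
            sds[name] = sd
        return cls(means, sds, source="cohort")

    def z(self, table: pd.DataFrame, name: str) -> pd.Series:
        if name not in self.means:
            raise MissingDataError(f"no reference moments for measure {name!r}")
        return (table[name] - self.means[name]) / self.sds[name]


def _require_columns(table: pd.DataFrame, measures: Sequence[str]) -> None:
    missing = [m for m in measures if m not in table.columns]
    if missing:
        raise MissingDataError(f"missing measure column(s): {', '.join(missing)}")


def zscore_composite(
    table: pd.DataFrame,
    measures: Sequence[str],
    signs: Mapping[str, int] | None = None,
    ref: ZReference | None = None,
) -> pd.Series:
    """Signed z-average, re-standardized over the cohort.

    Each measure is standardized by ``ref`` (cohort-estimated when None),
    multiplied by its sign (+1/-1), averaged within participant, and the
    per-participant averages are z-scored over the cohort (sample SD, n-1).
    """
    _require_columns(table, measures)
    signs = dict(signs or {})
    for name, s in signs.items():
        if s not in (-1, 1):
            raise DomainError(f"sign for {name!r} must be -1 or +1, got {s}")
    if ref is None:
        ref = ZReference.from_cohort(table, measures)
    z = pd.DataFrame({m: ref.z(table, m) * signs.get(m, 1) for m in measures})
    avg = z.mean(axis=1)
    sd = float(avg.std(ddof=1, skipna=True))
    if not sd > 0:
        raise DegenerateMeasureError("composite has zero spread over the cohort")
    return (avg - float(avg.mean(skipna=True))) / sd


def pacc5(table: pd.DataFrame, ref: ZReference | None = None) -> pd.Series:
    """Sum (not mean) of the z-scores of the five cognitive measures."""
    _require_columns(table, PACC5_TESTS)
    if ref is None:
        ref = ZReference.from_cohort(table, PACC5_TESTS)
    return sum(ref.z(table, name) for name in PACC5_TESTS)


def occupation_score(history: LifestyleHistory) -> float:
    """Sum over jobs of cognitive load x weekly hours x years."""
    return float(
        sum(e.cognitive_load * e.hours_per_week * e.years for e in history.occupation_episodes)
    )


def physical_activity_score(history: LifestyleHistory) -> float:
    """Average MET·h/week over the four life periods (empty periods count 0)."""
    per_period = dict.fromkeys((1, 2, 3, 4), 0.0)
    for e in history.sport_episodes:
        per_period[e.life_period] += e.met * e.hours_per_week
    return float(sum(per_period.values()) / 4.0)


def leisure_score(history: LifestyleHistory) -> float:
    """Mean over the 9 leisure activities of sum(f x t x p) per activity.

    f = events per interval, t = intervals per year, p = years practiced;
    an activity never practiced contributes 0.
    """
    if len(history.leisure_activities) != 9:
        raise SchemaError("a leisure history must have exactly 9 activity slots")
    totals = [
        sum(b.frequency * b.interval * b.period_years for b in blocks)
        for blocks in history.leisure_activities
    ]
    return float(sum(totals) / 9.0)


def cognitive_reserve(
    table: pd.DataFrame, ref: ZReference | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Global reserve z-score plus each sub-score's z (for sub-factor models).

    Sub-scores: education years, fNART total, occupation score, physical
    activity (MET/week), leisure score — all entering positively.
    """
    _require_columns(table, CR_SUBSCORES)
    if ref is None:
        ref = ZReference.from_cohort(table, CR_SUBSCORES)
    subs = pd.DataFrame({name: ref.z(table, name) for name in CR_SUBSCORES})
    return zscore_composite(table, CR_SUBSCORES, ref=ref), subs


def _check_ranges(table: pd.DataFrame, measures: Sequence[str]) -> None:
    for name in measures:
        lo, hi = QUESTIONNAIRE_RANGES[name]
        col = table[name].dropna()
        if ((col < lo) | (col > hi)).any():
            raise DomainError(f"{name!r} scores must lie in [{lo}, {hi}]")


def affective_state(table: pd.DataFrame, ref: ZReference | None = None) -> pd.Series:
    """Composite of BDI and BAI; higher = worse affective state."""
    _require_columns(table, ("bdi", "bai"))
    _check_ranges(table, ("bdi", "bai"))
    return zscore_composite(table, ("bdi", "bai"), ref=ref)


def creatinine_correct(urine_value, serum_creatinine):
    """Divide a 24-h urinary excretion by serum creatinine (lean-mass
    adjustment). Scale-invariant: doubling both leaves the ratio unchanged."""
    serum = np.asarray(serum_creatinine, dtype=float)
    if np.any(serum <= 0):
        raise DomainError("serum creatinine must be positive")
    return np.asarray(urine_value, dtype=float) / serum


def _intervals(rr) -> np.ndarray:
    arr = rr.intervals if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 RR intervals")
    return arr


def rmssd(rr) -> float:
    """Root mean square of successive RR-interval differences (ms)."""
    arr = _intervals(rr)
    return float(np.sqrt(np.mean(np.diff(arr) ** 2)))


def sdnn(rr) -> float:
    """SD (n-1) of the beat-to-beat intervals (ms)."""
    return float(np.std(_intervals(rr), ddof=1))


def sdann(rr, segment_minutes: float = 5.0) -> float:
    """SD of per-segment mean intervals (ms), 5-min segments by default.

    On a recording shorter than two segments this degenerates to the SD of
    the beat intervals themselves (SDNN), which is what a single 5-min rest
    recording yields.
    """
    arr = _intervals(rr)
    if segment_minutes <= 0:
        raise DomainError("segment_minutes must be positive")
    seg = (np.cumsum(arr) - arr) // (segment_minutes * 60_000.0)
    n_segments = int(seg[-1]) + 1
    if n_segments < 2:
        return sdnn(arr)
    means = np.array([arr[seg == k].mean() for k in range(n_segments)])
    return float(np.std(means, ddof=1))


def allostatic_load(
    table: pd.DataFrame, ref: ZReference | None = None, strict: bool = False
) -> tuple[pd.Series, pd.DataFrame]:
    """Seven subdomain z-scores and the global allostatic-load z-score.

    Urinary analytes are creatinine-corrected first. With ``strict=True`` a
    NaN constituent raises, naming participant and measure; otherwise NaN
    rows propagate for listwise handling downstream.
    """
    raw_needed = sorted(
        {m for d in AL_DOMAINS.values() for m in d if not m.endswith("_corrected")}
        | set(_CREATININE_CORRECTED)
        | {"serum_creatinine"}
    )
    _require_columns(table, raw_needed)
    work = table.copy()
    for name in _CREATININE_CORRECTED:
        work[f"{name}_corrected"] = creatinine_correct(work[name], work["serum_creatinine"])

    if strict:
        members = sorted({m for d in AL_DOMAINS.values() for m in d})
        for name in members:
            na = work.index[work[name].isna()]
            if len(na):
                pid = work["pid"].loc[na[0]] if "pid" in work.columns else na[0]
                raise MissingDataError(f"participant {pid}: missing measure {name!r}")

    subs = pd.DataFrame(
        {
            domain: zscore_composite(work, list(members), signs=members, ref=ref)
            for domain, members in AL_DOMAINS.items()
        }
    )
    global_score = zscore_composite(subs, list(AL_DOMAINS))
    return global_score, subs


def sleep_quality(table: pd.DataFrame, ref: ZReference | None = None) -> pd.Series:
    """Composite of IV, PSQI and ESS; higher = worse sleep-wake quality."""
    _require_columns(table, ("iv", "psqi", "ess"))
    _check_ranges(table, ("psqi", "ess"))
    return zscore_composite(table, ("iv", "psqi", "ess"), ref=ref)


def score_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Compute every composite for a raw cohort table.

    Returns the table augmented with ``pacc5``, ``cr_global``,
    ``affective_global``, the seven ``al_*`` subdomain scores, ``al_global``
    and ``sleep_global``, plus a provenance manifest (signs, reference
    source, aggregation conventions).
    """
    out = table.copy()
    out["pacc5"] = pacc5(out)
    cr_global, _ = cognitive_reserve(out)
    out["cr_global"] = cr_global
    out["affective_global"] = affective_state(out)
    al_global, al_subs = allostatic_load(out)
    for domain in AL_DOMAINS:
        out[domain] = al_subs[domain]
    out["al_global"] = al_global
    out["sleep_global"] = sleep_quality(out)
    manifest = {
        "reference": "cohort-estimated (sample SD, n-1)",
        "pacc5": {"measures": list(PACC5_TESTS), "aggregation": "sum of z-scores"},
        "cr_global": {"measures": list(CR_SUBSCORES), "signs": "all +1"},
        "affective_global": {"measures": ["bdi", "bai"], "signs": "all +1"},
        "al_global": {
            "subdomains": {k: dict(v) for k, v in AL_DOMAINS.items()},
            "creatinine_corrected": list(_CREATININE_CORRECTED),
        },
        "sleep_global": {"measures": ["iv", "psqi", "ess"], "signs": "all +1"},
    }
    return out, manifest
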