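"""Synthetic cohorts with the statistical structure the analysis assumes.

No participant-level data were deposited with the source study, so every
pipeline stage is exercised against simulated cohorts built here. The
generative model is a latent-trait Gaussian copula:

* four independent standard-normal traits per participant — true cognitive
  reserve, true allostatic load, affective disposition and sleep-wake
  fragility — plus a standard-normal age latent and a 0/1 sex code
  (0 = female, 1 = male);
* latent cognition ``C = b_cr·CR + b_al·AL + b_sex·sex + b_age·z_age + e``
  with residual SD ``noise_sd``;
* every raw measure is a monotone quantile map of
  ``loading·trait + sqrt(1 - loading²)·noise`` onto the published bounded
  marginal for that measure (see :mod:`cogload.marginals`), so cohort-level
  means/SDs/ranges match the published descriptive tables while the injected
  effects stay recoverable by the inference stage.

Loadings are deliberately high (tests 0.90, reserve sub-scores 0.85,
physiology 0.70, affective 0.75, sleep 0.60): the composites are then
near-faithful proxies of the latent traits, which is what parameter-recovery
checks require. Real biomarker panels are noisier; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._errors import DomainError, SchemaError
from .actigraphy import ActigraphyRecord
from .config import CohortConfig
from .marginals import solve_marginal

__all__ = [
    "OccupationEpisode",
    "SportEpisode",
    "LeisureBlock",
    "LifestyleHistory",
    "RRSeries",
    "LOADINGS",
    "PACC5_TESTS",
    "CR_SUBSCORES",
    "AL_PROTECTIVE",
    "generate_cohort",
    "generate_actigraphy",
    "generate_rr_series",
]

PACC5_TESTS = ("fcsrt", "logical_memory", "dsst", "fluency", "mattis")
CR_SUBSCORES = ("education", "fnart", "occupation", "sport", "leisure")
AL_MEASURES = (
    "sbp", "heart_rate", "pulse_pressure",
    "sdann", "rmssd",
    "bmi", "whr", "ldl", "hdl", "triglycerides",
    "hba1c", "glucose",
    "crp", "il6",
    "dheas", "cortisol",
    "adrenaline", "noradrenaline",
)
# raw measures for which higher values mean *lower* physiological load
AL_PROTECTIVE = frozenset({"hdl", "dheas", "sdann", "rmssd"})

AFFECTIVE_MEASURES = ("bdi", "bai")
SLEEP_MEASURES = ("iv", "psqi", "ess")

LOADINGS = {
    "test": 0.90,       # PACC5 tests on latent cognition
    "cr": 0.85,         # reserve sub-scores on true reserve
    "al": 0.70,         # physiological constituents on true load
    "affective": 0.75,  # BDI/BAI on the affective trait
    "sleep": 0.60,      # IV/PSQI/ESS on the sleep trait
}


@dataclass(frozen=True)
class OccupationEpisode:
    """One job: ordinal cognitive load (1-9), weekly hours, years held."""

    cognitive_load: int
    hours_per_week: float
    years: float

    def __post_init__(self) -> None:
        if not 1 <= self.cognitive_load <= 9:
            raise DomainError(f"cognitive_load must be in 1..9, got {self.cognitive_load}")
        if self.hours_per_week < 0 or self.years < 0:
            raise DomainError("occupation hours and years must be non-negative")


@dataclass(frozen=True)
class SportEpisode:
    """One regular physical activity within one of the four life periods."""

    met: float
    hours_per_week: float
    life_period: int

    def __post_init__(self) -> None:
        if self.life_period not in (1, 2, 3, 4):
            raise DomainError(f"life_period must be in 1..4, got {self.life_period}")
        if self.met < 0 or self.hours_per_week < 0:
            raise DomainError("MET and hours must be non-negative")


@dataclass(frozen=True)
class LeisureBlock:
    """One practice block of a leisure activity: f events per interval,
    t intervals per year, over p years."""

    frequency: float
    interval: float
    period_years: float

    def __post_init__(self) -> None:
        if min(self.frequency, self.interval, self.period_years) < 0:
            raise DomainError("leisure frequency/interval/years must be non-negative")


@dataclass(frozen=True)
class LifestyleHistory:
    """Episode-level lifestyle questionnaire record for one participant."""

    occupation_episodes: tuple[OccupationEpisode, ...] = ()
    sport_episodes: tuple[SportEpisode, ...] = ()
    leisure_activities: tuple[tuple[LeisureBlock, ...], ...] = field(
        default_factory=lambda: tuple(() for _ in range(9))
    )

    def __post_init__(self) -> None:
        if len(self.leisure_activities) != 9:
            raise SchemaError(
                f"exactly 9 leisure activity slots required, got {len(self.leisure_activities)}"
            )


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat interval series in milliseconds."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        if arr.size < 2:
            raise DomainError("an RR series needs at least 2 intervals")
        if np.any(arr <= 0):
            raise DomainError("RR intervals must be positive")


def _measure_latent(rng: np.random.Generator, trait: np.ndarray, loading: float) -> np.ndarray:
    return loading * trait + np.sqrt(1.0 - loading**2) * rng.standard_normal(trait.size)


def generate_cohort(
    config: CohortConfig, with_histories: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, list[LifestyleHistory]]:
    """Generate one participant-level cohort table.

    Returns a DataFrame with one row per participant holding every raw
    measure the scoring stage consumes. With ``with_histories=True`` also
    returns episode-level :class:`LifestyleHistory` objects whose
    occupation / physical-activity / leisure scores reproduce the table's
    score columns exactly.
    """
    n = config.n_participants
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    marginals = config.resolved_marginals()
    maps = {name: solve_marginal(m) for name, m in marginals.items()}

    # sex: fixed female share, randomly assigned
    n_male = int(round((1.0 - config.prop_female) * n))
    sex = np.zeros(n)
    sex[:n_male] = 1.0
    rng.shuffle(sex)
    p_male = n_male / n

    z_age = rng.standard_normal(n)
    cr_true = rng.standard_normal(n)
    al_true = rng.standard_normal(n)
    aff_true = rng.standard_normal(n)
    slp_true = rng.standard_normal(n)

    cognition = (
        config.effect_cr * cr_true
        + config.effect_al * al_true
        + config.effect_sex * sex
        + config.effect_age * z_age
        + config.noise_sd * rng.standard_normal(n)
    )
    var_c = (
        config.effect_cr**2
        + config.effect_al**2
        + config.effect_sex**2 * p_male * (1.0 - p_male)
        + config.effect_age**2
        + config.noise_sd**2
    )
    cognition_z = (cognition - config.effect_sex * p_male) / np.sqrt(var_c)

    table: dict[str, np.ndarray] = {
        "pid": np.arange(1, n + 1),
        "sex": sex.astype(int),
        "age": maps["age"].transform(z_age),
    }
    for name in PACC5_TESTS:
        table[name] = maps[name].transform(
            _measure_latent(rng, cognition_z, LOADINGS["test"])
        )
    for name in CR_SUBSCORES:
        table[name] = maps[name].transform(_measure_latent(rng, cr_true, LOADINGS["cr"]))
    for name in AL_MEASURES:
        direction = -1.0 if name in AL_PROTECTIVE else 1.0
        table[name] = maps[name].transform(
            _measure_latent(rng, direction * al_true, LOADINGS["al"])
        )
    for name in AFFECTIVE_MEASURES:
        table[name] = maps[name].transform(
            _measure_latent(rng, aff_true, LOADINGS["affective"])
        )
    for name in SLEEP_MEASURES:
        table[name] = maps[name].transform(_measure_latent(rng, slp_true, LOADINGS["sleep"]))
    table["serum_creatinine"] = maps["serum_creatinine"].transform(rng.standard_normal(n))

    df = pd.DataFrame(table)
    if not with_histories:
        return df

    histories = [
        _history_for_scores(
            rng,
            occupation=float(df["occupation"].iat[i]),
            sport=float(df["sport"].iat[i]),
            leisure=float(df["leisure"].iat[i]),
        )
        for i in range(n)
    ]
    return df, histories


def _history_for_scores(
    rng: np.random.Generator, occupation: float, sport: float, leisure: float
) -> LifestyleHistory:
    """Build an episode-level history whose three lifestyle scores equal the
    given targets exactly (splits across episodes are randomised)."""
    occ_eps: list[OccupationEpisode] = []
    if occupation > 0:
        k = int(rng.integers(1, 4))
        weights = rng.dirichlet(np.ones(k))
        for w in weights:
            c = int(rng.integers(1, 10))
            h = float(rng.uniform(10.0, 45.0))
            occ_eps.append(OccupationEpisode(c, h, w * occupation / (c * h)))

    sport_eps: list[SportEpisode] = []
    if sport > 0:
        weights = rng.dirichlet(np.ones(4))
        for period, w in enumerate(weights, start=1):
            met = float(rng.uniform(3.0, 9.0))
            # per-period MET·h/week totals average to the target over 4 periods
            sport_eps.append(SportEpisode(met, 4.0 * w * sport / met, period))

    slots: list[tuple[LeisureBlock, ...]] = []
    if leisure > 0:
        weights = rng.dirichlet(np.ones(9))
        active = rng.random(9) >= 0.15
        if not active.any():
            active[int(rng.integers(9))] = True
        weights = weights * active
        weights = weights / weights.sum()
        for w in weights:
            if w == 0:
                slots.append(())
                continue
            freq = float(rng.integers(1, 4))
            interval = float(rng.choice([365.0, 52.0, 12.0]))
            slots.append((LeisureBlock(freq, interval, 9.0 * w * leisure / (freq * interval)),))
    else:
        slots = [() for _ in range(9)]

    return LifestyleHistory(tuple(occ_eps), tuple(sport_eps), tuple(slots))


def generate_actigraphy(days: int, fragmentation: float, seed: int) -> ActigraphyRecord:
    """Simulate a minute-epoch activity-count record.

    A two-state (rest/active) minute-level Markov process is modulated by a
    24-h sinusoidal drive (day preference roughly 07:00-19:00); the
    ``fragmentation`` parameter in [0, 1] adds to both state-switch hazards,
    so higher fragmentation produces a more broken rest-activity cycle and a
    higher intradaily variability in expectation. ``fragmentation = 0`` is
    the deterministic limit: strictly alternating 12-h rest/active blocks
    (rest minutes emit count 1, keeping every epoch observed).
    """
    if days < 1:
        raise DomainError(f"days must be >= 1, got {days}")
    if not 0.0 <= fragmentation <= 1.0:
        raise DomainError(f"fragmentation must be in [0, 1], got {fragmentation}")

    n = int(days) * 1440
    minutes = np.arange(n)
    if fragmentation == 0.0:
        active = (minutes // 720) % 2 == 1
        counts = np.where(active, 10, 1)
        return ActigraphyRecord(counts=counts.astype(float), valid=np.ones(n, dtype=bool))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAC71]))
    mod = minutes % 1440
    day_drive = 0.5 - 0.5 * np.cos(2.0 * np.pi * (mod - 780) / 1440.0)
    preferred_active = day_drive > 0.5
    switch_add = 0.35 * fragmentation
    u = rng.random(n)

    active = np.empty(n, dtype=bool)
    state = bool(preferred_active[0])
    pref = preferred_active
    for t in range(n):
        base = 0.004 if state == pref[t] else 0.09
        if u[t] < min(base + switch_add, 0.95):
            state = not state
        active[t] = state

    counts = np.zeros(n)
    lam = 10.0 + 30.0 * day_drive
    act_idx = np.flatnonzero(active)
    counts[act_idx] = rng.poisson(lam[act_idx])
    rest_idx = np.flatnonzero(~active)
    waking = rng.random(rest_idx.size) < 0.08
    counts[rest_idx[waking]] = rng.poisson(2.0, waking.sum()) + 1.0
    return ActigraphyRecord(counts=counts, valid=np.ones(n, dtype=bool))


def generate_rr_series(
    mean_rr: float,
    short_term_sd: float,
    n_beats: int,
    seed: int,
    autocorr: float = 0.9,
) -> RRSeries:
    """Simulate an autocorrelated RR-interval series (AR(1), milliseconds).

    ``short_term_sd`` controls the successive-difference dispersion: the
    innovation SD is chosen so that the expected root-mean-square of
    successive differences equals ``short_term_sd``.
    """
    if mean_rr <= 0:
        raise DomainError(f"mean_rr must be positive, got {mean_rr}")
    if n_beats < 2:
        raise DomainError(f"n_beats must be >= 2, got {n_beats}")
    if short_term_sd < 0:
        raise DomainError("short_term_sd must be non-negative")
    if not 0.0 <= autocorr < 1.0:
        raise DomainError("autocorr must be in [0, 1)")

    if short_term_sd == 0.0:
        return RRSeries(np.full(n_beats, float(mean_rr)))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xECC]))
    # for AR(1): E[(x_{t+1}-x_t)^2] = 2 sigma_e^2 / (1 + phi)
    sigma_e = short_term_sd * np.sqrt((1.0 + autocorr) / 2.0)
    e = sigma_e * rng.standard_normal(n_beats)
    sigma_x = sigma_e / np.sqrt(1.0 - autocorr**2)
    x0 = sigma_x * rng.standard_normal()
    dev = lfilter([1.0], [1.0, -autocorr], e, zi=np.array([autocorr * x0]))[0]
    intervals = np.maximum(mean_rr + dev, 1.0)
    return RRSeries(intervals)
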