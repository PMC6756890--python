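"""Intradaily variability (IV) from minute-epoch actigraphy counts.

The fragmentation of the rest-activity cycle is quantified in four fixed
stages: (1) mask runs of zero counts longer than 120 min as invalid
(device-off proxy), (2) binarize each remaining epoch against an activity
threshold of 4 counts/min, (3) cluster the binary series into hours of
active-minute totals, dropping any hour containing a masked epoch, and
(4) compute

    IV = c1h / d1h,
    c1h = mean squared first difference of the hourly totals,
    d1h = population variance (denominator n) of the hourly totals.

IV is ~2 for an uncorrelated (white-noise) hourly series and 4 for a series
strictly alternating between its extremes; higher IV means a more fragmented
rest-activity cycle. Successive differences that would span a dropped hour
are excluded from c1h: only temporally adjacent retained hours form pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DegenerateInputError, DomainError, InsufficientDataError

__all__ = [
    "ActigraphyRecord",
    "HourlySeries",
    "IVResult",
    "mask_inactivity",
    "binarize",
    "hourly_totals",
    "intradaily_variability",
    "iv_from_record",
]

DEFAULT_THRESHOLD = 4.0  # counts/min at or above which an epoch is active
DEFAULT_MAX_GAP = 120  # min; zero-runs strictly longer than this are masked


@dataclass(frozen=True)
class ActigraphyRecord:
    """Minute-epoch activity counts with a per-epoch validity mask."""

    counts: np.ndarray
    valid: np.ndarray
    epoch_length: int = 1  # minutes
    start_time: object | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "valid", valid)
        if counts.shape != valid.shape:
            raise DomainError("counts and valid must have equal length")
        if counts.size and np.nanmin(counts) < 0:
            raise DomainError("activity counts must be non-negative")
        if self.epoch_length != 1:
            raise DomainError("only 1-min epochs are supported")

    def __len__(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class HourlySeries:
    """Active minutes per retained hour, with each hour's original position."""

    values: np.ndarray
    indices: np.ndarray  # hour positions in the original record (sorted)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        indices = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "indices", indices)
        if values.shape != indices.shape:
            raise DomainError("values and indices must have equal length")
        if values.size and (values.min() < 0 or values.max() > 60):
            raise DomainError("hourly active-minute totals must lie in [0, 60]")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class IVResult:
    iv: float
    c1h: float
    d1h: float
    n_hours: int
    n_pairs: int


def _zero_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def mask_inactivity(record: ActigraphyRecord, max_gap: int = DEFAULT_MAX_GAP) -> ActigraphyRecord:
    """Invalidate maximal runs of zero counts strictly longer than ``max_gap``.

    The boundary is strict ("exceeding"): a run of exactly ``max_gap``
    zero-count minutes is kept. All other epochs keep their validity.
    """
    if max_gap < 0:
        raise DomainError(f"max_gap must be non-negative, got {max_gap}")
    valid = record.valid.copy()
    for start, stop in _zero_runs(record.counts == 0):
        if stop - start > max_gap:
            valid[start:stop] = False
    return ActigraphyRecord(counts=record.counts, valid=valid, start_time=record.start_time)


def binarize(record: ActigraphyRecord, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Active (1.0) iff count >= threshold and the epoch is valid.

    Invalid epochs propagate as NaN so downstream hourly clustering can drop
    the hours they fall in.
    """
    if threshold < 0:
        raise DomainError(f"threshold must be non-negative, got {threshold}")
    out = np.where(record.counts >= threshold, 1.0, 0.0)
    out[~record.valid] = np.nan
    return out


def hourly_totals(binary: np.ndarray) -> HourlySeries:
    """Cluster a binary minute series into active-minutes-per-hour totals.

    Hours are aligned to the start of the recording; a trailing partial hour
    is discarded, and any hour containing a masked (NaN) epoch is dropped in
    its entirety while its position is recorded.
    """
    binary = np.asarray(binary, dtype=float)
    if binary.size < 60:
        raise InsufficientDataError(f"need at least 60 epochs, got {binary.size}")
    n_hours = binary.size // 60
    hours = binary[: n_hours * 60].reshape(n_hours, 60)
    keep = ~np.isnan(hours).any(axis=1)
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"fewer than 2 complete hours remain after masking ({int(keep.sum())})"
        )
    return HourlySeries(values=hours[keep].sum(axis=1), indices=np.flatnonzero(keep))


def intradaily_variability(hours: HourlySeries) -> IVResult:
    """IV = c1h / d1h on the retained hourly totals.

    ``d1h`` is the population variance (denominator n); ``c1h`` averages
    squared differences over temporally adjacent retained hour pairs
    (denominator n-1 on a gap-free series).
    """
    x = hours.values
    if hours.n < 2:
        raise InsufficientDataError("IV needs at least 2 hourly periods")
    d1h = float(((x - x.mean()) ** 2).mean())
    if d1h == 0.0:
        raise DegenerateInputError("constant hourly series: IV undefined (zero variance)")
    adjacent = np.diff(hours.indices) == 1
    n_pairs = int(adjacent.sum())
    if n_pairs == 0:
        raise InsufficientDataError("no adjacent hour pairs remain after masking")
    diffs = np.diff(x)[adjacent]
    c1h = float((diffs**2).sum() / n_pairs)
    return IVResult(iv=c1h / d1h, c1h=c1h, d1h=d1h, n_hours=hours.n, n_pairs=n_pairs)


def iv_from_record(
    record: ActigraphyRecord,
    threshold: float = DEFAULT_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
    apply_mask: bool = True,
) -> IVResult:
    """Full fixed-order pipeline: mask -> binarize -> hourly -> IV."""
    if apply_mask:
        record = mask_inactivity(record, max_gap=max_gap)
    return intradaily_variability(hourly_totals(binarize(record, threshold=threshold)))
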