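"""Time-series staging of per-part elasticity and composition.

Transition days are found by model selection, not hypothesis testing: for
every admissible ordered pair of interior changepoint days a continuous
three-segment piecewise-linear model is fitted by least squares, and the
pair with minimal SSE wins (lexicographically earliest pair on ties). A
changepoint day is the last day of its preceding segment; each segment must
contain at least 2 observation days. Nothing is tested, only fitted.

Recanalization is read off the composition series as the first day, at or
after a configurable window start, showing two consecutive increases
(one-day blips are ignored).

Heterogeneity is plain sample standard deviation (n-1 denominator):
*within* a thrombus across its three parts on one day, and *between*
animals for one day/part/quantity.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    CardinalityError,
    DuplicationError,
    SeriesGapError,
    SeriesLengthError,
    ValidationError,
    WindowError,
)
from .io_model import CompositionRecord, ElasticityRecord, Part
from .qpia import triplicate_mean

log = logging.getLogger(__name__)

MIN_SEGMENT_DAYS = 2
MIN_FIT_LENGTH = 6  # 3 segments x 2 days
DEFAULT_REVERSAL_WINDOW_START = 8

_QUANTITIES = ("ym_kpa", "rr", "rp", "rb")
_SSE_REL_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class DailySeries:
    """One value per observed day for a (part, quantity) pair.

    Missing days are simply absent; nothing is imputed. ``sds`` carries the
    across-animal sample SD per day when at least two animals contribute.
    """

    part: str  # head | body | tail | whole
    quantity: str  # ym_kpa | rr | rp | rb
    days: tuple[int, ...]
    values: tuple[float, ...]
    sds: tuple[float | None, ...] | None = None

    def __post_init__(self) -> None:
        if self.quantity.lower() not in _QUANTITIES:
            raise ValidationError(f"unknown quantity {self.quantity!r}")
        if len(self.days) != len(self.values):
            raise ValidationError("days and values must have equal length")
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise ValidationError("days must be strictly increasing")
        if not all(np.isfinite(v) for v in self.values):
            raise ValidationError("series values must be finite")
        if self.sds is not None and len(self.sds) != len(self.days):
            raise ValidationError("sds must align with days")

    def __len__(self) -> int:
        return len(self.days)

    def value_at(self, day: int) -> float:
        try:
            return self.values[self.days.index(day)]
        except ValueError as exc:
            raise KeyError(f"day {day} not in series") from exc


@dataclass(frozen=True)
class TransitionReport:
    """Fitted changepoint days, per-segment slopes and the fit residual."""

    changepoint_days: tuple[int, int]
    segment_slopes: tuple[float, float, float]
    sse: float

    def __post_init__(self) -> None:
        d1, d2 = self.changepoint_days
        if not d1 < d2:
            raise ValidationError("changepoint days must be strictly ordered")
        if self.sse < 0:
            raise ValidationError("sse must be non-negative")

    def to_report_dict(self) -> dict:
        return {
            "changepoint_days": list(self.changepoint_days),
            "segment_slopes": [float(s) for s in self.segment_slopes],
            "sse": float(self.sse),
        }


@dataclass(frozen=True)
class ReversalReport:
    """First sustained-increase day (recanalization signature), if any."""

    reversal_day: int | None

    def to_report_dict(self) -> dict:
        return {"reversal_day": self.reversal_day}


@dataclass(frozen=True)
class HeterogeneityReport:
    """Sample SDs within one thrombus (across parts) and between animals."""

    within_sd: float | None = None
    between_sd: float | None = None

    def to_report_dict(self) -> dict:
        return {"within_sd": self.within_sd, "between_sd": self.between_sd}


# ---------------------------------------------------------------------------
# series assembly
# ---------------------------------------------------------------------------


def build_series(
    records: Iterable[ElasticityRecord] | Iterable[CompositionRecord],
    part: Part | str,
    quantity: str = "ym_kpa",
    strict_replicates: bool = False,
) -> DailySeries:
    """Assemble one per-day series for a part from raw records.

    Elasticity replicates for each (animal, day) are collapsed via
    :func:`triplicate_mean` first; the day value is then the mean across
    animals, with the across-animal sample SD attached when >= 2 animals
    contribute. Conflicting duplicate (animal, day, replicate) rows raise.
    """
    part_val = part.value if isinstance(part, Part) else str(part).lower()
    quantity = quantity.lower()
    recs = list(records)
    if not recs:
        raise ValidationError("no records supplied")

    if isinstance(recs[0], ElasticityRecord):
        if quantity != "ym_kpa":
            raise ValidationError(
                f"elasticity records only provide ym_kpa, not {quantity!r}"
            )
        per_animal_day: dict[tuple[str, int], dict[int, float]] = {}
        for r in recs:
            if r.part.value != part_val:
                continue
            reps = per_animal_day.setdefault((r.animal_id, r.day), {})
            if r.replicate in reps and reps[r.replicate] != r.emean_kpa:
                raise DuplicationError(
                    f"conflicting duplicate row: animal {r.animal_id} day {r.day} "
                    f"part {part_val} replicate {r.replicate}"
                )
            reps[r.replicate] = r.emean_kpa
        if not per_animal_day:
            raise ValidationError(f"no records for part {part_val!r}")
        by_day: dict[int, list[float]] = {}
        for (animal, day), reps in sorted(per_animal_day.items()):
            vals = [reps[k] for k in sorted(reps)]
            if len(vals) != 3 and not strict_replicates:
                log.warning(
                    "animal %s day %d part %s: %d replicate(s), falling back to "
                    "mean of available",
                    animal,
                    day,
                    part_val,
                    len(vals),
                )
            by_day.setdefault(day, []).append(
                triplicate_mean(vals, strict=strict_replicates)
            )
    else:
        attr = {"rr": "rr", "rp": "rp", "rb": "rb"}.get(quantity)
        if attr is None:
            raise ValidationError(
                f"composition records provide rr/rp/rb, not {quantity!r}"
            )
        seen: dict[tuple[str, int], float] = {}
        by_day = {}
        for r in recs:
            part_r = r.part.value if isinstance(r.part, Part) else str(r.part).lower()
            if part_r != part_val:
                continue
            v = float(getattr(r.fractions, attr))
            key = (r.animal_id, r.day)
            if key in seen and seen[key] != v:
                raise DuplicationError(
                    f"conflicting duplicate row: animal {r.animal_id} day {r.day} "
                    f"part {part_val}"
                )
            if key in seen:
                continue
            seen[key] = v
            by_day.setdefault(r.day, []).append(v)
        if not by_day:
            raise ValidationError(f"no records for part {part_val!r}")

    days = tuple(sorted(by_day))
    values = tuple(statistics.fmean(by_day[d]) for d in days)
    sds = tuple(
        statistics.stdev(by_day[d]) if len(by_day[d]) >= 2 else None for d in days
    )
    return DailySeries(
        part=part_val,
        quantity=quantity,
        days=days,
        values=values,
        sds=None if all(s is None for s in sds) else sds,
    )


# ---------------------------------------------------------------------------
# changepoint detection
# ---------------------------------------------------------------------------


def candidate_changepoints(days: Sequence[int]) -> list[tuple[int, int]]:
    """All admissible (day1, day2) pairs: each of the three segments keeps
    at least MIN_SEGMENT_DAYS observation days."""
    days = list(days)
    n = len(days)
    m = MIN_SEGMENT_DAYS
    pairs = []
    # segment point counts: (i + 1), (j - i), (n - 1 - j); each >= m
    for i in range(m - 1, n - 2 * m):
        for j in range(i + m, n - m):
            pairs.append((days[i], days[j]))
    return pairs


def fit_three_segments(
    days: Sequence[int], values: Sequence[float], day1: int, day2: int
) -> tuple[float, tuple[float, float, float]]:
    """Continuous piecewise-linear least squares with knots at (day1, day2).

    Returns (sse, slopes). Basis: intercept, t, hinge(t - day1), hinge(t - day2).
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    X = np.column_stack(
        [
            np.ones_like(t),
            t,
            np.maximum(0.0, t - day1),
            np.maximum(0.0, t - day2),
        ]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    s1 = float(coef[1])
    s2 = s1 + float(coef[2])
    s3 = s2 + float(coef[3])
    return sse, (s1, s2, s3)


def detect_transitions(series: DailySeries) -> TransitionReport:
    """Exhaustive two-changepoint search minimizing SSE.

    Requires at least MIN_FIT_LENGTH consecutive days. Ties (within a tiny
    relative tolerance, so a perfectly linear series is handled
    deterministically) go to the lexicographically earliest pair.
    """
    if len(series) < MIN_FIT_LENGTH:
        raise SeriesLengthError(
            f"need >= {MIN_FIT_LENGTH} days for changepoint fitting, got {len(series)}"
        )
    gaps = [d2 - d1 for d1, d2 in zip(series.days, series.days[1:])]
    if any(g != 1 for g in gaps):
        raise SeriesGapError(f"days must be consecutive, got gaps {gaps}")

    results: dict[tuple[int, int], tuple[float, tuple[float, float, float]]] = {}
    for pair in candidate_changepoints(series.days):
        results[pair] = fit_three_segments(series.days, series.values, *pair)

    best_sse = min(sse for sse, _ in results.values())
    tol = _SSE_REL_TOL * (1.0 + best_sse)
    best_pair = min(p for p, (sse, _) in results.items() if sse <= best_sse + tol)
    sse, slopes = results[best_pair]
    return TransitionReport(changepoint_days=best_pair, segment_slopes=slopes, sse=sse)


# ---------------------------------------------------------------------------
# reversal (recanalization) detection
# ---------------------------------------------------------------------------


def detect_reversal(
    series: DailySeries, window_start: int = DEFAULT_REVERSAL_WINDOW_START
) -> ReversalReport:
    """First day d >= window_start with v(d) > v(d-1) and v(d+1) > v(d)."""
    lookup = dict(zip(series.days, series.values))
    if window_start - 1 < series.days[0] or window_start + 1 > series.days[-1]:
        raise WindowError(
            f"window start {window_start} (needing days {window_start - 1}.."
            f"{window_start + 1}) falls outside series days "
            f"{series.days[0]}..{series.days[-1]}"
        )
    for d in range(window_start, series.days[-1]):
        if d - 1 in lookup and d in lookup and d + 1 in lookup:
            if lookup[d] > lookup[d - 1] and lookup[d + 1] > lookup[d]:
                return ReversalReport(reversal_day=d)
    return ReversalReport(reversal_day=None)


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------


def within_thrombus_heterogeneity(head: float, body: float, tail: float) -> float:
    """Sample SD across the three parts of one thrombus on one day."""
    vals = (head, body, tail)
    if not all(np.isfinite(v) for v in vals):
        raise ValidationError(f"non-finite part value in {vals}")
    return statistics.stdev(vals)


def between_thrombus_heterogeneity(values: Sequence[float]) -> float:
    """Sample SD across animals for one day/part/quantity (needs >= 2)."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise CardinalityError(f"need >= 2 animals, got {len(vals)}")
    if not all(np.isfinite(v) for v in vals):
        raise ValidationError(f"non-finite value in {vals}")
    return statistics.stdev(vals)
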