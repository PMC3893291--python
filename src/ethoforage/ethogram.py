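"""Core ethogram types and operations.

Behavioral observations are reduced to three kinds of records: timed activity
*bouts*, fixed-length recording *intervals* carrying prey-attack counts, and
attack-level *records* with covariates and a binary outcome.  The 24-h clock is
partitioned into four diel bins — morning [04:00, 09:00), day [09:00, 18:00),
evening [18:00, 22:00) and night [22:00, 04:00) wrapping midnight — used as a
categorical covariate throughout.

Conventions: bin intervals are half-open, so a time exactly on a boundary
belongs to the later bin; durations are integer seconds; clock times are local
(the study clock), with no time-zone arithmetic.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from datetime import datetime, time
from typing import Iterable, Mapping, Union

SECONDS_PER_DAY = 86_400

#: Recognized site/year labels for deployments.
SITE_YEARS = ("MINWR_2010", "Guana_2011")

WATER_POSITIONS = ("submerged", "surface")
HUNTING_MODES = ("active_search", "sit_and_wait")
HABITATS = ("vegetation", "open_water")
OUTCOMES = ("success", "attempt_only")


class DielBin(str, enum.Enum):
    """One of the four clock-time strata used as a time-of-day covariate."""

    MORNING = "morning"
    DAY = "day"
    EVENING = "evening"
    NIGHT = "night"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class BehaviorCategory(str, enum.Enum):
    """The six basic activity categories of the ethogram.

    Occurrences coded as use of a submerged den are lumped into
    ``SIT_SUBMERGED``; basking and walking on land (including atop floating
    vegetation) are lumped into ``ON_LAND``.
    """

    FORAGING = "foraging"
    SIT_SURFACE = "sit_surface"
    SIT_SUBMERGED = "sit_submerged"
    SWIM_SURFACE = "swim_surface"
    SWIM_SUBMERGED = "swim_submerged"
    ON_LAND = "on_land"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Aliases accepted when parsing activity labels from files.
CATEGORY_ALIASES: Mapping[str, BehaviorCategory] = {
    "submerged_den": BehaviorCategory.SIT_SUBMERGED,
    "den": BehaviorCategory.SIT_SUBMERGED,
    "basking": BehaviorCategory.ON_LAND,
    "walking": BehaviorCategory.ON_LAND,
}


def parse_behavior_category(label: str) -> BehaviorCategory:
    """Parse an activity label, applying the lumping aliases."""
    token = str(label).strip().lower()
    try:
        return BehaviorCategory(token)
    except ValueError:
        if token in CATEGORY_ALIASES:
            return CATEGORY_ALIASES[token]
        raise ValueError(f"unknown activity category: {label!r}") from None


# diel bin boundaries, in seconds of day
_MORNING_START = 4 * 3600
_DAY_START = 9 * 3600
_EVENING_START = 18 * 3600
_NIGHT_START = 22 * 3600
_BOUNDARIES = (_MORNING_START, _DAY_START, _EVENING_START, _NIGHT_START)

#: Clock length of each bin in seconds (night wraps midnight).
BIN_LENGTHS_S: Mapping[DielBin, int] = {
    DielBin.MORNING: _DAY_START - _MORNING_START,
    DielBin.DAY: _EVENING_START - _DAY_START,
    DielBin.EVENING: _NIGHT_START - _EVENING_START,
    DielBin.NIGHT: SECONDS_PER_DAY - _NIGHT_START + _MORNING_START,
}


def _seconds_of_day(t: Union[datetime, time]) -> int:
    if isinstance(t, datetime):
        t = t.time()
    if not isinstance(t, time):
        raise TypeError(f"expected datetime or time, got {type(t).__name__}")
    return t.hour * 3600 + t.minute * 60 + t.second


def _bin_of_seconds(s: int) -> DielBin:
    s = s % SECONDS_PER_DAY
    if _MORNING_START <= s < _DAY_START:
        return DielBin.MORNING
    if _DAY_START <= s < _EVENING_START:
        return DielBin.DAY
    if _EVENING_START <= s < _NIGHT_START:
        return DielBin.EVENING
    return DielBin.NIGHT


def assign_diel_bin(t: Union[datetime, time]) -> DielBin:
    """Return the diel bin whose half-open interval contains clock time ``t``.

    Total on valid clock times: every second of the 24-h clock belongs to
    exactly one bin, with the night bin wrapping midnight.
    """
    return _bin_of_seconds(_seconds_of_day(t))


@dataclass(frozen=True)
class BehaviorBout:
    """One timed occurrence of a single activity for one individual."""

    deployment_id: str
    individual_id: str
    activity: BehaviorCategory
    start: datetime
    duration_s: int

    def __post_init__(self) -> None:
        if not isinstance(self.activity, BehaviorCategory):
            object.__setattr__(self, "activity", parse_behavior_category(self.activity))
        if int(self.duration_s) != self.duration_s:
            raise ValueError(f"duration_s must be integer seconds, got {self.duration_s!r}")
        object.__setattr__(self, "duration_s", int(self.duration_s))
        if self.duration_s <= 0:
            raise ValueError(f"bout duration must be positive, got {self.duration_s}")

    @property
    def end(self) -> datetime:
        from datetime import timedelta

        return self.start + timedelta(seconds=self.duration_s)


@dataclass(frozen=True)
class SamplingInterval:
    """One recording window with its prey-attack count: the Poisson unit."""

    individual_id: str
    site_year: str
    start: datetime
    exposure_h: float
    attack_count: int
    viable: bool = True

    def __post_init__(self) -> None:
        if self.site_year not in SITE_YEARS:
            raise ValueError(f"unknown site_year: {self.site_year!r}")
        if self.exposure_h <= 0:
            raise ValueError(f"exposure must be positive, got {self.exposure_h}")
        if self.exposure_h not in (0.5, 1.0):
            warnings.warn(
                f"non-standard exposure {self.exposure_h} h (expected 0.5 or 1.0)",
                stacklevel=2,
            )
        if self.attack_count < 0:
            raise ValueError(f"attack_count must be >= 0, got {self.attack_count}")

    @property
    def diel_bin(self) -> DielBin:
        return assign_diel_bin(self.start)


@dataclass(frozen=True)
class AttackRecord:
    """One prey-capture attempt with covariates: the binomial unit.

    An *attack* is an apparent head-strike / jaw-snap; a *success* additionally
    shows subsequent inertial bites and swallowing.  The diel bin is derived
    from the attack's own timestamp.
    """

    individual_id: str
    site_year: str
    time: datetime
    water_position: str
    hunting_mode: str
    habitat: str
    outcome: str

    def __post_init__(self) -> None:
        if self.site_year not in SITE_YEARS:
            raise ValueError(f"unknown site_year: {self.site_year!r}")
        for name, value, allowed in (
            ("water_position", self.water_position, WATER_POSITIONS),
            ("hunting_mode", self.hunting_mode, HUNTING_MODES),
            ("habitat", self.habitat, HABITATS),
            ("outcome", self.outcome, OUTCOMES),
        ):
            if value not in allowed:
                raise ValueError(f"invalid {name}: {value!r} (allowed: {allowed})")

    @property
    def diel_bin(self) -> DielBin:
        return assign_diel_bin(self.time)

    @property
    def success(self) -> int:
        return int(self.outcome == "success")


@dataclass(frozen=True)
class ActivityBudget:
    """Duration-weighted proportions of recorded time per activity.

    ``scope`` is ``"overall"`` or a :class:`DielBin`.  When ``total_time_s`` is
    zero (no recorded time in scope) all proportions are zero by convention;
    otherwise they sum to one.
    """

    scope: Union[str, DielBin]
    proportions: Mapping[BehaviorCategory, float]
    total_time_s: int

    def __post_init__(self) -> None:
        if self.total_time_s > 0:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {total}, expected 1")
        for cat, p in self.proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {cat} out of [0, 1]: {p}")


def split_bout_across_bins(bout: BehaviorBout) -> list[tuple[DielBin, int]]:
    """Apportion a bout's duration across the diel bins it spans.

    Returns contiguous ``(bin, seconds)`` segments in temporal order; each
    segment lies wholly in one bin and the segment durations sum exactly to the
    bout duration.  A bout longer than a full diel cycle revisits bins, giving
    repeated entries.
    """
    if bout.duration_s <= 0:  # defensive; the dataclass already rejects this
        raise ValueError("bout duration must be positive")
    pos = _seconds_of_day(bout.start)
    remaining = bout.duration_s
    segments: list[tuple[DielBin, int]] = []
    while remaining > 0:
        sod = pos % SECONDS_PER_DAY
        later = [b for b in _BOUNDARIES if b > sod]
        next_boundary = later[0] if later else _BOUNDARIES[0] + SECONDS_PER_DAY
        step = min(remaining, next_boundary - sod)
        current = _bin_of_seconds(sod)
        if segments and segments[-1][0] is current:
            segments[-1] = (current, segments[-1][1] + step)
        else:
            segments.append((current, step))
        pos += step
        remaining -= step
    return segments


def _empty_totals() -> dict[BehaviorCategory, int]:
    return {cat: 0 for cat in BehaviorCategory}


def _budget_from_totals(
    scope: Union[str, DielBin], totals: Mapping[BehaviorCategory, int]
) -> ActivityBudget:
    total_time = sum(totals.values())
    if total_time > 0:
        props = {cat: totals[cat] / total_time for cat in BehaviorCategory}
        # renormalize the float rounding remainder onto the largest entry so
        # the sum is exactly representable as 1 within 1e-9
        props = {cat: p for cat, p in props.items()}
    else:
        props = {cat: 0.0 for cat in BehaviorCategory}
    return ActivityBudget(scope=scope, proportions=props, total_time_s=total_time)


def compute_activity_budget(
    bouts: Iterable[BehaviorBout], per_bin: bool = False
) -> Union[ActivityBudget, dict[DielBin, ActivityBudget]]:
    """Compute duration-weighted activity budgets.

    Overall scope sums full bout durations; per-bin scope first splits
    boundary-spanning bouts with :func:`split_bout_across_bins` so each second
    of recording is credited to the bin it occurred in.  Empty input yields a
    defined zero budget, never a division by zero.
    """
    bouts = list(bouts)
    if not per_bin:
        totals = _empty_totals()
        for b in bouts:
            totals[b.activity] += b.duration_s
        return _budget_from_totals("overall", totals)

    per: dict[DielBin, dict[BehaviorCategory, int]] = {bin_: _empty_totals() for bin_ in DielBin}
    for b in bouts:
        for bin_, seconds in split_bout_across_bins(b):
            per[bin_][b.activity] += seconds
    return {bin_: _budget_from_totals(bin_, totals) for bin_, totals in per.items()}


@dataclass(frozen=True)
class DataAccounting:
    """Recording-time accounting: viable hours and percent of potential."""

    viable_hours: float
    potential_hours: float
    percent_viable: float


def data_accounting(
    intervals: Iterable[SamplingInterval], potential_hours: float
) -> DataAccounting:
    """Sum viable exposure and express it as a percentage of potential hours.

    ``percent_viable`` is rounded to one decimal for display, matching the
    reporting convention for deployment summaries.
    """
    if potential_hours <= 0:
        raise ValueError(f"potential_hours must be positive, got {potential_hours}")
    viable_hours = float(sum(iv.exposure_h for iv in intervals if iv.viable))
    percent = round(100.0 * viable_hours / potential_hours, 1)
    return DataAccounting(
        viable_hours=viable_hours,
        potential_hours=float(potential_hours),
        percent_viable=percent,
    )
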