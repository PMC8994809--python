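"""Scheduled beep grid for time-contingent EMA sampling.

EMA protocols deliver a fixed number of prompts ("beeps") per day at
roughly equal spacing.  All analyses in this package are anchored to the
*scheduled* grid: a slot exists for every prompt whether or not the
participant answered it.  Slot indices are 0-based and ranges half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

WEEKDAY_NAMES = (
    "monday",
    "tuesday",
    "wednesday",
    "thursday",
    "friday",
    "saturday",
    "sunday",
)

DAYS_PER_WEEK = 7


@dataclass(frozen=True)
class BeepGrid:
    """Calendar bookkeeping for a scheduled EMA beep grid.

    Parameters
    ----------
    days : int
        Length of the monitoring period in calendar days.
    beeps_per_day : int
        Number of scheduled prompts per day (default 5, a three-hourly
        daytime schedule).
    start_weekday : int
        Weekday of day 0; 0 = Monday ... 6 = Sunday.
    """

    days: int
    beeps_per_day: int = 5
    start_weekday: int = 0

    def __post_init__(self) -> None:
        if self.days < 1 or self.beeps_per_day < 1:
            raise ValueError("days and beeps_per_day must be positive")
        if not 0 <= self.start_weekday < 7:
            raise ValueError("start_weekday must be in 0..6")

    @property
    def n_slots(self) -> int:
        return self.days * self.beeps_per_day

    @property
    def n_weeks(self) -> int:
        """Number of complete monitoring weeks."""
        return self.days // DAYS_PER_WEEK

    def day_of(self, slot: int) -> int:
        return slot // self.beeps_per_day

    def slot_in_day(self, slot: int) -> int:
        return slot % self.beeps_per_day

    def weekday_of_day(self, day: int) -> int:
        return (self.start_weekday + day) % 7

    def weekday_of(self, slot: int) -> int:
        return self.weekday_of_day(self.day_of(slot))

    def is_weekend_day(self, day: int) -> bool:
        return self.weekday_of_day(day) >= 5

    def same_day(self, slot_a: int, slot_b: int) -> bool:
        """True when two slots fall on the same calendar day.

        Consecutive slots on different days form an *overnight* lag; the
        AR(1) estimator never pairs across such a boundary.
        """
        return self.day_of(slot_a) == self.day_of(slot_b)

    def week_start_slot(self, week: int) -> int:
        """First scheduled slot of a monitoring week (0-based)."""
        return week * DAYS_PER_WEEK * self.beeps_per_day

    def weekend_days_in(self, start_slot: int, end_slot: int) -> int:
        """Count calendar weekend days touched by the half-open slot range."""
        if end_slot <= start_slot:
            return 0
        first_day = self.day_of(start_slot)
        last_day = self.day_of(end_slot - 1)
        return sum(
            1 for d in range(first_day, last_day + 1) if self.is_weekend_day(d)
        )
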