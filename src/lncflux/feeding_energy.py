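"""Force-feeding schedule model and energy-intake arithmetic.

The high-intake group is force fed on a fixed schedule: meals grow linearly
by calendar day (``base_meal_g`` on day 1, plus ``daily_increment_g`` each
subsequent day) while the number of meals per day is piecewise constant over
contiguous phases. The control group eats a constant daily amount ad
libitum. Both groups eat the same diet, so the cumulative energy-intake
difference is (grams treated − grams control) × metabolizable energy
density.

The packaged default reproduces the published foie-gras-style 18-day
schedule: 130 g meals on day 1 growing by 5 g/day, 2 meals/day on days 1–3,
3 on days 4–6, 4 on days 7–17 and 3 on day 18, against a 325 g/day control
at 14.29 MJ/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_UP))


@dataclass(frozen=True)
class FeedingSchedule:
    """Phased force-feeding schedule with linearly growing meal size.

    ``phases`` is an ordered list of ``(day_start, day_end, meals_per_day)``
    with inclusive day bounds; phases must be contiguous from day 1.
    """

    phases: tuple[tuple[int, int, int], ...]
    base_meal_g: float
    daily_increment_g: float
    energy_density_mj_per_kg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(tuple(p) for p in self.phases))
        if self.base_meal_g < 0 or self.daily_increment_g < 0:
            raise ValueError("meal sizes must be non-negative")
        if self.energy_density_mj_per_kg < 0:
            raise ValueError("energy density must be non-negative")
        expected_start = 1
        for day_start, day_end, meals in self.phases:
            if day_start != expected_start:
                raise ValueError(
                    f"phases must be contiguous: expected day {expected_start}, "
                    f"got {day_start}"
                )
            if day_end < day_start or meals < 0:
                raise ValueError("invalid phase")
            expected_start = day_end + 1

    @property
    def n_days(self) -> int:
        return self.phases[-1][1] if self.phases else 0

    def meal_size(self, day: int) -> float:
        """Meal size in grams on a 1-based calendar day."""
        if day < 1:
            raise ValueError("day index starts at 1")
        return self.base_meal_g + self.daily_increment_g * (day - 1)

    def meals_on_day(self, day: int) -> int:
        for day_start, day_end, meals in self.phases:
            if day_start <= day <= day_end:
                return meals
        raise ValueError(f"day {day} outside schedule")


@dataclass(frozen=True)
class ControlIntake:
    """Constant ad-libitum intake of the control group."""

    daily_g: float
    days: int
    energy_density_mj_per_kg: float

    def __post_init__(self) -> None:
        if self.daily_g < 0 or self.days < 0 or self.energy_density_mj_per_kg < 0:
            raise ValueError("control intake quantities must be non-negative")

    @property
    def total_g(self) -> float:
        return self.daily_g * self.days


def published_schedule() -> FeedingSchedule:
    """The packaged default 18-day force-feeding schedule."""
    return FeedingSchedule(
        phases=((1, 3, 2), (4, 6, 3), (7, 17, 4), (18, 18, 3)),
        base_meal_g=130.0,
        daily_increment_g=5.0,
        energy_density_mj_per_kg=14.29,
    )


def published_control() -> ControlIntake:
    return ControlIntake(daily_g=325.0, days=18, energy_density_mj_per_kg=14.29)


def total_intake(schedule: FeedingSchedule) -> float:
    """Total grams force fed: closed form over phases.

    Each phase contributes ``meals × Σ meal_size(day)`` where the inner sum
    is an arithmetic series; ``total_intake_by_day`` is the day-loop oracle
    and both must agree exactly.
    """
    total = 0.0
    for day_start, day_end, meals in schedule.phases:
        n = day_end - day_start + 1
        first = schedule.meal_size(day_start)
        last = schedule.meal_size(day_end)
        total += meals * n * (first + last) / 2.0
    return total


def total_intake_by_day(schedule: FeedingSchedule) -> float:
    """Brute-force day loop; must agree exactly with the closed form."""
    return float(
        sum(
            schedule.meals_on_day(day) * schedule.meal_size(day)
            for day in range(1, schedule.n_days + 1)
        )
    )


def energy_difference(treated: FeedingSchedule, control: ControlIntake) -> float:
    """Cumulative energy-intake difference in MJ, rounded half-up to 2 dp.

    Signed: negative when the control group ate more energy.
    """
    treated_mj = total_intake(treated) / 1000.0 * treated.energy_density_mj_per_kg
    control_mj = control.total_g / 1000.0 * control.energy_density_mj_per_kg
    return _round_half_up(treated_mj - control_mj, 2)
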