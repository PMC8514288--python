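"""Analyzer acquisition conditions and per-m/z lap determination.

An acquisition condition is defined by a reference ion and its intended
lap count: the control software opens the ejection sector roughly half a
reference orbital period before the reference ion's arrival, so the
reference peak sits mid-window.  Every other m/z is then observed at
whatever lap it happens to be on when the sector opens — the smallest lap
number whose TOF is at or after the opening.  The observation window is
one reference orbital period wide, which is the unambiguous mass
bandwidth of the acquisition.

Measured open timings need not follow the half-period rule exactly, so an
explicit ejection-time override is first-class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .ion_optics import (
    InstrumentModel,
    IonSpecies,
    _mz,
    _velocity,
    orbital_period,
    time_of_flight,
)

__all__ = [
    "AnalyzerCondition",
    "make_condition",
    "lap_for_mz",
    "lap_range_for_mz_interval",
    "near_ejection_edge",
]


@dataclass(frozen=True)
class AnalyzerCondition:
    """Reference ion + lap count and the derived ejection timing (SI).

    ``reference_laps = 0`` is half-cycle mode: no closed orbit, no
    ejection timing, every ion at lap 0.
    """

    reference_ion: IonSpecies
    reference_laps: int
    ejection_open_time: float
    window_width: float

    def __post_init__(self) -> None:
        if self.reference_laps < 0:
            raise ValueError("reference lap count must be >= 0")
        if self.reference_laps > 0 and self.ejection_open_time <= 0:
            raise ValueError("ejection open time must be positive")

    @property
    def is_half_cycle(self) -> bool:
        return self.reference_laps == 0

    @property
    def label(self) -> str:
        if self.is_half_cycle:
            return "half-cycle"
        return f"{self.reference_ion.label}/{self.reference_laps} laps"


def make_condition(
    reference: IonSpecies,
    laps: int,
    model: InstrumentModel,
    ejection_open_time: float | None = None,
) -> AnalyzerCondition:
    """Build a condition for ``laps`` laps of ``reference``.

    By default the ejection sector opens half a reference orbital period
    before the reference TOF; pass ``ejection_open_time`` (seconds) to use
    a measured timing instead.  ``laps = 0`` builds a half-cycle condition
    whose window covers all arrivals.
    """
    if laps < 0:
        raise ValueError("lap count must be >= 0")
    period = orbital_period(reference, model)
    if laps == 0:
        return AnalyzerCondition(reference, 0, 0.0, math.inf)
    if ejection_open_time is None:
        ejection_open_time = time_of_flight(reference, laps, model) - period / 2
    return AnalyzerCondition(reference, laps, ejection_open_time, period)


def lap_for_mz(ion, condition: AnalyzerCondition,
               model: InstrumentModel) -> int:
    """Lap number at which ``ion`` (IonSpecies or m/z) is observed.

    First-arrival rule: the smallest n with TOF(n) >= ejection open time.
    Heavier ions complete fewer laps by any fixed opening time.
    """
    if condition.is_half_cycle:
        return 0
    g, cal = model.geometry, model.calibration
    v = _velocity(ion, model)
    # smallest n with t0 + (L_k + n L_c)/v >= open
    x = ((condition.ejection_open_time - cal.time_delay) * v
         - g.half_cycle_length) / g.orbit_length
    return max(int(math.ceil(x - 1e-12)), 0)


def lap_range_for_mz_interval(
    mz_min: float,
    mz_max: float,
    condition: AnalyzerCondition,
    model: InstrumentModel,
) -> tuple[int, int]:
    """Inclusive lap-number range covering all m/z in [mz_min, mz_max].

    The lightest ion makes the most laps, so the range runs from
    lap_for_mz(mz_max) to lap_for_mz(mz_min).
    """
    if not (0 < mz_min <= mz_max):
        raise ValueError("need 0 < mz_min <= mz_max")
    return (lap_for_mz(mz_max, condition, model),
            lap_for_mz(mz_min, condition, model))


def near_ejection_edge(ion, condition: AnalyzerCondition,
                       model: InstrumentModel,
                       guard: float | None = None) -> bool:
    """Whether the ion arrives while the ejection sector is still opening.

    Ions whose TOF falls within the sector transit time (L_ed/v, or an
    explicit ``guard`` in seconds) of the opening cross a partially
    switched sector and their peaks are unreliable.
    """
    if condition.is_half_cycle:
        return False
    v = _velocity(ion, model)
    if guard is None:
        guard = model.geometry.ejection_to_detector_length / v
    n = lap_for_mz(ion, condition, model)
    t = time_of_flight(_mz(ion), n, model)
    return (t - condition.ejection_open_time) < guard
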