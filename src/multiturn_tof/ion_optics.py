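"""Closed-form ion optics of a figure-eight multi-turn TOF analyzer.

A multi-turn time-of-flight mass spectrometer injects ions onto a closed
figure-eight orbit of length ``L_c`` and ejects them onto the detector path
after ``n`` laps, so the total flight length is ``L_k + n*L_c`` where
``L_k`` (the half-cycle length) is the open source-to-detector path.  An
ion of mass-to-charge ratio ``m/z`` accelerated through ``V_acc`` volts
travels at

    v = sqrt(2 * z * e * V_acc / (m * K_amc))

and arrives at

    t = t0 + (L_k + n * L_c) / v

where ``t0`` is the instrumental time delay between the ion-push trigger
and true flight-time zero.  Inverting for ``m/z`` at an assumed lap number
gives the "apparent m/z" of a peak; only ions that actually flew that many
laps get their true mass back.  This module implements these closed forms
plus exact (electron-corrected) ion masses from chemical formulae.

Internal units are strictly SI (seconds, meters, volts); masses are kept
in unified atomic mass units (u) because the acceleration constant
``K = 2 e / K_amc`` absorbs the u-to-kg conversion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "InstrumentGeometry",
    "AnalyzerCalibration",
    "InstrumentModel",
    "IonSpecies",
    "FormulaError",
    "parse_formula",
    "exact_ion_mass",
    "ion_velocity",
    "time_of_flight",
    "mz_from_tof",
    "flight_length",
    "lap_number",
    "orbital_period",
]


# --------------------------------------------------------------------------
# constants and domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 values used throughout.

    ``elementary_charge`` in coulombs, ``atomic_mass_constant`` in kg,
    ``electron_mass`` in u.
    """

    elementary_charge: float = 1.602176634e-19
    atomic_mass_constant: float = 1.66053906660e-27
    electron_mass: float = 0.000548579909

    def __post_init__(self) -> None:
        if min(self.elementary_charge, self.atomic_mass_constant,
               self.electron_mass) <= 0:
            raise ValueError("physical constants must be strictly positive")

    @property
    def K(self) -> float:
        """Acceleration constant 2*e/K_amc, C/kg."""
        return 2.0 * self.elementary_charge / self.atomic_mass_constant


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class InstrumentGeometry:
    """Flight-path lengths in meters.

    ``half_cycle_length`` (L_k): open source-to-detector path.
    ``orbit_length`` (L_c): one figure-eight lap.
    ``ejection_to_detector_length`` (L_ed): ejection sector to detector,
    about a tenth of the orbit on this class of instrument.
    """

    half_cycle_length: float
    orbit_length: float
    ejection_to_detector_length: float = 0.063

    def __post_init__(self) -> None:
        if min(self.half_cycle_length, self.orbit_length,
               self.ejection_to_detector_length) <= 0:
            raise ValueError("geometry lengths must be strictly positive")
        if self.ejection_to_detector_length >= self.orbit_length:
            raise ValueError("L_ed must be shorter than the orbit length")
        ratio = self.ejection_to_detector_length / self.orbit_length
        if not (0.05 <= ratio <= 0.2):
            raise ValueError(
                f"L_ed/L_c = {ratio:.3f} outside the plausible ~1/10 range")


@dataclass(frozen=True)
class AnalyzerCalibration:
    """Acceleration voltage (V) and instrumental time delay (s)."""

    acceleration_voltage: float
    time_delay: float

    def __post_init__(self) -> None:
        if self.acceleration_voltage <= 0:
            raise ValueError("acceleration voltage must be positive")
        if self.time_delay < 0:
            raise ValueError("time delay must be non-negative")


@dataclass(frozen=True)
class InstrumentModel:
    """Geometry plus calibration: everything the TOF equation needs."""

    geometry: InstrumentGeometry
    calibration: AnalyzerCalibration
    constants: PhysicalConstants = field(default=CONSTANTS)


# --------------------------------------------------------------------------
# chemical formulae and exact ion masses
# --------------------------------------------------------------------------

# Monoisotopic masses (u) of the most abundant isotope, plus the minor
# isotopes addressable via bracket labels like [15N].
_MONOISOTOPIC: dict[str, float] = {
    "H": 1.00782503207,
    "He": 4.00260325413,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840316273,
    "Na": 22.9897692820,
    "Si": 27.9769265346,
    "P": 30.97376199842,
    "S": 31.9720711744,
    "Cl": 34.968852682,
    "Ar": 39.9623831237,
    "K": 38.9637064864,
    "Kr": 83.9114977282,
    "Xe": 131.9041550856,
}
_ISOTOPES: dict[str, float] = {
    "2H": 2.01410177812,
    "13C": 13.00335483507,
    "15N": 15.0001088989,
    "17O": 16.9991317565,
    "18O": 17.9991596129,
    "34S": 33.967867004,
}


class FormulaError(ValueError):
    """Raised when a chemical formula cannot be parsed."""


_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``formula`` into an {element-or-isotope: count} map.

    Isotope labels use brackets: ``"[15N]N"`` is one 15N and one 14N.
    Unknown symbols raise :class:`FormulaError` naming the token.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        if m.group(2):  # bracketed isotope
            key = m.group(1) + m.group(2)
            if key not in _ISOTOPES:
                raise FormulaError(f"unknown isotope [{key}]")
            n = int(m.group(3) or 1)
        else:
            key = m.group(4)
            if key not in _MONOISOTOPIC:
                raise FormulaError(f"unknown element {key!r}")
            n = int(m.group(5) or 1)
        counts[key] = counts.get(key, 0) + n
    if pos != len(formula):
        raise FormulaError(
            f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return counts


def exact_ion_mass(formula: str, charge: int = 1,
                   constants: PhysicalConstants = CONSTANTS) -> float:
    """Exact m/z (u) of the ion: monoisotopic neutral mass minus the mass
    of the removed electrons, divided by the charge state.

    Only positive charge states are supported (electron loss).
    """
    if charge < 1:
        raise ValueError("charge state must be a positive integer")
    counts = parse_formula(formula)
    neutral = 0.0
    for key, n in counts.items():
        neutral += n * (_ISOTOPES.get(key) or _MONOISOTOPIC[key])
    return (neutral - charge * constants.electron_mass) / charge


@dataclass(frozen=True)
class IonSpecies:
    """An ion identified by chemical formula and charge state.

    ``mz`` is the exact electron-corrected mass-to-charge ratio in u,
    computed from the formula unless given explicitly (which allows
    nominal-mass placeholders such as "an ion of m/z 600").
    """

    formula: str
    charge: int = 1
    mz: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge state must be >= 1")
        if self.mz == 0.0:
            object.__setattr__(self, "mz",
                               exact_ion_mass(self.formula, self.charge))
        if self.mz <= 0:
            raise ValueError("ion m/z must be positive")

    @property
    def label(self) -> str:
        return f"{self.formula}{'+' * self.charge}"


def _mz(ion) -> float:
    """Accept an IonSpecies or a bare m/z value in u."""
    return ion.mz if isinstance(ion, IonSpecies) else float(ion)


# --------------------------------------------------------------------------
# the TOF equation and its rearrangements
# --------------------------------------------------------------------------

def ion_velocity(m: float, z: int, V_acc: float,
                 constants: PhysicalConstants = CONSTANTS) -> float:
    """Ion speed (m/s) after acceleration: sqrt(2 z e V_acc / (m K_amc)).

    ``m`` in u; non-relativistic, valid for the keV energies used here.
    """
    if m <= 0 or V_acc <= 0:
        raise ValueError("mass and acceleration voltage must be positive")
    if z < 1:
        raise ValueError("charge state must be >= 1")
    return math.sqrt(z * constants.K * V_acc / m)


def _velocity(ion, model: InstrumentModel) -> float:
    # all closed forms below work on m/z, so z is folded in once here
    return ion_velocity(_mz(ion), 1,
                        model.calibration.acceleration_voltage,
                        model.constants)


def time_of_flight(ion, n: int, model: InstrumentModel) -> float:
    """TOF (s) of ``ion`` after ``n`` laps: t0 + (L_k + n*L_c)/v.

    ``n = 0`` is half-cycle mode (no closed orbit traversed).
    """
    if n < 0:
        raise ValueError("lap number must be >= 0")
    g, c = model.geometry, model.calibration
    path = g.half_cycle_length + n * g.orbit_length
    return c.time_delay + path / _velocity(ion, model)


def mz_from_tof(t: float, n: int, model: InstrumentModel) -> float:
    """m/z (u) implied by a peak at TOF ``t`` under an ``n``-lap hypothesis.

    This is the "apparent m/z" when ``n`` is only assumed: inverting the
    TOF equation, m/z = K * V_acc * ((t - t0) / (L_k + n*L_c))**2.
    """
    if n < 0:
        raise ValueError("lap number must be >= 0")
    g, c = model.geometry, model.calibration
    if t <= c.time_delay:
        raise ValueError(
            f"TOF {t:.4e} s not after the time delay {c.time_delay:.4e} s")
    path = g.half_cycle_length + n * g.orbit_length
    v = path / (t - c.time_delay)
    return model.constants.K * c.acceleration_voltage / v**2


def flight_length(ion, t: float, model: InstrumentModel) -> float:
    """Distance (m) an ion of known m/z has flown by time ``t``: v*(t-t0)."""
    c = model.calibration
    if t <= c.time_delay:
        raise ValueError("TOF must exceed the instrumental time delay")
    return _velocity(ion, model) * (t - c.time_delay)


def lap_number(ion, t: float, model: InstrumentModel,
               rounding: str = "nearest") -> int:
    """Lap count of an ion of known m/z observed at TOF ``t``.

    Computes x = (flight_length - L_k) / L_c and rounds it to an integer.
    ``rounding="nearest"`` (default) is appropriate for assigning a lap to
    an observed peak, where measurement error scatters x around an
    integer; ``"floor"`` counts completed laps of an ion still in flight.
    """
    g = model.geometry
    x = (flight_length(ion, t, model) - g.half_cycle_length) / g.orbit_length
    if x < -0.5:
        raise ValueError(
            "TOF precedes the half-cycle arrival of this m/z "
            f"(implied lap count {x:.2f})")
    if rounding == "nearest":
        n = round(x)
    elif rounding == "floor":
        n = math.floor(x)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return max(int(n), 0)


def orbital_period(ion, model: InstrumentModel) -> float:
    """Time (s) per lap, L_c/v — the unambiguous mass-window width."""
    return model.geometry.orbit_length / _velocity(ion, model)
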