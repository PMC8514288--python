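"""Estimation of instrument constants from multi-lap TOF observations.

The TOF equation t = t0 + (L_k + n*L_c)/v is linear in L_k (velocity
known) and, after the substitution x = (L_k + n*L_c)*sqrt(m*K_amc/(2 z e)),
linear in (1/sqrt(V_acc), t0).  Both calibration steps are therefore
ordinary linear least squares, and they are performed in the staged order
an operator calibrates the instrument: the half-cycle length first from
multi-lap TOFs of several ions, then the acceleration voltage and time
delay from multi-lap TOFs of a single reference ion.

``geometry_from_anchor_tofs`` solves the complementary problem: given
(V_acc, t0) and at least two (lap, TOF) anchors of one known ion, recover
both path lengths from the linear system L_k + n_i*L_c = v*(t_i - t0).
The package's default instrument model is built this way from published
multi-lap CO2+ arrival times, since the actual path lengths of the
instrument are not public.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ion_optics import (
    CONSTANTS,
    AnalyzerCalibration,
    InstrumentGeometry,
    InstrumentModel,
    IonSpecies,
    ion_velocity,
)

__all__ = [
    "CalibrationObservation",
    "fit_half_cycle_length",
    "fit_acceleration_and_delay",
    "geometry_from_anchor_tofs",
    "reanchor_half_cycle_length",
    "default_instrument_model",
    "read_observations_csv",
    "DEFAULT_ACCELERATION_VOLTAGE",
    "DEFAULT_TIME_DELAY",
    "CO2_ANCHORS_US",
]

#: Calibration constants and CO2+ (lap, TOF/us) anchors used to build the
#: default instrument model.
DEFAULT_ACCELERATION_VOLTAGE = 3893.22
DEFAULT_TIME_DELAY = 0.240e-6
CO2_ANCHORS_US: tuple[tuple[int, float], ...] = ((30, 156.0695), (50, 257.4951))


@dataclass(frozen=True)
class CalibrationObservation:
    """One measured multi-lap arrival: ion, lap count, observed TOF (s)."""

    ion: IonSpecies
    laps: int
    observed_tof: float

    def __post_init__(self) -> None:
        if self.laps < 0:
            raise ValueError("lap number must be >= 0")
        if self.observed_tof <= 0:
            raise ValueError("observed TOF must be positive")


def _check_design(laps: Sequence[int]) -> None:
    if len(laps) < 2 or len(set(laps)) < 2:
        raise ValueError(
            "calibration needs >= 2 observations at >= 2 distinct lap "
            f"numbers (got laps {sorted(set(laps))})")


def fit_half_cycle_length(
    observations: Sequence[CalibrationObservation],
    orbit_length: float,
    calibration: AnalyzerCalibration,
    weights: Sequence[float] | None = None,
) -> tuple[float, np.ndarray]:
    """Least-squares half-cycle length L_k given L_c and (V_acc, t0).

    Minimizes sum of squared TOF residuals
    (t_i - t0 - (L_k + n_i*L_c)/v_i)^2 over the single unknown L_k.
    Returns (L_k in meters, per-observation TOF residuals in seconds).
    """
    _check_design([o.laps for o in observations])
    v = np.array([ion_velocity(o.ion.mz, 1,
                               calibration.acceleration_voltage)
                  for o in observations])
    t = np.array([o.observed_tof for o in observations])
    n = np.array([o.laps for o in observations], dtype=float)
    # t - t0 - n*L_c/v = L_k/v  →  regress b on coefficient a = 1/v
    a = 1.0 / v
    b = t - calibration.time_delay - n * orbit_length / v
    w = np.ones_like(a) if weights is None else np.sqrt(np.asarray(weights, float))
    L_k = float(np.dot(w * a, w * b) / np.dot(w * a, w * a))
    residuals = b - L_k * a
    return L_k, residuals


def fit_acceleration_and_delay(
    observations: Sequence[CalibrationObservation],
    geometry: InstrumentGeometry,
    weights: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Least-squares (V_acc in volts, t0 in seconds) from multi-lap TOFs.

    With x_i = (L_k + n_i*L_c) * sqrt(m_i * K_amc / (2 z e)), the model is
    t_i = t0 + x_i / sqrt(V_acc): a straight line in x with slope
    1/sqrt(V_acc) and intercept t0.
    """
    _check_design([o.laps for o in observations])
    path = np.array([geometry.half_cycle_length + o.laps * geometry.orbit_length
                     for o in observations])
    x = path * np.sqrt(np.array([o.ion.mz for o in observations])
                       / CONSTANTS.K)
    t = np.array([o.observed_tof for o in observations])
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    slope, intercept = np.polyfit(x, t, 1, w=np.sqrt(w))
    if slope <= 0:
        raise ValueError("fit produced a non-physical acceleration voltage")
    return float(1.0 / slope**2), float(intercept)


def geometry_from_anchor_tofs(
    ion: IonSpecies,
    anchors: Sequence[tuple[int, float]],
    calibration: AnalyzerCalibration,
    ejection_to_detector_length: float = 0.063,
) -> InstrumentGeometry:
    """Recover (L_k, L_c) from >= 2 (lap, TOF-in-seconds) anchors of one ion.

    Solves L_k + n_i*L_c = v*(t_i - t0); least squares when
    over-determined.  Raises on rank deficiency (all anchors at one lap).
    """
    laps = [n for n, _ in anchors]
    _check_design(laps)
    v = ion_velocity(ion.mz, 1, calibration.acceleration_voltage)
    A = np.column_stack([np.ones(len(anchors)),
                         np.array(laps, dtype=float)])
    b = v * (np.array([t for _, t in anchors]) - calibration.time_delay)
    (L_k, L_c), *_ = np.linalg.lstsq(A, b, rcond=None)
    return InstrumentGeometry(
        half_cycle_length=float(L_k),
        orbit_length=float(L_c),
        ejection_to_detector_length=ejection_to_detector_length,
    )


def default_instrument_model() -> InstrumentModel:
    """The instrument model used throughout examples and defaults.

    Built from the published multi-lap CO2+ anchors (30 laps at
    156.0695 us, 50 laps at 257.4951 us) with V_acc = 3893.22 V and
    t0 = 0.240 us, giving L_k ~ 0.4824 m and L_c ~ 0.6627 m.
    """
    cal = AnalyzerCalibration(DEFAULT_ACCELERATION_VOLTAGE,
                              DEFAULT_TIME_DELAY)
    co2 = IonSpecies("CO2")
    anchors = [(n, t_us * 1e-6) for n, t_us in CO2_ANCHORS_US]
    geom = geometry_from_anchor_tofs(co2, anchors, cal)
    return InstrumentModel(geometry=geom, calibration=cal)


def reanchor_half_cycle_length(mz: float, lap: int, tof: float,
                               model: InstrumentModel) -> InstrumentModel:
    """Copy of ``model`` with L_k shifted so an ion of ``mz`` arrives at
    ``tof`` (seconds) after ``lap`` laps.

    Useful when a published arrival time must be reproduced exactly while
    keeping the orbit length and calibration: a single (lap, TOF) anchor
    determines the half-cycle length alone.
    """
    v = ion_velocity(mz, 1, model.calibration.acceleration_voltage)
    L_k = v * (tof - model.calibration.time_delay) \
        - lap * model.geometry.orbit_length
    geom = InstrumentGeometry(
        L_k, model.geometry.orbit_length,
        model.geometry.ejection_to_detector_length)
    return InstrumentModel(geometry=geom, calibration=model.calibration,
                           constants=model.constants)


def read_observations_csv(path) -> list[CalibrationObservation]:
    """Read observations from CSV with columns formula, charge, laps, tof_us."""
    df = pd.read_csv(path)
    required = {"formula", "laps", "tof_us"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        ion = IonSpecies(str(row["formula"]),
                         int(row.get("charge", 1) or 1))
        out.append(CalibrationObservation(ion, int(row["laps"]),
                                          float(row["tof_us"]) * 1e-6))
    return out
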