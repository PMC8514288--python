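"""Forward simulation of lap-superimposed and half-cycle peak lists.

Given an ion mixture and an analyzer condition, each ion arrives at its
first lap whose TOF falls after the ejection-sector opening; centroids
are placed exactly at the TOF-equation arrival times, optionally jittered
with seeded Gaussian noise (default sigma 1 ns, matching the 4-decimal
microsecond precision of real centroid lists) and optionally given
Poisson-fluctuated abundances.  Peaks outside the one-orbital-period
observation window are dropped.  The simulator reproduces the signature
phenomenon of closed-path analyzers — light ions overtaking heavy ones,
reordering the spectrum relative to the mass order seen in half-cycle
mode — and returns the ground truth (ion, lap, exact TOF) alongside the
peak list so assignment algorithms can be tested closed-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conditions import AnalyzerCondition, lap_for_mz
from .ion_optics import InstrumentModel, IonSpecies, time_of_flight
from .assignment import Peak

__all__ = ["SimulationSpec", "GroundTruthRow",
           "simulate_peak_list", "simulate_half_cycle"]


@dataclass(frozen=True)
class SimulationSpec:
    """Mixture, condition and noise settings for one simulated acquisition."""

    ions: Sequence[tuple[IonSpecies, float]]
    condition: AnalyzerCondition
    tof_jitter_sigma: float = 1e-9
    abundance_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tof_jitter_sigma < 0:
            raise ValueError("TOF jitter sigma must be >= 0")
        if any(ab < 0 for _, ab in self.ions):
            raise ValueError("abundances must be >= 0")


@dataclass(frozen=True)
class GroundTruthRow:
    ion: IonSpecies
    lap: int
    true_tof: float


def _emit(spec: SimulationSpec, model: InstrumentModel,
          condition: AnalyzerCondition) -> tuple[list[Peak], list[GroundTruthRow]]:
    rng = np.random.default_rng(spec.seed)
    events = []
    for ion, abundance in spec.ions:
        lap = lap_for_mz(ion, condition, model)
        t_true = time_of_flight(ion, lap, model)
        if not condition.is_half_cycle:
            if not (condition.ejection_open_time <= t_true
                    <= condition.ejection_open_time + condition.window_width):
                continue
        events.append((ion, abundance, lap, t_true))
    # draw noise in a fixed (input) order, then sort by arrival time
    peaks, truth = [], []
    for ion, abundance, lap, t_true in events:
        t = t_true + (rng.normal(0.0, spec.tof_jitter_sigma)
                      if spec.tof_jitter_sigma > 0 else 0.0)
        counts = float(rng.poisson(abundance)) if spec.abundance_noise \
            else float(abundance)
        peaks.append(Peak(tof=t, intensity=counts, label=ion.label))
        truth.append(GroundTruthRow(ion=ion, lap=lap, true_tof=t_true))
    order = np.argsort([p.tof for p in peaks])
    return ([peaks[i] for i in order], [truth[i] for i in order])


def simulate_peak_list(
    spec: SimulationSpec, model: InstrumentModel
) -> tuple[list[Peak], list[GroundTruthRow]]:
    """Simulate one acquisition under ``spec.condition``.

    Returns (peaks sorted by TOF, ground truth in the same order).  Under
    a multi-turn condition each ion appears at its condition-determined
    lap; ions falling outside the observation window are dropped.
    """
    return _emit(spec, model, spec.condition)


def simulate_half_cycle(
    spec: SimulationSpec, model: InstrumentModel
) -> tuple[list[Peak], list[GroundTruthRow]]:
    """Simulate the same mixture in half-cycle mode (lap 0 for all ions).

    Half-cycle arrivals are monotone in m/z, so the peak list preserves
    mass order — the unambiguous counterpart spectrum for lap matching.
    """
    half = AnalyzerCondition(spec.condition.reference_ion, 0, 0.0,
                             float("inf"))
    return _emit(spec, model, half)
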