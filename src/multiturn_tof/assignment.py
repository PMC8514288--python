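"""Peak assignment for lap-superimposed multi-turn TOF spectra.

Two algorithms are implemented.

Known targets: for each candidate species the condition fixes its lap
number, hence its predicted TOF and its "apparent m/z" (the m/z a peak
would be assigned under the reference-lap assumption).  Observed peaks
are matched to predictions within a TOF tolerance; an assignment is
confirmed by checking that the assigned m/z agrees across spectra taken
at different lap conditions — a wrong lap hypothesis disagrees at the
dalton scale, the correct one at the sub-millidalton scale.

Unknown ions: one observed TOF constrains m/z only up to the unknown lap
number, yielding a discrete candidate-mass sequence (one m/z per
admissible lap).  Two spectra of the same sample under different ejection
timings yield two sequences per ion whose only common value, to within a
small tolerance, is the true m/z.  The sequences are monotone in lap
number, so the common value is found by a sorted-list merge in
O(|a| + |b|) comparisons; against a half-cycle spectrum (whose masses are
unambiguous) a binary search suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conditions import AnalyzerCondition, lap_range_for_mz_interval
from .ion_optics import InstrumentModel, IonSpecies, mz_from_tof, time_of_flight
from .conditions import lap_for_mz

__all__ = [
    "Peak",
    "Assignment",
    "TargetPrediction",
    "CandidateSequence",
    "IntersectionMatch",
    "HalfCycleMatch",
    "ValidationEntry",
    "DEFAULT_TOF_TOLERANCE",
    "DEFAULT_MZ_TOLERANCE",
    "predict_known_targets",
    "assign_known",
    "cross_validate",
    "candidate_masses",
    "intersect_candidates",
    "match_half_cycle",
    "assign_unknown_pair",
]

#: Default matching tolerances: 20 ns on TOF (narrower than any peak
#: spacing the method needs to resolve), 10 mDa on m/z (the accuracy a
#: half-cycle spectrum delivers).
DEFAULT_TOF_TOLERANCE = 20e-9
DEFAULT_MZ_TOLERANCE = 0.010


@dataclass(frozen=True)
class Peak:
    """A centroided peak: TOF in seconds, optional intensity and label."""

    tof: float
    intensity: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.tof <= 0:
            raise ValueError("peak TOF must be positive")


@dataclass(frozen=True)
class TargetPrediction:
    """Predicted observables of one target under one condition."""

    ion: IonSpecies
    lap: int
    predicted_tof: float
    apparent_mz: float


@dataclass
class Assignment:
    """One (peak, lap, m/z) assignment, possibly flagged.

    ``assigned_mz`` is the m/z under the assigned lap; ``apparent_mz`` is
    the m/z under the condition's reference-lap assumption.  ``flags`` may
    contain "ambiguous" (several candidates fit), "near_ejection_edge",
    or "unmatched" (no candidate fit; lap/mz fields are then None).
    """

    peak: Peak
    lap: int | None
    assigned_mz: float | None
    apparent_mz: float | None
    target: IonSpecies | None = None
    mass_error: float | None = None
    flags: set = field(default_factory=set)


# --------------------------------------------------------------------------
# algorithm A: known target ions
# --------------------------------------------------------------------------

def predict_known_targets(
    targets: Sequence[IonSpecies],
    condition: AnalyzerCondition,
    model: InstrumentModel,
) -> list[TargetPrediction]:
    """Predict (lap, TOF, apparent m/z) for each target under a condition.

    These are computable before acquisition, so matching peaks can be
    monitored in real time against a chemical-formula watch list.
    """
    out = []
    for ion in targets:
        lap = lap_for_mz(ion, condition, model)
        tof = time_of_flight(ion, lap, model)
        apparent = mz_from_tof(tof, condition.reference_laps, model)
        out.append(TargetPrediction(ion, lap, tof, apparent))
    return out


def assign_known(
    peaks: Sequence[Peak],
    predictions: Sequence[TargetPrediction],
    condition: AnalyzerCondition,
    model: InstrumentModel,
    tolerance_tof: float = DEFAULT_TOF_TOLERANCE,
) -> list[Assignment]:
    """Match observed peaks to target predictions within a TOF tolerance.

    Each peak gets the nearest prediction within ``tolerance_tof``; peaks
    fitting no prediction are flagged "unmatched", peaks fitting several
    are flagged "ambiguous" and return one Assignment per candidate.
    """
    if tolerance_tof <= 0:
        raise ValueError("TOF tolerance must be positive")
    out: list[Assignment] = []
    for peak in peaks:
        hits = [p for p in predictions
                if abs(p.predicted_tof - peak.tof) <= tolerance_tof]
        if not hits:
            out.append(Assignment(peak, None, None, None,
                                  flags={"unmatched"}))
            continue
        hits.sort(key=lambda p: abs(p.predicted_tof - peak.tof))
        flags = {"ambiguous"} if len(hits) > 1 else set()
        for p in hits:
            assigned = mz_from_tof(peak.tof, p.lap, model)
            apparent = mz_from_tof(peak.tof, condition.reference_laps, model)
            out.append(Assignment(
                peak, p.lap, assigned, apparent, target=p.ion,
                mass_error=assigned - p.ion.mz, flags=set(flags)))
    return out


@dataclass(frozen=True)
class ValidationEntry:
    """Cross-condition agreement of one target's assigned m/z."""

    key: str
    assigned_mz: tuple[float, ...]
    spread: float
    validated: bool


def cross_validate(
    assignment_sets: Sequence[Sequence[Assignment]],
    tolerance_mz: float = 0.002,
) -> list[ValidationEntry]:
    """Self-validate assignments across >= 2 lap conditions.

    For each target appearing in every set, reports the maximum pairwise
    difference of assigned m/z; "validated" if the spread is within
    ``tolerance_mz``.  A wrong lap hypothesis shows dalton-scale spread.
    """
    if len(assignment_sets) < 2:
        raise ValueError("cross-validation needs >= 2 assignment sets")
    by_key: dict[str, list[list[float]]] = {}
    for i, aset in enumerate(assignment_sets):
        for a in aset:
            if a.assigned_mz is None:
                continue
            key = a.target.label if a.target is not None else f"mz{a.assigned_mz:.3f}"
            by_key.setdefault(key, [[] for _ in assignment_sets])[i].append(
                a.assigned_mz)
    out = []
    for key, per_set in sorted(by_key.items()):
        values = tuple(v for vs in per_set for v in vs)
        present_everywhere = all(vs for vs in per_set)
        spread = max(values) - min(values) if len(values) > 1 else 0.0
        out.append(ValidationEntry(
            key, values, spread,
            validated=present_everywhere and spread <= tolerance_mz))
    return out


# --------------------------------------------------------------------------
# algorithm B: unknown ions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSequence:
    """m/z candidates of one TOF, one per hypothesized lap number.

    ``mz`` is strictly decreasing (more laps → longer path → lighter
    ion), ``laps`` ascending and aligned with ``mz``.
    """

    tof: float
    laps: np.ndarray
    mz: np.ndarray

    def __len__(self) -> int:
        return len(self.mz)


def candidate_masses(
    t: float,
    lap_range: tuple[int, int],
    model: InstrumentModel,
) -> CandidateSequence:
    """All m/z consistent with TOF ``t`` over laps n_min..n_max inclusive."""
    n_min, n_max = lap_range
    if n_min > n_max:
        raise ValueError("lap range must satisfy n_min <= n_max")
    if n_min < 0:
        raise ValueError("lap numbers must be >= 0")
    g, c = model.geometry, model.calibration
    if t <= c.time_delay:
        raise ValueError("TOF must exceed the instrumental time delay")
    laps = np.arange(n_min, n_max + 1)
    path = g.half_cycle_length + laps * g.orbit_length
    mz = (model.constants.K * c.acceleration_voltage
          * ((t - c.time_delay) / path) ** 2)
    return CandidateSequence(tof=t, laps=laps, mz=mz)


@dataclass(frozen=True)
class IntersectionMatch:
    """One agreeing pair of candidates from two sequences."""

    mz: float
    index_a: int
    index_b: int


def _as_descending(seq) -> np.ndarray:
    arr = seq.mz if isinstance(seq, CandidateSequence) else np.asarray(seq, float)
    if len(arr) > 1 and np.any(np.diff(arr) >= 0):
        raise ValueError("candidate list must be strictly decreasing")
    return arr


def intersect_candidates(
    a,
    b,
    tolerance_mz: float = DEFAULT_MZ_TOLERANCE,
) -> tuple[list[IntersectionMatch], int]:
    """Find common values of two descending candidate lists by linear merge.

    Returns (matches, comparison count); the count never exceeds
    2*(|a| + |b|).  Near-equal values match within ``tolerance_mz``, with
    ties broken toward the lower lap number (earlier index).  Inputs may
    be CandidateSequence or plain descending arrays.
    """
    if tolerance_mz <= 0:
        raise ValueError("m/z tolerance must be positive")
    va, vb = _as_descending(a), _as_descending(b)
    matches: list[IntersectionMatch] = []
    comparisons = 0
    i = j = 0
    while i < len(va) and j < len(vb):
        comparisons += 1
        if abs(va[i] - vb[j]) <= tolerance_mz:
            matches.append(IntersectionMatch(
                mz=float((va[i] + vb[j]) / 2.0), index_a=i, index_b=j))
            i += 1
            j += 1
            continue
        comparisons += 1
        if va[i] > vb[j]:  # a ahead (heavier): advance a toward b
            i += 1
        else:
            j += 1
    assert comparisons <= 2 * (len(va) + len(vb))
    return matches, comparisons


@dataclass(frozen=True)
class HalfCycleMatch:
    """Result of matching a half-cycle mass into a candidate sequence."""

    lap: int
    mz: float
    comparisons: int


def match_half_cycle(
    half_cycle_mz: float,
    candidates: CandidateSequence,
    tolerance_mz: float = DEFAULT_MZ_TOLERANCE,
) -> HalfCycleMatch | None:
    """Binary-search a half-cycle m/z against one candidate sequence.

    The half-cycle spectrum has no lap ambiguity, so its m/z (good to
    ~10 mDa) picks the lap directly; ceil(log2 n) + 1 comparisons at
    most.  Returns None when no candidate lies within tolerance.
    """
    mz = candidates.mz
    if len(mz) == 0:
        return None
    lo, hi = 0, len(mz) - 1
    comparisons = 0  # bisection steps only; ceil(log2 n) of them
    while lo < hi:  # descending array: larger values first
        mid = (lo + hi) // 2
        comparisons += 1
        if mz[mid] > half_cycle_mz:
            lo = mid + 1
        else:
            hi = mid
    # nearest of mz[lo] and its heavier neighbour
    best = lo
    if lo > 0 and abs(mz[lo - 1] - half_cycle_mz) < abs(mz[lo] - half_cycle_mz):
        best = lo - 1
    assert comparisons <= math.ceil(math.log2(max(len(mz), 2)))
    if abs(mz[best] - half_cycle_mz) > tolerance_mz:
        return None
    return HalfCycleMatch(lap=int(candidates.laps[best]),
                          mz=float(mz[best]), comparisons=comparisons)


def assign_unknown_pair(
    peaks_a: Sequence[Peak],
    condition_a: AnalyzerCondition,
    peaks_b: Sequence[Peak],
    condition_b: AnalyzerCondition,
    mz_bounds: tuple[float, float],
    model: InstrumentModel,
    tolerance_mz: float = DEFAULT_MZ_TOLERANCE,
) -> list[Assignment]:
    """Assign m/z to unknown ions from two spectra at different timings.

    For every peak pair across the two spectra, builds the candidate-mass
    sequences over the lap ranges admissible for ``mz_bounds`` and
    intersects them; each agreeing candidate pair becomes an Assignment
    (flagged "ambiguous" when a peak pair agrees at several lap pairs).
    Peaks of spectrum A with no counterpart anywhere in B are returned
    flagged "unmatched".
    """
    range_a = lap_range_for_mz_interval(*mz_bounds, condition_a, model)
    range_b = lap_range_for_mz_interval(*mz_bounds, condition_b, model)
    seqs_b = [candidate_masses(pb.tof, range_b, model) for pb in peaks_b]
    out: list[Assignment] = []
    for pa in peaks_a:
        seq_a = candidate_masses(pa.tof, range_a, model)
        found = False
        for seq_b in seqs_b:
            matches, _ = intersect_candidates(seq_a, seq_b, tolerance_mz)
            flags = {"ambiguous"} if len(matches) > 1 else set()
            for m in matches:
                found = True
                out.append(Assignment(
                    peak=pa,
                    lap=int(seq_a.laps[m.index_a]),
                    assigned_mz=m.mz,
                    apparent_mz=mz_from_tof(pa.tof,
                                            condition_a.reference_laps,
                                            model),
                    flags=set(flags)))
        if not found:
            out.append(Assignment(pa, None, None, None, flags={"unmatched"}))
    return out
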