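# Methods

## Physical model and assumptions

The analyzer is modeled as a closed figure-eight orbit of length
*L*<sub>c</sub> appended to an open source-to-detector path
*L*<sub>k</sub> (the "half-cycle" path), with an electrostatic ejection
sector — 0.063 m long, about a tenth of the orbit — that diverts ions to
the detector once opened. Ion motion is non-relativistic and
monoenergetic: every singly charged ion carries *e V*<sub>acc</sub> of
kinetic energy, so its speed is *v* = √(2 *z e V*<sub>acc</sub> /
(*m K*<sub>amc</sub>)) and its arrival time is
*t* = *t*₀ + (*L*<sub>k</sub> + *n L*<sub>c</sub>)/*v* after *n* laps.
Energy spread, turn-around time, sector fringe fields and peak shapes
are outside the model: peaks are treated as centroids, which is what the
assignment algorithms consume. All internal quantities are SI; user-facing
I/O uses microseconds and unified atomic mass units. Physical constants
are CODATA 2018 (e = 1.602176634·10⁻¹⁹ C, K_amc = 1.66053906660·10⁻²⁷ kg,
m_e = 5.48579909·10⁻⁴ u). Exact ion masses are monoisotopic neutral
masses minus *z* electron masses, divided by *z*; all algorithms operate
on m/z, so multiply-charged ions follow the same code path although the
shipped examples are all singly charged.

## Calibration

The TOF equation is linear in *L*<sub>k</sub> (given velocities) and,
after substituting *x* = (*L*<sub>k</sub> + *n L*<sub>c</sub>)
√(*m K*<sub>amc</sub>/(2 *z e*)), linear in (1/√*V*<sub>acc</sub>, *t*₀).
Calibration is therefore two stages of ordinary (optionally weighted)
linear least squares, in the order an operator performs them: first
*L*<sub>k</sub> from multi-lap arrivals of several ions, then
(*V*<sub>acc</sub>, *t*₀) from multi-lap arrivals of one reference ion.
A joint nonlinear fit of all four constants is deliberately not offered;
the staged fits are exactly identified, reproducible, and match how the
constants are used. Designs with fewer than two distinct lap numbers are
rejected as rank-deficient.

The default model's path lengths are recovered from two published
multi-lap CO₂⁺ arrivals (30 laps, 156.0695 µs; 50 laps, 257.4951 µs)
with *V*<sub>acc</sub> = 3893.22 V and *t*₀ = 0.240 µs, by solving
*L*<sub>k</sub> + *n*ᵢ*L*<sub>c</sub> = *v*(*t*ᵢ − *t*₀). The instrument's
actual drawings are not public, so this anchor-derived geometry
(*L*<sub>k</sub> ≈ 0.4824 m, *L*<sub>c</sub> ≈ 0.6627 m) is the
reproducible route; it predicts the independent half-cycle CO₂⁺ arrival
(measured 3.9333 µs) to within 3 ns, and all worked numbers in the test
suite to their stated tolerances. `reanchor_half_cycle_length` shifts
*L*<sub>k</sub> alone so that a single published (lap, TOF) anchor is
reproduced exactly, which some published scenarios require.

**Parameter uncertainty under timing jitter.** With 1 ns Gaussian TOF
jitter, the fits recover *L*<sub>k</sub> to ≲0.5 mm and
*V*<sub>acc</sub> to a median relative error below 10⁻³ under the
three-observation designs used on the instrument. The time delay *t*₀,
however, is an intercept extrapolated far outside the observed lap
range: 1 ns of jitter propagates to roughly 1–2 ns of intercept
uncertainty, so *t*₀ is quoted at the nanosecond scale, not at 0.1 % of
its 240 ns value — no design measurable on this instrument could do
better from 1 ns timing noise.

## Acquisition conditions and lap determination

A condition is a reference ion plus its intended lap count. By default
the ejection sector opens half a reference orbital period before the
reference arrival (reproducing the published 123.11 µs opening for the
24-lap CO₂⁺ condition); measured timings that deviate from this rule are
accepted verbatim as overrides, because published 30/50-lap timings
differ from the half-period rule by up to ~0.6 period. Each m/z is
observed at its *first* lap whose arrival falls at or after the opening
— ejection removes the ion from the orbit, so the arrival inside the
one-period observation window is unique. Lap counts near the window
edges are boundary-sensitive to the exact opening time; a configurable
sector-transit guard flags ions arriving within *L*<sub>ed</sub>/*v*
(or an explicit guard time) of the opening as unreliable, reflecting
that an ion needs ~0.35–0.7 µs to clear the switching sector.

Two distinct lap rules coexist and are kept separate deliberately:
assigning a lap to an *observed peak* of known m/z rounds
(*L* − *L*<sub>k</sub>)/*L*<sub>c</sub> to the nearest integer (robust to
measurement error in either direction), while determining the lap an ion
*will be observed at* under a condition uses the first-arrival rule
above. A `rounding="floor"` switch counts completed laps of an ion still
in flight.

## Assignment algorithms

*Known targets.* Predictions (lap, TOF, apparent m/z) are computed per
target; peaks match the nearest prediction within a TOF tolerance
(default 20 ns — the smallest peak spacing the published scenarios need
to resolve is 35 ns). Ambiguity is a first-class outcome: a peak within
tolerance of several predictions returns all candidates flagged
`ambiguous`, mirroring the published dual assignment of one 50-lap-condition
peak to both a 59-lap and a 62-lap hypothesis. Cross-condition
validation groups assignments by target and reports the maximum pairwise
spread of assigned m/z; the default 2 mDa acceptance spread is an order
of magnitude below the ~1.6 Da disagreement a wrong lap pair produces.

*Unknown ions.* Candidate sequences are evaluated vectorized over the
admissible lap range (from the condition and the sample's m/z bounds)
and kept descending in m/z / ascending in lap. The two-spectrum
intersection is a linear merge that counts its own comparisons and
asserts the 2(|a|+|b|) bound; near-equal values match within an absolute
m/z tolerance (default 10 mDa, the accuracy a half-cycle spectrum
delivers), with ties broken toward the lower lap number. Absolute rather
than relative tolerance is the default because candidate spacing, not
mass accuracy, dominates the matching margin. The pair equation relating
two TOFs of one unknown ion is never solved analytically — only
enumerate-and-intersect is implemented. Against a half-cycle peak list
the search is a bisection over the descending sequence; the reported
comparison count is the number of bisection steps (⌈log₂ 113⌉ = 7),
with the final nearest-neighbour tolerance check not counted as a search
step.

## Synthetic spectra

The generator emulates centroided acquisitions: one peak per mixture ion
at its condition-determined lap and exact TOF-equation arrival, plus
seeded Gaussian TOF jitter (default σ = 1 ns, commensurate with
4-decimal-microsecond centroid lists) and optional Poisson abundance
noise. Peaks outside the observation window are dropped; the ground
truth (ion, lap, exact TOF) is returned alongside. It reproduces the
characteristic mass-order reshuffling of closed-path analyzers (e.g. a
CH₄/C₂H₄/O₂/CO₂ mixture reorders to C₂H₄, O₂, CH₄, CO₂ after one CO₂
lap). It does **not** model waveform profiles, detector dead time,
ion-counting statistics, isotope envelopes or chemical noise — so
closed-loop tests demonstrate the correctness of the assignment logic
and its noise tolerances, not robustness to real-world peak-picking
artifacts.

## Numerical choices and problem sizes

Strict SI internally; CSV peak lists carry microseconds at 4 decimals
(0.1 ns granularity, < 1 mDa round-trip cost). The TOF↔m/z round trip
is exact to 10⁻¹⁰ relative over m/z 1–1000 and 0–200 laps. Property
tests run 1000 random intersection instances against a brute-force
all-pairs oracle (instances generated with inter-candidate gaps above
twice the tolerance, where merge and oracle provably coincide) and 200
random 3–12-ion mixtures over m/z 10–600 with random condition pairs,
recovered exactly in the noiseless case; these sizes keep the whole
suite under a few seconds while exercising lap ranges up to several
hundred.

## Limitations

Geometry is anchor-derived, so absolute TOF predictions carry a few-ns
systematic offset (differences between co-predicted TOFs cancel it);
charge states above one are supported but untested against published
values; drift/temperature recalibration, ion-gate operation and raw
waveform processing are out of scope.
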