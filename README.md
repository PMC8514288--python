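# multiturn-tof

Lap-number and m/z assignment for **lap-superimposed spectra** from
multi-turn time-of-flight (TOF) mass spectrometers with a closed
figure-eight flight path.

On a closed orbit, light ions overtake heavy ones: after a few laps a
single acquisition window contains peaks from ions at *different* lap
numbers, and a peak's flight time no longer determines its mass. This
package turns that superposition from a limitation into extra mass range.
It is aimed at practitioners of multi-turn / multi-reflection TOF
instruments and at anyone building acquisition or post-processing
software for them.

## The model

An ion of mass-to-charge ratio *m/z* (in u) accelerated through
*V*<sub>acc</sub> volts travels at

&nbsp;&nbsp;&nbsp;&nbsp;*v* = √(2 *z e V*<sub>acc</sub> / (*m K*<sub>amc</sub>))

and, after *n* laps of an orbit of length *L*<sub>c</sub> appended to the
open source-to-detector path *L*<sub>k</sub>, arrives at

&nbsp;&nbsp;&nbsp;&nbsp;*t* = *t*₀ + (*L*<sub>k</sub> + *n L*<sub>c</sub>) / *v*,

where *t*₀ is the instrumental time delay. Inverting at an assumed lap
number gives the **apparent m/z** of a peak,
*m/z* = *K V*<sub>acc</sub> ((*t* − *t*₀)/(*L*<sub>k</sub> + *n L*<sub>c</sub>))²
with *K* = 2 *e*/*K*<sub>amc</sub> — correct only for ions that really
flew *n* laps.

Two assignment algorithms build on this:

* **Known targets** — a condition (reference ion + lap count) fixes the
  ejection-sector open time, hence every target's lap number, predicted
  TOF and apparent m/z, all computable before acquisition. Assignments
  are self-validated across conditions: the right lap hypothesis agrees
  to sub-millidalton, a wrong one disagrees at the dalton scale.
* **Unknown ions** — one TOF constrains m/z only up to the lap number,
  giving a discrete, sorted candidate-mass sequence (one m/z per
  admissible lap). Two spectra under different ejection timings share
  exactly one candidate — found by a linear sorted-merge intersection in
  ≤ 2(|a|+|b|) comparisons, or by binary search (≤ 7 comparisons for 113
  candidates) against an unambiguous half-cycle spectrum.

The default instrument model derives its geometry from published
multi-lap CO₂⁺ arrival times (30 laps at 156.0695 µs, 50 laps at
257.4951 µs) with *V*<sub>acc</sub> = 3893.22 V and *t*₀ = 0.240 µs,
giving *L*<sub>k</sub> ≈ 0.4824 m and *L*<sub>c</sub> ≈ 0.6627 m.

## Worked example

```python
from multiturn_tof import (IonSpecies, default_instrument_model,
                           make_condition, predict_known_targets)

model = default_instrument_model()
cond = make_condition(IonSpecies("CO2"), 24, model)
print(f"ejection opens at {cond.ejection_open_time * 1e6:.2f} us, "
      f"window {cond.window_width * 1e6:.2f} us")
targets = [IonSpecies(f) for f in ("O2", "Ar", "C2H4", "CO2")]
for p in predict_known_targets(targets, cond, model):
    print(f"{p.ion.label:6s} lap {p.lap:2d}  TOF {p.predicted_tof*1e6:9.4f} us"
          f"  apparent m/z {p.apparent_mz:7.3f}")
```

prints

```
ejection opens at 123.11 us, window 5.07 us
O2+    lap 28  TOF  124.4766 us  apparent m/z  43.176
Ar+    lap 25  TOF  124.5970 us  apparent m/z  43.259
C2H4+  lap 30  TOF  124.6323 us  apparent m/z  43.284
CO2+   lap 24  TOF  125.6418 us  apparent m/z  43.989
```

Read: with the analyzer set for 24 laps of CO₂⁺, the ejection sector
opens 123.11 µs after the ion push and the whole spectrum is only one
CO₂⁺ orbital period (5.07 µs) wide. O₂⁺ is caught on its 28th lap and
lands at 124.4766 µs; a naive 24-lap reading of that peak would call it
m/z 43.176. Ar⁺ and C₂H₄⁺ arrive only 35 ns apart under this condition —
switching to a 26-lap condition separates them by 2.51 µs, which is how
cross-condition validation rejects false assignments.

The same functionality is available from the shell via the `mtof`
command (`calibrate`, `predict`, `assign-known`, `assign-unknown`,
`simulate`, `validate`), driven by a TOML config; peak lists are CSV or
JSON with times in microseconds.

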