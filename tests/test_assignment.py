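"""Known-target and unknown-ion assignment algorithms."""

import math

import numpy as np
import pytest

from multiturn_tof import (
    IonSpecies,
    Peak,
    assign_known,
    assign_unknown_pair,
    candidate_masses,
    cross_validate,
    intersect_candidates,
    lap_for_mz,
    lap_range_for_mz_interval,
    make_condition,
    match_half_cycle,
    mz_from_tof,
    predict_known_targets,
    reanchor_half_cycle_length,
    time_of_flight,
)
from multiturn_tof.assignment import Assignment


@pytest.fixture(scope="module")
def fig4_model(model):
    """Model with L_k re-anchored so 30 laps of m/z 43.989 arrive at 156.40 us."""
    return reanchor_half_cycle_length(43.989, 30, 156.40e-6, model)


@pytest.fixture(scope="module")
def fig4_conditions(fig4_model):
    co2 = IonSpecies("CO2")
    a = make_condition(co2, 30, fig4_model, ejection_open_time=153.74e-6)
    b = make_condition(co2, 32, fig4_model, ejection_open_time=163.89e-6)
    return a, b


class TestPredictKnownTargets:
    def test_confusable_pair_separated_by_35ns_at_24_laps(self, model,
                                                          cond24):
        preds = {p.ion.formula: p for p in predict_known_targets(
            [IonSpecies("C2H4"), IonSpecies("Ar")], cond24, model)}
        assert preds["C2H4"].lap == 30 and preds["Ar"].lap == 25
        assert preds["C2H4"].predicted_tof * 1e6 == pytest.approx(124.631,
                                                                  abs=0.05)
        assert preds["Ar"].predicted_tof * 1e6 == pytest.approx(124.596,
                                                                abs=0.05)
        assert preds["C2H4"].apparent_mz == pytest.approx(43.284, abs=0.03)
        assert preds["Ar"].apparent_mz == pytest.approx(43.259, abs=0.03)

    def test_o2_prediction_under_24_lap_condition(self, model, cond24):
        (p,) = predict_known_targets([IonSpecies("O2")], cond24, model)
        assert p.lap == 28
        assert p.predicted_tof * 1e6 == pytest.approx(124.477, abs=0.05)
        assert p.apparent_mz == pytest.approx(43.176, abs=0.02)

    def test_reference_ion_apparent_mz_is_its_exact_mass(self, model, co2,
                                                         cond24):
        (p,) = predict_known_targets([co2], cond24, model)
        assert p.lap == 24
        assert p.predicted_tof == pytest.approx(
            time_of_flight(co2, 24, model), rel=1e-14)
        assert p.apparent_mz == pytest.approx(co2.mz, rel=1e-12)


class TestAssignKnown:
    def test_exact_synthetic_peaks_all_assigned_clean(self, model, cond24,
                                                      gas_mixture_ions):
        preds = predict_known_targets(gas_mixture_ions, cond24, model)
        peaks = [Peak(p.predicted_tof) for p in preds]
        out = assign_known(peaks, preds, cond24, model)
        assert len(out) == len(preds)
        assert all(not a.flags for a in out)
        for a in out:
            assert a.assigned_mz == pytest.approx(a.target.mz, abs=1e-9)

    def test_coincident_peak_at_50_laps_yields_two_candidates(
            self, model, co2, gas_mixture_ions):
        # one observed TOF fits both a 62-lap and a 59-lap hypothesis
        cond = make_condition(co2, 50, model)
        preds = predict_known_targets(gas_mixture_ions, cond, model)
        out = assign_known([Peak(258.5387e-6)], preds, cond, model)
        assert len(out) == 2
        assert all("ambiguous" in a.flags for a in out)
        by_lap = {a.lap: a.assigned_mz for a in out}
        assert set(by_lap) == {59, 62}
        assert by_lap[62] == pytest.approx(29.0, abs=0.02)
        assert by_lap[59] == pytest.approx(32.0, abs=0.02)

    def test_unmatched_peak_is_flagged(self, model, cond24,
                                       gas_mixture_ions):
        preds = predict_known_targets(gas_mixture_ions, cond24, model)
        (a,) = assign_known([Peak(123.5e-6)], preds, cond24, model)
        assert a.flags == {"unmatched"} and a.lap is None

    def test_empty_peak_list_gives_empty_assignments(self, model, cond24):
        assert assign_known([], [], cond24, model) == []


class TestCrossValidate:
    def _assign_observed(self, model, ions, laps, tof_us_list):
        cond = make_condition(IonSpecies("CO2"), laps, model)
        preds = predict_known_targets(ions, cond, model)
        peaks = [Peak(t * 1e-6) for t in tof_us_list]
        return assign_known(peaks, preds, cond, model,
                            tolerance_tof=50e-9)

    def test_co2_validates_across_three_lap_conditions(self, model, co2):
        # observed CO2+ arrivals at the 30- and 50-lap anchors
        sets = [
            self._assign_observed(model, [co2], 30, [156.0695]),
            self._assign_observed(model, [co2], 30, [156.0695]),
            self._assign_observed(model, [co2], 50, [257.4951]),
        ]
        (entry,) = cross_validate(sets, tolerance_mz=0.002)
        assert entry.validated
        assert entry.spread < 0.002

    def test_wrong_lap_hypothesis_is_refuted_at_the_dalton_scale(
            self, model, cond24):
        # Ar+'s 24-lap peak mistaken for C2H4+ (35 ns away): at the 26-lap
        # condition the two species separate by 2.51 us, i.e. ~1.6 Da
        c2h4, ar = IonSpecies("C2H4"), IonSpecies("Ar")
        ar_peak_24 = Peak(time_of_flight(ar, 25, model))
        wrong = Assignment(
            peak=ar_peak_24, lap=30,
            assigned_mz=mz_from_tof(ar_peak_24.tof, 30, model),
            apparent_mz=None, target=c2h4)
        cond26 = make_condition(IonSpecies("CO2"), 26, model)
        ar_peak_26 = Peak(time_of_flight(ar, lap_for_mz(ar, cond26, model),
                                         model))
        right = Assignment(
            peak=ar_peak_26, lap=27,
            assigned_mz=mz_from_tof(ar_peak_26.tof, 27, model),
            apparent_mz=None, target=c2h4)
        (entry,) = cross_validate([[wrong], [right]], tolerance_mz=0.002)
        assert not entry.validated
        assert entry.spread > 1.0  # dalton-scale disagreement

    def test_duplicated_set_validates_with_zero_spread(self, model, co2):
        aset = self._assign_observed(model, [co2], 30, [156.0695])
        (entry,) = cross_validate([aset, aset])
        assert entry.validated and entry.spread == 0.0

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            cross_validate([[]])


class TestCandidateMasses:
    def test_wide_scan_has_113_candidates(self, model):
        seq = candidate_masses(377.2e-6, (20, 132), model)
        assert len(seq) == 113
        assert np.all(np.diff(seq.mz) < 0)

    def test_single_lap_range(self, model):
        seq = candidate_masses(125.3506e-6, (24, 24), model)
        assert len(seq) == 1
        assert seq.mz[0] == pytest.approx(mz_from_tof(125.3506e-6, 24, model))

    def test_endpoints_of_the_observed_n_peak(self, model):
        seq = candidate_masses(125.3506e-6, (24, 43), model)
        assert seq.mz[0] == pytest.approx(43.79, abs=0.02)
        assert seq.mz[-1] == pytest.approx(14.00, abs=0.02)

    def test_tof_before_delay_rejected(self, model):
        with pytest.raises(ValueError):
            candidate_masses(0.1e-6, (0, 10), model)


class TestIntersectCandidates:
    def test_fig4_pair_matches_uniquely_at_laps_31_and_33(self, fig4_model,
                                                          fig4_conditions):
        cond_a, cond_b = fig4_conditions
        seq_a = candidate_masses(
            156.40e-6, lap_range_for_mz_interval(40, 47, cond_a, fig4_model),
            fig4_model)
        seq_b = candidate_masses(
            166.22e-6, lap_range_for_mz_interval(40, 47, cond_b, fig4_model),
            fig4_model)
        matches, comparisons = intersect_candidates(seq_a, seq_b)
        assert len(matches) == 1
        m = matches[0]
        assert m.mz == pytest.approx(41.266, abs=0.01)
        assert seq_a.laps[m.index_a] == 31
        assert seq_b.laps[m.index_b] == 33
        assert comparisons <= 2 * (len(seq_a) + len(seq_b))

    def test_disjoint_lists_give_empty_intersection(self):
        matches, _ = intersect_candidates([30.0, 20.0, 10.0],
                                          [25.0, 15.0, 5.0],
                                          tolerance_mz=0.01)
        assert matches == []

    def test_unsorted_input_is_detected(self):
        with pytest.raises(ValueError, match="decreasing"):
            intersect_candidates([1.0, 2.0, 3.0], [3.0, 2.0])

    def test_equivalent_to_brute_force_on_random_instances(self):
        """Merge intersection reproduces the all-pairs oracle, 1000 trials."""
        rng = np.random.default_rng(2021)
        for _ in range(1000):
            tol = rng.uniform(0.001, 0.05)
            # descending lists with gaps > 2*tol so matches are unambiguous
            a = np.cumsum(rng.uniform(2.5 * tol, 5.0, rng.integers(1, 40)))[::-1]
            b = np.cumsum(rng.uniform(2.5 * tol, 5.0, rng.integers(1, 40)))[::-1]
            b = b + rng.uniform(-0.5 * tol, 0.5 * tol)
            matches, comparisons = intersect_candidates(a, b, tolerance_mz=tol)
            oracle = {(i, j) for i in range(len(a)) for j in range(len(b))
                      if abs(a[i] - b[j]) <= tol}
            assert {(m.index_a, m.index_b) for m in matches} == oracle
            assert comparisons <= 2 * (len(a) + len(b))


class TestMatchHalfCycle:
    def test_half_cycle_mass_picks_the_43_lap_hypothesis(self, model):
        seq = candidate_masses(125.3506e-6, (24, 43), model)
        hit = match_half_cycle(14.01, seq, tolerance_mz=0.01)
        assert hit is not None and hit.lap == 43

    def test_at_most_7_comparisons_over_113_candidates(self, model):
        seq = candidate_masses(377.2e-6, (20, 132), model)
        for target in seq.mz[::7]:
            hit = match_half_cycle(float(target), seq)
            assert hit is not None
            assert hit.comparisons <= 7

    def test_empty_candidate_list_is_no_match(self, model):
        seq = candidate_masses(125.3506e-6, (24, 43), model)
        empty = type(seq)(tof=seq.tof, laps=seq.laps[:0], mz=seq.mz[:0])
        assert match_half_cycle(14.01, empty) is None

    def test_far_off_mass_is_no_match(self, model):
        seq = candidate_masses(125.3506e-6, (24, 43), model)
        assert match_half_cycle(100.0, seq, tolerance_mz=0.01) is None


class TestAssignUnknownPair:
    def test_noiseless_mixture_fully_recovered(self, model, co2,
                                               gas_mixture_ions):
        cond_a = make_condition(co2, 24, model)
        cond_b = make_condition(co2, 30, model)
        peaks_a = [Peak(time_of_flight(i, lap_for_mz(i, cond_a, model), model))
                   for i in gas_mixture_ions]
        peaks_b = [Peak(time_of_flight(i, lap_for_mz(i, cond_b, model), model))
                   for i in gas_mixture_ions]
        out = assign_unknown_pair(peaks_a, cond_a, peaks_b, cond_b,
                                  (14.0, 44.0), model)
        for ion in gas_mixture_ions:
            hits = [a for a in out if a.assigned_mz is not None
                    and abs(a.assigned_mz - ion.mz) < 1e-6]
            assert hits, f"{ion.label} not recovered"
            assert hits[0].lap == lap_for_mz(ion, cond_a, model)

    def test_fig4_peak_pair_assigned_41266(self, fig4_model,
                                           fig4_conditions):
        cond_a, cond_b = fig4_conditions
        out = assign_unknown_pair([Peak(156.40e-6)], cond_a,
                                  [Peak(166.22e-6)], cond_b,
                                  (40.0, 47.0), fig4_model)
        real = [a for a in out if a.assigned_mz is not None]
        assert len(real) == 1
        assert real[0].assigned_mz == pytest.approx(41.266, abs=0.01)
        assert real[0].lap == 31

    def test_peak_without_counterpart_is_flagged_unmatched(self, model, co2):
        cond_a = make_condition(co2, 24, model)
        cond_b = make_condition(co2, 30, model)
        lone = Peak(time_of_flight(31.9893, 28, model))
        out = assign_unknown_pair([lone], cond_a, [], cond_b,
                                  (14.0, 44.0), model)
        assert len(out) == 1
        assert out[0].flags == {"unmatched"}


def test_apparent_mz_curves_only_overlay_at_the_true_lap_pair(
        fig4_model, fig4_conditions):
    """Across two lap conditions, only the correct lap pair matches a dense
    m/z grid within 10 mDa; wrong pairs agree nowhere on the grid."""
    cond_a, cond_b = fig4_conditions
    range_a = lap_range_for_mz_interval(40, 47, cond_a, fig4_model)
    range_b = lap_range_for_mz_interval(40, 47, cond_b, fig4_model)
    wrong_pair_hits = 0
    for k in range(141):
        m = 40.0 + 0.05 * k
        ta = time_of_flight(m, lap_for_mz(m, cond_a, fig4_model), fig4_model)
        tb = time_of_flight(m, lap_for_mz(m, cond_b, fig4_model), fig4_model)
        seq_a = candidate_masses(ta, range_a, fig4_model)
        seq_b = candidate_masses(tb, range_b, fig4_model)
        matches, _ = intersect_candidates(seq_a, seq_b)
        true_pair = (lap_for_mz(m, cond_a, fig4_model),
                     lap_for_mz(m, cond_b, fig4_model))
        pairs = {(int(seq_a.laps[x.index_a]), int(seq_b.laps[x.index_b]))
                 for x in matches}
        assert true_pair in pairs
        wrong_pair_hits += len(pairs - {true_pair})
    assert wrong_pair_hits <= 3  # isolated crossings at most
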