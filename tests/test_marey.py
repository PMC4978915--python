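import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdrscan.distortion import analyze
from sdrscan.marey import (
    MareyMap,
    _longest_nondecreasing,
    average_rates,
    default_grid,
    filter_marey_outliers,
    fit_monotone_interpolant,
    local_rates,
    rate_vs_distortion,
    round_half_up,
    spans_from_loci,
)
from sdrscan.simulate import design_from_dict, simulate_population

from conftest import make_locus


def brute_force_lnds_length(values):
    """Longest non-decreasing subsequence by subset enumeration (n <= 12)."""
    best = 0
    n = len(values)
    for mask in range(1 << n):
        sub = [values[i] for i in range(n) if mask >> i & 1]
        if all(a <= b for a, b in zip(sub, sub[1:])):
            best = max(best, len(sub))
    return best


class TestOutlierFilter:
    def test_monotone_map_nothing_excluded(self):
        loci = [make_locus(f"m{i}", cM=float(i), Mb=float(i * 2)) for i in range(10)]
        mm = filter_marey_outliers(loci)
        assert mm.excluded_loci == []
        assert mm.n_points == 10

    def test_single_swapped_locus_excluded(self):
        cms = [0, 1, 2, 3, 4, 50, 5, 6, 7, 8]  # index 5 breaks monotonicity
        loci = [make_locus(f"m{i}", cM=float(c), Mb=float(i)) for i, c in enumerate(cms)]
        mm = filter_marey_outliers(loci)
        assert [m for m, r in mm.excluded_loci] == ["m5"]
        assert brute_force_lnds_length(cms) == 9

    def test_unanchored_excluded_with_reason(self):
        loci = [make_locus(f"m{i}", cM=float(i), Mb=float(i)) for i in range(3)]
        loci.append(make_locus("m_un", cM=3.0, Mb=None))
        mm = filter_marey_outliers(loci)
        assert ("m_un", "unanchored") in mm.excluded_loci

    def test_too_few_anchored_is_error(self):
        loci = [make_locus("m0", cM=0.0, Mb=0.0), make_locus("m1", cM=1.0, Mb=None)]
        with pytest.raises(ValueError, match="fewer than 2"):
            filter_marey_outliers(loci)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=12))
    def test_lnds_matches_brute_force(self, values):
        idx = _longest_nondecreasing(values)
        sub = [values[i] for i in idx]
        assert all(a <= b for a, b in zip(sub, sub[1:]))
        assert idx == sorted(idx)
        assert len(idx) == brute_force_lnds_length(values)


class TestInterpolant:
    def test_two_points_linear(self):
        mm = MareyMap("c", np.array([0.0, 10.0]), np.array([0.0, 5.0]))
        f = fit_monotone_interpolant(mm)
        assert f(5.0) == pytest.approx(2.5)
        assert f.derivative()(3.0) == pytest.approx(0.5)

    def test_parabola_recovered(self):
        mb = np.arange(0.0, 100.0 + 1e-9, 5.0)
        mm = MareyMap("c", mb, 0.01 * mb**2)
        f = fit_monotone_interpolant(mm)
        grid = np.linspace(0, 100, 500)
        assert np.max(np.abs(f(grid) - 0.01 * grid**2)) < 0.5

    def test_duplicate_mb_collapsed_with_warning(self):
        mm = MareyMap("c", np.array([0.0, 5.0, 5.0, 10.0]),
                      np.array([0.0, 2.0, 4.0, 6.0]))
        with pytest.warns(UserWarning, match="duplicate"):
            f = fit_monotone_interpolant(mm)
        assert f(5.0) == pytest.approx(3.0)  # mean of 2 and 4

    def test_monotone_on_simulator_maps(self):
        design = design_from_dict({
            "n_progeny": 150, "seed": 31,
            "chromosomes": [{"name": "chr01", "length_cM": 70, "length_Mb": 55,
                             "seg_class": "paternal", "marker_spacing_cM": 1.0}],
        })
        g, _ = simulate_population(design)
        mm = filter_marey_outliers(g.loci)
        f = fit_monotone_interpolant(mm)
        grid = np.linspace(mm.points_Mb[0], mm.points_Mb[-1], 1000)
        vals = f(grid)
        assert np.all(np.diff(vals) >= -1e-9)


class TestLocalRates:
    def test_linear_map_constant_rate(self):
        mm = MareyMap("c", np.array([0.0, 50.0]), np.array([0.0, 75.0]))
        f = fit_monotone_interpolant(mm)
        prof = local_rates(f, np.linspace(0, 50, 11), chromosome="c")
        np.testing.assert_allclose(prof.local_rate, 1.5)
        assert prof.chromosome_avg == pytest.approx(1.5)

    def test_parabola_rate_at_50(self):
        mb = np.arange(0.0, 100.0 + 1e-9, 5.0)
        mm = MareyMap("c", mb, 0.01 * mb**2)
        f = fit_monotone_interpolant(mm)
        prof = local_rates(f, np.array([50.0]))
        assert prof.local_rate[0] == pytest.approx(1.0, abs=0.05)

    def test_telomere_enriched_rates_higher_at_ends(self):
        # cubic S-curve Marey map: steep at the ends, flat in the middle
        mb = np.linspace(0, 100, 41)
        x = mb / 100 - 0.5
        cm = 100 * (0.5 + 4 * x**3)  # derivative 12 x^2: zero at center
        f = fit_monotone_interpolant(MareyMap("c", mb, cm))
        prof = local_rates(f, np.linspace(0, 100, 201))
        ends = np.concatenate([prof.local_rate[:20], prof.local_rate[-20:]])
        center = prof.local_rate[90:110]
        assert np.median(ends) > np.median(center)

    def test_rate_integral_recovers_cm_span(self):
        # conservation within 1% on a simulated map
        design = design_from_dict({
            "n_progeny": 120, "seed": 32,
            "chromosomes": [{"name": "chr01", "length_cM": 60, "length_Mb": 45,
                             "seg_class": "paternal", "marker_spacing_cM": 1.0}],
        })
        g, _ = simulate_population(design)
        mm = filter_marey_outliers(g.loci)
        f = fit_monotone_interpolant(mm)
        grid = np.linspace(mm.points_Mb[0], mm.points_Mb[-1], 4001)
        prof = local_rates(f, grid)
        integral = np.trapezoid(prof.local_rate, grid)
        assert integral == pytest.approx(mm.cM_span, rel=0.01)

    def test_invariant_to_point_on_curve(self):
        mb = np.arange(0.0, 50.0 + 1e-9, 5.0)
        mm = MareyMap("c", mb, 1.2 * mb)
        f = fit_monotone_interpolant(mm)
        mb2 = np.sort(np.append(mb, 7.0))
        mm2 = MareyMap("c", mb2, 1.2 * mb2)
        f2 = fit_monotone_interpolant(mm2)
        grid = np.linspace(0, 50, 101)
        np.testing.assert_allclose(f(grid), f2(grid), atol=1e-9)


class TestAverageRates:
    def test_single_chromosome(self):
        table = average_rates({"chr01": (100.0, 100.0)})
        assert table[table.chromosome == "chr01"]["rate_cM_per_Mb"].iloc[0] == 1.0

    def test_genome_wide_values_round_to_reported(self):
        t1 = average_rates({"all": (813.2, 715.8)})
        assert t1[t1.chromosome == "genome-wide"]["rounded"].iloc[0] == 1.1
        t2 = average_rates({"all": (637.9, 713.2)})
        assert t2[t2.chromosome == "genome-wide"]["rounded"].iloc[0] == 0.9

    def test_zero_span_is_error(self):
        with pytest.raises(ValueError, match="Mb span"):
            average_rates({"chr01": (10.0, 0.0)})

    def test_simulator_spans_exact(self):
        design = design_from_dict({
            "n_progeny": 20, "seed": 33,
            "chromosomes": [
                {"name": "chr01", "length_cM": 60, "length_Mb": 40, "seg_class": "paternal"},
                {"name": "chr02", "length_cM": 30, "length_Mb": 30, "seg_class": "paternal"},
            ],
        })
        g, _ = simulate_population(design)
        spans = spans_from_loci(g.loci)
        assert spans["chr01"] == (60.0, 40.0)
        table = average_rates(spans)
        gw = table[table.chromosome == "genome-wide"]["rate_cM_per_Mb"].iloc[0]
        assert gw == pytest.approx(90.0 / 70.0)

    def test_round_half_up(self):
        assert round_half_up(7.875, 1) == 7.9
        assert round_half_up(1.1360, 1) == 1.1
        assert round_half_up(0.85, 1) == 0.9
        assert round_half_up(-1.25, 1) == -1.3


class TestRateVsDistortion:
    def _results(self, n=30, seed=34):
        design = design_from_dict({
            "n_progeny": 96, "seed": seed,
            "chromosomes": [{"name": "chr01", "length_cM": 50, "length_Mb": 40,
                             "seg_class": "paternal", "marker_spacing_cM": 50.0 / (n - 1)}],
        })
        g, _ = simulate_population(design)
        return g, analyze(g)

    def test_constant_rate_reports_zero_with_note(self):
        g, results = self._results()
        mm = filter_marey_outliers(g.loci)
        f = fit_monotone_interpolant(mm)
        reg = rate_vs_distortion(f, results, chromosome="chr01")
        # simulator maps are exactly linear in Mb -> constant predictor
        assert reg.r_squared == 0.0
        assert "undefined" in reg.note

    def test_exact_linear_relation(self):
        # construct results whose -log10 p is a linear function of the rate
        mb = np.arange(0.0, 50.0 + 1e-9, 2.5)
        cm = 0.02 * mb**2  # rate = 0.04 * Mb, strictly increasing
        f = fit_monotone_interpolant(MareyMap("c", mb, cm))
        rates = np.maximum(f.derivative()(mb), 0)

        class FakeResult:
            def __init__(self, mb_pos, nlp):
                self.locus = make_locus(f"m{mb_pos}", cM=0.0, Mb=mb_pos)
                self.neg_log10_p = nlp

        results = [FakeResult(m, 2.0 + 3.0 * r) for m, r in zip(mb, rates)]
        reg = rate_vs_distortion(f, results, chromosome="c")
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope_sign == 1

    def test_too_few_loci(self):
        g, results = self._results()
        mm = filter_marey_outliers(g.loci)
        f = fit_monotone_interpolant(mm)
        reg = rate_vs_distortion(f, results[:2], chromosome="chr01")
        assert reg.r_squared is None and reg.note == "n < 3"

    def test_selection_in_low_recombination_trough_negative_slope(self):
        # markers dense in Mb but flat in cM around the middle (trough), with
        # gametic selection there: distortion peaks where the rate is lowest
        neg = 0
        for seed in range(12):
            mb = np.linspace(0, 60, 61)
            cm = np.piecewise(
                mb,
                [mb < 20, (mb >= 20) & (mb <= 40), mb > 40],
                [lambda x: x, lambda x: 20 + 0.05 * (x - 20), lambda x: 21 + (x - 40)],
            )
            design = design_from_dict({
                "n_progeny": 96, "seed": 600 + seed,
                "chromosomes": [{"name": "chr01", "length_cM": float(cm[-1]),
                                 "length_Mb": 60.0, "seg_class": "paternal"}],
            })
            # replace marker coordinates with the trough geometry
            design.maps[0].marker_cM = cm
            design.maps[0].marker_Mb = mb
            design.marker_classes["chr01"] = ["paternal"] * len(cm)
            design.selections = []
            from sdrscan.simulate import SelectionSpec
            design.selections.append(
                SelectionSpec("gametic", "chr01", 20.5, parent="paternal", t=0.80))
            g, _ = simulate_population(design)
            results = analyze(g)
            mm = filter_marey_outliers(g.loci)
            f = fit_monotone_interpolant(mm)
            reg = rate_vs_distortion(f, results, chromosome="chr01")
            if reg.slope_sign < 0:
                neg += 1
        assert neg >= 9
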