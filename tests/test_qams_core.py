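import itertools
import io

import numpy as np
import pytest

from qams.chromio import CalibrationCurve, Peak, SamplePrep
from qams.qams_core import (
    QamsQuantifier,
    RCFTable,
    assign_peaks,
    build_rcf_table,
    compare_methods,
    quantify_es,
    quantify_qams,
    read_rcf_table,
    relative_correction_factor,
    relative_retention_time,
    spectral_similarity,
    to_mass_fraction,
    write_rcf_table,
)

PUBLISHED_FACTORS = {
    "7-hydroxycholesterol": 1.5354,
    "stigmasterol": 8.2591,
    "7-ketocholesterol": 5.3021,
    "4-cholesten-3-one": 5.4305,
    "7-dehydrocholesterol": 3.0043,
}


def _curve(name, slope, wl=205.0, intercept=0.0):
    return CalibrationCurve(name, wl, slope, intercept, 1.0, 1.0, 100.0)


class TestRelativeCorrectionFactor:
    def test_published_factor_values(self, published_curves):
        table = build_rcf_table(published_curves, "cholesterol")
        rounded = table.rounded(4)
        for name, expected in PUBLISHED_FACTORS.items():
            assert rounded[name] == expected
        assert table.factors["cholesterol"] == 1.0

    def test_identity(self):
        c = _curve("x", 100.0)
        assert relative_correction_factor(c, c) == 1.0

    def test_reciprocal_identity_over_all_pairs(self, published_curves):
        for a, b in itertools.permutations(published_curves, 2):
            f_ab = relative_correction_factor(a, b)
            f_ba = relative_correction_factor(b, a)
            assert f_ab * f_ba == pytest.approx(1.0, abs=1e-12)

    def test_swapped_reference_reciprocal(self, published_curves):
        table = build_rcf_table(published_curves, "stigmasterol")
        forward = build_rcf_table(published_curves, "cholesterol")
        assert table.factors["cholesterol"] == pytest.approx(
            206.39 / 1704.6, rel=1e-12)
        assert table.factors["cholesterol"] == pytest.approx(
            1.0 / forward.factors["stigmasterol"], abs=1e-9)

    def test_scale_invariance(self, published_curves):
        table = build_rcf_table(published_curves, "cholesterol")
        scaled = [
            CalibrationCurve(c.analyte, c.wavelength, 3.7 * c.slope_a,
                             c.intercept_b, c.r_squared, c.range_low,
                             c.range_high)
            for c in published_curves
        ]
        rescaled = build_rcf_table(scaled, "cholesterol")
        for name in table.factors:
            assert rescaled.factors[name] == pytest.approx(
                table.factors[name], rel=1e-12)

    def test_single_curve_table(self):
        table = build_rcf_table([_curve("only", 5.0)], "only")
        assert table.factors == {"only": 1.0}

    def test_missing_reference_rejected(self, published_curves):
        with pytest.raises(ValueError, match="reference"):
            build_rcf_table(published_curves, "ergosterol")

    def test_non_ignorable_intercept_warns(self):
        k = _curve("k", 100.0, intercept=2.0)  # |a/b| = 50
        s = _curve("s", 100.0)
        with pytest.warns(UserWarning, match="not ignorable"):
            relative_correction_factor(k, s)

    def test_table_round_trip(self, published_curves):
        table = build_rcf_table(published_curves, "cholesterol")
        buf = io.StringIO()
        write_rcf_table(table, buf, ndigits=None)
        back = read_rcf_table(io.StringIO(buf.getvalue()))
        assert back.factors == pytest.approx(table.factors)
        assert back.reference_slope == table.reference_slope


class TestRelativeRetentionTime:
    def test_values(self):
        assert relative_retention_time(10.0, 10.0) == 1.0
        assert relative_retention_time(12.0, 10.0) == pytest.approx(1.2)

    def test_flow_rescale_invariance(self):
        assert relative_retention_time(1.1 * 12.0, 1.1 * 10.0) == \
            pytest.approx(relative_retention_time(12.0, 10.0), rel=1e-15)

    def test_positive_required(self):
        with pytest.raises(ValueError):
            relative_retention_time(0.0, 10.0)


def _peak(apex, area=100.0, height=50.0):
    return Peak(apex_time=apex, start_time=apex - 0.2, end_time=apex + 0.2,
                height=height, area=area, width_half=0.1)


class TestAssignPeaks:
    def test_all_six_assigned(self, panel):
        rts = {"7-hydroxycholesterol": 4.5, "7-ketocholesterol": 6.0,
               "4-cholesten-3-one": 7.5, "7-dehydrocholesterol": 9.0,
               "cholesterol": 10.5, "stigmasterol": 12.5}
        peaks = [_peak(t, area=5000.0 if n == "cholesterol" else 100.0)
                 for n, t in rts.items()]
        out = assign_peaks(peaks, panel, rtt_tolerance=0.02)
        assert {a.analyte for a in out} == set(panel.names)
        for a in out:
            assert a.peak.apex_time == rts[a.analyte]
            assert abs(a.rtt_deviation) <= 0.02

    def test_missing_analyte_omitted(self, panel):
        rts = {"7-ketocholesterol": 6.0, "cholesterol": 10.5,
               "stigmasterol": 12.5}
        peaks = [_peak(t, area=5000.0 if n == "cholesterol" else 100.0)
                 for n, t in rts.items()]
        out = assign_peaks(peaks, panel, rtt_tolerance=0.02)
        assert {a.analyte for a in out} == set(rts)

    def test_decoy_outside_tolerance_ignored(self, panel):
        peaks = [_peak(10.5, area=5000.0), _peak(10.5 * 1.2 * 1.03)]
        out = assign_peaks(peaks, panel, rtt_tolerance=0.02)
        assert {a.analyte for a in out} == {"cholesterol"}

    def test_uniform_rescale_leaves_assignment(self, panel):
        rts = {"7-hydroxycholesterol": 4.5, "cholesterol": 10.5,
               "stigmasterol": 12.5}
        for c in (1.0, 1.1, 0.9):
            peaks = [_peak(c * t, area=5000.0 if n == "cholesterol" else 100.0)
                     for n, t in rts.items()]
            out = assign_peaks(peaks, panel, rtt_tolerance=0.02)
            assert {a.analyte for a in out} == set(rts)
            for a in out:
                assert a.rtt_observed == pytest.approx(
                    panel[a.analyte].expected_rtt, rel=1e-12)

    def test_no_reference_candidate_raises(self, panel):
        with pytest.raises(ValueError, match="reference"):
            assign_peaks([], panel)

    def test_reference_window_restricts_choice(self, panel):
        # huge early decoy would win on area; the window excludes it
        peaks = [_peak(2.0, area=9999.0), _peak(10.5, area=5000.0)]
        out = assign_peaks(peaks, panel, rtt_tolerance=0.02,
                           reference_window=(10.0, 11.0))
        ref = next(a for a in out if a.analyte == "cholesterol")
        assert ref.peak.apex_time == 10.5

    def test_exact_tie_is_ambiguous(self, panel):
        # two identical-area peaks symmetric around the expected position
        exp = 10.5 * panel["stigmasterol"].expected_rtt
        peaks = [_peak(10.5, area=5000.0),
                 _peak(exp * 1.01, area=100.0), _peak(exp * 0.99, area=100.0)]
        with pytest.raises(ValueError, match="ambiguous"):
            assign_peaks(peaks, panel, rtt_tolerance=0.02)

    def test_no_double_assignment(self, panel):
        peaks = [_peak(10.5, area=5000.0), _peak(12.5, area=100.0)]
        out = assign_peaks(peaks, panel, rtt_tolerance=0.2)
        ids = [id(a.peak) for a in out]
        apexes = [a.peak.apex_time for a in out]
        assert len(set(apexes)) == len(apexes)


class TestSpectralSimilarity:
    def _spec(self):
        wl = np.linspace(200, 400, 41)
        return wl, np.exp(-0.5 * ((wl - 280) / 20.0) ** 2)

    def test_identical_is_one(self):
        wl, y = self._spec()
        assert spectral_similarity((wl, y), (wl, y)) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        wl, y = self._spec()
        assert spectral_similarity((wl, y), (wl, -y)) == pytest.approx(-1.0)

    def test_scale_invariance(self):
        wl, y = self._spec()
        assert spectral_similarity((wl, y), (wl, 7.0 * y)) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        wl, y = self._spec()
        with pytest.raises(ValueError, match="zero-variance"):
            spectral_similarity((wl, y), (wl, np.ones_like(y)))

    def test_overlap_required(self):
        wl, y = self._spec()
        with pytest.raises(ValueError, match="overlap"):
            spectral_similarity((wl, y), (wl + 500, y))


class TestQuantification:
    def test_qams_inverts_simulated_area(self, published_curves):
        table = build_rcf_table(published_curves, "cholesterol")
        area = 316.9 * 10.0
        conc = quantify_qams(area, table, "7-hydroxycholesterol")
        assert conc == pytest.approx(10.0, rel=1e-4)

    def test_reference_identity(self, published_curves):
        table = build_rcf_table(published_curves, "cholesterol")
        assert quantify_qams(206.39 * 5.0, table, "cholesterol") == \
            pytest.approx(5.0, rel=1e-15)

    def test_zero_area(self, published_curves):
        table = build_rcf_table(published_curves, "cholesterol")
        assert quantify_qams(0.0, table, "stigmasterol") == 0.0

    def test_unknown_analyte(self, published_curves):
        table = build_rcf_table(published_curves, "cholesterol")
        with pytest.raises(KeyError):
            quantify_qams(1.0, table, "ergosterol")

    def test_es_equals_qams_for_zero_intercepts(self):
        curves = [_curve("ref", 206.39), _curve("k", 316.9)]
        table = build_rcf_table(curves, "ref")
        for area in (0.0, 1.0, 123.456, 9.9e5):
            es = quantify_es(area, curves[1])
            qa = quantify_qams(area, table, "k")
            assert qa == pytest.approx(es, rel=1e-12, abs=1e-15)

    def test_es_published_arithmetic(self, published_curves):
        chol = next(c for c in published_curves if c.analyte == "cholesterol")
        with pytest.warns(UserWarning, match="outside"):
            assert quantify_es(2063.9, chol) == pytest.approx(
                (2063.9 + 1.93) / 206.39)

    @pytest.mark.parametrize(
        "conc,mass,volume,expected",
        [(74.30, 2.0, 2.0, 74.30), (0.0, 2.0, 2.0, 0.0), (10.0, 1.0, 2.0, 20.0)],
    )
    def test_mass_fraction(self, conc, mass, volume, expected):
        prep = SamplePrep(sample_mass=mass, extract_volume=volume)
        assert to_mass_fraction(conc, prep) == pytest.approx(expected)


class TestCompareMethods:
    def test_batch_arithmetic(self):
        errors, max_abs, flagged = compare_methods(
            {"7-hydroxycholesterol": 75.1}, {"7-hydroxycholesterol": 75.2})
        assert errors["7-hydroxycholesterol"] == pytest.approx(0.13316, rel=1e-3)
        assert not flagged

    def test_identical_vectors(self):
        vals = {"a": 1.0, "b": 2.0}
        errors, max_abs, flagged = compare_methods(vals, dict(vals))
        assert max_abs == 0.0 and not flagged
        assert all(v == 0.0 for v in errors.values())

    def test_exceedance_flagged(self):
        errors, max_abs, flagged = compare_methods({"a": 100.0}, {"a": 103.0})
        assert errors["a"] == pytest.approx(3.0)
        assert flagged

    def test_zero_es_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compare_methods({"a": 0.0}, {"a": 1.0})

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            compare_methods({"a": 1.0}, {"b": 1.0})


class TestQamsQuantifierEstimator:
    def test_fit_predict_mapping(self, published_curves):
        est = QamsQuantifier(reference="cholesterol").fit(published_curves)
        conc = est.predict({c.analyte: c.slope_a * 5.0
                            for c in published_curves})
        assert np.allclose(conc, 5.0, rtol=1e-12)

    def test_es_mode_matches_inversion(self, published_curves):
        import warnings

        est = QamsQuantifier(reference="cholesterol", mode="es")
        est.fit(published_curves)
        areas = np.array([[c.slope_a * 7.0 + c.intercept_b
                           for c in published_curves]])
        order = {c.analyte: i for i, c in enumerate(published_curves)}
        areas = areas[:, [order[n] for n in est.analytes_]]
        assert np.allclose(est.predict(areas), 7.0, rtol=1e-12)

    def test_get_params_round_trip(self):
        est = QamsQuantifier(reference="x", mode="es")
        assert QamsQuantifier(**est.get_params()).get_params() == \
            est.get_params()
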