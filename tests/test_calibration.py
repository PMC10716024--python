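import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpsize.calibration import (
    CalibrationCurve,
    CalibrationPoint,
    build_linear_calibration,
    convert_bp_to_bases,
    convert_mass_diff_to_bases,
    delta_contrast_to_bases,
    load_calibration,
    point_leverage,
    predict_response,
    save_calibration,
    theoretical_conversion_factor_kda,
)
from mpsize.errors import DegenerateCurveError, FamilyMisuseError, ValidationError


def _points(responses, contrasts, names=None):
    names = names or [f"p{i}" for i in range(len(responses))]
    return [
        CalibrationPoint(name=n, contrast=c, response=r)
        for n, c, r in zip(names, contrasts, responses)
    ]


def _curve(slope, intercept=0.0, family="protein_mass", **kw):
    unit = {"protein_mass": "kDa", "dsDNA_bp": "bp"}.get(family, "bases")
    return CalibrationCurve(
        family=family, slope=slope, intercept=intercept, response_unit=unit,
        points=[], r_squared=1.0, **kw,
    )


def _ols_oracle(x, y):
    """Normal-equation solution for y = b0 + b1 x (independent oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    b0, b1 = np.linalg.solve(X.T @ X, X.T @ y)
    return b1, b0


class TestBuildLinearCalibration:
    def test_collinear_protein_points_fit_exactly(self):
        masses = [272.0, 545.0, 670.0, 3700.0]
        pts = _points(masses, [-3e-5 * m for m in masses])
        curve = build_linear_calibration(pts, "protein_mass")
        assert curve.slope == pytest.approx(-3e-5, rel=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_points_match_normal_equation_oracle(self, rng):
        x = np.array([272.0, 545.0, 670.0])
        y = -3e-5 * x + rng.normal(0, 1e-3, size=3)
        y = np.minimum(y, 0.0)
        curve = build_linear_calibration(_points(x, y), "protein_mass")
        slope, intercept = _ols_oracle(x, y)
        assert curve.slope == pytest.approx(slope, abs=1e-12)
        assert curve.intercept == pytest.approx(intercept, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="at least 3"):
            build_linear_calibration(_points([272, 545], [-0.008, -0.016]), "protein_mass")

    def test_ssdna_zero_point_appended_as_ordinary_datum(self):
        pts = _points([5386.0, 7249.0], [-0.0474, -0.0638])
        curve = build_linear_calibration(pts, "ssDNA_plasmid_bases")
        assert len(curve.points) == 3
        assert any(p.response == 0 and p.contrast == 0 for p in curve.points)
        # the zero point is a datum, not a constraint: intercept is estimated
        slope, intercept = _ols_oracle([5386, 7249, 0], [-0.0474, -0.0638, 0.0])
        assert curve.slope == pytest.approx(slope, abs=1e-15)
        assert curve.intercept == pytest.approx(intercept, abs=1e-15)

    def test_duplicate_conflicting_responses_warn_but_kept(self):
        pts = _points([272, 272, 545], [-0.0080, -0.0082, -0.0163])
        with pytest.warns(UserWarning, match="duplicate response"):
            curve = build_linear_calibration(pts, "protein_mass")
        assert len(curve.points) == 3

    def test_including_offline_empty_point_steepens_abs_slope(self):
        # filled AAVs on a shallow line; an empty point above the line's
        # intercept pivots the regression to a steeper slope
        lengths = [3793.0, 4142.0, 4504.0, 4596.0, 4658.0]
        filled = _points(lengths, [-6.2e-6 * L - 0.12 for L in lengths])
        empty = CalibrationPoint(name="empty", contrast=-0.105, response=0.0)
        with_empty = build_linear_calibration(filled + [empty], "aav_abs_bases", include_empty=True)
        without = build_linear_calibration(filled + [empty], "aav_abs_bases", include_empty=False)
        assert abs(with_empty.slope) > abs(without.slope)
        assert without.slope == pytest.approx(-6.2e-6, rel=1e-9)

    def test_empty_point_changes_slope_iff_off_the_filled_line(self):
        lengths = [3793.0, 4142.0, 4504.0, 4596.0]
        filled = _points(lengths, [-6.2e-6 * L - 0.12 for L in lengths])
        on_line = CalibrationPoint(name="empty", contrast=-0.12, response=0.0)
        a = build_linear_calibration(filled + [on_line], "aav_abs_bases", include_empty=True)
        b = build_linear_calibration(filled, "aav_abs_bases", include_empty=False)
        assert a.slope == pytest.approx(b.slope, rel=1e-9)


class TestPredictResponse:
    def test_exact_inversion(self):
        assert predict_response(_curve(-3e-5), -0.111) == pytest.approx(3700.0)

    def test_contrast_at_intercept_predicts_zero(self):
        assert predict_response(_curve(-3e-5, intercept=-0.01), -0.01) == 0.0

    def test_zero_slope_raises(self):
        with pytest.raises(DegenerateCurveError):
            predict_response(_curve(0.0), -0.1)

    def test_negative_prediction_flagged(self):
        with pytest.warns(UserWarning, match="negative predicted"):
            predict_response(_curve(-3e-5), 0.01)

    @settings(deadline=None, max_examples=100)
    @given(
        slope=st.floats(-1e-3, -1e-7, allow_nan=False),
        intercept=st.floats(-0.05, 0.0),
        x=st.floats(0.0, 1e5),
    )
    def test_round_trip_identity(self, slope, intercept, x):
        curve = _curve(slope, intercept)
        got = predict_response(curve, slope * x + intercept)
        assert got == pytest.approx(x, rel=1e-9, abs=1e-9)


class TestConversions:
    @pytest.mark.parametrize(
        "kda,bases",
        [(309.0, 1000.0), (0.0, 0.0), (1172.037, 3793.0), (-309.0, -1000.0)],
    )
    def test_mass_to_bases(self, kda, bases):
        assert convert_mass_diff_to_bases(kda) == pytest.approx(bases, rel=1e-12)

    @pytest.mark.parametrize("bp,bases", [(0, 0), (100, 200), (2329, 4658)])
    def test_bp_to_bases_doubles(self, bp, bases):
        assert convert_bp_to_bases(bp) == bases

    def test_conversion_factor_matches_mean_dnmp_residue_mass(self):
        # mean dNMP chain-residue mass per 1,000 bases reproduces 309 kDa
        assert theoretical_conversion_factor_kda(1000.0) == pytest.approx(309.0, abs=0.5)


class TestDeltaContrastToBases:
    def test_protein_chain(self):
        # slope -3e-5 contrast/kDa: -0.0309 -> 1,030 kDa -> 3,333.3 bases
        got = delta_contrast_to_bases(_curve(-3e-5), -0.0309)
        assert got == pytest.approx(1030.0 * 1000.0 / 309.0, rel=1e-12)
        assert got == pytest.approx(3333.33, abs=0.01)

    def test_dsdna_chain_doubles(self):
        got = delta_contrast_to_bases(_curve(-2e-5, family="dsDNA_bp"), -0.04)
        assert got == pytest.approx(4000.0, rel=1e-12)

    @pytest.mark.parametrize("family", ["protein_mass", "dsDNA_bp", "RNA_bases"])
    def test_zero_delta_gives_zero_bases(self, family):
        assert delta_contrast_to_bases(_curve(-1e-5, intercept=-0.3, family=family), 0.0) == 0.0

    def test_intercept_cancels_for_difference_families(self):
        a = delta_contrast_to_bases(_curve(-3e-5, intercept=0.0), -0.02)
        b = delta_contrast_to_bases(_curve(-3e-5, intercept=-0.7), -0.02)
        assert a == b

    def test_aav_delta_family_uses_its_intercept(self):
        curve = _curve(-8.8e-6, intercept=-0.001, family="aav_delta_bases")
        assert delta_contrast_to_bases(curve, -0.042) == pytest.approx(
            (-0.042 + 0.001) / -8.8e-6
        )

    def test_abs_family_is_a_misuse(self):
        with pytest.raises(FamilyMisuseError):
            delta_contrast_to_bases(_curve(-8.8e-6, family="aav_abs_bases"), -0.01)

    def test_linear_and_origin_preserving_in_delta(self):
        curve = _curve(-3e-5)
        d = -0.01
        assert delta_contrast_to_bases(curve, 2 * d) == pytest.approx(
            2 * delta_contrast_to_bases(curve, d), rel=1e-12
        )


class TestPointLeverage:
    @staticmethod
    def _leverage_oracle(x):
        x = np.asarray(x, float)
        return 1 / x.size + (x - x.mean()) ** 2 / np.sum((x - x.mean()) ** 2)

    def test_zero_base_point_dominates_the_study_response_set(self):
        responses = [0.0, 3793.0, 4142.0, 4504.0, 4596.0, 4658.0]
        pts = _points(responses, [-1e-5 * r - 0.1 for r in responses])
        curve = build_linear_calibration(pts, "aav_abs_bases", include_empty=True)
        h = point_leverage(curve)
        np.testing.assert_allclose(h, self._leverage_oracle(responses), rtol=1e-12)
        i_zero = [p.response for p in curve.points].index(0.0)
        assert h[i_zero] == pytest.approx(0.973, abs=0.001)
        assert h[i_zero] == h.max()

    def test_symmetric_three_points(self):
        pts = _points([0.0, 100.0, 200.0], [0.0, -0.001, -0.002])
        curve = build_linear_calibration(pts, "aav_delta_bases")
        np.testing.assert_allclose(point_leverage(curve), [5 / 6, 1 / 3, 5 / 6], rtol=1e-12)

    def test_sum_is_two_and_bounds_hold(self, rng):
        responses = np.sort(rng.uniform(100, 5000, size=7))
        pts = _points(responses, -1e-5 * responses)
        curve = build_linear_calibration(pts, "aav_delta_bases")
        h = point_leverage(curve)
        assert h.sum() == pytest.approx(2.0, rel=1e-12)
        assert np.all(h >= 1 / len(responses) - 1e-12)
        assert np.all(h <= 1 + 1e-12)

    def test_two_points_rejected(self):
        pts = _points([100.0, 200.0], [-0.001, -0.002])
        curve = build_linear_calibration(pts, "aav_delta_bases")
        with pytest.raises(ValidationError):
            point_leverage(curve)


class TestCalibrationIO:
    def test_json_round_trip_is_bit_exact(self, tmp_path):
        pts = _points([272.0, 545.0, 670.0], [-0.00816, -0.01635, -0.0201])
        curve = build_linear_calibration(pts, "protein_mass")
        path = tmp_path / "cal.json"
        save_calibration(curve, path)
        back = load_calibration(path)
        assert back.slope == curve.slope
        assert back.intercept == curve.intercept
        assert back.r_squared == curve.r_squared
        assert back.to_dict() == curve.to_dict()
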