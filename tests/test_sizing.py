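import numpy as np
import pytest

from mpsize.calibration import (
    CalibrationCurve,
    fit_calibration_from_measurements,
)
from mpsize.errors import (
    IncompleteDisassemblyError,
    MissingPeakError,
    NoRouteError,
    ValidationError,
)
from mpsize.events_io import ContrastMeasurement
from mpsize.simulate import (
    SimConfig,
    simulate_calibrant_set,
    simulate_genome_release,
    simulate_intact_aav_sample,
)
from mpsize.sizing import (
    aggregate_study,
    build_aav_abs_calibration,
    build_aav_delta_calibration,
    estimate_resolution_limit,
    recommend_approach,
    size_approach1,
    size_approach2_abs,
    size_approach2_delta,
    size_approach3,
)


@pytest.fixture(scope="module")
def noiseless_world():
    """Noiseless simulated calibrations + one intact sample (truth 4,658)."""
    cfg = SimConfig(seed=11).noiseless()
    cfg.class_ratio["protein_mass_route"] = 1.0
    rng = cfg.rng()
    world = {"cfg": cfg}
    pairs = simulate_calibrant_set("protein_mass", cfg, rng=rng)
    world["protein"] = fit_calibration_from_measurements(pairs, "protein_mass")
    world["m"] = simulate_intact_aav_sample(4658.0, 0.5, 600, cfg, rng=rng)
    items = [
        (simulate_intact_aav_sample(L, 0.5, 600, cfg, rng=rng, sample_id=f"s{int(L)}"), L)
        for L in (3793.0, 4142.0, 4504.0, 4596.0)
    ]
    world["delta"] = build_aav_delta_calibration(items)
    world["abs"] = build_aav_abs_calibration(items, include_empty=False)
    return world


class TestApproach1:
    def test_noiseless_round_trip_recovers_truth(self, noiseless_world):
        est = size_approach1(noiseless_world["m"], noiseless_world["protein"])
        assert est == pytest.approx(4658.0, rel=1e-6)

    def test_zero_genome_sample_has_single_population(self, noiseless_world):
        cfg = noiseless_world["cfg"]
        m = simulate_intact_aav_sample(0.0, 0.5, 600, cfg, rng=cfg.rng())
        # filled and empty populations coincide: no separate filled peak
        with pytest.raises(MissingPeakError):
            size_approach1(m, noiseless_world["protein"])

    def test_missing_empty_peak_advises_spiking(self, noiseless_world):
        cfg = noiseless_world["cfg"]
        m = simulate_intact_aav_sample(4658.0, 0.0, 300, cfg, rng=cfg.rng())
        with pytest.raises(MissingPeakError, match="[Ss]pike"):
            size_approach1(m, noiseless_world["protein"])

    def test_dsdna_calibration_overestimates_by_class_ratio(self):
        cfg = SimConfig(seed=12).noiseless()
        cfg.class_ratio["protein_mass_route"] = 1.0
        rng = cfg.rng()
        curve = fit_calibration_from_measurements(
            simulate_calibrant_set("dsDNA_bp", cfg, rng=rng), "dsDNA_bp"
        )
        m = simulate_intact_aav_sample(4658.0, 0.5, 600, cfg, rng=rng)
        est = size_approach1(m, curve)
        assert est == pytest.approx(cfg.class_ratio["dsDNA_per_2bases"] * 4658.0, rel=1e-6)

    def test_wrong_family_rejected(self, noiseless_world):
        with pytest.raises(ValidationError):
            size_approach1(noiseless_world["m"], noiseless_world["delta"])


class TestApproach2:
    def test_delta_leave_one_out_noiseless_recovery(self, noiseless_world):
        est = size_approach2_delta(noiseless_world["m"], noiseless_world["delta"])
        assert est == pytest.approx(4658.0, rel=1e-6)

    def test_abs_noiseless_recovery(self, noiseless_world):
        est = size_approach2_abs(noiseless_world["m"], noiseless_world["abs"])
        assert est == pytest.approx(4658.0, rel=1e-6)

    def test_delta_invariant_under_additive_drift(self, noiseless_world):
        # drift-scale offsets (the band classification caps usable offsets)
        m, curve = noiseless_world["m"], noiseless_world["delta"]
        a = size_approach2_delta(m, curve)
        b = size_approach2_delta(m.shifted(+0.003), curve)
        assert b == pytest.approx(a, abs=1e-6)

    def test_abs_shifts_by_offset_over_slope(self, noiseless_world):
        m, curve = noiseless_world["m"], noiseless_world["abs"]
        offset = +0.001
        a = size_approach2_abs(m, curve)
        b = size_approach2_abs(m.shifted(offset), curve)
        assert b - a == pytest.approx(offset / curve.slope, rel=1e-4)

    def test_reference_mismatch_rejected(self, noiseless_world):
        with pytest.raises(ValidationError, match="reference"):
            size_approach2_delta(
                noiseless_world["m"], noiseless_world["delta"], reference_label="hmw_standard"
            )

    def test_hmw_reference_agrees_with_empty_reference_noiselessly(self):
        cfg = SimConfig(seed=13).noiseless()
        rng = cfg.rng()

        def sample(length, **kw):
            return simulate_intact_aav_sample(length, 0.0, 600, cfg, rng=rng,
                                              hmw_fraction=0.5, **kw)

        items_hmw = [(sample(L), L) for L in (3793.0, 4142.0, 4504.0, 4596.0)]
        curve_hmw = build_aav_delta_calibration(items_hmw, reference_label="hmw_standard")
        est_hmw = size_approach2_delta(
            sample(4658.0), curve_hmw, reference_label="hmw_standard"
        )
        assert est_hmw == pytest.approx(4658.0, rel=1e-6)
        # the HMW line shares the slope of the empty-reference line but has a
        # shifted intercept (3,643 vs 3,700 kDa reference mass)
        rng2 = cfg.rng()
        items_empty = [
            (simulate_intact_aav_sample(L, 0.5, 600, cfg, rng=rng2), L)
            for L in (3793.0, 4142.0, 4504.0, 4596.0)
        ]
        curve_empty = build_aav_delta_calibration(items_empty)
        assert curve_hmw.slope == pytest.approx(curve_empty.slope, rel=1e-9)
        assert curve_hmw.intercept != pytest.approx(curve_empty.intercept, abs=1e-6)

    def test_drift_degrades_abs_but_not_delta(self):
        # same events, constant offset: a1/a2-delta invariant, a2-abs not
        cfg = SimConfig(seed=14).noiseless()
        rng = cfg.rng()
        items = [
            (simulate_intact_aav_sample(L, 0.5, 600, cfg, rng=rng), L)
            for L in (3793.0, 4142.0, 4504.0, 4596.0)
        ]
        delta_curve = build_aav_delta_calibration(items)
        abs_curve = build_aav_abs_calibration(items, include_empty=False)
        m = simulate_intact_aav_sample(4658.0, 0.5, 600, cfg, rng=rng)
        shifted = m.shifted(0.002)
        assert size_approach2_delta(shifted, delta_curve) == pytest.approx(
            size_approach2_delta(m, delta_curve), abs=1e-6
        )
        assert abs(size_approach2_abs(shifted, abs_curve) - size_approach2_abs(m, abs_curve)) > 100


class TestApproach3:
    @pytest.fixture(scope="class")
    @staticmethod
    def plasmid_curve():
        cfg = SimConfig(seed=15).noiseless()
        cfg.class_ratio["ssDNA_circular"] = 1.0
        return fit_calibration_from_measurements(
            simulate_calibrant_set("ssDNA_plasmid_bases", cfg), "ssDNA_plasmid_bases"
        )

    def test_noiseless_release_recovery(self, plasmid_curve):
        cfg = SimConfig(seed=16).noiseless()
        m = simulate_genome_release(4658.0, "sds", cfg)
        assert size_approach3(m, plasmid_curve) == pytest.approx(4658.0, rel=1e-6)

    def test_intact_aav_peak_refuses_sizing(self, plasmid_curve):
        cfg = SimConfig(seed=17)
        rng = cfg.rng()
        released = simulate_genome_release(4658.0, "sds", cfg, rng=rng)
        intact = simulate_intact_aav_sample(4658.0, 0.0, 300, cfg, rng=rng)
        mixed = ContrastMeasurement(
            "mixed", np.concatenate([released.events, intact.events])
        )
        with pytest.raises(IncompleteDisassemblyError):
            size_approach3(mixed, plasmid_curve)

    def test_pure_fragments_have_no_released_peak(self, plasmid_curve, rng):
        m = ContrastMeasurement("frags", -rng.uniform(0.0, 0.029, size=400))
        with pytest.raises(MissingPeakError):
            size_approach3(m, plasmid_curve)


class TestMonotonicity:
    def test_larger_genome_gives_larger_estimate_for_every_approach(self):
        cfg = SimConfig(seed=18)
        rng = cfg.rng()
        protein = fit_calibration_from_measurements(
            simulate_calibrant_set("protein_mass", cfg, rng=rng), "protein_mass"
        )
        items = [
            (simulate_intact_aav_sample(L, 0.5, 600, cfg, rng=rng), L)
            for L in (3793.0, 4142.0, 4504.0, 4596.0)
        ]
        delta_curve = build_aav_delta_calibration(items)
        abs_curve = build_aav_abs_calibration(items, include_empty=False)
        m_small = simulate_intact_aav_sample(4200.0, 0.5, 600, cfg, rng=rng)
        m_large = simulate_intact_aav_sample(4658.0, 0.5, 600, cfg, rng=rng)
        for sizer, curve in [
            (size_approach1, protein),
            (size_approach2_delta, delta_curve),
            (size_approach2_abs, abs_curve),
        ]:
            assert sizer(m_small, curve) < sizer(m_large, curve)


class TestAggregateStudy:
    def test_published_style_accuracy_and_cv_arithmetic(self):
        # day means 3,900/3,991/4,082 -> mean 3,991, SD 91 vs expected 3,793
        per_m = [("m1", "d1", 3900.0), ("m2", "d2", 3991.0), ("m3", "d3", 4082.0)]
        est = aggregate_study(per_m, expected=3793.0)
        assert est.mean_bases == pytest.approx(3991.0)
        assert est.sd_bases == pytest.approx(91.0)
        d = est.display()
        assert d["accuracy_percent"] == 105
        assert d["cv_percent"] == 2.3

    def test_within_day_mean_then_across_day_statistics(self, rng):
        per_m = [
            (f"m{i}", f"d{1 + i % 3}", float(v))
            for i, v in enumerate(rng.normal(4500, 100, size=10))
        ]
        est = aggregate_study(per_m)
        # oracle: direct recomputation
        days = {}
        for _, d, v in per_m:
            days.setdefault(d, []).append(v)
        day_means = np.array([np.mean(v) for v in days.values()])
        assert est.mean_bases == pytest.approx(day_means.mean(), rel=1e-12)
        assert est.sd_bases == pytest.approx(day_means.std(ddof=1), rel=1e-12)
        assert est.cv_percent == pytest.approx(
            100 * day_means.std(ddof=1) / day_means.mean(), rel=1e-12
        )

    def test_identical_day_means_give_zero_sd_and_full_accuracy(self):
        per_m = [("m1", "d1", 4000.0), ("m2", "d2", 4000.0), ("m3", "d3", 4000.0)]
        est = aggregate_study(per_m, expected=4000.0)
        assert est.sd_bases == 0.0
        assert est.display()["cv_percent"] == 0.0
        assert est.display()["accuracy_percent"] == 100

    def test_single_day_reports_sd_not_applicable(self):
        est = aggregate_study([("m1", "d1", 4000.0), ("m2", "d1", 4100.0)])
        assert est.sd_bases is None
        assert est.cv_percent is None

    def test_unknown_expected_omits_accuracy(self):
        est = aggregate_study([("m1", "d1", 4000.0)])
        assert est.accuracy_percent is None


class TestResolutionLimit:
    def _bases_curve(self, slope):
        return CalibrationCurve(
            family="aav_delta_bases", slope=slope, intercept=0.0,
            response_unit="bases", points=[], r_squared=1.0,
        )

    def test_fwhm_criterion_gives_about_400_bases(self):
        curve = self._bases_curve(-8.8e-6)
        assert estimate_resolution_limit(0.0015, curve) == pytest.approx(401.4, abs=0.5)

    def test_zero_sigma_limit_is_zero(self):
        assert estimate_resolution_limit(0.0, self._bases_curve(-8.8e-6)) == 0.0

    def test_linear_in_sigma(self):
        curve = self._bases_curve(-8.8e-6)
        assert estimate_resolution_limit(0.003, curve) == pytest.approx(
            2 * estimate_resolution_limit(0.0015, curve), rel=1e-12
        )

    def test_mass_family_slope_converted_per_base(self):
        curve = CalibrationCurve(
            family="protein_mass", slope=-2.848e-5, intercept=0.0,
            response_unit="kDa", points=[], r_squared=1.0,
        )
        # contrast per base = slope * 0.309 kDa/base
        expected = 2.355 * 0.0015 / (2.848e-5 * 0.309)
        assert estimate_resolution_limit(0.0015, curve) == pytest.approx(expected, rel=1e-12)


class TestRecommendApproach:
    def test_aav_set_with_reference_prefers_delta_contrast(self):
        rec = recommend_approach(
            {"has_aav_calibration_set": True, "has_empty_reference": True}
        )
        assert rec.approach == "a2_delta"

    def test_reference_and_protein_without_aav_set_is_fastest_route(self):
        rec = recommend_approach(
            {"has_empty_reference": True, "has_protein_calibrants": True}
        )
        assert rec.approach == "a1"

    def test_release_route_needs_no_aav_material(self):
        rec = recommend_approach(
            {"has_ss_nucleic_calibrants": True, "can_release_genome": True}
        )
        assert rec.approach == "a3"

    def test_aav_set_without_reference_uses_absolute_contrast(self):
        rec = recommend_approach({"has_aav_calibration_set": True})
        assert rec.approach == "a2_abs"

    def test_nothing_available_raises(self):
        with pytest.raises(NoRouteError):
            recommend_approach({})
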