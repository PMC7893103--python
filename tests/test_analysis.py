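"""Sensitivity derivation, logistic fitting, alignment, synthetic data."""

import numpy as np
import pandas as pd
import pytest

from circlight import (
    CSParams,
    DoseResponseCurve,
    ExposureContext,
    SuppressionDataset,
    align_log_shift,
    cla_for_target_cs,
    criterion_level,
    derive_relative_sensitivity,
    fit_duration_exponent,
    fit_half_saturation,
    generate_synthetic_dataset,
    predict_suppression_curve,
    simulate_dose_response,
)
from circlight.errors import (
    AlignmentError,
    DegenerateFitError,
    OutOfRangeError,
    ValidationError,
)


def logistic_curve(levels, half_sat=355.7, t=1.0, f=1.0):
    levels = np.asarray(levels, dtype=float)
    resp = 0.7 * (1.0 - 1.0 / (1.0 + (t * f * levels / half_sat) ** 1.1026))
    return DoseResponseCurve(levels, resp)


class TestPredictSuppressionCurve:
    def test_monotone_and_dim_limit(self, fns):
        levels = np.logspace(-2, 4, 25)
        curve = predict_suppression_curve(460.0, 10.0, levels, fns=fns)
        assert np.all(np.diff(curve.responses) >= 0)
        assert curve.responses[0] < 1e-3

    def test_blue_reaches_criterion_at_lower_irradiance_than_orange(self, fns):
        from circlight import generate_spd, scale_spd_to, total_irradiance

        levels = np.logspace(-1, 5, 60)
        criterion_irradiance = {}
        for center in (460.0, 600.0):
            curve = predict_suppression_curve(center, 10.0, levels, fns=fns)
            slx = criterion_level(curve, 0.35)
            spd = generate_spd("narrowband", {"center_nm": center, "fwhm_nm": 10.0}, fns.grid)
            spd = scale_spd_to(spd, "scotopic_lux", slx, fns)
            criterion_irradiance[center] = total_irradiance(spd)
        assert criterion_irradiance[460.0] < criterion_irradiance[600.0]


class TestCriterionLevel:
    def test_recovers_half_saturation_from_logistic(self):
        curve = logistic_curve(np.logspace(0, 5, 60))
        assert criterion_level(curve, 0.35) == pytest.approx(355.7, rel=1e-3)

    def test_boundary_criterion_returns_first_level(self):
        curve = logistic_curve(np.logspace(0, 4, 20))
        assert criterion_level(curve, curve.responses[0]) == curve.levels[0]

    def test_unreachable_criterion_names_side(self):
        curve = logistic_curve(np.logspace(0, 4, 20))
        with pytest.raises(OutOfRangeError) as err:
            criterion_level(curve, 0.9)
        assert err.value.side == "high"


@pytest.fixture(scope="module")
def sensitivity_curve(fns):
    return derive_relative_sensitivity(np.arange(400.0, 655.0, 5.0), fns=fns)


class TestRelativeSensitivity:

    def test_peak_near_460(self, sensitivity_curve):
        """Constant-criterion peak lies in the short-wavelength blue region."""
        peak = sensitivity_curve.wavelengths[int(np.argmax(sensitivity_curve.relative_sensitivity))]
        assert 450.0 <= peak <= 470.0

    def test_self_normalized(self, sensitivity_curve):
        assert sensitivity_curve.relative_sensitivity.max() == 1.0
        assert np.sum(sensitivity_curve.relative_sensitivity == 1.0) == 1

    def test_orange_less_sensitive_than_cyan(self, sensitivity_curve):
        s = dict(zip(sensitivity_curve.wavelengths, sensitivity_curve.relative_sensitivity))
        assert s[600.0] < s[500.0]

    def test_rescaling_invariance_of_ratios(self, sensitivity_curve):
        """The criterion method is ratio-based: scaling all criterion
        irradiances by a constant leaves relative sensitivity unchanged."""
        irr = sensitivity_curve.meta["criterion_irradiance_w_m2"]
        scaled = {w: 7.3 * v for w, v in irr.items()}
        best = min(scaled.values())
        rebuilt = np.array([best / scaled[w] for w in sensitivity_curve.wavelengths])
        np.testing.assert_allclose(rebuilt, sensitivity_curve.relative_sensitivity, rtol=1e-12)

    def test_criterion_inverts_prediction(self, fns):
        """criterion_level on a predicted curve matches the direct inversion."""
        ctx = ExposureContext()
        levels = np.logspace(-1, 4, 120)
        curve = predict_suppression_curve(460.0, 10.0, levels, ctx=ctx, fns=fns)
        slx = criterion_level(curve, 0.35)
        # at the interpolated level, cla_2020 should equal the inverted target
        from circlight import cla_2020, generate_spd, scale_spd_to

        spd = generate_spd("narrowband", {"center_nm": 460.0, "fwhm_nm": 10.0}, fns.grid)
        spd = scale_spd_to(spd, "scotopic_lux", slx, fns)
        assert cla_2020(spd, fns) == pytest.approx(cla_for_target_cs(0.35, ctx), rel=0.02)


class TestFitHalfSaturation:
    def test_noiseless_self_consistency(self):
        data = simulate_dose_response(np.logspace(1, 4, 8), half_sat=500.0)
        fit = fit_half_saturation(data)
        assert fit.half_sat_estimate == pytest.approx(500.0, rel=1e-3)
        assert fit.r_squared > 0.9999

    def test_monte_carlo_recovery(self):
        """>= 90% of noisy study replicates (8 levels spanning the dynamic
        range, panel means of 8 subjects) recover the half-saturation within 5%."""
        hits = 0
        levels = np.logspace(np.log10(500.0) - 0.6, np.log10(500.0) + 0.6, 8)
        for seed in range(100):
            data = simulate_dose_response(levels, half_sat=500.0, noise_sigma=0.03, seed=seed)
            fit = fit_half_saturation(data)
            if abs(fit.half_sat_estimate - 500.0) / 500.0 < 0.05:
                hits += 1
        assert hits >= 90

    def test_degenerate_identical_responses(self):
        table = pd.DataFrame(
            {
                "spd_label": "x",
                "level": [10.0, 100.0, 1000.0],
                "level_units": "cla",
                "t_hours": 1.0,
                "f_factor": 1.0,
                "suppression": [0.2, 0.2, 0.2],
            }
        )
        with pytest.raises(DegenerateFitError):
            fit_half_saturation(SuppressionDataset(table))

    def test_two_distinct_levels_rejected(self):
        table = pd.DataFrame(
            {
                "spd_label": "x",
                "level": [10.0, 100.0],
                "level_units": "cla",
                "t_hours": 1.0,
                "f_factor": 1.0,
                "suppression": [0.1, 0.3],
            }
        )
        with pytest.raises(DegenerateFitError):
            fit_half_saturation(SuppressionDataset(table))


class TestAlignment:
    def test_identity(self):
        curve = logistic_curve(np.logspace(0, 5, 40))
        assert abs(align_log_shift(curve, curve)) < 1e-6

    def test_constructed_translation(self):
        a = logistic_curve(np.logspace(0, 5, 40))
        b = DoseResponseCurve(a.levels * 10**0.3, a.responses)
        assert align_log_shift(a, b) == pytest.approx(-0.3, abs=0.01)

    def test_duration_curves_shift_by_log_duration_ratio(self):
        """Curves for t=0.5 vs t=1.5 differ by a log10(3) lateral shift."""
        levels = np.logspace(0, 5, 50)
        short = logistic_curve(levels, t=0.5)
        long = logistic_curve(levels, t=1.5)
        shift = align_log_shift(short, long)
        assert abs(shift) == pytest.approx(np.log10(3.0), abs=0.02)

    def test_disjoint_response_ranges_rejected(self):
        lo = DoseResponseCurve(np.array([1.0, 2.0, 4.0]), np.array([0.0, 0.01, 0.02]))
        hi = DoseResponseCurve(np.array([1.0, 2.0, 4.0]), np.array([0.5, 0.6, 0.69]))
        with pytest.raises(AlignmentError):
            align_log_shift(lo, hi)


class TestDurationExponentFit:
    def test_exact_pairs(self):
        pairs = [(0.5, 711.4), (1.0, 355.7), (2.0, 177.85), (3.0, 355.7 / 3.0)]
        expo, r2 = fit_duration_exponent(pairs)
        assert expo == pytest.approx(-1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery(self):
        """Mean exponent over 100 noisy replicates within 0.1 of -1."""
        rng = np.random.default_rng(5)
        estimates = []
        ts = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        for _ in range(100):
            hs = 355.7 / ts * (1.0 + 0.05 * rng.standard_normal(ts.size))
            expo, _ = fit_duration_exponent(zip(ts, hs))
            estimates.append(expo)
        assert abs(np.mean(estimates) + 1.0) < 0.1

    def test_free_coefficient_variant(self):
        pairs = [(0.5, 2 * 711.4), (1.0, 2 * 355.7), (2.0, 2 * 177.85)]
        expo, r2 = fit_duration_exponent(pairs, fix_coefficient=False)
        assert expo == pytest.approx(-1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            fit_duration_exponent([(1.0, 355.7), (2.0, 177.85)])

    def test_nonpositive_half_sat(self):
        with pytest.raises(ValidationError):
            fit_duration_exponent([(0.5, 711.4), (1.0, 0.0), (2.0, 177.85)])


class TestSyntheticDataset:
    PROTOCOL = [
        {
            "spd": {"kind": "narrowband", "params": {"center_nm": 460.0}},
            "level": lv,
            "level_units": "scotopic_lux",
            "t": 1.0,
            "f": 1.0,
        }
        for lv in (30.0, 100.0, 300.0, 1000.0, 3000.0)
    ]

    def test_zero_noise_matches_model(self, fns):
        from circlight import cs_tf as _cs_tf

        data = generate_synthetic_dataset(self.PROTOCOL, noise_sigma=0.0, fns=fns)
        for _, row in data.table.iterrows():
            expected = _cs_tf(row["level"], ExposureContext(row["t_hours"], row["f_factor"]))
            assert row["suppression"] == pytest.approx(expected, rel=1e-12)

    def test_same_seed_identical(self, fns):
        a = generate_synthetic_dataset(self.PROTOCOL, noise_sigma=0.05, seed=3, fns=fns)
        b = generate_synthetic_dataset(self.PROTOCOL, noise_sigma=0.05, seed=3, fns=fns)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_noise_sd_matches_sigma(self):
        """Residual SD of 200 noisy samples within 15% of sigma = 0.03."""
        levels = np.full(200, 355.7)
        data = simulate_dose_response(levels.tolist(), noise_sigma=0.03, seed=9, n_per_level=1)
        # all levels equal: residuals relative to the common model prediction
        resid = data.table["suppression"] - 0.35
        assert np.std(resid) == pytest.approx(0.03, rel=0.15)

    def test_invalid_protocol_rejected(self, fns):
        with pytest.raises(ValidationError):
            generate_synthetic_dataset([{"level": 100.0}], fns=fns)

    def test_csv_round_trip(self, tmp_path, fns):
        data = generate_synthetic_dataset(self.PROTOCOL, noise_sigma=0.02, seed=1, fns=fns)
        path = tmp_path / "dataset.csv"
        data.to_csv(path)
        back = SuppressionDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.table, data.table)
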