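"""4PL calibration, inversion, limits, conversions, recovery, precision."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

import epistab as ep
from epistab.errors import InputError, NumericalError

TRUE_PARAMS = (1.8, 1.2, 4.0, 0.06)
SERIES = np.array([0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0])


def noise_free_fit(params=TRUE_PARAMS, series=SERIES):
    y = ep.eval_4pl(series, *params)
    return ep.fit_4pl(series, y)


class TestFourPL:
    def test_midpoint_identity(self):
        a, b, c, d = TRUE_PARAMS
        assert ep.eval_4pl(c, a, b, c, d) == pytest.approx((a + d) / 2, abs=1e-12)

    def test_zero_concentration_hits_upper_asymptote(self):
        assert ep.eval_4pl(0.0, *TRUE_PARAMS) == TRUE_PARAMS[0]

    def test_noise_free_parameter_recovery(self):
        fit = noise_free_fit()
        for got, true in zip((fit.a, fit.b, fit.c, fit.d), TRUE_PARAMS):
            assert got == pytest.approx(true, rel=1e-6)
        assert fit.valid_range == (0.1, 500.0)

    def test_too_few_levels_rejected(self):
        x = np.array([1.0, 5.0, 10.0])
        with pytest.raises(InputError):
            ep.fit_4pl(x, ep.eval_4pl(x, *TRUE_PARAMS))

    def test_flat_data_not_identifiable(self):
        x = np.array([1.0, 5.0, 10.0, 50.0])
        with pytest.raises(NumericalError):
            ep.fit_4pl(x, np.full(4, 0.9))

    @pytest.mark.parametrize("noise_cv", [0.0, 0.01, 0.05])
    def test_recovery_error_shrinks_with_noise(self, noise_cv):
        rng = np.random.default_rng(17)
        x = np.repeat(SERIES, 3)
        y = ep.eval_4pl(x, *TRUE_PARAMS) * (1 + rng.normal(0, noise_cv, x.size))
        fit = ep.fit_4pl(x, y)
        rel_err = abs(fit.c - TRUE_PARAMS[2]) / TRUE_PARAMS[2]
        assert rel_err <= max(1e-6, 10 * noise_cv)


class TestInversion:
    def test_midpoint_inverts_to_c(self):
        fit = noise_free_fit()
        a, _, c, d = TRUE_PARAMS
        result = ep.invert_4pl(fit, (a + d) / 2)
        assert result.censored is None
        assert result.concentration == pytest.approx(c, rel=1e-8)

    def test_round_trip_identity(self):
        fit = noise_free_fit()
        rng = np.random.default_rng(3)
        xs = np.exp(rng.uniform(np.log(0.1), np.log(500.0), size=20))
        for x in xs:
            back = ep.invert_4pl(fit, fit(x))
            assert back.censored is None
            assert back.concentration == pytest.approx(x, rel=1e-8)

    def test_matches_root_finder_oracle(self):
        fit = noise_free_fit()
        for y in (0.2, 0.5, 0.9, 1.5):
            algebraic = ep.invert_4pl(fit, y).concentration
            numeric = brentq(lambda x: fit(x) - y, 1e-9, 1e9, xtol=1e-12, rtol=1e-14)
            assert algebraic == pytest.approx(numeric, rel=1e-6)

    def test_censoring_beyond_asymptotes(self):
        fit = noise_free_fit()
        low = ep.invert_4pl(fit, TRUE_PARAMS[0] + 0.1)
        assert low.censored == "low" and low.concentration == 0.0
        high = ep.invert_4pl(fit, TRUE_PARAMS[3])
        assert high.censored == "high" and np.isinf(high.concentration)


class TestNormalization:
    def test_b_equals_b0_gives_one(self):
        assert ep.normalize_b_over_b0(np.array([1.8]), 1.8)[0] == 1.0

    def test_zero_response(self):
        assert ep.normalize_b_over_b0(np.array([0.0]), 1.8)[0] == 0.0

    def test_nonpositive_b0_rejected(self):
        with pytest.raises(InputError):
            ep.normalize_b_over_b0(np.array([1.0]), 0.0)

    def test_non_monotone_standards_warn(self):
        plate = ep.generate_plate(ep.PlateSpec(noise_cv=0.0, seed=0))
        std = plate["role"] == "standard"
        plate.loc[std & (plate["concentration"] == 500.0), "od450"] = 1.9
        with pytest.warns(UserWarning, match="monotone"):
            ep.fit_standard_curve(plate)


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "control, sample, expected",
        [(1.0, 1.0, 0.0), (1.0, 0.0, 100.0), (1.0, 0.25, 75.0)],
    )
    def test_inhibition_rate_spot_values(self, control, sample, expected):
        assert ep.inhibition_rate(control, sample) == pytest.approx(expected)

    def test_inhibition_rate_negative_allowed(self):
        assert ep.inhibition_rate(1.0, 1.5) == pytest.approx(-50.0)

    def test_inhibition_rate_invalid_control(self):
        with pytest.raises(InputError):
            ep.inhibition_rate(0.0, 0.5)

    def test_inhibition_strictly_decreasing_in_sample_od(self):
        samples = np.linspace(0, 2, 30)
        rates = [ep.inhibition_rate(1.3, s) for s in samples]
        assert np.all(np.diff(rates) < 0)

    def test_pn_series_and_cutoff(self):
        series = ep.pn_series([1.0, 2.0, 4.0, 8.0], [1.5, 2.0, 2.2, 3.0], 1.0)
        assert ep.min_effective_concentration(series) == 4.0

    def test_pn_equal_not_effective(self):
        series = ep.pn_series([1.0], [0.8], 0.8)
        assert series["pn"].iloc[0] == 1.0
        assert ep.min_effective_concentration(series) is None

    def test_pn_all_below_cutoff(self):
        series = ep.pn_series([1.0, 2.0], [1.0, 2.0], 1.0)
        assert ep.min_effective_concentration(series) is None

    def test_pn_invalid_negative_control(self):
        with pytest.raises(InputError):
            ep.pn_series([1.0], [1.0], 0.0)


class TestDetectionLimits:
    def test_hand_computed_blanks(self):
        lod, loq, mean, sd, n = ep.lod_loq([0.01, 0.02, 0.03])
        assert mean == pytest.approx(0.02)
        assert sd == pytest.approx(0.01)
        assert lod == pytest.approx(0.05)
        assert loq == pytest.approx(0.12)
        assert n == 3

    def test_degenerate_equal_blanks(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lod, loq, *_ = ep.lod_loq([0.04] * 5)
        assert lod == loq == pytest.approx(0.04)

    def test_too_few_blanks(self):
        with pytest.raises(InputError):
            ep.lod_loq([0.01])

    def test_sampling_oracle_converges(self):
        # ten-blank design, repeated: the average LOD approaches mu + 3 sigma
        mu, sigma, reps = 0.02, 0.01, 200
        rng = np.random.default_rng(42)
        lods = []
        for _ in range(reps):
            blanks = rng.normal(mu, sigma, size=10)
            lods.append(ep.lod_loq(blanks)[0])
        lods = np.asarray(lods)
        se = lods.std(ddof=1) / np.sqrt(reps)
        assert abs(lods.mean() - (mu + 3 * sigma)) < 3 * se

    @given(
        st.lists(
            st.floats(0.0, 1.0, allow_nan=False, width=32), min_size=2, max_size=12
        )
    )
    def test_lod_never_exceeds_loq(self, blanks):
        lod, loq, *_ = ep.lod_loq(blanks)
        assert lod <= loq + 1e-12


class TestUnitConversions:
    def test_reported_chain_values(self):
        assert ep.convert_to_food(0.025, 10) == pytest.approx(0.25)
        assert ep.convert_to_food(0.107, 10) == pytest.approx(1.07)
        assert ep.milk_protein_equivalent(0.25, 0.10) == pytest.approx(2.5)
        assert ep.milk_protein_equivalent(1.07, 0.10) == pytest.approx(10.7)

    def test_zero_and_identity(self):
        assert ep.convert_to_food(0.0, 10) == 0.0
        assert ep.milk_protein_equivalent(3.3, 1.0) == pytest.approx(3.3)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_invalid_factors(self, bad):
        with pytest.raises(InputError):
            ep.convert_to_food(1.0, bad)
        with pytest.raises(InputError):
            ep.milk_protein_equivalent(1.0, bad)

    @given(
        st.floats(0, 1e3, allow_nan=False),
        st.floats(0.1, 100, allow_nan=False),
        st.floats(0.01, 1.0, allow_nan=False),
    )
    def test_chain_is_exactly_linear(self, x, k, fraction):
        chained = ep.milk_protein_equivalent(ep.convert_to_food(x, k), fraction)
        assert chained == pytest.approx(x * k / fraction, rel=1e-12)


class TestRecoveryAndPrecision:
    def test_recovery_spot_values(self):
        assert ep.recovery(1.5, 1.5) == pytest.approx(100.0)
        assert ep.recovery(1.266, 1.5) == pytest.approx(84.4)
        assert ep.recovery(0.0, 1.5) == 0.0
        with pytest.raises(InputError):
            ep.recovery(1.0, 0.0)

    def test_identical_values_zero_cv(self):
        panel = ep.precision_panel([2.0] * 25, [[2.0] * 5] * 5)
        assert panel.intra_cv == 0.0
        assert panel.inter_cv == 0.0

    def test_hand_computed_cv(self):
        panel = ep.precision_panel([1.0, 2.0, 3.0], [[1.0, 3.0], [2.0, 2.0]])
        assert panel.intra_mean == pytest.approx(2.0)
        assert panel.intra_sd == pytest.approx(1.0)
        assert panel.intra_cv == pytest.approx(50.0)
        assert panel.day_means == (2.0, 2.0)

    def test_insufficient_replicates(self):
        with pytest.raises(InputError):
            ep.precision_panel([1.0], [[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(InputError):
            ep.precision_panel([1.0, 2.0], [[1.0, 2.0]])

    def test_cv_sampling_oracle(self):
        # 25 replicates at 8% multiplicative noise: mean estimated CV -> 8%
        rng = np.random.default_rng(7)
        reps, cv = 100, 0.08
        estimates = []
        for _ in range(reps):
            values = 2.0 * (1 + rng.normal(0, cv, size=25))
            estimates.append(ep.precision_panel(values, [[1.0] * 5] * 5).intra_cv)
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(reps)
        assert abs(estimates.mean() - 100 * cv) < 3 * se


class TestCensoring:
    @pytest.fixture()
    def limits(self):
        return ep.detection_limits([0.01, 0.02, 0.03])  # LOD 0.05, LOQ 0.12

    def make_results(self, *concs):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(concs))],
                "concentration_solution": list(concs),
            }
        )

    def test_boundaries(self, limits):
        table = ep.censor_and_report(
            self.make_results(
                0.1 * limits.lod_solution,
                limits.lod_solution,
                limits.loq_solution,
                2 * limits.loq_solution,
            ),
            limits,
        )
        assert table["censoring"].tolist() == [
            "below_lod",
            "below_loq",
            "quantified",
            "quantified",
        ]
        assert table["display_food_mg_per_kg"].tolist()[:2] == ["<LOD", "<LOQ"]
        expected_food = 2 * limits.loq_solution * limits.dilution_factor
        assert table["display_food_mg_per_kg"].iloc[3] == f"{expected_food:.2f}"

    def test_missing_column(self, limits):
        with pytest.raises(InputError):
            ep.censor_and_report(pd.DataFrame({"x": [1.0]}), limits)


class TestAnalyzePlate:
    def test_zero_noise_end_to_end_exact(self):
        truth = {"S_low": 0.5, "S_mid": 4.0, "S_high": 40.0}
        spec = ep.PlateSpec(
            true_params=TRUE_PARAMS,
            noise_cv=0.0,
            seed=1,
            sample_true_concentrations=truth,
        )
        analysis = ep.analyze_plate(ep.generate_plate(spec))
        for _, row in analysis.samples.iterrows():
            assert row["concentration_solution"] == pytest.approx(
                truth[row["sample_id"]], rel=1e-6
            )
            assert row["concentration_food"] == pytest.approx(
                truth[row["sample_id"]] * 10, rel=1e-6
            )

    def test_noisy_mean_recovery_within_five_percent(self):
        truth = {f"S{i:03d}": 4.0 for i in range(100)}
        spec = ep.PlateSpec(
            true_params=TRUE_PARAMS,
            noise_cv=0.05,
            seed=2,
            n_replicates=3,
            sample_true_concentrations=truth,
        )
        analysis = ep.analyze_plate(ep.generate_plate(spec))
        recoveries = [
            ep.recovery(row["concentration_solution"], 4.0)
            for _, row in analysis.samples.iterrows()
        ]
        assert 95.0 <= np.mean(recoveries) <= 105.0

    def test_raw_od_scale_also_supported(self):
        spec = ep.PlateSpec(noise_cv=0.0, seed=3)
        analysis = ep.analyze_plate(ep.generate_plate(spec), response="od")
        assert analysis.b0 is None
        assert analysis.fit.a == pytest.approx(1.8, rel=1e-6)
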