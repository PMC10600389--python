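"""D_min search, parameter sweeps, landscape grids, exponential fits."""

import math

import numpy as np
import pytest

from radresponse import (
    GrowthParameters,
    ccr_model,
    combined_artifact_survey,
    dmin_grid,
    dvr_model,
    fit_exponential,
    half_open_grid,
    interior_grid,
    minimum_dose_for_lrc,
    sweep_growth_rate,
    sweep_radiosensitivity,
)


def dmin_lambda0_dvr_oracle(psi, alpha, threshold=0.322, max_fractions=40,
                            dose=2.0, ratio=10.0):
    """Brute-force discrete iteration, independent of the simulator.

    With lambda = 0 there is no inter-fraction growth, so the volume after
    n fractions is the product iteration V <- V * (1 - gamma * (1 - V/K)).
    Returns the cumulative dose at the first crossing, or None if censored.
    """
    gamma = 1.0 - math.exp(-(alpha * dose + (alpha / ratio) * dose**2))
    V, K = psi, 1.0  # only the V/K ratio matters; work in units of K
    V0 = V
    for n in range(1, max_fractions + 1):
        V = V * (1.0 - gamma * (1.0 - V / K))
        if 1.0 - V / V0 >= threshold:
            return dose * n
    return None


class TestMinimumDose:
    def test_no_treatment_effect_is_censored(self):
        params = GrowthParameters.from_psi(0.07, 0.7)
        assert minimum_dose_for_lrc(params, dvr_model(0.0)).censored
        assert minimum_dose_for_lrc(params, ccr_model(0.0)).censored

    def test_censored_result_has_no_values(self):
        r = minimum_dose_for_lrc(GrowthParameters.from_psi(0.07, 0.7), dvr_model(0.0))
        assert r.d_min is None and r.n_fractions is None and r.crossing_time is None
        assert r.d_min_or_inf == np.inf

    @pytest.mark.parametrize("psi", [0.65, 0.7, 0.8, 0.9])
    @pytest.mark.parametrize("alpha", [0.07, 0.1, 0.13])
    def test_lambda_zero_matches_discrete_oracle(self, psi, alpha):
        params = GrowthParameters.from_psi(0.0, psi)
        r = minimum_dose_for_lrc(params, dvr_model(alpha))
        expected = dmin_lambda0_dvr_oracle(psi, alpha)
        if expected is None:
            assert r.censored
        else:
            assert r.d_min == expected

    def test_dose_is_quantized_to_fraction_multiples(self):
        for model in (dvr_model(0.1), ccr_model(0.05)):
            r = minimum_dose_for_lrc(GrowthParameters.from_psi(0.07, 0.8), model)
            assert not r.censored
            assert r.d_min % 2.0 == 0.0
            assert r.d_min == r.n_fractions * 2.0
            assert r.d_min <= 80.0

    def test_threshold_monotonicity(self):
        params = GrowthParameters.from_psi(0.07, 0.8)
        doses = [
            minimum_dose_for_lrc(params, dvr_model(0.1), threshold=th).d_min_or_inf
            for th in (0.1, 0.322, 0.5, 0.9)
        ]
        assert doses == sorted(doses)

    def test_ccr_can_cross_between_fractions(self):
        # capacity-reduction shrinkage is continuous, so the crossing time
        # need not coincide with a fraction instant
        r = minimum_dose_for_lrc(
            GrowthParameters.from_psi(0.07, 0.95), ccr_model(0.02)
        )
        assert not r.censored
        frac_hours = {round((7 * w + d + 9 / 24) * 24) for w in range(8) for d in range(5)}
        assert round(r.crossing_time * 24) not in frac_hours

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            minimum_dose_for_lrc(
                GrowthParameters.from_psi(0.07, 0.7), dvr_model(0.1), threshold=1.5
            )


@pytest.fixture(scope="module")
def grids():
    psi = interior_grid(0.6, 1.0, 0.08)
    return {
        "dvr": dmin_grid("dvr", psi, interior_grid(0.06, 0.14, 0.016)),
        "ccr": dmin_grid("ccr", psi, interior_grid(0.01, 0.09, 0.016)),
    }


class TestDminGrid:
    def test_dvr_dose_rises_with_psi(self, grids):
        # censored cells (NaN) sit above every attainable dose
        m = np.nan_to_num(grids["dvr"].dmin_matrix(), nan=1e9)
        assert np.all(np.diff(m, axis=0) >= 0)

    def test_ccr_dose_falls_with_psi(self, grids):
        m = np.nan_to_num(grids["ccr"].dmin_matrix(), nan=1e9)
        assert np.all(np.diff(m, axis=0) <= 0)

    def test_dose_falls_with_radiosensitivity_in_both_models(self, grids):
        for g in grids.values():
            m = np.nan_to_num(g.dmin_matrix(), nan=1e9)
            assert np.all(np.diff(m, axis=1) <= 0)

    def test_cells_recompute_bit_exactly(self, grids):
        g = grids["dvr"]
        i, j = 2, 3
        cell = minimum_dose_for_lrc(
            GrowthParameters.from_psi(g.lambda_, g.psi_axis[i]),
            dvr_model(g.sens_axis[j]),
        )
        assert cell == g.cells[i][j]

    def test_long_and_matrix_frames(self, grids):
        g = grids["ccr"]
        long = g.to_long_frame()
        assert len(long) == g.psi_axis.size * g.sens_axis.size
        assert set(long.columns) == {
            "psi", "sensitivity", "d_min_Gy", "n_fractions", "censored",
        }
        mat = g.to_matrix_frame()
        assert mat.shape == (g.psi_axis.size, g.sens_axis.size)
        assert long["censored"].sum() == g.n_censored

    def test_iso_dose_mask(self, grids):
        g = grids["dvr"]
        mask = g.iso_dose_mask(20.0)
        m = g.dmin_matrix()
        assert np.array_equal(mask, np.isclose(m, 20.0) & ~np.isnan(m))

    def test_default_axes_stay_inside_stated_ranges(self):
        from radresponse import fig5_psi_axis, fig5_sensitivity_axis

        psi = fig5_psi_axis()
        assert 0.6 < psi.min() and psi.max() < 1.0 and psi.size == 39
        alpha = fig5_sensitivity_axis("dvr")
        assert 0.06 < alpha.min() and alpha.max() < 0.14
        delta = fig5_sensitivity_axis("ccr")
        assert 0.01 < delta.min() and delta.max() < 0.09


class TestSweeps:
    def test_radiosensitivity_sweep_default_grid(self):
        trajs = sweep_radiosensitivity("dvr")
        assert len(trajs) == 20  # (0, 0.20] step 0.01
        ends = [t.final_volume for t in trajs]
        assert np.all(np.diff(ends) < 0)

    def test_zero_sensitivity_gives_untreated_growth(self):
        from radresponse import build_weekday_schedule, grow, simulate

        t = sweep_radiosensitivity("ccr", sens_values=[0.0])[0]
        params = GrowthParameters.from_psi(0.1, 0.9)
        np.testing.assert_allclose(
            t.volumes, grow(params.V0, params.K0, 0.1, t.times), rtol=1e-12
        )

    def test_growth_rate_sweep_orderings(self):
        dvr = sweep_growth_rate("dvr")
        ccr = sweep_growth_rate("ccr")
        assert len(dvr) == len(ccr) == 10  # (0, 0.10] step 0.01
        assert np.all(np.diff([t.final_volume for t in dvr]) > 0)
        assert np.all(np.diff([t.final_volume for t in ccr]) < 0)

    def test_ccr_early_transient_ordering_reverses(self):
        # in the first week higher lambda still means a *larger* tumor
        ccr = sweep_growth_rate("ccr")
        early = [t.volume_at(2.0) for t in ccr]
        assert np.all(np.diff(early) > 0)


class TestArtifactSurvey:
    def test_majority_of_cells_spike(self):
        survey = combined_artifact_survey(
            psi_values=[0.7, 0.8, 0.9],
            alpha_values=[0.08, 0.12],
            delta_values=[0.03, 0.07],
        )
        assert survey.n_cells == 12
        assert survey.spike_fraction > 0.5

    def test_spiking_cells_are_recorded(self):
        survey = combined_artifact_survey(
            psi_values=[0.9], alpha_values=[0.12], delta_values=[0.07]
        )
        assert survey.n_spiking == len(survey.spiking_cells) == 1


class TestExponentialFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0.0, 1.0, 10)
        y = 10.0 * np.exp(2.0 * x) + 5.0
        fit = fit_exponential(x, y)
        assert fit.converged and not fit.degenerate
        assert fit.a == pytest.approx(10.0, rel=1e-6)
        assert fit.b == pytest.approx(2.0, rel=1e-6)
        assert fit.c == pytest.approx(5.0, rel=1e-6)
        assert fit.residual_norm < 1e-8

    def test_negative_amplitude_branch(self):
        x = np.linspace(0.0, 1.0, 12)
        y = -5.0 * np.exp(3.0 * x) + 60.0
        fit = fit_exponential(x, y)
        assert fit.converged
        assert fit.a == pytest.approx(-5.0, rel=1e-6)
        assert fit.b == pytest.approx(3.0, rel=1e-6)

    def test_constant_data_is_degenerate(self):
        fit = fit_exponential(np.linspace(0, 1, 6), np.full(6, 42.0))
        assert fit.degenerate
        assert fit.a == 0.0 and fit.c == pytest.approx(42.0)

    def test_predict_matches_parameters(self):
        x = np.linspace(0.0, 1.0, 8)
        y = 3.0 * np.exp(-1.5 * x) + 20.0
        fit = fit_exponential(x, y)
        np.testing.assert_allclose(fit.predict(x), y, rtol=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1, 2, 3])  # too few points
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2, 3], [1, 2, np.nan, 4])  # censored value

    def test_grid_column_fit_signs_follow_model_direction(self):
        psi = interior_grid(0.6, 1.0, 0.04)
        dvr = dmin_grid("dvr", psi, np.array([0.1]))
        ccr = dmin_grid("ccr", psi, np.array([0.05]))
        for grid, sign in ((dvr, 1), (ccr, -1)):
            col = grid.dmin_matrix()[:, 0]
            keep = ~np.isnan(col)
            fit = fit_exponential(psi[keep], col[keep], "psi")
            assert fit.converged
            assert np.sign(fit.b) == sign
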