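"""Forward model, initial estimates and the joint (A, d) WLS fit."""

import numpy as np
import pytest

from luquant.calibration import BuildupModel, SensitivityModel
from luquant.errors import DegenerateDesignError, ValidationError
from luquant.physics import AttenuationContext
from luquant.quantify import (MeasurementSet, depth_error, estimate,
                              forward_model, initial_estimate,
                              relative_deviation)
from luquant.simulate import ScenarioSpec, simulate_measurement


def measurement_from_rates(rates, duration=200.0, clamped=None):
    return MeasurementSet(
        rates=dict(rates),
        variances={w: r / duration for w, r in rates.items()},
        duration_s=duration, collimator="MEGP", scatter_corrected=True,
        clamped=clamped or {})


class TestForwardModel:
    def test_zero_depth_leaves_only_sensitivity(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        rates = forward_model(5.0, 0.0, soft_tissue_mu, sens, bu)
        for w in rates:
            assert rates[w] == pytest.approx(5.0 * (sens[w].c0 + sens[w].c1))

    def test_zero_activity_gives_zero_rates(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        assert all(r == 0.0 for r in
                   forward_model(0.0, 30.0, soft_tissue_mu, sens, bu).values())

    def test_matches_hand_evaluated_expression(self):
        sens = {113: SensitivityModel(c0=1.0, c1=10.0, c2=0.02, window=113,
                                      collimator="MEGP", scatter_corrected=True)}
        bu = {113: BuildupModel(k=0.2, window=113, collimator="MEGP",
                                scatter_corrected=True)}
        mu = AttenuationContext({113: 0.0164})
        r = forward_model(10.0, 30.0, mu, sens, bu)[113]
        x = 30.0 * 0.0164
        expected = 10.0 * (1.0 + 10.0 * np.exp(-30.0 * 0.02)) * np.exp(-x) * (1 + 0.2 * x)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_negative_depth_warns(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        with pytest.warns(UserWarning, match="negative depth"):
            forward_model(1.0, -5.0, soft_tissue_mu, sens, bu)

    def test_monotone_decreasing_in_depth(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        d_grid = np.linspace(0.0, 120.0, 241)
        for w in sens:
            r = [forward_model(1.0, d, soft_tissue_mu, sens, bu, [w])[w]
                 for d in d_grid]
            assert np.all(np.diff(r) < 0)


class TestInitialEstimate:
    def test_exact_recovery_from_fixed_sensitivity_model(self, truth_megp_tew,
                                                         soft_tissue_mu):
        sens, _ = truth_megp_tew
        a_true, d_true, d_fix = 5.0, 25.0, 20.0
        rates = {w: a_true * float(sens[w].epsilon(d_fix))
                 * np.exp(-d_true * soft_tissue_mu[w]) for w in sens}
        a0, d0 = initial_estimate(measurement_from_rates(rates), soft_tissue_mu,
                                  sens, d_fix=d_fix)
        assert a0 == pytest.approx(5.0, rel=1e-9)
        assert d0 == pytest.approx(25.0, rel=1e-9)

    def test_two_windows_match_closed_form(self, truth_megp_tew, soft_tissue_mu):
        sens, _ = truth_megp_tew
        rates = {55: 40.0, 208: 70.0}
        a0, d0 = initial_estimate(measurement_from_rates(rates), soft_tissue_mu,
                                  sens, d_fix=20.0)
        y1 = np.log(40.0 / float(sens[55].epsilon(20.0)))
        y2 = np.log(70.0 / float(sens[208].epsilon(20.0)))
        d_closed = (y2 - y1) / (soft_tissue_mu[55] - soft_tissue_mu[208])
        assert d0 == pytest.approx(d_closed, rel=1e-9)

    def test_equal_scaled_rates_give_zero_depth(self, soft_tissue_mu):
        sens = {w: SensitivityModel(c0=1.0, c1=5.0, c2=0.02, window=w,
                                    collimator="MEGP", scatter_corrected=True)
                for w in (55, 113, 208)}
        rates = {w: 3.0 * float(sens[w].epsilon(20.0)) for w in sens}
        a0, d0 = initial_estimate(measurement_from_rates(rates), soft_tissue_mu,
                                  sens, d_fix=20.0)
        assert d0 == pytest.approx(0.0, abs=1e-9)
        assert a0 == pytest.approx(3.0, rel=1e-9)

    def test_equal_mu_is_degenerate(self, truth_megp_tew):
        sens, _ = truth_megp_tew
        mu = AttenuationContext({55: 0.02, 113: 0.02, 208: 0.02})
        with pytest.raises(DegenerateDesignError):
            initial_estimate(measurement_from_rates({55: 1.0, 113: 2.0, 208: 3.0}),
                             mu, sens)


class TestEstimate:
    def test_noise_free_exact_recovery(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        rates = forward_model(8.0, 35.0, soft_tissue_mu, sens, bu)
        res = estimate(measurement_from_rates(rates), soft_tissue_mu, sens, bu)
        assert res.converged
        assert res.activity_mbq == pytest.approx(8.0, rel=1e-6)
        assert res.depth_mm == pytest.approx(35.0, rel=1e-6)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        spec = ScenarioSpec(seed=11, duration_s=200.0,
                            sensitivity=sens, buildup=bu)
        ms = simulate_measurement(spec)
        res1 = estimate(ms, soft_tissue_mu, sens, bu, weight_mode="provided")
        lam = 3.7
        scaled = MeasurementSet(
            rates={w: lam * r for w, r in ms.rates.items()},
            variances={w: lam ** 2 * v for w, v in ms.variances.items()},
            duration_s=ms.duration_s, collimator=ms.collimator,
            scatter_corrected=True, clamped=dict(ms.clamped))
        res2 = estimate(scaled, soft_tissue_mu, sens, bu, weight_mode="provided")
        assert res2.activity_mbq == pytest.approx(lam * res1.activity_mbq, rel=1e-6)
        assert res2.depth_mm == pytest.approx(res1.depth_mm, abs=1e-4)

    def test_weight_modes_share_optimum_for_common_duration(self, truth_megp_tew,
                                                            soft_tissue_mu):
        sens, bu = truth_megp_tew
        ms = simulate_measurement(ScenarioSpec(seed=3, duration_s=200.0,
                                               sensitivity=sens, buildup=bu))
        a = estimate(ms, soft_tissue_mu, sens, bu, weight_mode="poisson")
        b = estimate(ms, soft_tissue_mu, sens, bu, weight_mode="inverse_rate")
        assert a.activity_mbq == pytest.approx(b.activity_mbq, rel=1e-6)
        assert a.depth_mm == pytest.approx(b.depth_mm, abs=1e-4)

    def test_clamped_zero_window_excluded(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        rates = forward_model(8.0, 35.0, soft_tissue_mu, sens, bu)
        rates[55] = 0.0
        ms = measurement_from_rates(rates, clamped={55: True})
        ms.variances[55] = 1.0
        with pytest.warns(UserWarning, match="clamped"):
            res = estimate(ms, soft_tissue_mu, sens, bu)
        assert res.windows_used == [113, 208]
        assert res.activity_mbq == pytest.approx(8.0, rel=1e-6)

    def test_identifiability_guard(self, truth_megp_tew):
        sens, bu = truth_megp_tew
        mu = AttenuationContext({55: 0.0200, 113: 0.0199, 208: 0.01995})
        with pytest.raises(DegenerateDesignError, match="1%"):
            estimate(measurement_from_rates({55: 10.0, 113: 20.0, 208: 15.0}),
                     mu, sens, bu)

    def test_window_mask_drops_208(self, truth_megp_tew, soft_tissue_mu):
        sens, bu = truth_megp_tew
        rates = forward_model(8.0, 35.0, soft_tissue_mu, sens, bu)
        res = estimate(measurement_from_rates(rates), soft_tissue_mu, sens, bu,
                       windows=[55, 113])
        assert res.windows_used == [55, 113]
        assert res.activity_mbq == pytest.approx(8.0, rel=1e-6)

    def test_negative_depth_pathology_and_bounded_mode(self, truth_megp_tew,
                                                       soft_tissue_mu):
        """Excess 55 keV signal drives the unconstrained fit below d = 0;
        bounded mode lands exactly on the boundary."""
        sens, bu = truth_megp_tew
        with pytest.warns(UserWarning, match="negative depth"):
            rates = forward_model(10.0, -8.0, soft_tissue_mu, sens, bu)
        ms = measurement_from_rates(rates)
        free = estimate(ms, soft_tissue_mu, sens, bu)
        assert free.negative_depth
        assert free.depth_mm == pytest.approx(-8.0, rel=1e-5)
        bounded = estimate(ms, soft_tissue_mu, sens, bu, bounded=True)
        assert bounded.depth_mm == 0.0
        assert not bounded.negative_depth
        assert bounded.converged

    def test_fewer_than_two_positive_windows_rejected(self, truth_megp_tew,
                                                      soft_tissue_mu):
        with pytest.raises(ValidationError):
            measurement_from_rates({113: 10.0, 208: 0.0, 55: 0.0})


class TestMetrics:
    def test_relative_deviation_identity_and_arithmetic(self):
        assert relative_deviation(5.0, 5.0) == 0.0
        assert relative_deviation(5.85, 5.0) == pytest.approx(0.17)

    def test_relative_deviation_with_decay(self):
        from luquant.physics import LU177_HALF_LIFE_S
        # measured one half-life after the reference assay: corrected back
        # by a factor 2 before comparing
        assert relative_deviation(2.5, 5.0, dt_s=LU177_HALF_LIFE_S) == \
            pytest.approx(0.0, abs=1e-12)

    def test_reference_must_be_positive(self):
        with pytest.raises(ValidationError):
            relative_deviation(1.0, 0.0)

    def test_depth_error_is_signed_difference(self):
        assert depth_error(28.0, 24.0) == pytest.approx(4.0)
        assert depth_error(24.0, 28.0) == -depth_error(28.0, 24.0)
        assert depth_error(10.0, 10.0) == 0.0
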