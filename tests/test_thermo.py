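"""Van't Hoff / Eyring regression, rate prediction, ratio prediction."""

import math

import numpy as np
import pytest

from dnmrfit import (
    ActivationFitResult,
    ExchangeRates,
    NoiseSpec,
    TemperatureSeries,
    ThermoFitResult,
    UnderdeterminedError,
    ValidationError,
    equilibrium_populations,
    eyring_fit,
    eyring_rate,
    gen_temperature_study,
    predict_population_ratio,
    vant_hoff_fit,
)
from dnmrfit.thermo import H_PLANCK, K_BOLTZMANN, R_GAS, vant_hoff_k

TEMPS = np.array([280.0, 290.0, 300.0, 310.0, 320.0])


def vh_series(dH, dS, temps=TEMPS):
    K = np.exp(-(dH - temps * dS) / (R_GAS * temps))
    return TemperatureSeries(temperatures=temps, equilibrium_constants=K)


class TestVantHoff:
    def test_noiseless_recovery_is_exact(self):
        result = vant_hoff_fit(vh_series(6000.0, 16.8))
        assert result.dH == pytest.approx(6000.0, rel=1e-9)
        assert result.dS == pytest.approx(16.8, rel=1e-9)
        assert result.se_dH == pytest.approx(0.0, abs=1e-6)

    def test_constant_k_gives_zero_enthalpy(self):
        series = TemperatureSeries(temperatures=TEMPS, equilibrium_constants=np.full(5, 1.7))
        result = vant_hoff_fit(series)
        assert result.dH == pytest.approx(0.0, abs=1e-9)
        assert result.dS == pytest.approx(R_GAS * math.log(1.7), rel=1e-9)

    def test_two_points_interpolate_exactly(self):
        series = vh_series(6000.0, 16.8, np.array([280.0, 320.0]))
        result = vant_hoff_fit(series)
        assert result.rss == pytest.approx(0.0, abs=1e-20)
        assert result.dH == pytest.approx(6000.0, rel=1e-9)

    def test_single_temperature_rejected(self):
        series = TemperatureSeries(
            temperatures=[300.0], equilibrium_constants=[1.5]
        )
        with pytest.raises(UnderdeterminedError):
            vant_hoff_fit(series)

    def test_nonpositive_k_rejected(self):
        series = TemperatureSeries(
            temperatures=[280.0, 300.0], equilibrium_constants=[1.0, -0.5]
        )
        with pytest.raises(ValidationError):
            vant_hoff_fit(series)

    def test_nonlinear_option_agrees_on_noiseless_data(self):
        result = vant_hoff_fit(vh_series(6000.0, 16.8), nonlinear=True)
        assert result.dH == pytest.approx(6000.0, rel=1e-6)
        assert result.dS == pytest.approx(16.8, rel=1e-6)


class TestEyring:
    def ey_series(self, dH_act, dS_act, temps=TEMPS):
        k_ab = (K_BOLTZMANN * temps / H_PLANCK) * np.exp(
            -(dH_act - temps * dS_act) / (R_GAS * temps)
        )
        rates = [ExchangeRates(k_ab=k, k_ba=1.0) for k in k_ab]
        return TemperatureSeries(temperatures=temps, rates=rates)

    def test_noiseless_recovery_is_exact(self):
        result = eyring_fit(self.ey_series(69300.0, -11.3), "ab")
        assert result.dH_act == pytest.approx(69300.0, rel=1e-9)
        assert result.dS_act == pytest.approx(-11.3, rel=1e-9)
        assert result.transmission_coefficient == 1.0

    def test_rate_proportional_to_temperature_has_zero_barrier(self):
        rates = [ExchangeRates(k_ab=K_BOLTZMANN * t / H_PLANCK, k_ba=1.0) for t in TEMPS]
        series = TemperatureSeries(temperatures=TEMPS, rates=rates)
        result = eyring_fit(series, "ab")
        assert result.dH_act == pytest.approx(0.0, abs=1e-6)
        assert result.dS_act == pytest.approx(0.0, abs=1e-9)

    def test_fit_then_rate_reproduces_inputs(self):
        series = self.ey_series(69300.0, -11.3)
        result = eyring_fit(series, "ab")
        for t, r in zip(series.temperatures, series.rates):
            assert eyring_rate(result, t) == pytest.approx(r.k_ab, rel=1e-9)

    def test_noisy_rates_recover_within_two_se(self):
        rng_sd = 0.02
        truth = ActivationFitResult(69300.0, -11.3, 0.0, 0.0)
        thermo = ThermoFitResult(6000.0, 16.8, 0.0, 0.0)
        study = gen_temperature_study(
            thermo, truth, noise=NoiseSpec(sd=rng_sd, seed=11)
        )
        result = eyring_fit(study, "ab")
        assert abs(result.dH_act - 69300.0) <= 2.0 * result.se_dH_act

    def test_direction_ba_fits_reverse_rates(self):
        temps = TEMPS
        k_ba = (K_BOLTZMANN * temps / H_PLANCK) * np.exp(
            -(63300.0 - temps * (-28.1)) / (R_GAS * temps)
        )
        rates = [ExchangeRates(k_ab=1.0, k_ba=k) for k in k_ba]
        result = eyring_fit(TemperatureSeries(temperatures=temps, rates=rates), "ba")
        assert result.dH_act == pytest.approx(63300.0, rel=1e-9)
        assert result.dS_act == pytest.approx(-28.1, rel=1e-9)


class TestEyringRate:
    def test_reference_parameters_near_measured_rate(self):
        # multi-temperature activation parameters evaluated at 300 K land
        # close to the 300 K EXSY forward rate (1.432 s^-1)
        k = eyring_rate(ActivationFitResult(69300.0, -11.3, 0.0, 0.0), 300.0)
        assert k == pytest.approx(1.377, abs=0.01)
        assert abs(k - 1.432) / 1.432 < 0.10

    def test_zero_barrier_gives_kbt_over_h(self):
        k = eyring_rate(ActivationFitResult(0.0, 0.0, 0.0, 0.0), 300.0)
        assert k == pytest.approx(K_BOLTZMANN * 300.0 / H_PLANCK, rel=1e-12)

    def test_monotone_increasing_in_temperature_for_positive_barrier(self):
        act = ActivationFitResult(69300.0, -11.3, 0.0, 0.0)
        ks = [eyring_rate(act, t) for t in np.linspace(250.0, 350.0, 50)]
        assert np.all(np.diff(ks) > 0)


class TestPopulationRatio:
    @pytest.mark.parametrize(
        "temp, expected, rounded",
        [(291.0, 1.58, 1.6), (277.0, 1.79, 1.8)],
    )
    def test_reference_ratios(self, temp, expected, rounded):
        thermo = ThermoFitResult(6000.0, 16.8, 0.0, 0.0)
        ratio = predict_population_ratio(thermo, temp)
        assert ratio == pytest.approx(expected, abs=0.01)
        assert round(ratio, 1) == rounded

    def test_zero_energy_difference_gives_unity(self):
        thermo = ThermoFitResult(0.0, 0.0, 0.0, 0.0)
        assert predict_population_ratio(thermo, 300.0) == 1.0
        assert predict_population_ratio(thermo, 77.0) == 1.0

    def test_monotone_decreasing_where_dG_positive(self):
        thermo = ThermoFitResult(6000.0, 16.8, 0.0, 0.0)
        temps = np.linspace(250.0, 350.0, 60)
        ratios = [predict_population_ratio(thermo, t) for t in temps]
        assert np.all(np.diff(ratios) < 0)

    def test_single_temperature_consistency_with_rates(self):
        # thermo parameters built from one temperature's rates reproduce
        # k_ba/k_ab as the population ratio there
        rates = ExchangeRates(1.432, 2.233)
        T = 300.0
        K = rates.k_ab / rates.k_ba
        dG = -R_GAS * T * math.log(K)
        thermo = ThermoFitResult(dH=dG, dS=0.0, se_dH=0.0, se_dS=0.0)
        assert predict_population_ratio(thermo, T) == pytest.approx(
            rates.k_ba / rates.k_ab, rel=1e-12
        )
        p = equilibrium_populations(rates)
        assert p.p_a / p.p_b == pytest.approx(rates.k_ba / rates.k_ab, rel=1e-12)


def test_k_from_rates_matches_populations():
    rates = [ExchangeRates(1.0, 2.0), ExchangeRates(1.5, 2.2)]
    series = TemperatureSeries(temperatures=[290.0, 300.0], rates=rates)
    for K, r in zip(series.k_values(), rates):
        p = equilibrium_populations(r)
        assert K == pytest.approx(p.p_b / p.p_a, rel=1e-12)


def test_vant_hoff_k_inverse_of_ratio():
    thermo = ThermoFitResult(6000.0, 16.8, 0.0, 0.0)
    assert vant_hoff_k(thermo, 291.0) * predict_population_ratio(thermo, 291.0) == pytest.approx(1.0)
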