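"""Lineshape simulation and fitting: oracle equivalence, exchange limits,
coalescence, parameter recovery."""

import math

import numpy as np
import pytest

from dnmrfit import (
    ExchangeRates,
    LineshapeModel,
    NoiseSpec,
    ResonancePair,
    ValidationError,
    fit_lineshape,
    gen_spectrum_dataset,
    simulate_fid,
    simulate_spectrum,
)


def make_model(k_ab=1.432, k_ba=2.233, shift_a=3.815, shift_b=3.885, amp=1.0,
               r2=4.0, freq=600.0, baseline=0.0):
    return LineshapeModel(
        pairs=(ResonancePair(shift_a, shift_b, amp),),
        rates=ExchangeRates(k_ab, k_ba),
        r2_free=r2,
        spectrometer_freq=freq,
        baseline_offset=baseline,
    )


def fwhm_hz(axis_ppm, y, freq, window=None):
    if window is not None:
        mask = (axis_ppm >= window[0]) & (axis_ppm <= window[1])
        axis_ppm, y = axis_ppm[mask], y[mask]
    half = y.max() / 2.0
    above = axis_ppm[y > half]
    return (above.max() - above.min()) * freq


class TestSimulateSpectrum:
    def test_no_exchange_gives_two_lorentzians_of_width_r2_over_pi(self):
        model = make_model(k_ab=0.0, k_ba=0.0, shift_a=3.80, shift_b=3.90)
        axis = np.linspace(3.75, 3.95, 200001)
        spec = simulate_spectrum(model, axis)
        for window in [(3.78, 3.82), (3.88, 3.92)]:
            assert fwhm_hz(axis, spec.intensity, 600.0, window) == pytest.approx(
                4.0 / math.pi, rel=5e-3
            )
        # peaks centred on the state shifts
        i = np.argmax(spec.intensity[axis < 3.85])
        assert axis[i] == pytest.approx(3.80, abs=1e-3)

    def test_fast_exchange_collapses_to_population_weighted_shift(self):
        model = make_model(k_ab=4000.0, k_ba=6000.0)
        axis = np.linspace(3.75, 3.95, 100001)
        spec = simulate_spectrum(model, axis)
        p_a = 6000.0 / 10000.0
        centre = p_a * 3.815 + (1 - p_a) * 3.885
        assert axis[np.argmax(spec.intensity)] == pytest.approx(centre, abs=2e-3)

    def test_slow_exchange_linewidth_is_r2_plus_k_over_pi(self):
        # well-separated lines, k small compared with the shift difference
        model = make_model(k_ab=1.0, k_ba=1.0, shift_a=3.78, shift_b=3.92)
        axis = np.linspace(3.70, 4.00, 400001)
        spec = simulate_spectrum(model, axis)
        width = fwhm_hz(axis, spec.intensity, 600.0, (3.75, 3.81))
        assert width == pytest.approx((4.0 + 1.0) / math.pi, rel=2e-2)

    def test_integrated_area_independent_of_exchange_rate(self):
        # window wide enough that truncated Lorentzian tails are negligible
        axis = np.linspace(2.85, 4.85, 200001)
        areas = []
        for k in [0.01, 1.0, 50.0, 2000.0]:
            spec = simulate_spectrum(make_model(k_ab=k, k_ba=k), axis)
            areas.append(np.trapezoid(spec.intensity, axis))
        np.testing.assert_allclose(areas, areas[0], rtol=1e-3)

    def test_coalescence_near_pi_delta_nu_over_sqrt2(self):
        """Equal populations: two maxima below the coalescence rate, one
        above, with the transition where the per-site rate k_ab = k_ba
        crosses pi * delta_nu / sqrt(2)."""
        from scipy.signal import find_peaks

        delta_nu = 0.07 * 600.0  # Hz
        k_c = math.pi * delta_nu / math.sqrt(2.0)
        axis = np.linspace(3.75, 3.95, 20001)

        def n_peaks(k):
            model = make_model(k_ab=k, k_ba=k)
            y = simulate_spectrum(model, axis).intensity
            peaks, _ = find_peaks(y, prominence=1e-5 * y.max())
            return len(peaks)

        assert n_peaks(0.2 * k_c) == 2
        assert n_peaks(5.0 * k_c) == 1
        ks = np.geomspace(0.2 * k_c, 5.0 * k_c, 25)
        counts = np.array([n_peaks(k) for k in ks])
        switch = ks[np.argmax(counts == 1)]
        # finite R2 and the discrete scan put the switch slightly above k_c
        assert 0.7 * k_c <= switch <= 1.5 * k_c
        assert np.all(np.diff(counts) <= 0)  # single transition


class TestSimulateFid:
    def test_t0_equals_sum_of_amplitudes(self):
        model = LineshapeModel(
            pairs=(ResonancePair(3.80, 3.84, 2.0), ResonancePair(3.88, 3.92, 3.0)),
            rates=ExchangeRates(1.0, 2.0),
            r2_free=4.0,
            spectrometer_freq=600.0,
        )
        t = np.linspace(0, 1.0, 4096)
        fid = simulate_fid(model, t)
        assert fid[0] == pytest.approx(5.0, rel=1e-12)

    def test_no_exchange_fid_is_two_damped_exponentials(self):
        model = make_model(k_ab=0.0, k_ba=0.0, r2=3.0)
        t = np.arange(8192) / 6000.0
        fid = simulate_fid(model, t)
        wa = 2 * math.pi * 3.815 * 600.0
        wb = 2 * math.pi * 3.885 * 600.0
        expected = 0.5 * np.exp((1j * wa - 3.0) * t) + 0.5 * np.exp((1j * wb - 3.0) * t)
        np.testing.assert_allclose(fid, expected, atol=1e-9)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValidationError):
            simulate_fid(make_model(), np.array([0.0, 0.1, 0.3]))

    @pytest.mark.parametrize("k_ab,k_ba", [(1.432, 2.233), (0.05, 0.1), (200.0, 150.0)])
    def test_fft_of_fid_matches_resolvent_spectrum(self, k_ab, k_ba):
        """The time- and frequency-domain routes must agree to <0.5% of
        the peak height (trapezoid-corrected DFT of the decaying FID)."""
        model = make_model(k_ab=k_ab, k_ba=k_ba)
        sw = 6000.0  # Hz, covers the methoxy carrier at 600 MHz
        n = 2**17
        t = np.arange(n) / sw
        fid = simulate_fid(model, t)
        spectrum_fft = (np.fft.fft(fid) - fid[0] / 2.0).real / sw
        ppm = np.fft.fftfreq(n, 1.0 / sw) / 600.0
        mask = (ppm > 3.75) & (ppm < 3.95)
        reference = simulate_spectrum(model, ppm[mask]).intensity
        err = np.abs(spectrum_fft[mask] - reference).max() / reference.max()
        assert err < 5e-3


class TestFitLineshape:
    def test_noiseless_round_trip_recovers_all_parameters(self, ppm_axis):
        truth = make_model(baseline=0.002)
        spec = simulate_spectrum(truth, ppm_axis)
        result = fit_lineshape(spec, init=None, fixed_r2=4.0, n_pairs=1)
        assert result.converged and not result.at_bound
        assert result.model.rates.k_ab == pytest.approx(1.432, rel=1e-3)
        assert result.model.rates.k_ba == pytest.approx(2.233, rel=1e-3)
        pair = result.model.pairs[0]
        assert pair.shift_a == pytest.approx(3.815, abs=2e-5)
        assert pair.shift_b == pytest.approx(3.885, abs=2e-5)
        assert pair.amplitude == pytest.approx(1.0, rel=1e-3)
        assert result.model.baseline_offset == pytest.approx(0.002, rel=1e-2)

    def test_two_pair_joint_fit_shares_rates(self, ppm_axis):
        truth = LineshapeModel(
            pairs=(ResonancePair(3.78, 3.82, 1.0), ResonancePair(3.87, 3.91, 0.7)),
            rates=ExchangeRates(1.432, 2.233),
            r2_free=4.0,
            spectrometer_freq=600.0,
        )
        spec = simulate_spectrum(truth, ppm_axis)
        result = fit_lineshape(spec, init=None, fixed_r2=4.0, n_pairs=2)
        assert result.converged
        assert result.model.rates.k_ab == pytest.approx(1.432, rel=1e-2)
        assert result.model.rates.k_ba == pytest.approx(2.233, rel=1e-2)
        amps = sorted(p.amplitude for p in result.model.pairs)
        assert amps == pytest.approx([0.7, 1.0], rel=1e-2)

    def test_shielded_convention_enforced_after_fit(self, ppm_axis):
        truth = make_model()
        spec = simulate_spectrum(truth, ppm_axis)
        # initialise with the labels deliberately crossed
        init = LineshapeModel(
            pairs=(ResonancePair(3.884, 3.816, 1.0),),
            rates=ExchangeRates(2.0, 1.5),
            r2_free=4.0,
            spectrometer_freq=600.0,
        )
        # construction does not reorder pairs; the fitter must
        result = fit_lineshape(spec, init=init, fixed_r2=4.0)
        assert result.model.pairs[0].shift_a <= result.model.pairs[0].shift_b

    def test_monte_carlo_coverage_of_rate_standard_errors(self, ppm_axis):
        """At 1% noise the +-2 se interval for k_ab covers the generating
        value in >= 90% of 50 seeded replicates."""
        truth = make_model()
        hits = 0
        for seed in range(50):
            spec = gen_spectrum_dataset(
                truth,
                axis=ppm_axis,
                noise=NoiseSpec(sd=0.01, fraction_of_max=True, seed=seed),
            )
            result = fit_lineshape(spec, init=None, fixed_r2=4.0, n_pairs=1)
            if abs(result.model.rates.k_ab - 1.432) <= 2.0 * result.se["k_ab"]:
                hits += 1
        assert hits >= 45
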