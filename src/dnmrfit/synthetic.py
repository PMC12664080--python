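"""Seeded synthetic data with the statistical structure of the real assay.

Every pipeline stage (lineshape, EXSY, thermodynamics) can be exercised
on data generated here with known ground truth, so parameter-recovery
and coverage tests never need the original spectra.  Generators are
pure functions of (parameters, seed): noise is additive Gaussian on
intensities and multiplicative log-normal on rates, and a single
integer seed is expanded through ``numpy.random.SeedSequence`` so
sub-generators draw independent streams.

``COMPOUND25_D2O`` collects the reference parameter set of the
asymmetric acid/tetrazole sulfonamide in D2O buffer: EXSY-derived
rates and R1 values at 300 K, the van't Hoff (ΔH = 6.0 kJ/mol,
ΔS = 16.8 J/(mol·K)) and Eyring (ΔH‡ = 69.3 kJ/mol,
ΔS‡ = -11.3 J/(mol·K)) parameters of the A→B transition, and the
experimental design (13 mixing times from 5 to 1000 ms; 280–320 K in
10 K steps; exchange-free R2 = 4 s^-1; methoxy window 3.75–3.95 ppm).
The methoxy shifts of the A/B states are not published; the preset
uses plausible values inside the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .exchange import ExchangeRates
from .exsy import ExsyParams, ExsySeries, predict_exsy
from .lineshape import LineshapeModel, ResonancePair, Spectrum1D, simulate_spectrum
from .thermo import (
    ActivationFitResult,
    TemperatureSeries,
    ThermoFitResult,
    eyring_rate,
    vant_hoff_k,
)

__all__ = [
    "NoiseSpec",
    "COMPOUND25_D2O",
    "gen_exsy_dataset",
    "gen_spectrum_dataset",
    "gen_temperature_study",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise description.

    sd : standard deviation, absolute or as a fraction of the maximum
    signal when ``fraction_of_max`` is set; seed : integer controlling
    the stream (same seed + parameters → bit-identical output).
    """

    sd: float = 0.0
    fraction_of_max: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"noise sd must be >= 0, got {self.sd}")

    def sigma(self, signal: np.ndarray) -> float:
        if self.sd == 0:
            return 0.0
        return self.sd * float(np.max(np.abs(signal))) if self.fraction_of_max else self.sd

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class Compound25Preset:
    """Reference parameters of the A⇌B rotamer exchange in D2O buffer."""

    k_ab: float = 1.432  # s^-1, 300 K
    k_ba: float = 2.233  # s^-1, 300 K
    r1_a: float = 0.936  # s^-1
    r1_b: float = 0.842  # s^-1
    dH: float = 6000.0  # J/mol
    dS: float = 16.8  # J/(mol*K)
    dH_act: float = 69300.0  # J/mol (A→B)
    dS_act: float = -11.3  # J/(mol*K)
    r2_free: float = 4.0  # s^-1 (D2O)
    exsy_freq: float = 700.0  # MHz (EXSY spectrometer)
    spectrum_freq: float = 600.0  # MHz (1D spectrometer)
    shift_a: float = 3.815  # ppm (chosen inside the methoxy window)
    shift_b: float = 3.885  # ppm
    region: tuple = (3.75, 3.95)
    temperature: float = 300.0  # K

    @property
    def rates(self) -> ExchangeRates:
        return ExchangeRates(k_ab=self.k_ab, k_ba=self.k_ba)

    def exsy_params(self, i_a0: float = 1.0, i_b0: float = 1.0) -> ExsyParams:
        return ExsyParams(
            rates=self.rates, r1_a=self.r1_a, r1_b=self.r1_b, i_a0=i_a0, i_b0=i_b0
        )

    def lineshape_model(self, amplitude: float = 1.0) -> LineshapeModel:
        return LineshapeModel(
            pairs=(ResonancePair(self.shift_a, self.shift_b, amplitude),),
            rates=self.rates,
            r2_free=self.r2_free,
            spectrometer_freq=self.spectrum_freq,
        )

    def thermo(self) -> ThermoFitResult:
        return ThermoFitResult(dH=self.dH, dS=self.dS, se_dH=0.0, se_dS=0.0)

    def activation(self) -> ActivationFitResult:
        return ActivationFitResult(
            dH_act=self.dH_act, dS_act=self.dS_act, se_dH_act=0.0, se_dS_act=0.0
        )


COMPOUND25_D2O = Compound25Preset()

#: 13 log-spaced mixing times spanning 5–1000 ms, the standard design
DEFAULT_MIXING_TIMES = np.geomspace(0.005, 1.0, 13)

#: the five temperatures of the variable-temperature study (K)
DEFAULT_TEMPERATURES = np.array([280.0, 290.0, 300.0, 310.0, 320.0])


def gen_exsy_dataset(
    params: ExsyParams,
    mixing_times: Optional[Sequence[float]] = None,
    noise: NoiseSpec = NoiseSpec(),
    temperature: float = 300.0,
    spectrometer_freq: float = 700.0,
) -> ExsySeries:
    """EXSY series from the build-up model plus i.i.d. Gaussian noise.

    The generating truth is recorded on the returned series for
    recovery tests.  With sd = 0 the output equals ``predict_exsy``
    exactly.
    """
    times = DEFAULT_MIXING_TIMES if mixing_times is None else np.asarray(mixing_times, float)
    clean = predict_exsy(params, times)
    sigma = noise.sigma(clean)
    noisy = clean + noise.rng(stream=0).normal(0.0, sigma, clean.shape) if sigma else clean
    return ExsySeries(
        mixing_times=times,
        intensities=noisy,
        temperature=temperature,
        spectrometer_freq=spectrometer_freq,
        truth=params,
    )


def gen_spectrum_dataset(
    model: LineshapeModel,
    axis: Optional[Sequence[float]] = None,
    noise: NoiseSpec = NoiseSpec(),
    temperature: float = 300.0,
    region: Optional[tuple] = None,
    n_points: int = 2048,
) -> Spectrum1D:
    """Noisy 1D spectrum of the model over the methoxy window.

    A default axis of ``n_points`` evenly spaced shifts across
    ``region`` (3.75–3.95 ppm when unspecified) is used when ``axis`` is
    None.
    """
    if region is None:
        region = COMPOUND25_D2O.region
    if axis is None:
        axis = np.linspace(region[0], region[1], n_points)
    spec = simulate_spectrum(model, axis, temperature=temperature, region=region)
    sigma = noise.sigma(spec.intensity)
    if sigma:
        spec.intensity = spec.intensity + noise.rng(stream=1).normal(
            0.0, sigma, spec.intensity.shape
        )
    return spec


def gen_temperature_study(
    thermo: ThermoFitResult,
    activation: ActivationFitResult,
    temperatures: Optional[Sequence[float]] = None,
    noise: NoiseSpec = NoiseSpec(),
) -> TemperatureSeries:
    """Temperature series of rate constants consistent with both fits.

    k_ab(T) comes from the Eyring form with the activation parameters;
    k_ba(T) = k_ab(T)/K_AB(T) with K_AB(T) from the van't Hoff form, so
    the rates embed both the kinetic and the thermodynamic truth.
    Optional noise is multiplicative log-normal on each rate.
    """
    temps = DEFAULT_TEMPERATURES if temperatures is None else np.asarray(temperatures, float)
    k_ab = np.array([eyring_rate(activation, t) for t in temps])
    K = np.array([vant_hoff_k(thermo, t) for t in temps])
    k_ba = k_ab / K
    if noise.sd > 0:
        rng = noise.rng(stream=2)
        k_ab = k_ab * np.exp(rng.normal(0.0, noise.sd, k_ab.shape))
        k_ba = k_ba * np.exp(rng.normal(0.0, noise.sd, k_ba.shape))
    rates = [ExchangeRates(k_ab=a, k_ba=b) for a, b in zip(k_ab, k_ba)]
    return TemperatureSeries(
        temperatures=temps,
        rates=rates,
        truth={
            "dH_j_per_mol": thermo.dH,
            "dS_j_per_mol_k": thermo.dS,
            "dH_act_j_per_mol": activation.dH_act,
            "dS_act_j_per_mol_k": activation.dS_act,
        },
    )
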