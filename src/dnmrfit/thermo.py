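"""Van't Hoff and Eyring analysis of temperature-resolved exchange data.

The equilibrium constant K_AB = p_B/p_A = k_ab/k_ba obeys

    ln K = -ΔH/(R·T) + ΔS/R                     (van't Hoff)

so ordinary least squares of ln K on 1/T yields ΔH = -slope·R and
ΔS = intercept·R.  Rate constants obey transition-state theory with
unit transmission coefficient,

    k = (k_B·T/h) · exp(-(ΔH‡ - T·ΔS‡)/(R·T))   (Eyring)

so regressing ln(k/T) on 1/T gives ΔH‡ = -slope·R and
ΔS‡ = R·(intercept - ln(k_B/h)).

Energies are stored in J/mol and entropies in J/(mol·K); presentation
layers convert to kJ/mol.  Linear regression is the default, matching
the standard linearised presentation of both equations; a direct
nonlinear fit of the exponential forms is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import UnderdeterminedError, ValidationError
from .exchange import ExchangeRates

__all__ = [
    "R_GAS",
    "K_BOLTZMANN",
    "H_PLANCK",
    "TemperatureSeries",
    "ThermoFitResult",
    "ActivationFitResult",
    "vant_hoff_fit",
    "eyring_fit",
    "eyring_rate",
    "predict_population_ratio",
]

R_GAS = 8.314  # J/(mol*K)
K_BOLTZMANN = 1.380649e-23  # J/K (CODATA exact)
H_PLANCK = 6.62607015e-34  # J*s (CODATA exact)


@dataclass
class TemperatureSeries:
    """Rates and/or equilibrium constants across temperatures.

    Either per-temperature ``rates`` (list of :class:`ExchangeRates`) or
    ``equilibrium_constants`` (K_AB = p_B/p_A = k_ab/k_ba) must be
    supplied; K values are derived from rates on demand when absent.
    """

    temperatures: np.ndarray
    rates: Optional[list] = None
    equilibrium_constants: Optional[np.ndarray] = None
    truth: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.size < 1:
            raise ValidationError("temperatures must be a non-empty 1D array")
        if np.any(self.temperatures <= 0):
            raise ValidationError("temperatures must be > 0 K")
        if self.rates is not None and len(self.rates) != self.temperatures.size:
            raise ValidationError("one ExchangeRates per temperature required")
        if self.equilibrium_constants is not None:
            self.equilibrium_constants = np.asarray(
                self.equilibrium_constants, dtype=float
            )
            if self.equilibrium_constants.shape != self.temperatures.shape:
                raise ValidationError("one equilibrium constant per temperature required")
        if self.rates is None and self.equilibrium_constants is None:
            raise ValidationError("series needs rates or equilibrium constants")

    def k_values(self) -> np.ndarray:
        """Equilibrium constants K_AB = k_ab/k_ba, derived if necessary."""
        if self.equilibrium_constants is not None:
            return self.equilibrium_constants
        if any(r.k_ba == 0 for r in self.rates):
            raise ValidationError("k_ba = 0: equilibrium constant undefined")
        return np.array([r.k_ab / r.k_ba for r in self.rates])

    def rate_values(self, direction: str) -> np.ndarray:
        if self.rates is None:
            raise ValidationError("series carries no rate constants")
        if direction == "ab":
            return np.array([r.k_ab for r in self.rates])
        if direction == "ba":
            return np.array([r.k_ba for r in self.rates])
        raise ValidationError(f"direction must be 'ab' or 'ba', got {direction!r}")


@dataclass
class ThermoFitResult:
    """Van't Hoff estimates: ΔH (J/mol), ΔS (J/(mol·K)), standard errors
    and simple regression diagnostics."""

    dH: float
    dS: float
    se_dH: float
    se_dS: float
    rss: float = 0.0
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "dH_j_per_mol": self.dH,
            "dS_j_per_mol_k": self.dS,
            "se_dH_j_per_mol": self.se_dH,
            "se_dS_j_per_mol_k": self.se_dS,
            "rss": self.rss,
            "n": self.n,
        }


@dataclass
class ActivationFitResult:
    """Eyring estimates: ΔH‡ (J/mol), ΔS‡ (J/(mol·K)); transmission
    coefficient fixed at 1."""

    dH_act: float
    dS_act: float
    se_dH_act: float
    se_dS_act: float
    direction: str = "ab"
    rss: float = 0.0
    n: int = 0
    transmission_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.transmission_coefficient != 1.0:
            raise ValidationError("transmission coefficient is fixed at 1")

    def to_dict(self) -> dict:
        return {
            "dH_act_j_per_mol": self.dH_act,
            "dS_act_j_per_mol_k": self.dS_act,
            "se_dH_act_j_per_mol": self.se_dH_act,
            "se_dS_act_j_per_mol_k": self.se_dS_act,
            "direction": self.direction,
            "rss": self.rss,
            "n": self.n,
            "transmission_coefficient": self.transmission_coefficient,
        }


def _linfit(x: np.ndarray, y: np.ndarray, weights: Optional[np.ndarray]) -> tuple:
    """Weighted least squares y = a·x + b; returns (a, b, se_a, se_b, rss).

    Standard errors follow the usual unbiased-variance formula; with
    only two points the fit interpolates exactly and the errors are 0.
    """
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    rss = float(resid @ (w * resid))
    dof = x.size - 2
    if dof > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(xtwx)
        se_a, se_b = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    else:
        se_a = se_b = 0.0
    return float(beta[0]), float(beta[1]), se_a, se_b, rss


def vant_hoff_fit(
    series: TemperatureSeries,
    weights: Optional[Sequence[float]] = None,
    nonlinear: bool = False,
) -> ThermoFitResult:
    """Fit ln K_AB against 1/T to estimate reaction ΔH and ΔS.

    Unweighted by default; per-point weights and a direct nonlinear fit
    of K(T) = exp(-(ΔH - T·ΔS)/(R·T)) are available as options.

    Raises
    ------
    UnderdeterminedError for fewer than 2 distinct temperatures;
    ValidationError for non-positive equilibrium constants.
    """
    temps = series.temperatures
    if np.unique(temps).size < 2:
        raise UnderdeterminedError("van't Hoff fit needs >= 2 distinct temperatures")
    K = series.k_values()
    if np.any(K <= 0):
        raise ValidationError("equilibrium constants must be > 0")
    x = 1.0 / temps
    y = np.log(K)
    slope, intercept, se_a, se_b, rss = _linfit(
        x, y, None if weights is None else np.asarray(weights)
    )
    dH, dS = -slope * R_GAS, intercept * R_GAS
    se_dH, se_dS = se_a * R_GAS, se_b * R_GAS
    if nonlinear:
        popt, pcov = optimize.curve_fit(
            lambda T, h, s: np.exp(-(h - T * s) / (R_GAS * T)),
            temps,
            K,
            p0=[dH, dS],
        )
        dH, dS = popt
        se_dH, se_dS = np.sqrt(np.diag(pcov))
        rss = float(np.sum((K - np.exp(-(dH - temps * dS) / (R_GAS * temps))) ** 2))
    return ThermoFitResult(
        dH=float(dH),
        dS=float(dS),
        se_dH=float(se_dH),
        se_dS=float(se_dS),
        rss=rss,
        n=int(temps.size),
    )


def eyring_fit(
    series: TemperatureSeries,
    direction: str = "ab",
    weights: Optional[Sequence[float]] = None,
) -> ActivationFitResult:
    """Fit ln(k/T) against 1/T to estimate activation ΔH‡ and ΔS‡.

    Transmission coefficient is fixed at 1, so the intercept equals
    ln(k_B/h) + ΔS‡/R.
    """
    temps = series.temperatures
    if np.unique(temps).size < 2:
        raise UnderdeterminedError("Eyring fit needs >= 2 distinct temperatures")
    k = series.rate_values(direction)
    if np.any(k <= 0):
        raise ValidationError("rate constants must be > 0 for the Eyring fit")
    x = 1.0 / temps
    y = np.log(k / temps)
    slope, intercept, se_a, se_b, rss = _linfit(
        x, y, None if weights is None else np.asarray(weights)
    )
    return ActivationFitResult(
        dH_act=-slope * R_GAS,
        dS_act=R_GAS * (intercept - math.log(K_BOLTZMANN / H_PLANCK)),
        se_dH_act=se_a * R_GAS,
        se_dS_act=se_b * R_GAS,
        direction=direction,
        rss=rss,
        n=int(temps.size),
    )


def eyring_rate(result: ActivationFitResult, temperature: float) -> float:
    """Transition-state-theory rate k(T) implied by activation parameters.

    k = (k_B·T/h)·exp(-(ΔH‡ - T·ΔS‡)/(R·T)), κ = 1.
    """
    if temperature <= 0:
        raise ValidationError(f"temperature must be > 0, got {temperature}")
    T = temperature
    return (
        K_BOLTZMANN
        * T
        / H_PLANCK
        * math.exp(-(result.dH_act - T * result.dS_act) / (R_GAS * T))
    )


def vant_hoff_k(thermo: ThermoFitResult, temperature: float) -> float:
    """Equilibrium constant K_AB(T) = exp(-(ΔH - T·ΔS)/(R·T))."""
    if temperature <= 0:
        raise ValidationError(f"temperature must be > 0, got {temperature}")
    T = temperature
    return math.exp(-(thermo.dH - T * thermo.dS) / (R_GAS * T))


def predict_population_ratio(thermo: ThermoFitResult, temperature: float) -> float:
    """Predicted population ratio p_A/p_B at a temperature.

    Since K_AB = p_B/p_A = exp(-ΔG/RT) with ΔG = ΔH - T·ΔS, the A:B
    ratio is exp(+ΔG/RT).  Full precision is returned; round at the
    presentation layer (e.g. "1.6:1").
    """
    return 1.0 / vant_hoff_k(thermo, temperature)
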