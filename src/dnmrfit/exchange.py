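"""Core two-site exchange data model and elementary kinetic relations.

Two NMR-distinguishable states A and B interconvert by first-order
kinetics with rates ``k_ab`` (A→B) and ``k_ba`` (B→A), both in s^-1.
By convention state A is the more shielded (lower-ppm) resonance; the
:class:`ExchangeSystem` constructor enforces this by swapping labels
(and relabelling the rates) when violated.

All rates are stored in s^-1 and shifts in ppm.  Conversion to angular
frequency (2π · ppm · spectrometer_freq) happens only inside spectral
simulation, never in the data model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import UndefinedPopulationError, ValidationError

__all__ = [
    "ExchangeRates",
    "Populations",
    "ExchangeSystem",
    "equilibrium_populations",
    "exsy_generator_matrix",
]


@dataclass(frozen=True)
class ExchangeRates:
    """First-order interconversion rates between states A and B.

    Parameters
    ----------
    k_ab : float
        Forward rate A→B in s^-1.
    k_ba : float
        Reverse rate B→A in s^-1.
    se_k_ab, se_k_ba : float, optional
        Standard errors of the rates (s^-1), e.g. from a fit covariance.
    """

    k_ab: float
    k_ba: float
    se_k_ab: Optional[float] = None
    se_k_ba: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.k_ab >= 0 and math.isfinite(self.k_ab)):
            raise ValidationError(f"k_ab must be finite and >= 0, got {self.k_ab}")
        if not (self.k_ba >= 0 and math.isfinite(self.k_ba)):
            raise ValidationError(f"k_ba must be finite and >= 0, got {self.k_ba}")
        for name in ("se_k_ab", "se_k_ba"):
            se = getattr(self, name)
            if se is not None and se < 0:
                raise ValidationError(f"{name} must be >= 0, got {se}")

    @property
    def k_ex(self) -> float:
        """Total exchange rate k_ab + k_ba (s^-1)."""
        return self.k_ab + self.k_ba

    def swapped(self) -> "ExchangeRates":
        """Rates with the A/B labels exchanged."""
        return ExchangeRates(
            k_ab=self.k_ba, k_ba=self.k_ab, se_k_ab=self.se_k_ba, se_k_ba=self.se_k_ab
        )

    def to_dict(self) -> dict:
        return {
            "k_ab_per_s": self.k_ab,
            "k_ba_per_s": self.k_ba,
            "se_k_ab_per_s": self.se_k_ab,
            "se_k_ba_per_s": self.se_k_ba,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeRates":
        return cls(
            k_ab=d["k_ab_per_s"],
            k_ba=d["k_ba_per_s"],
            se_k_ab=d.get("se_k_ab_per_s"),
            se_k_ba=d.get("se_k_ba_per_s"),
        )


@dataclass(frozen=True)
class Populations:
    """Equilibrium fractions of states A and B; p_a + p_b = 1."""

    p_a: float
    p_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_a <= 1.0):
            raise ValidationError(f"p_a must lie in [0, 1], got {self.p_a}")
        if abs(self.p_a + self.p_b - 1.0) > 1e-12:
            raise ValidationError(
                f"populations must sum to 1 within 1e-12, got {self.p_a + self.p_b}"
            )

    @property
    def ratio_ab(self) -> float:
        """Population ratio p_a / p_b."""
        return self.p_a / self.p_b

    def to_dict(self) -> dict:
        return {"p_a": self.p_a, "p_b": self.p_b}


@dataclass(frozen=True)
class ExchangeSystem:
    """Complete kinetic and spectral description of a two-site system.

    State A is the more shielded (lower-ppm) state.  If constructed with
    ``shift_a > shift_b`` the labels are swapped automatically, which also
    exchanges ``k_ab``/``k_ba``, so downstream code can rely on the
    convention deterministically.

    Parameters
    ----------
    shift_a, shift_b : float
        Chemical shifts of the two states (ppm), shift_a <= shift_b.
    rates : ExchangeRates
        Interconversion rates (s^-1).
    r2_free : float
        Exchange-free transverse relaxation rate (s^-1); 3 s^-1 is
        typical for DMSO samples and 4 s^-1 for D2O in this assay.
    spectrometer_freq : float
        Proton Larmor frequency (MHz).
    temperature : float
        Sample temperature (K).
    """

    shift_a: float
    shift_b: float
    rates: ExchangeRates
    r2_free: float
    spectrometer_freq: float
    temperature: float

    def __post_init__(self) -> None:
        if self.r2_free <= 0:
            raise ValidationError(f"r2_free must be > 0, got {self.r2_free}")
        if self.spectrometer_freq <= 0:
            raise ValidationError(
                f"spectrometer_freq must be > 0, got {self.spectrometer_freq}"
            )
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0, got {self.temperature}")

    def __init__(
        self,
        shift_a: float,
        shift_b: float,
        rates: ExchangeRates,
        r2_free: float,
        spectrometer_freq: float,
        temperature: float,
    ) -> None:
        # "A = more shielded": swap labels (and rates) if given reversed
        if shift_a > shift_b:
            shift_a, shift_b = shift_b, shift_a
            rates = rates.swapped()
        object.__setattr__(self, "shift_a", shift_a)
        object.__setattr__(self, "shift_b", shift_b)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "r2_free", r2_free)
        object.__setattr__(self, "spectrometer_freq", spectrometer_freq)
        object.__setattr__(self, "temperature", temperature)
        self.__post_init__()

    @property
    def populations(self) -> Populations:
        return equilibrium_populations(self.rates)

    @property
    def delta_omega(self) -> float:
        """Frequency separation of the two states in rad/s."""
        return 2.0 * math.pi * (self.shift_b - self.shift_a) * self.spectrometer_freq

    def to_dict(self) -> dict:
        return {
            "shift_a_ppm": self.shift_a,
            "shift_b_ppm": self.shift_b,
            "rates": self.rates.to_dict(),
            "r2_free_per_s": self.r2_free,
            "spectrometer_freq_mhz": self.spectrometer_freq,
            "temperature_k": self.temperature,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeSystem":
        return cls(
            shift_a=d["shift_a_ppm"],
            shift_b=d["shift_b_ppm"],
            rates=ExchangeRates.from_dict(d["rates"]),
            r2_free=d["r2_free_per_s"],
            spectrometer_freq=d["spectrometer_freq_mhz"],
            temperature=d["temperature_k"],
        )

    @classmethod
    def from_json(cls, s: str) -> "ExchangeSystem":
        return cls.from_dict(json.loads(s))


def equilibrium_populations(rates: ExchangeRates) -> Populations:
    """Equilibrium state fractions implied by the exchange rates.

    At equilibrium the fluxes balance, p_a * k_ab = p_b * k_ba, giving

        p_a = k_ba / (k_ab + k_ba),   p_b = k_ab / (k_ab + k_ba).

    Raises
    ------
    UndefinedPopulationError
        If both rates are zero (no exchange, populations undefined).
    """
    total = rates.k_ab + rates.k_ba
    if total <= 0:
        raise UndefinedPopulationError(
            "equilibrium populations are undefined when k_ab = k_ba = 0"
        )
    # both fractions computed directly so detailed balance holds to
    # machine precision even for extreme rate ratios
    return Populations(p_a=rates.k_ba / total, p_b=rates.k_ab / total)


def exsy_generator_matrix(
    k_ab: float, k_ba: float, r1_a: float, r1_b: float
) -> np.ndarray:
    """Longitudinal-magnetisation evolution matrix for two-site EXSY.

    Returns the 2x2 generator

        M = [[-r1_a - k_ab,  k_ba],
             [ k_ab,        -r1_b - k_ba]]

    so that the mixing-time-dependent intensity matrix is
    I(T) = expm(M T) @ diag(i_a0, i_b0).  With zero relaxation each
    column of M sums to zero, i.e. exchange conserves total
    magnetisation.

    All four input rates must be >= 0 (s^-1).
    """
    for name, v in (("k_ab", k_ab), ("k_ba", k_ba), ("r1_a", r1_a), ("r1_b", r1_b)):
        if not (v >= 0 and math.isfinite(v)):
            raise ValidationError(f"{name} must be finite and >= 0, got {v}")
    return np.array(
        [[-r1_a - k_ab, k_ba], [k_ab, -r1_b - k_ba]], dtype=float
    )


def propagate_population_se(rates: ExchangeRates) -> Optional[tuple]:
    """First-order propagation of rate standard errors into populations.

    Returns ``(se_p_a, se_p_b)`` or ``None`` when the rates carry no
    standard errors.  Treats the rate errors as independent.  This is an
    extension beyond the plain population formulas: the partials are
    d p_a/d k_ab = -k_ba/total^2 and d p_a/d k_ba = k_ab/total^2.
    """
    if rates.se_k_ab is None or rates.se_k_ba is None:
        return None
    total = rates.k_ab + rates.k_ba
    if total <= 0:
        raise UndefinedPopulationError(
            "population uncertainty undefined when k_ab = k_ba = 0"
        )
    dpa_dkab = -rates.k_ba / total**2
    dpa_dkba = rates.k_ab / total**2
    se = math.hypot(dpa_dkab * rates.se_k_ab, dpa_dkba * rates.se_k_ba)
    return (se, se)
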