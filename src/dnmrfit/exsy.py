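"""EXSY build-up prediction and fitting for two-site exchange.

In a 2D exchange (EXSY) experiment the longitudinal magnetisation of
states A and B mixes for a delay T.  The four peak intensities — the
diagonals I_AA, I_BB and the cross peaks I_AB, I_BA — follow

    I(T) = expm(M T) @ diag(I_A0, I_B0)

where M is the 2x2 kinetic/relaxation generator built by
:func:`dnmrfit.exchange.exsy_generator_matrix`.  Fitting all four
channels jointly over a series of mixing times determines k_ab, k_ba,
the longitudinal relaxation rates R1_A, R1_B, and the initial
intensities.

Entry [i][j] of each intensity matrix is the signal that started in
state j and is detected in state i, so I[0,1] is the B→A cross peak
I_AB (detected at the A frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import lmfit

from .errors import UnderdeterminedError, ValidationError
from .exchange import ExchangeRates, exsy_generator_matrix

__all__ = [
    "ExsyParams",
    "ExsySeries",
    "ExsyFitResult",
    "predict_exsy",
    "fit_exsy",
    "init_guess_exsy",
]

# log-parameter bounds used by the fitter and the zero-cross-peak fallback
_K_FLOOR = 1e-4
_LOG_LO, _LOG_HI = math.log(1e-6), math.log(1e4)


@dataclass(frozen=True)
class ExsyParams:
    """Parameter set of the EXSY build-up model.

    rates : ExchangeRates (s^-1); r1_a, r1_b : longitudinal relaxation
    rates of A and B (s^-1); i_a0, i_b0 : initial diagonal intensities
    at T = 0 (arbitrary units).
    """

    rates: ExchangeRates
    r1_a: float
    r1_b: float
    i_a0: float
    i_b0: float

    def __post_init__(self) -> None:
        if self.r1_a < 0 or self.r1_b < 0:
            raise ValidationError(
                f"relaxation rates must be >= 0, got r1_a={self.r1_a}, r1_b={self.r1_b}"
            )
        if self.i_a0 <= 0 or self.i_b0 <= 0:
            raise ValidationError(
                f"initial intensities must be > 0, got i_a0={self.i_a0}, i_b0={self.i_b0}"
            )

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "r1_a_per_s": self.r1_a,
            "r1_b_per_s": self.r1_b,
            "i_a0_au": self.i_a0,
            "i_b0_au": self.i_b0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExsyParams":
        return cls(
            rates=ExchangeRates.from_dict(d["rates"]),
            r1_a=d["r1_a_per_s"],
            r1_b=d["r1_b_per_s"],
            i_a0=d["i_a0_au"],
            i_b0=d["i_b0_au"],
        )


@dataclass
class ExsySeries:
    """Mixing-time-resolved EXSY intensities.

    ``intensities`` has shape (n_times, 2, 2) with entry [t, i, j] the
    intensity that started in state j and is detected in state i at
    mixing time ``mixing_times[t]``.
    """

    mixing_times: np.ndarray
    intensities: np.ndarray
    temperature: float
    spectrometer_freq: float
    truth: Optional[ExsyParams] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mixing_times.ndim != 1:
            raise ValidationError("mixing_times must be one-dimensional")
        if np.any(self.mixing_times < 0):
            raise ValidationError("mixing times must be >= 0")
        if np.any(np.diff(self.mixing_times) <= 0):
            raise ValidationError("mixing times must be strictly increasing")
        if self.intensities.shape != (self.mixing_times.size, 2, 2):
            raise ValidationError(
                f"intensities must have shape (n, 2, 2) matching {self.mixing_times.size} "
                f"mixing times, got {self.intensities.shape}"
            )

    def __len__(self) -> int:
        return self.mixing_times.size

    @property
    def i_aa(self) -> np.ndarray:
        return self.intensities[:, 0, 0]

    @property
    def i_ab(self) -> np.ndarray:
        """Cross peak detected at A, originating from B."""
        return self.intensities[:, 0, 1]

    @property
    def i_ba(self) -> np.ndarray:
        """Cross peak detected at B, originating from A."""
        return self.intensities[:, 1, 0]

    @property
    def i_bb(self) -> np.ndarray:
        return self.intensities[:, 1, 1]


@dataclass
class ExsyFitResult:
    """Result of a six-parameter EXSY fit.

    ``se`` maps parameter names (k_ab, k_ba, r1_a, r1_b, i_a0, i_b0) to
    standard errors on the natural (not log) scale; ``covariance`` is
    the 6x6 covariance in the same order.
    """

    params: ExsyParams
    se: dict
    covariance: Optional[np.ndarray]
    rss: float
    converged: bool
    n_obs: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se_per_s_or_au": dict(self.se),
            "rss": self.rss,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "message": self.message,
        }


def _expm_2x2(m: np.ndarray, times: np.ndarray) -> np.ndarray:
    """expm(m*T) for a real 2x2 matrix over a vector of times.

    Uses the eigendecomposition closed form

        expm(mT) = e^{l1 T} (m - l2 I)/(l1 - l2) + e^{l2 T} (m - l1 I)/(l2 - l1)

    with a first-order series fallback expm(mT) = e^{lT}(I + (m - lI)T)
    when the eigenvalues are (near-)degenerate, which keeps the
    evaluation stable as the rates approach zero.
    """
    tr = m[0, 0] + m[1, 1]
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    disc = tr * tr - 4.0 * det
    # generators of this form (non-negative off-diagonals) have real spectra
    sq = math.sqrt(max(disc, 0.0))
    l1 = 0.5 * (tr + sq)
    l2 = 0.5 * (tr - sq)
    times = np.asarray(times, dtype=float)
    eye = np.eye(2)
    if abs(l1 - l2) < 1e-10 * max(abs(l1), 1.0):
        lam = 0.5 * (l1 + l2)
        e = np.exp(lam * times)
        out = e[:, None, None] * (
            eye[None, :, :] + (m - lam * eye)[None, :, :] * times[:, None, None]
        )
        return out
    p1 = (m - l2 * eye) / (l1 - l2)
    p2 = (m - l1 * eye) / (l2 - l1)
    e1 = np.exp(l1 * times)[:, None, None]
    e2 = np.exp(l2 * times)[:, None, None]
    return e1 * p1[None, :, :] + e2 * p2[None, :, :]


def predict_exsy(params: ExsyParams, mixing_times: Sequence[float]) -> np.ndarray:
    """Predicted EXSY intensity matrices I(T) for each mixing time.

    Returns an array of shape (n_times, 2, 2);
    I(T) = expm(M T) @ diag(i_a0, i_b0).
    """
    times = np.asarray(mixing_times, dtype=float)
    if np.any(times < 0):
        raise ValidationError("mixing times must be >= 0")
    m = exsy_generator_matrix(
        params.rates.k_ab, params.rates.k_ba, params.r1_a, params.r1_b
    )
    props = _expm_2x2(m, times)
    i0 = np.diag([params.i_a0, params.i_b0])
    return props @ i0


def init_guess_exsy(series: ExsySeries) -> ExsyParams:
    """Data-driven starting values for :func:`fit_exsy`.

    Initial intensities come from the smallest-T diagonals; rates from
    the initial-rate (linear build-up) approximation
    i_ba(T)/i_a0 ≈ k_ab·T at the earliest mixing time with a usable
    cross peak; relaxation from the log-linear decay of the total
    magnetisation in each channel.  Cross peaks indistinguishable from
    zero fall back to k = 1e-4 s^-1.
    """
    if np.all(series.intensities == 0):
        raise ValidationError("cannot initialise from an all-zero series")
    i_a0 = max(float(series.i_aa[0]), 1e-12)
    i_b0 = max(float(series.i_bb[0]), 1e-12)

    def _k_from_crosspeak(cross: np.ndarray, origin0: float) -> float:
        for t, c in zip(series.mixing_times, cross):
            if t > 0 and c > 0.01 * origin0:
                return min(max(c / (origin0 * t), _K_FLOOR), 1e3)
        return _K_FLOOR

    k_ab = _k_from_crosspeak(series.i_ba, i_a0)
    k_ba = _k_from_crosspeak(series.i_ab, i_b0)

    def _r1_from_decay(total: np.ndarray, total0: float) -> float:
        mask = (total > 1e-6 * total0) & (series.mixing_times > 0)
        if mask.sum() < 2:
            return 1.0
        slope = np.polyfit(series.mixing_times[mask], np.log(total[mask]), 1)[0]
        return min(max(-slope, 1e-3), 1e3)

    # column sums decay purely by relaxation (a population-weighted mix)
    r1_a = _r1_from_decay(series.i_aa + series.i_ba, i_a0)
    r1_b = _r1_from_decay(series.i_bb + series.i_ab, i_b0)
    return ExsyParams(
        rates=ExchangeRates(k_ab=k_ab, k_ba=k_ba),
        r1_a=r1_a,
        r1_b=r1_b,
        i_a0=i_a0,
        i_b0=i_b0,
    )


_PARAM_ORDER = ("k_ab", "k_ba", "r1_a", "r1_b", "i_a0", "i_b0")


def _params_from_lmfit(lp: lmfit.Parameters) -> ExsyParams:
    v = {name: math.exp(lp[f"log_{name}"].value) for name in _PARAM_ORDER}
    return ExsyParams(
        rates=ExchangeRates(k_ab=v["k_ab"], k_ba=v["k_ba"]),
        r1_a=v["r1_a"],
        r1_b=v["r1_b"],
        i_a0=v["i_a0"],
        i_b0=v["i_b0"],
    )


def fit_exsy(
    series: ExsySeries, init: Optional[ExsyParams] = None
) -> ExsyFitResult:
    """Joint least-squares fit of all four EXSY channels.

    All 4·|T| observations are fitted simultaneously and unweighted for
    the six parameters (k_ab, k_ba, r1_a, r1_b, i_a0, i_b0).  Each
    parameter is optimised as its logarithm to enforce positivity;
    standard errors are mapped back to the natural scale by the delta
    method (se_x = x · se_log_x), and the covariance likewise.

    Raises
    ------
    UnderdeterminedError
        If the series has fewer than 4 mixing times (6 free parameters
        against 4 observations per time point).
    """
    if len(series) < 4:
        raise UnderdeterminedError(
            f"need >= 4 mixing times to fit 6 parameters, got {len(series)}"
        )
    if init is None:
        init = init_guess_exsy(series)

    lp = lmfit.Parameters()
    init_values = {
        "k_ab": init.rates.k_ab,
        "k_ba": init.rates.k_ba,
        "r1_a": init.r1_a,
        "r1_b": init.r1_b,
        "i_a0": init.i_a0,
        "i_b0": init.i_b0,
    }
    for name in _PARAM_ORDER:
        v = max(init_values[name], 1e-6)
        lp.add(f"log_{name}", value=math.log(v), min=_LOG_LO, max=_LOG_HI)

    obs = series.intensities.ravel()

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = predict_exsy(_params_from_lmfit(p), series.mixing_times)
        return model.ravel() - obs

    minres = lmfit.minimize(
        residual, lp, method="least_squares", xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    fitted = _params_from_lmfit(minres.params)
    values = np.array(
        [
            fitted.rates.k_ab,
            fitted.rates.k_ba,
            fitted.r1_a,
            fitted.r1_b,
            fitted.i_a0,
            fitted.i_b0,
        ]
    )

    se: dict = {}
    cov = None
    if minres.covar is not None and minres.covar.shape == (6, 6):
        jac = np.diag(values)  # d x / d log x = x
        cov = jac @ minres.covar @ jac
        se = {
            name: float(math.sqrt(max(cov[i, i], 0.0)))
            for i, name in enumerate(_PARAM_ORDER)
        }
    else:
        se = {name: float("nan") for name in _PARAM_ORDER}

    rates = ExchangeRates(
        k_ab=fitted.rates.k_ab,
        k_ba=fitted.rates.k_ba,
        se_k_ab=se.get("k_ab"),
        se_k_ba=se.get("k_ba"),
    )
    fitted = ExsyParams(
        rates=rates,
        r1_a=fitted.r1_a,
        r1_b=fitted.r1_b,
        i_a0=fitted.i_a0,
        i_b0=fitted.i_b0,
    )
    rss = float(np.sum(np.asarray(minres.residual) ** 2))
    return ExsyFitResult(
        params=fitted,
        se=se,
        covariance=cov,
        rss=rss,
        converged=bool(minres.success),
        n_obs=obs.size,
        message=str(getattr(minres, "message", "")),
    )
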