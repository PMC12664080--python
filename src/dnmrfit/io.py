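"""Delimited-text readers/writers and the end-to-end analysis pipeline.

All on-disk formats are plain text: a small ``# key: value`` metadata
header followed by a CSV table.

spectrum     ``# spectrometer_freq_mhz: .. / # temperature_k: ..`` then
             columns ``shift_ppm,intensity``
EXSY         ``# temperature_k: .. / # field_mhz: ..`` then columns
             ``mixing_time_s,i_aa,i_ab,i_ba,i_bb``
temperature  columns ``temperature_k,k_ab,k_ba`` (or ``temperature_k,K_ab``)

Parse errors name the offending file, line and column.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .exchange import ExchangeRates, equilibrium_populations
from .exsy import ExsySeries, fit_exsy
from .lineshape import Spectrum1D
from .thermo import (
    TemperatureSeries,
    eyring_fit,
    predict_population_ratio,
    vant_hoff_fit,
)

__all__ = [
    "RunConfig",
    "read_spectrum",
    "write_spectrum",
    "read_exsy",
    "write_exsy",
    "read_temperature_series",
    "write_temperature_series",
    "run_pipeline",
]

SOLVENT_R2 = {"dmso": 3.0, "d2o": 4.0}  # exchange-free R2 presets, s^-1


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``solvent`` selects the fixed exchange-free R2 (dmso → 3 s^-1,
    d2o → 4 s^-1); an explicit ``r2_free`` overrides the preset.
    """

    solvent: str = "d2o"
    r2_free: Optional[float] = None
    spectrometer_freq: float = 700.0
    region: tuple = (3.75, 3.95)
    predict_at: Sequence[float] = field(default_factory=tuple)
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.solvent.lower() not in SOLVENT_R2:
            raise ValidationError(
                f"unknown solvent preset {self.solvent!r}; choose from {sorted(SOLVENT_R2)}"
            )
        if self.r2_free is not None and self.r2_free <= 0:
            raise ValidationError(f"r2_free must be > 0, got {self.r2_free}")

    @property
    def effective_r2(self) -> float:
        return self.r2_free if self.r2_free is not None else SOLVENT_R2[self.solvent.lower()]


def _read_table(path, required: Sequence[str]) -> tuple:
    """Read metadata header + CSV body; returns (meta dict, DataFrame).

    Raises ParseError naming missing columns and unparseable cells with
    1-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            header_lines += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                try:
                    meta[key.strip()] = float(value.strip())
                except ValueError:
                    meta[key.strip()] = value.strip()
        elif line.strip():
            break
        else:
            header_lines += 1
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: could not parse table: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +1 header row, +1 1-based
            lineno = header_lines + int(bad[0]) + 2
            raise ParseError(
                f"{path}, line {lineno}: non-numeric value in column {col!r}"
            )
        df[col] = pd.to_numeric(df[col])
    return meta, df, header_lines


def read_spectrum(path) -> Spectrum1D:
    meta, df, _ = _read_table(path, ["shift_ppm", "intensity"])
    freq = float(meta.get("spectrometer_freq_mhz", 0.0))
    temp = float(meta.get("temperature_k", 0.0))
    if freq <= 0:
        raise ParseError(f"{path}: header must set spectrometer_freq_mhz > 0")
    if temp <= 0:
        raise ParseError(f"{path}: header must set temperature_k > 0")
    axis = df["shift_ppm"].to_numpy()
    region = (
        float(meta.get("region_low_ppm", axis.min())),
        float(meta.get("region_high_ppm", axis.max())),
    )
    return Spectrum1D(
        shift_axis=axis,
        intensity=df["intensity"].to_numpy(),
        spectrometer_freq=freq,
        temperature=temp,
        region=region,
    )


def write_spectrum(spectrum: Spectrum1D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spectrometer_freq_mhz: {spectrum.spectrometer_freq}\n")
        fh.write(f"# temperature_k: {spectrum.temperature}\n")
        lo, hi = spectrum.region
        if not math.isnan(lo):
            fh.write(f"# region_low_ppm: {lo}\n# region_high_ppm: {hi}\n")
        pd.DataFrame(
            {"shift_ppm": spectrum.shift_axis, "intensity": spectrum.intensity}
        ).to_csv(fh, index=False, float_format="%.10g")


EXSY_COLUMNS = ["mixing_time_s", "i_aa", "i_ab", "i_ba", "i_bb"]


def read_exsy(path) -> ExsySeries:
    meta, df, header_lines = _read_table(path, EXSY_COLUMNS)
    temp = float(meta.get("temperature_k", 0.0))
    freq = float(meta.get("field_mhz", meta.get("spectrometer_freq_mhz", 0.0)))
    if temp <= 0:
        raise ParseError(f"{path}: header must set temperature_k > 0")
    if freq <= 0:
        raise ParseError(f"{path}: header must set field_mhz > 0")
    times = df["mixing_time_s"].to_numpy()
    neg = np.flatnonzero(times < 0)
    if neg.size:
        lineno = header_lines + int(neg[0]) + 2
        raise ValidationError(f"{path}, line {lineno}: negative mixing time")
    n = times.size
    intens = np.empty((n, 2, 2))
    intens[:, 0, 0] = df["i_aa"].to_numpy()
    intens[:, 0, 1] = df["i_ab"].to_numpy()
    intens[:, 1, 0] = df["i_ba"].to_numpy()
    intens[:, 1, 1] = df["i_bb"].to_numpy()
    return ExsySeries(
        mixing_times=times, intensities=intens, temperature=temp, spectrometer_freq=freq
    )


def write_exsy(series: ExsySeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_k: {series.temperature}\n")
        fh.write(f"# field_mhz: {series.spectrometer_freq}\n")
        pd.DataFrame(
            {
                "mixing_time_s": series.mixing_times,
                "i_aa": series.i_aa,
                "i_ab": series.i_ab,
                "i_ba": series.i_ba,
                "i_bb": series.i_bb,
            }
        ).to_csv(fh, index=False, float_format="%.12g")


def read_temperature_series(path) -> TemperatureSeries:
    meta, df, _ = _read_table(path, ["temperature_k"])
    temps = df["temperature_k"].to_numpy()
    if {"k_ab", "k_ba"}.issubset(df.columns):
        rates = [
            ExchangeRates(k_ab=a, k_ba=b)
            for a, b in zip(pd.to_numeric(df["k_ab"]), pd.to_numeric(df["k_ba"]))
        ]
        return TemperatureSeries(temperatures=temps, rates=rates)
    if "K_ab" in df.columns:
        return TemperatureSeries(
            temperatures=temps,
            equilibrium_constants=pd.to_numeric(df["K_ab"]).to_numpy(),
        )
    raise ParseError(f"{path}: need columns k_ab,k_ba or K_ab")


def write_temperature_series(series: TemperatureSeries, path) -> None:
    data = {"temperature_k": series.temperatures}
    if series.rates is not None:
        data["k_ab"] = [r.k_ab for r in series.rates]
        data["k_ba"] = [r.k_ba for r in series.rates]
    else:
        data["K_ab"] = series.equilibrium_constants
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: RunConfig, exsy_paths: Sequence) -> dict:
    """Fit every per-temperature EXSY file and run both thermodynamic fits.

    Per-file failures are recorded under ``failures`` and the pipeline
    continues with the remaining temperatures.  The report carries all
    fitted parameters with explicit unit suffixes in the keys, the
    populations at each temperature, and predicted A:B ratios at the
    requested temperatures.
    """
    per_temperature = []
    failures = []
    for p in exsy_paths:
        try:
            series = read_exsy(p)
            fit = fit_exsy(series)
            pops = equilibrium_populations(fit.params.rates)
            per_temperature.append(
                {
                    "file": str(p),
                    "temperature_k": series.temperature,
                    "fit": fit.to_dict(),
                    "populations": pops.to_dict(),
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            failures.append({"file": str(p), "error": f"{type(exc).__name__}: {exc}"})
    per_temperature.sort(key=lambda d: d["temperature_k"])
    report: dict = {
        "config": {
            "solvent": config.solvent,
            "r2_free_per_s": config.effective_r2,
            "spectrometer_freq_mhz": config.spectrometer_freq,
            "seed": config.seed,
        },
        "per_temperature": per_temperature,
        "failures": failures,
    }
    if len(per_temperature) >= 2:
        temps = np.array([d["temperature_k"] for d in per_temperature])
        rates = [
            ExchangeRates(
                k_ab=d["fit"]["params"]["rates"]["k_ab_per_s"],
                k_ba=d["fit"]["params"]["rates"]["k_ba_per_s"],
            )
            for d in per_temperature
        ]
        tseries = TemperatureSeries(temperatures=temps, rates=rates)
        thermo = vant_hoff_fit(tseries)
        report["vant_hoff"] = thermo.to_dict()
        report["eyring_ab"] = eyring_fit(tseries, "ab").to_dict()
        report["eyring_ba"] = eyring_fit(tseries, "ba").to_dict()
        report["predicted_ratio_a_to_b"] = {
            f"{t:g}_k": predict_population_ratio(thermo, t) for t in config.predict_at
        }
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of a pipeline report."""
    lines = ["Two-site exchange analysis", "=" * 26]
    for d in report["per_temperature"]:
        r = d["fit"]["params"]["rates"]
        lines.append(
            f"T = {d['temperature_k']:.0f} K: "
            f"k_AB = {r['k_ab_per_s']:.3f} s^-1, k_BA = {r['k_ba_per_s']:.3f} s^-1, "
            f"p_A = {d['populations']['p_a']:.3f}, p_B = {d['populations']['p_b']:.3f}"
        )
    for f in report.get("failures", []):
        lines.append(f"FAILED {f['file']}: {f['error']}")
    if "vant_hoff" in report:
        vh = report["vant_hoff"]
        lines.append(
            f"van't Hoff: dH = {vh['dH_j_per_mol'] / 1000:.1f} kJ/mol, "
            f"dS = {vh['dS_j_per_mol_k']:.1f} J/(mol K)"
        )
        ey = report["eyring_ab"]
        lines.append(
            f"Eyring (A->B): dH‡ = {ey['dH_act_j_per_mol'] / 1000:.1f} kJ/mol, "
            f"dS‡ = {ey['dS_act_j_per_mol_k']:.1f} J/(mol K)"
        )
        for t, ratio in report.get("predicted_ratio_a_to_b", {}).items():
            lines.append(f"predicted A:B at {t}: {ratio:.1f}:1")
    return "\n".join(lines)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
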