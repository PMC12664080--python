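# dnmrfit

Quantitative analysis of **two-site chemical exchange** in solution NMR,
built for slowly interconverting conformers — e.g. the cis/trans
sulfonamide rotamers of naphthalene-bis-sulfonamide Keap1–Nrf2 PPI
inhibitors, whose methoxy singlets double in the 3.75–3.95 ppm region.

Two states A (more shielded, lower ppm) and B interconvert with
first-order rates k<sub>AB</sub>, k<sub>BA</sub>. The package covers the
three ways these rates are measured and interpreted:

1. **Lineshape fitting** — the Bloch–McConnell absorption spectrum of an
   exchanging singlet pair,
   S(ω) = a · Re{ **1**ᵀ [R₂I + iΩ − X − iωI]⁻¹ **p** },
   with Ω = diag(ω_A, ω_B), X = [[−k_AB, k_BA], [k_AB, −k_BA]] and
   equilibrium populations **p**. R₂ (exchange-free) is fixed, not
   fitted: 3 s⁻¹ in DMSO, 4 s⁻¹ in D₂O.
2. **EXSY build-up fitting** — diagonal and cross-peak intensities as a
   function of mixing time T,
   I(T) = exp{[[−R₁A−k_AB, k_BA], [k_AB, −R₁B−k_BA]] T} · diag(I_A0, I_B0),
   fitted jointly in all four channels for
   (k_AB, k_BA, R₁A, R₁B, I_A0, I_B0).
3. **Thermodynamics** — populations p_A = k_BA/(k_AB+k_BA),
   p_B = k_AB/(k_AB+k_BA); van't Hoff regression of ln K_AB on 1/T for
   ΔH, ΔS; Eyring regression of ln(k/T) on 1/T (unit transmission
   coefficient) for ΔH‡, ΔS‡; and population-ratio prediction
   p_A/p_B = exp(+ΔG/RT) at any temperature.

A seeded synthetic-data generator produces spectra, EXSY series and
temperature studies with known ground truth, so every stage is testable
end to end without proprietary spectrometer data.

## Worked example

Fit a five-temperature EXSY study (here synthetic, 1 % noise) and
predict the cis:trans ratio at two crystallisation temperatures:

```python
from dnmrfit import *
from dnmrfit.io import RunConfig, run_pipeline, format_report, write_exsy

pre = COMPOUND25_D2O                       # reference D2O parameter set
study = gen_temperature_study(pre.thermo(), pre.activation())
paths = []
for t, r in zip(study.temperatures, study.rates):
    series = gen_exsy_dataset(
        ExsyParams(rates=r, r1_a=0.936, r1_b=0.842, i_a0=1.0, i_b0=1.0),
        noise=NoiseSpec(sd=0.01, fraction_of_max=True, seed=int(t)),
        temperature=t, spectrometer_freq=700.0)
    paths.append(f"exsy_{int(t)}k.csv")
    write_exsy(series, paths[-1])

report = run_pipeline(RunConfig(solvent="d2o", predict_at=(277.0, 291.0)), paths)
print(format_report(report))
```

```
Two-site exchange analysis
==========================
T = 280 K: k_AB = 0.185 s^-1, k_BA = 0.353 s^-1, p_A = 0.657, p_B = 0.343
T = 290 K: k_AB = 0.517 s^-1, k_BA = 0.793 s^-1, p_A = 0.605, p_B = 0.395
T = 300 K: k_AB = 1.419 s^-1, k_BA = 2.001 s^-1, p_A = 0.585, p_B = 0.415
T = 310 K: k_AB = 3.436 s^-1, k_BA = 4.625 s^-1, p_A = 0.574, p_B = 0.426
T = 320 K: k_AB = 8.326 s^-1, k_BA = 10.521 s^-1, p_A = 0.558, p_B = 0.442
van't Hoff: dH = 7.2 kJ/mol, dS = 20.9 J/(mol K)
Eyring (A->B): dH‡ = 68.4 kJ/mol, dS‡ = -14.2 J/(mol K)
predicted A:B at 277_k: 1.9:1
predicted A:B at 291_k: 1.6:1
```

Each line reports the per-temperature exchange rates recovered from the
four EXSY channels and the equilibrium fractions they imply; the
regressions then turn the temperature dependence of K_AB into a
reaction enthalpy/entropy and of k_AB into an activation barrier. With
1 % noise the estimates scatter around the generating values
(ΔH = 6.0 kJ/mol, ΔS = 16.8 J/(mol·K), ΔH‡ = 69.3 kJ/mol,
ΔS‡ = −11.3 J/(mol·K)); noiseless input returns them exactly.

The same steps are available as a CLI:

```sh
dnmrfit simulate-exsy --preset compound25 --noise 0.02 --seed 7 --out exsy.csv
dnmrfit fit-exsy exsy.csv
dnmrfit run-pipeline exsy_*.csv --solvent d2o --predict-at 277 --predict-at 291
dnmrfit predict-ratio --dh 6000 --ds 16.8 --temp 291
```

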