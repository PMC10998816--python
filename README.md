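# fermkin

Batch-fermentation kinetics for ethanol-producing yeasts: a simulator of
Monod/Luedeking–Piret batch cultures, the standard per-condition kinetic
descriptors, Monod saturation fitting of specific rates versus initial
substrate, and Tukey-HSD condition comparison with compact letter displays.

## Who it is for

Bioprocess and microbiology researchers who screen isolates or optimise
fermentation conditions (carbon load, salinity, pH) from shake-flask batch
time courses, and who want the whole analysis — from raw X(t)/P(t)/S(t)
series to "which condition is best, and is it significantly better?" — as
one reproducible, tested pipeline.  Because such studies typically publish
summary tables rather than raw trajectories, the package ships a synthetic
batch-fermentation generator with known ground truth, so every stage can be
validated end-to-end.

## The model and statistics at its core

For a batch culture with biomass X, ethanol P and substrate S (g/L):

- growth: dX/dt = μX with Monod kinetics μ = μ_max·S/(K_s + S), optionally
  damped by Andrews/Haldane substrate inhibition 1/(1 + S/K_i) and product
  toxicity (1 − P/P_crit)^n;
- production: dP/dt = (α·μ + β)·X (Luedeking–Piret);
- substrate: dS/dt = −(dX/dt)/Y_xs − (dP/dt)/Y_ps − m_s·X, S clamped at 0;
- pH/salinity stress enters as a cardinal-pH × salinity multiplier on μ_max
  and β.

Per-condition descriptors: peak ethanol E_p and biomass X_m, yields on
supplied sugar Y_P/S = E_p/S_G0 and Y_X/S = X_m/S_G0, volumetric
productivity Q_p = E_p/t_peak, substrate uptake Q_s, specific production
rate v_g = Q_p/X_m, and the log-linear specific growth rate μ (slope of
ln X vs t over the best exponential window).  Replicate-averaged rates
across initial-substrate levels are fitted by non-linear least squares to
rate(S_G0) = rate_max·S_G0/(K_s + S_G0), and condition grids are compared
by one-way ANOVA + Tukey HSD at α = 0.05 with compact letters (conditions
sharing a letter are not significantly different).

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

```python
from fermkin import (Condition, StressParams, simulate_batch,
                     compute_descriptors, ze75_preset, generate_study,
                     rate_vs_substrate, fit_monod)

# one noise-free batch: 150 g/L glucose, pH 4.5, seawater medium
params = ze75_preset(noise_cv=0.0)
cond = Condition(condition_id="glucose-150", s_g0=150.0, ph=4.5,
                 salinity="seawater")
d = compute_descriptors(simulate_batch(params, cond, StressParams()))
print(f"E_p  = {d.e_p:.2f} g/L at t = {d.t_peak:.0f} h")
print(f"Y_P/S = {d.y_ps:.3f} g/g   Q_p = {d.q_p:.3f} g/(L h)")

# growth-rate saturation across a glucose gradient, refit by Monod
records = generate_study(params, StressParams(),
                         s0_grid=[50, 100, 150, 200, 250], ph_grid=[4.5],
                         salinity_grid=["seawater"], replicates=1, seed=0)
fit = fit_monod(rate_vs_substrate(records, which="growth"))
print(f"mu_max = {fit.rate_max:.4f} 1/h, Ks = {fit.ks:.2f} g/L, R^2 = {fit.r2:.4f}")
```

prints

```
E_p  = 89.69 g/L at t = 72 h
Y_P/S = 0.598 g/g   Q_p = 1.246 g/(L h)
mu_max = 0.1369 1/h, Ks = 24.58 g/L, R^2 = 1.0000
```

i.e. the 150 g/L reference batch peaks at ~90 g/L ethanol after 72 h (a
0.598 g/g yield on supplied sugar), and log-linear growth rates estimated
from the simulated gradient recover the generating Monod parameters
(μ_max = 0.141 1/h, K_s = 24.40 g/L) to within ~3% and 1%.

The same workflow is available from the shell:

```bash
fermkin simulate tc.csv --seed 1 --s0 150 --replicates 3
fermkin descriptors tc.csv --out descriptors.csv
fermkin compare descriptors.csv --metric e_p
fermkin run-study --seed 1 --out study_out/
```

`run-study` chains everything — glucose gradient, pH grid (3–7), salinity
grid (distilled to 4 M NaCl), Monod fits, Tukey letter tables and optimum
identification — and writes a manifest for full reproducibility.

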