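# Methods

## Scope

`fermkin` analyses batch-fermentation time courses — biomass X(t), ethanol
P(t) and residual substrate S(t) in g/L over hours — the standard design for
screening and optimising ethanol-producing yeasts.  Because such studies
rarely deposit raw trajectories (they publish per-condition summary tables
and fitted saturation curves), the package pairs the analysis layer with a
synthetic-data generator that emulates the experiments: every downstream
stage is exercised end-to-end on data whose ground truth is known.

## Generative model

The generator integrates the minimal textbook structure consistent with the
summary kinetics this kind of study reports:

- **Growth** — Monod kinetics, μ(S) = μ_max·S/(K_s + S), optionally damped by
  - Andrews/Haldane substrate inhibition, ×1/(1 + S/K_i), reproducing the
    decline of performance at very high initial sugar (osmotic stress,
    catabolite repression), and
  - product toxicity, ×max(0, 1 − P/P_crit)^n, so growth ceases at high
    ethanol while fermentation can continue.
- **Product formation** — Luedeking–Piret: dP/dt = (α·μ + β·f)·X, a
  growth-associated term plus a non-growth-associated term.  The β term is
  deliberately *not* damped by product toxicity, so ethanol keeps
  accumulating slowly after growth stops, which is what stretches the
  production curve to the full horizon.
- **Substrate balance** — dS/dt = −(dX/dt)/Y_xs − (dP/dt)/Y_ps − m_s·X,
  clamped at S = 0 by a terminal integration event; all rates are zero
  afterwards.  With m_s = 0 the balance ΔS + ΔX/Y_xs + ΔP/Y_ps = 0 holds
  exactly at every output time (to integrator tolerance), which the tests
  verify at < 1e−6·s0.
- **Environmental stress** — a single multiplier f ∈ [0, 1] on μ_max and β:
  the three-parameter cardinal-pH model (zero at pH_min and pH_max, one at
  pH_opt) times a salinity term exp(−k·|m − m_opt|-style) on the molar-NaCl
  axis, with separate decay rates above (`sal_decay`, default 0.5 /M) and
  below (`sal_decay_hypo`, default 0.22 /M) the optimum.  The sub-optimum
  branch exists because a marine yeast grows best at seawater strength
  (~0.6 M NaCl); without it, distilled water would tie seawater and the
  salinity optimum would be undefined.  Labels map to molar equivalents:
  distilled → 0.0 M, half_seawater → 0.3 M, seawater → 0.6 M (≈35 g/L salt).
- **Noise** — multiplicative log-normal with mean 1 and stated CV
  (σ² = ln(1+cv²), μ = −σ²/2), applied after integration, per-replicate
  seeds derived from a study seed via `numpy.random.SeedSequence` spawn
  keys.  Concentrations are positive and heteroscedastic, as replicate
  assays are; the default replicate CV is 2%.

Integration uses LSODA with rtol 1e−8 / atol 1e−10; output sampling
(`dt_out`, default 2 h) is independent of internal stepping (halving
`dt_out` leaves shared-time values unchanged).

### Default parameter set (`ze75_preset`)

| parameter | default | unit | rationale |
|---|---|---|---|
| μ_max | 0.141 | 1/h | fitted growth saturation curve of the emulated study |
| K_s | 24.40 | g/L | idem |
| α | 3.93 | g/g | calibrated (below) |
| β | 0.125 | g/(g·h) | calibrated |
| Y_xs | 0.72 | g/g | calibrated; apparent ODE yield, not a physiological aerobic yield |
| Y_ps | 0.66 | g/g | calibrated; the emulated study reports ethanol yields near 0.6 g/g on supplied sugar |
| m_s | 0 | g/(g·h) | maintenance folded into β |
| P_crit, n | 80.5, 2 | g/L, – | growth stops near 80 g/L ethanol |
| K_i | none (650 when enabled) | g/L | substrate inhibition is an explicit switch |
| x0, s0 | 0.5, 150 | g/L | inoculum and reference glucose load |
| t_end, dt_out | 72, 2 | h | fermentation horizon and sampling |
| noise_cv | 0.02 | – | replicate variability |

α, β, P_crit were calibrated once by least squares so a noise-free 150 g/L
batch lands on peak biomass ≈ 9.04 g/L, peak ethanol ≈ 89.8 g/L, and ≈ 2 g/L
residual sugar at 72 h — the magnitudes of the screening table the preset
emulates.  The resulting descriptors are E_p 89.7 g/L, X_m 9.07 g/L, Q_p
1.25 g/(L·h), Q_s 2.05 g/(L·h), Y_P/S 0.598, v_g 0.137, μ 0.118.  K_i = 650
g/L places the ethanol optimum of a 50–250 g/L gradient at 175 g/L with a
decline above it.  Substrate inhibition is off by default so that the Monod
law is the *true* growth model and parameter-recovery checks are
well-posed; the study driver switches it on for the glucose-gradient axis,
where the interior optimum is the phenomenon of interest.

### What the generator does not emulate

No aerobic/anaerobic phase switch (real protocols often start with a short
aerobic lead-in), no temperature dependence, no CO₂/gas stripping, no
carbon-source-specific kinetics (all simulated batches are "glucose"), no
assay-specific error structure (the dichromate ethanol and DNS sugar assays
have their own biases).  Passing tests therefore demonstrate correctness of
the *analysis* under a plausible kinetic model, not the fidelity of that
model to any particular organism.

## Descriptors

For one time course: E_p = max P, X_m = max X, with t_peak the earliest
time attaining E_p.  Yields are on *supplied* substrate, Y_P/S = E_p/S_G0
and Y_X/S = X_m/S_G0 — a deliberate convention (industrial yield on sugar
load), not yield on consumed sugar.  Q_p = E_p/t_peak; Q_s =
(S(0) − S(t_peak))/t_peak uses the same window as Q_p for consistency (Q_s
is reported absent when no substrate series exists).  The summary specific
production rate is v_g = Q_p/X_m; this identity reproduces every printed
specific rate in the tables the package was validated against, while the
pointwise rate v(t) = (dP/dt)/X (central differences interior, one-sided at
the ends, negative values floored at 0) is exposed separately with its
maximum as `v_peak`.

The specific growth rate μ is the classical log-linear estimate: the
least-squares slope of ln X versus t over the contiguous window of ≥ 4
positive-biomass points maximising R², subject to a positive slope.  Ties
in R² (within 1e−9) prefer the longer, then the earlier, window, so exactly
exponential data report the full range.  This is an automated, reproducible
version of reading the exponential phase off a logarithmic plot; on
simulated data it recovers the generating μ(s0) to a few per cent (the
residual bias comes from substrate depletion and early product toxicity
inside the window).

Three tabulated yield cells in the published screening tables the defaults
are calibrated against are inconsistent with the yield definition given
their own tabulated peaks: a biomass-yield cell printed as 0.066 where
9.044/150 = 0.0603, and ethanol-yield cells printed as 0.6606 and 0.0656
where 11.89/150 = 0.0793 and 13.78/150 = 0.0919 (the latter two look
swapped but match neither way).  These appear to be typographical; the
implementation follows the definitions and does not reproduce those three
values.

## Monod fitting

`fit_monod` minimises Σ(rate_i − rate_max·s_i/(K_s + s_i))² with positivity
enforced by optimising log-parameters (trust-region reflective, ftol = xtol
= 1e−10, ≤ 500 evaluations).  Starting values use the Hanes–Woolf
linearisation (regress s/rate on s), exact on noise-free Monod data, with a
fallback of (1.2·max rate, median s) for degenerate inputs.  R² = 1 −
SSE/SST about the mean (the convention non-linear regression packages
print); it can be negative and is NaN when SST = 0.  Non-convergence is a
returned state (`converged=False`), never a silent answer.  Asymptotic
standard errors come from the analytic Jacobian at the optimum.

`rate_vs_substrate` averages per-condition μ or v_g over replicates and
pairs them with s_g0; the optional `exclude_above_peak` flag drops points
beyond the rate-maximising s_g0, because a Haldane-type decline is outside
the Monod family and otherwise flattens the fit (the default keeps all
points).  `recovery_experiment` quantifies estimator behaviour: at 5%
multiplicative rate noise on a 5-point 50–250 g/L grid, 200 replicates,
μ_max is recovered with |median bias| ≪ 5% and median R² ≈ 0.9.

## Condition comparison

One-way fixed-effects ANOVA (direct sums of squares) feeds Tukey's HSD:
q_ij = |mean_i − mean_j| / sqrt(MSW·(1/n_i + 1/n_j)/2), i.e. the
Tukey–Kramer harmonic form for unbalanced designs, compared against the
studentized-range quantile at (k, df_within, α) computed numerically from
the distribution (scipy's `studentized_range`), α = 0.05 by default.  For
k = 2 the statistic reduces algebraically to √2·|t| of the pooled t test.

Compact letters use insert-and-absorb in descending mean order: letter
classes are maximal sets of mutually non-significant groups; the top class
is lettered 'a'.  The construction guarantees the defining invariant — two
groups share a letter *iff* their comparison is non-significant — which the
tests verify by round-trip against thousands of random significance
matrices.  `find_optimum` returns the highest-mean condition together with
every condition sharing a letter with it (statistically co-optimal set).

Letters are computed for every descriptor with replicate data, not only
peak ethanol and biomass.

## Study driver and problem sizes

`run_study` chains three one-factor designs: a glucose gradient
(50–250 g/L at pH 4.5, seawater, substrate inhibition on), a pH gradient
(3–7 in 0.5 steps at 175 g/L glucose, the load at which the emulated pH
optimum was reported), and a salinity gradient (distilled, half- and full
seawater, 1–4 M NaCl at 150 g/L), each with 3 replicates at 2% CV by
default — 63 simulated batches, which completes in a couple of seconds.
Per-stage seeds are derived from the single study seed by hashing the stage
name, so stages are individually reproducible and identical configs yield
byte-identical outputs.  `scripts/acceptance.py` re-runs the reference
batch, both saturation-curve refits, the 200-replicate recovery experiment
and a full study, and reports every headline number it computes.

With these design sizes the pH optimum (4.5) and salinity optimum
(seawater) are recovered as the top mean across seeds; at 0.5-pH
resolution the nearest neighbours of the optimum are often statistically
co-optimal at n = 3, which the letter display makes explicit.

## Known limitations

- The apparent ODE yields (Y_xs = 0.72 in particular) are calibration
  artefacts required to reconcile near-0.6 g/g ethanol yields on supplied
  sugar with ~9 g/L biomass from 150 g/L glucose; they are not
  physiological constants.
- μ estimation is windowed log-linear regression; on noisy, sparsely
  sampled data the best-R² window selection is slightly optimistic.
- The production saturation curve (v vs s0) of the default simulator is
  nearly flat-to-declining over 50–250 g/L, so a Monod fit to it is poorly
  identified (K_s → 0); the study driver still writes the fit, flagged by
  its diagnostics, because fitting all points is the documented default.
- No alternative rate laws (Moser, Tessier, Contois), no weighted or
  robust regression, no multi-factor ANOVA or interactions.
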