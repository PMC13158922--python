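# Methods

## The reaction model

`porphkin` models the oxidation of a drug substrate by tert-butyl
hydroperoxide (tBuOOH) catalysed by the water-soluble iron porphyrin
FeTPPS, a biomimetic stand-in for the cytochrome P450 heme centre. The
kinetic scheme has three elementary channels:

1. **Activation** — FeTPPS + tBuOOH → FeTPPS\* (rate constant k₁); the
   activated species is the high-valent iron–oxo oxidant.
2. **Substrate oxidation** — S + FeTPPS\* → metabolite + FeTPPS (k₂);
   the catalyst is regenerated, closing the cycle.
3. **Catalyst degradation** — FeTPPS + tBuOOH → FeTPPS⁰ (k₃); an
   apparent, lumped descriptor of oxidative self-destruction, treated
   as a single second-order channel.

The corresponding mass-action ODEs are

    d[FeTPPS]/dt   = −(k₁+k₃)[FeTPPS][tBuOOH] + k₂[S][FeTPPS*]
    d[FeTPPS*]/dt  =  k₁[FeTPPS][tBuOOH] − k₂[S][FeTPPS*]
    d[tBuOOH]/dt   = −(k₁+k₃)[FeTPPS][tBuOOH] + δ
    d[S]/dt        = −k₂[S][FeTPPS*]

with initial conditions [FeTPPS]₀ = S₀/eqv, [FeTPPS\*]₀ = 0, [S]₀ = S₀,
and oxidant handling set by the dosing mode: one-shot places
[tBuOOH]₀ = eqv·S₀ in solution at t = 0 with δ = 0; continuous dosing
starts at [tBuOOH]₀ = 0 and feeds at the constant rate
δ = eqv·S₀/t_max. The **extended** variant adds a direct, non-catalytic
oxidation channel S + tBuOOH → metabolite (k₄) to the tBuOOH and S
equations, needed for substrates whose decay is biphasic.

Three bookkeeping pools (catalytic metabolite, non-catalytic
metabolite, degraded catalyst) are integrated alongside even though
they do not feed back into the rate laws; they make the two exact
conservation laws — total catalyst and total substrate — assertable at
every grid point, which the test suite does.

**Units.** Concentrations are mol L⁻¹ and time is seconds internally
(rate constants in L mol⁻¹ s⁻¹); data files carry minutes and are
converted on read. Detector response is linear,
area = `response_scale` × concentration, default 1. Because jointly
rescaling all concentrations by c and all bimolecular constants by 1/c
leaves trajectory shapes unchanged, peak areas can be fitted directly;
when no absolute concentration scale is supplied the fitted constants
are effectively "per response-unit per second".

**What is deliberately not modelled:** temperature dependence, tBuOOH
reduction products, the small volume exchange of the continuous-feed
syringe, pH as a continuous input (pH is a dataset label only), and any
spatial transport in the reaction cell.

## Numerical integration

LSODA (via `scipy.integrate.odeint`) with rtol 10⁻⁸ / atol 10⁻¹² by
default; the system can be stiff when k₂ ≫ k₁. Small negative
undershoots are clipped to zero on output; an undershoot beyond
10³ × atol raises an integration failure. The dense output grid is 601
evenly spaced points over [0, t_max] unless a grid is given. The test
suite cross-checks the solver against an independently written
fixed-step explicit-Euler integration at 1 ms steps; agreement is
asserted at 10⁻⁴ relative to each species' trajectory maximum (several
species start at or pass through zero, so pointwise relative error is
not well defined).

## The synthetic-data generator

The generator reproduces the bench design used throughout: S₀ =
500 µmol L⁻¹, 10 oxidant equivalents fed continuously over 60 min,
sampling at 2, 4, 6, 8, 10, 15, 20, 25, 30, 40, 50, 60 min, three
replicates. Noise is multiplicative log-normal with mean 1 and
relative SD `cv` (default 0.05), plus an optional additive floor
(default 0), truncated at zero — so replicate scatter grows with
signal, the heteroscedastic pattern real chromatographic data show.
The default synthetic truth is k₁ = 2, k₂ = 200, k₃ = 0.2
L mol⁻¹ s⁻¹, which yields ~76% substrate conversion in 60 min with a
clear FeTPPS\* rise; published fitted constants are not reused because
their effective units depend on the unknown response scale. Metabolite
channels are generated at half the substrate response scale (their
molar response coefficients are unknown in practice) and are never
fitted.

The generator does **not** emulate chromatographic drift, carryover,
ionisation suppression, or replicate-level systematic offsets, so
passing recovery tests demonstrate estimator correctness under the
assumed noise model, not robustness to instrument artefacts.

## Parameter estimation

Only the substrate channel is fitted. Residuals (observed − predicted
areas, pooled over replicates in fixed replicate/time order) are
minimised by trust-region least squares in log-parameter space, which
enforces positivity and matches the log-scale Wald intervals used for
reporting. Manual initial-guess inspection is replaced by a multistart:
16 log-uniform draws (default) over [10⁻³, 10³] times the dimensional
scale k_ref = 1/(S₀·t_max), with a deterministic anchor start at k_ref.
Implementation details that matter in practice:

- residuals are normalised by the mean absolute observed area inside
  the optimiser (same least-squares problem, meaningful stopping
  criteria at mol/L-scale magnitudes);
- the search is bounded to k_ref × [10⁻⁸, 10⁸]: when a channel carries
  no information its log-constant otherwise drifts towards −∞ on a flat
  plateau, wasting thousands of evaluations;
- the finite-difference step (10⁻³ in log-parameters) is kept well
  above the integrator's error so numerical Jacobians are not noise;
- integration failures at trial points return large penalty residuals
  so a multistart sweep survives bad corners of parameter space;
- convergence: relative SSR change < 10⁻¹⁰ or projected gradient
  < 10⁻⁸, at most 500 iterations per start.

Uncertainty is the Gauss–Newton covariance σ̂²(JᵀJ)⁻¹ in log-space with
σ̂² = SSR/(n−p). A singular JᵀJ falls back to the pseudo-inverse and
sets an identifiability warning; note the pseudo-inverse assigns *zero*
variance to directions the data do not constrain at all, so such SEs
understate uncertainty — the warning, the |r| > 0.9 correlation flags
and unbounded-interval flags are the honest signal.

When the standard and extended models are fitted as a nested pair, the
extended fit is warm-started from the standard solution (with k₄ at
k_ref and nearly zero), and the standard fit is re-seeded from the
extended solution if that found a better region — so AIC differences
reflect the k₄ channel, not multistart luck.

**Initial-response refinement** evaluates 20 evenly spaced candidate
initial responses spanning the replicate-pooled mean of the earliest
sampled time ± 3 "global" standard deviations (interpreted as the
replicate SD of that earliest time; a `global_sd` option overrides it),
refits at each, and keeps the candidate minimising the residual SD,
never returning a fit worse than the unrefined one. With zero SD the
mean is returned unchanged.

## Uncertainty propagation

95% intervals are exp(log θ̂ ± 1.96·SE_log). Monte Carlo bands redraw
100 parameter sets, re-integrate each, and take pointwise 2.5/97.5
percentiles. The default draws normally in *log*-parameters
(consistent with positivity and the reported intervals); a
`scale="natural"` mode draws normally on the original scale truncated
at zero, the literal textbook recipe. Draws are independent per
parameter by default (`correlated=True` uses the fitted covariance).
Draws that fail to integrate are dropped and counted; more than 50%
failures aborts the band with a diagnostic — which in practice marks
fits whose standard errors were meaninglessly large to begin with.

## Model selection

Parsimony rule between the standard and extended variants: adopt the
extended model only if its Gaussian AIC (n·ln(SSR/n) + 2p, constants
dropped; differences only are meaningful) beats the standard model's by
at least 2 **and** the direct channel is non-negligible —
k₄·max([S][tBuOOH]) exceeding 5% of k₂·max([S][FeTPPS\*]) along the
fitted extended trajectory. Ties keep the standard model; an
unconverged fit defers the decision.

## Clearance normalisation

Under the steady-state reading of the cycle, the oxidation rate is
v = k₂[S][FeTPPS\*], so the system's clearance is CL = v/[S] =
k₂[FeTPPS\*] and k₂/CL·[FeTPPS\*] = 1 identically — an algebraic
identity the package asserts at 10⁻¹⁰ as a bookkeeping check. The
correspondence to enzyme kinetics (k₂ ≈ k_cat, [FeTPPS\*] ≈ [E]_total,
CL_int = k_cat[E]_total/K_M at low substrate) motivates normalising the
fitted k₂ by literature liver-microsome intrinsic clearance; the
package ships the published 14-row reference table of fitted constants
and clearances for the seven-drug panel and reproduces its normalised
column exactly under one-significant-figure round-half-up (one printed
row is internally inconsistent and flagged as such). Clearances quoted
per mg of microsomal protein are converted with the single standard
factor 0.07 (folding in 40–50 mg protein/g liver and 21–25 g liver/kg
body weight), applied exactly as published. Datasets whose simulated
[FeTPPS\*] varies rapidly — coefficient of variation above 0.5 over the
window [0.2·t_max, t_max], both configurable — are excluded from the
normalisation, since CL = k₂[FeTPPS\*] presumes a slowly varying
activated-catalyst pool. A Henderson–Hasselbalch helper computes mean
formal charge from user-supplied pKa values (each base contributes
+1/(1+10^(pH−pKa)), each acid −1/(1+10^(pKa−pH))).

## Study conditions and known limitations

The repeated-fit studies (parameter recovery, CI coverage, model
selection, band coverage) run 100 seeded repetitions at the default
design and cv = 0.05, with a leaner fit configuration (4 or 3 starts
anchored at k_ref, 150-iteration budget, integration rtol 10⁻⁶) that
reproduces the full-configuration results on probe seeds.

The biphasic study condition is k₁ = 10, k₂ = 200, k₃ = 10, k₄ = 0.3:
fast activation and equally fast catalyst death halt the catalytic
phase early and the direct channel continues — a two-step decay the
standard model cannot approximate (best-fit rms ≈ 3% of S₀), with
~89% of substrate flux through the direct channel and k₄ three orders
below k₂.

**Practical identifiability at the default truth.** With k₂ = 200 the
activated catalyst equilibrates on a ~10 s timescale while the first
sample is taken at 120 s, so the data sit deep in the quasi-steady-state
regime where substrate decay is governed by k₁[FeTPPS][tBuOOH]: the
likelihood is nearly flat in k₂ (a factor-2 shift changes SSR by ~0.2%
of the noise SSR) and bimodal — a second mode with k₃ → 0 and small k₂
fits 5%-noise data marginally better than the truth on a large fraction
of seeds. Consequently k₂ recovery within a factor of 2 and nominal
Wald coverage are *not* achieved at this design (measured ≈ 9% and
≈ 63–74% respectively over 100 seeds), and roughly one run in ten
yields standard errors so large that no Monte Carlo band can be
constructed. This is a property of the experimental design and noise
level, not of the optimiser — the same practical-identifiability
limitation the diagnostics module exists to flag (and that motivates
its correlation and SE warnings). Earlier sampling, one-shot dosing or
lower noise would restore identifiability; the package keeps the stated
study conditions and reports the honest rates.
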