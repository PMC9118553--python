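# Methods

## Kinetic model

The package assumes a one-compartment fish with first-order kinetics,
`dC_F/dt = k_U·C_W(t) − k_T·C_F`, `C_F(0) = 0`. During the exposure
phase the water concentration is a polynomial `C_W(t) = b0 + b1·t
(+ b2·t²)`; the fish trajectory is then available in closed form via
the integrating factor `e^{k_T t}` and exact antiderivatives of
`tⁿ·e^{k_T t}`. The closed form is written with `e^{−k_T t}` factors
kept inside the bracket so it stays numerically stable for stiff
elimination (`k_T·t ≫ 1`). A DOP853 integration of the same ODE
(`rtol 1e-11`, `atol 1e-13`) acts as an independent oracle; the two
agree to better than 1e-8 relative error wherever the trajectory is
more than 1e-6 of its peak (deeper in the depuration tail of stiff
cases the concentration underflows below any integrator's absolute
resolution, and the comparison is not meaningful).

After the exposure end the fish concentration decays exponentially
from its end-of-exposure value. Depuration-phase water forcing
defaults to zero, because measured depuration concentrations were at
least two orders of magnitude below exposure levels; a config switch
(`depuration_water="piecewise"`) instead carries the mean measured
depuration level as a constant residual forcing. Negative polynomial
predictions are clipped to zero (with a warning) wherever water
concentrations are *evaluated*; the closed-form fish solution uses the
unclipped polynomial and warns if the polynomial goes negative inside
its fitted range, since clipping would break the analytic solution.

Time zero is the start of exposure; the exposure/depuration boundary
is always passed explicitly and never inferred from the data.

## Water model pre-selection

A linear and a quadratic trend are fitted to the exposure-phase water
data by ordinary least squares and the order with the lower BIC is
kept (ties go to the lower order). BIC is computed on raw
concentrations in the Gaussian form `n·ln(RSS/n) + p·ln(n)` with
`p = order + 2` (the coefficients plus the residual variance). A
relative sigma floor of 1e-9 times the mean concentration keeps BIC
finite on exact-fit toy data. This step fixes only the polynomial
*order*; the coefficients are re-estimated jointly inside the Bayesian
model, so the selection does not leak water-fit point estimates into
the kinetic inference.

## Joint Bayesian inference

For one chemical the model has parameters `k_U, k_T, b0, b1 (, b2),
σ_w, σ_f`. The default error model is lognormal on both matrices —
reported variability is CV-like (water replicate RSD 7–22%, inter-fish
RSD 18–26%) and concentrations are strictly positive — with an
additive-normal alternative via `error_model="normal"`. Fish
observations enter at the individual-fish level, not as time-point
means.

Priors are weakly informative: half-normal with scale 10× a crude
moment estimate for `k_U` and `k_T` (the crude `k_T` comes from the
depuration log-slope, the crude `k_U` from the peak fish/water ratio),
normal with a wide data-scaled sd for the water coefficients, and
half-Cauchy(1) for both σ's. Sampling is over `log k_U, log k_T, b,
log σ_w, log σ_f` with the appropriate Jacobian terms.

The sampler is an affine-invariant ensemble (emcee, 32 walkers, 80%
differential-evolution moves + 20% snooker moves), initialized in a
tight ball around the posterior mode found by Nelder–Mead.
`n_chains` (default 4) independent ensembles are run from seeds
derived from the single config seed; convergence is assessed with the
rank-normalized split R-hat across ensembles (arviz), warning above
1.01. Runs are bit-reproducible for a fixed config. Defaults are 4000
iterations with 2000 discarded, which on the study-like designs used
in the tests yields R-hat ≲ 1.005 in a few seconds per chemical on one
CPU; the test suite uses 2-chain/2500-iteration settings for
repetition-heavy checks (coverage over 20 simulated studies), where
calibrated posteriors matter but publication-grade diagnostics do not.

Point estimates are posterior medians with central 95% credible
intervals. The BCF is summarized from the per-draw ratio `k_U/k_T`,
never from the ratio of summaries. Mechanistic quantities (`k_2`,
`k_B-BCF`, `D`) are computed draw-wise so their uncertainty is
propagated exactly.

A per-chemical `exclude_before_h` option drops early-time fish data;
this handles the surface-sorption artifact seen for the most
hydrophobic chemical (a fast initial step change inconsistent with a
single compartment) by exclusion rather than by adding a second
compartment.

## Stepwise analytic estimator

The simpler estimator assumes the water concentration is constant
between sampling occasions (the mean of that occasion's replicates)
and propagates the analytic solution interval by interval:

    C_F(t_{i+1}) = C_F(t_i)·e^{−k_T Δt} + (k_U/k_T)·C̄_W,i·(1 − e^{−k_T Δt})

`(k_U, k_T)` minimize squared residuals of log fish concentrations
(Levenberg–Marquardt over the log parameters). Confidence intervals
come from a nonparametric residual bootstrap (default 500 resamples,
seeded): log-scale fish residuals are pooled across time points,
resampled onto the fitted trajectory, and the water occasion means are
re-drawn from their replicate residuals, so the interval includes the
water-forcing uncertainty the point fit conditions on. Resampling
*cases* within 3-fish groups would understate the spread by roughly
√(2/3) — the standard small-group bootstrap bias — which is why the
residual form is used. On study-like synthetic data the stepwise
point estimates agree with the Bayesian medians within a few percent
and the interval widths are comparable; the stepwise route is a
cross-check, not a replacement.

## QA screens

- LOQ = control-fish mean + 10·sd; LOD = mean + 3·sd (sample sd).
- Kinetic fits use only time points where *all* fish exceed the LOQ
  (sub-LOQ data are positively biased and would bias k_T downward).
  Steady-state estimation keeps sub-LOQ values above the LOD, because
  discarding them would bias the plateau mean upward. Censored values
  keep their measured value plus a flag — no LOQ/2 substitution.
- Outlier rule: an interior point whose value exceeds the mean of the
  adjacent time points' means by more than 10× the mean RSD *as a
  relative deviation* (`(v − m)/m > 10·RSD`) is flagged; endpoints are
  never flagged. The rule is operationalized as a relative exceedance
  because RSD is dimensionless; this reading is isolated in one
  function should the absolute reading ever be preferred.

## Mechanistic layer

Physiological defaults describe the juvenile rainbow trout of the
reference experiment: `M = 0.024 kg`, `ρ_M = 1 kg L⁻¹`,
`f_MLF = 0.0125` (phospholipid fraction with equivalent sorption
properties). The gill area default `A = 5.9e-3 m²` was back-derived by
inverting the gill-uptake equation with the published `(k_U, D,
D_MLW)` of tridecylsulfonate; it is configurable, and
`gill_area_allometric` provides an allometric hook (`A = 0.114·M^0.794`,
calibrated through the same point) for other fish sizes. Note that
relative differences in `D` between chemicals are independent of `A`,
`ρ_M` and `M`; only absolute magnitudes are sensitive to them.

`k_B-BCF = k_T − k_2` is clamped at zero (with a flag) if the
estimated gill elimination exceeds total elimination, which can happen
through error in the physiological constants. The baseline screening
BCF is `f_MLF·D_MLW` — equilibrium partitioning with no
biotransformation — and shares its formula with the fish–water
distribution ratio by construction.

The hepatic clearance model is the well-stirred liver with a
blood/water distribution ratio proportional to `D_MLW`, reparameterized
to its two identifiable composites: `k_B = 1/(a + b·D_MLW)` with
`a = V_D/Q_B` (h) and `b = V_D·f_MLB/Q_LW` (h·kg L⁻¹). The individual
physiological constants are *not* identifiable from `(D_MLW, k_B)`
data and are deliberately not exposed as free parameters. The fit
minimizes squared log10 residuals (the quantity spans orders of
magnitude) with a deterministic 30-point multi-start Nelder–Mead over
`(log a, log b)`; it is invariant to input order and reproduces both
asymptotic regimes (constant at low `D_MLW`, `∝ 1/D_MLW` at high).

## S9 depletion and IVIVE

Depletion rates come from OLS of ln(concentration) on incubation time;
significance is a two-sided t-test of zero slope at α = 0.05 (the
conventional level; the reference analysis states only that some
chemicals showed "no significant clearance"). Non-significant assays
are reported at `LL_S9/3`, the assay's detection floor divided by
three. `LL_S9` is a supplied assay constant (default 0.006 h⁻¹, which
makes the floor 0.002 h⁻¹); `estimate_ll_s9` computes a candidate from
the residual scale and incubation design — the smallest slope whose
95% CI excludes zero — clearly an estimate, not a measurement.

The IVIVE chain is: intrinsic clearance per mg S9 protein
(`k_dep / P_assay`), scaled by S9 protein yield per gram liver and the
liver-somatic index to a per-kg-fish intrinsic clearance; a free
fraction `1/(f_MLB·D_MLW)` when binding is D_MLW-proportional;
well-stirred combination with hepatic blood flow `Q_B`; division by
the distribution volume `V_D`. All scaling constants live in
`IviveParams` with literature-style trout defaults and are logged per
call for audit. Absolute `k_B-S9` values depend directly on these
constants; the package's guarantees are the closed-form equivalence of
the chain, its monotonicity in `k_dep`, the flow-limited ceiling
`Q_B/V_D`, and the non-increasing dependence on `D_MLW` — the same
shape as the hepatic clearance model.

Single-vs-mixture assay comparison uses a two-regression
slope-difference t-test with `n₁ + n₂ − 4` degrees of freedom.

## Synthetic data generator

The generator emulates the reference study design: 96 h exposure +
168 h depuration; 14 exposure-phase water occasions in triplicate;
~10 fish occasions spanning both phases with 3 fish each; lognormal
multiplicative noise with unit median (water CV default 0.12, within
the reported 7–22%; fish CV default 0.22, within 18–26%); linearly
declining water trends for the chemicals that showed them (factor 2
over the exposure for three chemicals, factor 4 for one); depuration
water at 1/100 of the exposure level; control fish near zero defining
LOQ/LOD censoring flags. The ten ground-truth presets carry the
published `(k_U, k_T, log D_MLW)` of the eight kinetically
quantifiable chemicals; the two fast-eliminated chemicals (whose rate
constants were not quantifiable in vivo) are assigned `k_T = 0.5` and
`0.3 h⁻¹` — fast enough to plateau by ~6 h — with `k_U = BCF·k_T` so
their steady-state BCFs match the published values. These two rate
constants are assumptions, not measurements.

What the generator does **not** emulate: persistent per-fish random
effects (inter-fish noise is independent per observation, since only
per-time-point RSDs are reported), analytical bias, sorption to
aquarium surfaces, the mechanism of water decline (only its
phenomenological trend), and the real study's exact sampling schedule
(not published; the defaults are a plausible emulation and fully
configurable). Passing recovery/coverage tests on these simulations
therefore demonstrates estimator correctness under the stated noise
structure — not robustness to every artifact of real data.

## Numerical choices and degenerate inputs

- Non-finite or out-of-domain parameters score −∞ in the joint
  density (MCMC rejection), never raise.
- Sampler-space coordinates are bounded at |log x| ≤ 50 to avoid
  overflow excursions.
- BIC order selection ties break to the lower order; an exact fit is
  handled by the sigma floor.
- The clearance fit requires all `k_B, D_MLW > 0`; `loglog_ols`
  requires n ≥ 3 and a non-constant predictor.
- Steady-state estimation requires ≥2 fish and ≥1 water observation
  in the plateau window.
- Fewer than 3 usable fish time points raises an error directing the
  caller to the steady-state estimator.
- All randomness (MCMC, bootstrap, simulation) flows from explicit
  integer seeds through `numpy.random.Generator`; seeded runs are
  bit-reproducible.

## Problem sizes used in the test suite

Simulation-based checks run at sizes a reviewer can re-run casually:
200 replicates for scalar Monte-Carlo checks (water-model selection,
S9 type-I error and power, steady-state recovery), 20 simulated
studies for credible-interval coverage (binomial tolerance at n = 20:
at least 16 of 20 intervals must cover), and single seeded studies for
posterior recovery and cross-method agreement. These sizes were chosen
as the package's own trade-off between statistical resolution and a
suite that finishes in minutes.

## Known limitations

- One compartment only; chemicals with a fast surface-sorption
  compartment are handled by early-time exclusion, not modelled.
- The lognormal/normal error choice of the original analysis is
  unknown; both are implemented, lognormal is the default, and the
  choice is a config switch rather than a claim.
- IVIVE absolute values inherit the uncertainty of the physiological
  scaling constants; cross-chemical comparisons are more robust than
  absolute rates.
- The hepatic clearance composites `(a, b)` are fit-level parameters;
  no attempt is made to decompose them into `V_D, f_MLB, Q_LW, Q_B`.
- Below-LOQ fish values are used only by the steady-state path; no
  formal censored-likelihood treatment is implemented.
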