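# surfbcf

Toxicokinetic analysis of bioconcentration experiments for anionic
surfactants in fish: rate-constant estimation from fish/water time
series, mechanistic decomposition of elimination via membrane–water
partitioning, and in vitro–in vivo extrapolation (IVIVE) of liver S9
clearance assays.

## Who this is for

Environmental toxicologists and exposure modellers who run (or
evaluate) flow-through bioconcentration studies — e.g. OECD-305-style
designs — on ionizable surfactants, where water concentrations drift
during exposure, fish concentrations are censored near the limit of
quantitation, and the bioconcentration factor must be estimated
kinetically rather than from an assumed steady state.

## The model

Fish uptake and elimination follow a one-compartment model with
first-order kinetics:

    dC_F/dt = k_U · C_W(t) − k_T · C_F

with C_F the concentration in fish (µg kg⁻¹ ww), C_W the concentration
in water (µg L⁻¹), k_U the uptake rate constant (L kg⁻¹ ww h⁻¹) and
k_T the overall elimination rate constant (h⁻¹). The BCF is k_U/k_T.
C_W(t) is modelled as a linear or quadratic polynomial (order chosen
by BIC) because water concentrations can decline severalfold over the
exposure phase; the fish equation is then solved in closed form and
embedded in a joint Bayesian model with separate error scales for the
water and fish observations, sampled by ensemble MCMC. A simpler
stepwise analytic estimator (piecewise-constant water forcing,
log-least-squares, residual bootstrap) serves as a cross-check, and a
steady-state ratio estimator covers chemicals eliminated too fast for
kinetic fitting.

The mechanistic layer interprets the fitted constants through the
membrane lipid–water distribution ratio D_MLW:

    k_U = D · ρ_M · D_MLW · A · 1000 / M      (gill diffusion)
    k_T = k_2 + k_B,  k_2 = k_U / (f_MLF · D_MLW)
    k_B = 1 / (a + b · D_MLW)                 (well-stirred liver)

giving the membrane diffusion coefficient D, the gill elimination rate
constant k_2, the in vivo biotransformation rate constant
k_B-BCF = k_T − k_2, the baseline screening BCF f_MLF·D_MLW (the
partitioning ceiling absent biotransformation), and a two-parameter
hepatic clearance model linking biotransformation to membrane
sequestration. The S9 module fits first-order substrate-depletion
rates, applies the LL_S9/3 reporting floor to non-significant slopes,
and scales in vitro rates to whole-body k_B-S9 with a well-stirred
liver IVIVE chain.

## Worked example

`examples/01_simulate_and_fit.py` simulates a 4-day exposure / 7-day
depuration study for a slowly eliminated sulfonate (triplicate water
samples with 12% RSD, three fish per time point with 20% RSD, water
declining twofold over the exposure) and fits it both ways:

```
truth     : k_U=0.700  k_T=0.0240  BCF=29.2
bayes     : k_U=0.657 (0.608-0.710)  k_T=0.0240  BCF=27.4 (25.8-29.1)
stepwise  : k_U=0.645  k_T=0.0241  BCF=26.8
```

The joint posterior recovers the generating rate constants within a
few percent; the 95% interval shows the resolution such a design
affords. `examples/02_mechanistic_layer.py` runs the mechanistic layer
over the published ten-surfactant rainbow-trout panel and prints,
among other things, the fitted hepatic clearance model

```
clearance model: k_B = 1/(3.89 + 2.07e-04 * D_MLW)
RMSE of log10 residuals: 0.180
baseline BCF exceeds measured BCF by 1.2-2.5 orders of magnitude
```

— biotransformation dominates elimination (k_B-BCF exceeds gill
elimination k_2 by over an order of magnitude for every chemical), and
a single pair of clearance composites describes all ten surfactants.
`examples/03_s9_ivive.py` and `examples/04_full_pipeline.py` cover the
S9/IVIVE chain and the end-to-end pipeline; a thin CLI (`surfbcf
simulate|fit|mechanistic|ivive|report`) wraps the same functions for
shell use.

## Layout

- `src/surfbcf/` — library (`kinetics`, `water`, `inference`, `qa`,
  `mechanistic`, `s9`, `simulate`, `io`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — modelling assumptions, defaults and limitations
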