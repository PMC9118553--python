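"""Simulate a bioconcentration study and recover its kinetics.

Generates a synthetic 4-day exposure / 7-day depuration experiment for
one slowly eliminated surfactant (triplicate water samples, three fish
per time point, lognormal noise at the design RSDs), then estimates
the uptake rate constant k_U, the elimination rate constant k_T and
the BCF = k_U/k_T with the joint Bayesian model, and cross-checks with
the stepwise analytic estimator.
"""

import warnings

from surfbcf import (
    InferenceConfig,
    SimDesign,
    SimTruth,
    run_mcmc,
    simulate_study,
    stepwise_fit,
    summarize,
)

truth = SimTruth(
    chem_id="C14SO3", k_u=0.70, k_t=0.024,
    b0=7.6, b1=-7.6 * 0.5 / 96,  # water declines ~2x over the exposure
    log_dmlw=4.95,
)
dataset = simulate_study(truth, SimDesign(seed=42))

config = InferenceConfig(seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bayes = summarize(run_mcmc(dataset, config))
    stepwise = stepwise_fit(dataset, config)

print(f"truth     : k_U={truth.k_u:.3f}  k_T={truth.k_t:.4f}  "
      f"BCF={truth.bcf:.1f}")
print(f"bayes     : k_U={bayes.k_u:.3f} "
      f"({bayes.k_u_ci.lower:.3f}-{bayes.k_u_ci.upper:.3f})  "
      f"k_T={bayes.k_t:.4f}  BCF={bayes.bcf:.1f} "
      f"({bayes.bcf_ci.lower:.1f}-{bayes.bcf_ci.upper:.1f})")
print(f"stepwise  : k_U={stepwise.k_u:.3f}  k_T={stepwise.k_t:.4f}  "
      f"BCF={stepwise.bcf:.1f}")
print()
print("Both estimators recover the generating kinetics from noisy data;")
print("the 95% intervals quantify what an 11-day, 3-fish-per-point")
print("design can resolve at ~20% inter-fish variability.")
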