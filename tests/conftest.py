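"""Shared fixtures: simulated studies and (expensive) posterior runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from surfbcf import (
    InferenceConfig,
    SimDesign,
    SimTruth,
    run_mcmc,
    simulate_study,
    stepwise_fit,
    summarize,
)

# ground truth mirroring the tetradecylsulfonate preset: slow elimination,
# declining water trend, design noise levels
C14_TRUTH = SimTruth(
    chem_id="C14SO3",
    k_u=0.70,
    k_t=0.024,
    b0=7.6,
    b1=-7.6 * 0.5 / 96.0,
    log_dmlw=4.95,
)


@pytest.fixture(scope="session")
def c14_study():
    design = SimDesign(seed=42, water_cv=0.12, fish_cv=0.20)
    return simulate_study(C14_TRUTH, design)


@pytest.fixture(scope="session")
def c14_posterior(c14_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_mcmc(c14_study, InferenceConfig(seed=1))


@pytest.fixture(scope="session")
def c14_bayes(c14_posterior):
    return summarize(c14_posterior)


@pytest.fixture(scope="session")
def c14_stepwise(c14_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stepwise_fit(c14_study, InferenceConfig(seed=1))


@pytest.fixture(scope="session")
def coverage_fits():
    """Bayesian fits of 20 independently simulated studies (fixed seeds).

    Reduced chain settings: coverage and agreement checks need correct
    posteriors, not publication-grade diagnostics.
    """
    cfg = InferenceConfig(n_chains=2, n_iter=2500, n_warmup=1000, seed=0)
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(20):
            design = SimDesign(seed=1000 + rep, water_cv=0.12, fish_cv=0.20)
            ds = simulate_study(C14_TRUTH, design)
            cfg_rep = InferenceConfig(
                n_chains=2, n_iter=2500, n_warmup=1000, seed=1000 + rep
            )
            fits.append(summarize(run_mcmc(ds, cfg_rep)))
    return fits


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
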