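"""Polynomial water-concentration trend fitting and BIC order selection.

Exposure-phase water concentrations drifted for several chemicals
(microbial degradation is a plausible cause), so a linear or quadratic
time trend is fitted by ordinary least squares and the order is chosen
by the Bayesian information criterion. This pre-selection fixes the
polynomial order only; the coefficients are re-estimated jointly inside
the Bayesian kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import WaterPolynomial

__all__ = ["WaterFit", "fit_water_poly", "select_water_model"]

# Relative sigma floor keeping BIC finite on exact-fit (zero-residual) data.
_SIGMA_FLOOR_REL = 1e-9


@dataclass
class WaterFit:
    poly: WaterPolynomial
    sigma_w: float
    bic: float
    n_obs: int


def fit_water_poly(times, concs, order: int) -> WaterFit:
    """Least-squares polynomial fit of water concentration vs time.

    BIC = n·ln(RSS/n) + p·ln(n) with p = order + 2 free parameters
    (order+1 coefficients plus the residual variance).
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n = times.size
    if n < order + 2:
        raise ValueError(f"need at least {order + 2} observations")
    if np.ptp(times) == 0:
        raise ValueError("degenerate design: all sampling times equal")

    # ascending-power design matrix [1, t, (t^2)]
    X = np.vander(times, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, concs, rcond=None)
    resid = concs - X @ coef
    rss = float(resid @ resid)
    floor = (_SIGMA_FLOOR_REL * max(abs(float(np.mean(concs))), 1e-300)) ** 2 * n
    rss_b = max(rss, floor)
    p = order + 2
    bic = n * np.log(rss_b / n) + p * np.log(n)
    sigma_w = float(np.sqrt(rss / max(n - (order + 1), 1)))

    b = list(coef) + [0.0] * (3 - len(coef))
    poly = WaterPolynomial(
        order=order,
        b0=float(b[0]),
        b1=float(b[1]),
        b2=float(b[2]),
        valid_range=(float(times.min()), float(times.max())),
    )
    return WaterFit(poly=poly, sigma_w=sigma_w, bic=float(bic), n_obs=n)


def select_water_model(times, concs) -> WaterFit:
    """Fit orders 1 and 2 and return the fit with the lower BIC.

    Ties (within floating-point resolution) go to the lower order.
    """
    lin = fit_water_poly(times, concs, order=1)
    quad = fit_water_poly(times, concs, order=2)
    return quad if quad.bic < lin.bic else lin
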