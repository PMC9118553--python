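"""Mechanistic interpretation of the fitted kinetics.

Uptake is modelled as passive diffusion across the gill epithelial
membrane, with the membrane lipid-water distribution ratio D_MLW
setting the concentration gradient inside the membrane:

    k_U = D · ρ_M · D_MLW · A · 1000 / M              (uptake)

so the membrane diffusion coefficient D (m h⁻¹) follows from the fitted
k_U. Elimination decomposes into gill respiration and biotransformation,

    k_T = k_2 + k_B,    k_2 = k_U / D_FW,    D_FW ≈ f_MLF · D_MLW,

giving the in vivo biotransformation rate constant k_B-BCF = k_T − k_2.
The equilibrium-partitioning quantity f_MLF·D_MLW is also the baseline
screening BCF (the BCF a non-biotransformed surfactant would attain).

A two-parameter well-stirred hepatic clearance model links k_B to
D_MLW:

    k_B = 1 / (a + b · D_MLW),
    a = V_D / Q_B (h),   b = V_D · f_MLB / Q_LW (h kg L⁻¹),

which is constant at low D_MLW (flow limitation of the freely dissolved
chemical) and inversely proportional to D_MLW at high D_MLW
(sequestration into membrane-like sorbents limits availability). Only
the composites a and b are identifiable from (D_MLW, k_B) data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import ChemicalProperties, FishPhysiology, MechanisticResult

__all__ = [
    "ClearanceModelFit",
    "diffusion_coefficient",
    "fish_water_ratio",
    "gill_elimination_k2",
    "kb_from_kinetics",
    "baseline_screening_bcf",
    "gill_area_allometric",
    "loglog_ols",
    "fit_clearance_model",
    "predict_kb",
    "mechanistic_result",
]

_L_PER_M3 = 1000.0  # unit conversion in the gill-uptake equation


def diffusion_coefficient(
    k_u: float, log_dmlw: float, phys: FishPhysiology
) -> float:
    """Membrane diffusion coefficient D (m h⁻¹) from the uptake rate constant.

    Inverts k_U = D·ρ_M·D_MLW·A·1000/M for D.
    """
    if not k_u > 0:
        raise ValueError("k_u must be > 0")
    dmlw = 10.0 ** log_dmlw
    return k_u * phys.mass_kg / (
        phys.membrane_density * dmlw * phys.gill_area_m2 * _L_PER_M3
    )


def fish_water_ratio(log_dmlw: float, f_mlf: float = 0.0125) -> float:
    """Fish-water equilibrium distribution ratio D_FW ≈ f_MLF·D_MLW (L kg⁻¹).

    Membranes dominate the sorption capacity of fish tissue for ionic
    surfactants, so whole-body partitioning is approximated by the
    membrane-lipid fraction times the membrane-water ratio.
    """
    if f_mlf < 0:
        raise ValueError("f_mlf must be >= 0")
    return f_mlf * 10.0 ** log_dmlw


def gill_elimination_k2(
    k_u: float, log_dmlw: float, f_mlf: float = 0.0125
) -> float:
    """Gill (respiratory) elimination rate constant k_2 = k_U/(f_MLF·D_MLW)."""
    if not (k_u > 0 and f_mlf > 0):
        raise ValueError("k_u and f_mlf must be > 0")
    dmlw = 10.0 ** log_dmlw
    if not dmlw > 0:
        raise ValueError("D_MLW must be > 0")
    return k_u / (f_mlf * dmlw)


def kb_from_kinetics(k_t: float, k2: float) -> tuple[float, bool]:
    """In vivo biotransformation rate constant k_B-BCF = k_T − k_2 (h⁻¹).

    Returns ``(kb, clamped)``; if the estimated gill elimination exceeds
    the total elimination (possible through error in the physiological
    constants), kb is clamped to 0 with a warning and ``clamped=True``.
    """
    if k2 > k_t:
        warnings.warn(
            f"estimated gill elimination k2={k2:.3g} exceeds total "
            f"elimination k_t={k_t:.3g}; k_B clamped to 0",
            stacklevel=2,
        )
        return 0.0, True
    return k_t - k2, False


def baseline_screening_bcf(log_dmlw: float, f_mlf: float = 0.0125) -> float:
    """Equilibrium-partitioning BCF assuming no biotransformation.

    Numerically identical to :func:`fish_water_ratio`; exposed
    separately because it answers a screening question (the ceiling a
    surfactant's BCF would reach without metabolism).
    """
    return fish_water_ratio(log_dmlw, f_mlf)


def gill_area_allometric(
    mass_kg: float, coeff: float = 0.114, exponent: float = 0.794
) -> float:
    """Allometric gill-area hook A = coeff · M^exponent (m², M in kg).

    The default coefficient is calibrated so a 0.024 kg trout has
    A = 5.9e-3 m², matching the package's default physiology; both
    constants are configurable when species-specific allometry is
    available.
    """
    if not mass_kg > 0:
        raise ValueError("mass_kg must be > 0")
    return coeff * mass_kg ** exponent


def loglog_ols(x_log, y_log) -> tuple[float, float, float]:
    """OLS regression on log10-transformed data: (slope, intercept, r²)."""
    x = np.asarray(x_log, dtype=float)
    y = np.asarray(y_log, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class ClearanceModelFit:
    """Fitted composites of the well-stirred hepatic clearance model.

    a = V_D/Q_B (h); b = V_D·f_MLB/Q_LW (h kg L⁻¹); rmse_log is the
    root-mean-square of the log10 residuals.
    """

    a: float
    b: float
    rmse_log: float
    n: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (self.a > 0 and self.b > 0):
            raise ValueError("fitted composites must be positive")


# deterministic multi-start grid (log-space) for the clearance fit
_A_STARTS = (0.1, 1.0, 3.0, 10.0, 100.0)
_B_STARTS = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3)


def fit_clearance_model(dmlw_list, kb_list) -> ClearanceModelFit:
    """Fit k_B = 1/(a + b·D_MLW) by least squares on log10 residuals.

    Optimized over (log a, log b) with a deterministic multi-start
    Nelder-Mead; the best of all starts is returned. Inputs are linear
    D_MLW (L kg⁻¹) and k_B (h⁻¹), all positive.
    """
    dmlw = np.asarray(dmlw_list, dtype=float)
    kb = np.asarray(kb_list, dtype=float)
    if dmlw.size < 3:
        raise ValueError("need n >= 3")
    if np.any(kb <= 0) or np.any(dmlw <= 0):
        raise ValueError("all D_MLW and k_B values must be > 0")
    log_kb = np.log10(kb)

    def objective(p):
        a, b = np.exp(p)
        return float(np.sum((log_kb + np.log10(a + b * dmlw)) ** 2))

    best = None
    for a0 in _A_STARTS:
        for b0 in _B_STARTS:
            res = optimize.minimize(
                objective,
                np.log([a0, b0]),
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
            )
            if best is None or res.fun < best.fun:
                best = res
    converged = bool(best.success)
    a, b = np.exp(best.x)
    rmse = float(np.sqrt(best.fun / dmlw.size))
    return ClearanceModelFit(
        a=float(a), b=float(b), rmse_log=rmse, n=int(dmlw.size),
        converged=converged,
    )


def predict_kb(log_dmlw, fit: ClearanceModelFit):
    """Predicted biotransformation rate constant 1/(a + b·D_MLW) (h⁻¹)."""
    dmlw = 10.0 ** np.asarray(log_dmlw, dtype=float)
    out = 1.0 / (fit.a + fit.b * dmlw)
    return float(out) if out.ndim == 0 else out


def mechanistic_result(
    chem: ChemicalProperties,
    k_u: float,
    k_t: float,
    phys: FishPhysiology,
) -> MechanisticResult:
    """All mechanistic quantities for one chemical from its fitted kinetics."""
    d = diffusion_coefficient(k_u, chem.log_dmlw, phys)
    k2 = gill_elimination_k2(k_u, chem.log_dmlw, phys.f_mlf)
    kb, clamped = kb_from_kinetics(k_t, k2)
    return MechanisticResult(
        chem_id=chem.chem_id,
        diffusion_coeff=d,
        d_fw=fish_water_ratio(chem.log_dmlw, phys.f_mlf),
        k2=k2,
        kb_bcf=kb,
        baseline_bcf=baseline_screening_bcf(chem.log_dmlw, phys.f_mlf),
        kb_clamped=clamped,
    )
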