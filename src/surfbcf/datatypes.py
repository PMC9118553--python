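"""Shared domain types for the bioconcentration pipeline.

Units are fixed throughout the package: time in hours, water
concentrations in µg L⁻¹, fish concentrations in µg kg⁻¹ wet weight,
fish mass in kg. No unit auto-detection is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Phase(str, Enum):
    EXPOSURE = "exposure"
    DEPURATION = "depuration"


class DmlwSource(str, Enum):
    MEASURED = "measured"
    QSAR = "qsar"


class FitMethod(str, Enum):
    BAYES = "bayes"
    STEPWISE = "stepwise"
    STEADY_STATE = "steady_state"


@dataclass(frozen=True)
class ChemicalProperties:
    """Identity and physicochemical properties of one test chemical.

    log_dmlw is the log10 membrane lipid-water distribution ratio
    (L kg⁻¹), the partitioning descriptor that drives both gill uptake
    and internal sequestration of ionic surfactants.
    """

    chem_id: str
    name: str = ""
    log_dmlw: float = float("nan")
    nominal_cw: Optional[float] = None  # µg L⁻¹
    dmlw_source: DmlwSource = DmlwSource.MEASURED

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_dmlw):
            raise ValueError(f"{self.chem_id}: log_dmlw must be finite")
        if self.nominal_cw is not None and not self.nominal_cw > 0:
            raise ValueError(f"{self.chem_id}: nominal_cw must be > 0")

    @property
    def dmlw(self) -> float:
        """Membrane lipid-water distribution ratio on the linear scale."""
        return 10.0 ** self.log_dmlw


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured concentration in water or fish.

    ``value`` is µg L⁻¹ for water records and µg kg⁻¹ ww for fish
    records. Censoring flags keep the measured value (no LOQ/2
    substitution) so steady-state estimation can use sub-LOQ data.
    """

    chem_id: str
    time_h: float
    phase: Phase
    sample_id: str  # replicate label for water, fish id for fish
    value: float
    below_loq: bool = False
    below_lod: bool = False
    mass_g: Optional[float] = None  # individual fish wet mass, fish only

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")
        if self.value < 0:
            raise ValueError(
                f"{self.chem_id} @ {self.time_h} h: concentration must be >= 0"
            )
        if self.below_lod and not self.below_loq:
            raise ValueError("below_lod implies below_loq (LOD <= LOQ)")


@dataclass
class StudyDataset:
    """A complete uptake/depuration study for a panel of chemicals."""

    chemicals: list[ChemicalProperties]
    water: list[ConcentrationRecord]
    fish: list[ConcentrationRecord]
    controls: list[ConcentrationRecord] = field(default_factory=list)
    exposure_end_h: float = 96.0
    fish_mass_kg: float = 0.024

    def __post_init__(self) -> None:
        if not self.exposure_end_h > 0:
            raise ValueError("exposure_end_h must be > 0")
        known = {c.chem_id for c in self.chemicals}
        for rec in [*self.water, *self.fish, *self.controls]:
            if rec.chem_id not in known:
                raise ValueError(
                    f"record references unknown chem_id {rec.chem_id!r}"
                )
        for rec in [*self.water, *self.fish]:
            in_exposure = rec.time_h <= self.exposure_end_h + 1e-9
            if rec.phase is Phase.EXPOSURE and not in_exposure:
                raise ValueError(
                    f"{rec.chem_id}: exposure-phase record at t={rec.time_h} h "
                    f"after exposure_end_h={self.exposure_end_h}"
                )

    def chemical(self, chem_id: str) -> ChemicalProperties:
        for c in self.chemicals:
            if c.chem_id == chem_id:
                return c
        raise KeyError(chem_id)

    def subset(self, chem_id: str) -> "StudyDataset":
        """Restrict the dataset to one chemical (records are shared)."""
        return StudyDataset(
            chemicals=[self.chemical(chem_id)],
            water=[r for r in self.water if r.chem_id == chem_id],
            fish=[r for r in self.fish if r.chem_id == chem_id],
            controls=[r for r in self.controls if r.chem_id == chem_id],
            exposure_end_h=self.exposure_end_h,
            fish_mass_kg=self.fish_mass_kg,
        )


@dataclass(frozen=True)
class KineticParams:
    """First-order one-compartment parameters.

    k_u: uptake rate constant (L kg⁻¹ ww h⁻¹); k_t: overall elimination
    rate constant (h⁻¹).
    """

    k_u: float
    k_t: float

    def __post_init__(self) -> None:
        if self.k_u < 0:
            raise ValueError("k_u must be >= 0")
        if not self.k_t > 0:
            raise ValueError("k_t must be > 0")


@dataclass
class Interval:
    lower: float
    upper: float

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass
class FitResult:
    """Point estimates and 95% intervals for one chemical's kinetics."""

    chem_id: str
    method: FitMethod
    k_u: float = float("nan")
    k_t: float = float("nan")
    bcf: float = float("nan")
    k_u_ci: Optional[Interval] = None
    k_t_ci: Optional[Interval] = None
    bcf_ci: Optional[Interval] = None
    converged: bool = True
    n_points_used: int = 0
    notes: str = ""

    def __post_init__(self) -> None:
        for point, ci in [
            (self.k_u, self.k_u_ci),
            (self.k_t, self.k_t_ci),
            (self.bcf, self.bcf_ci),
        ]:
            if ci is not None and math.isfinite(point):
                if not (ci.lower <= point * (1 + 1e-12) + 1e-300
                        and point <= ci.upper * (1 + 1e-12) + 1e-300):
                    raise ValueError(
                        f"interval [{ci.lower}, {ci.upper}] does not "
                        f"contain point {point}"
                    )


@dataclass(frozen=True)
class FishPhysiology:
    """Physiological constants of the gill-diffusion and partitioning model.

    mass_kg
        Mean fish wet mass M (kg).
    gill_area_m2
        Gill epithelial surface area A (m²) over which diffusive
        transport occurs. Default back-derived for a 0.024 kg rainbow
        trout from the published diffusion coefficient of
        tridecylsulfonate (see docs/methods.md); configurable, with an
        allometric hook in :func:`surfbcf.mechanistic.gill_area_allometric`.
    membrane_density
        Density ρ_M of the gill epithelial membrane (kg L⁻¹).
    f_mlf
        Mass fraction of the fish that is membrane lipid or has
        equivalent sorption properties (kg kg⁻¹ ww).
    """

    mass_kg: float = 0.024
    gill_area_m2: float = 5.9e-3
    membrane_density: float = 1.0
    f_mlf: float = 0.0125

    def __post_init__(self) -> None:
        for name in ("mass_kg", "gill_area_m2", "membrane_density", "f_mlf"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MechanisticResult:
    """Mechanistic quantities derived from a chemical's fitted kinetics."""

    chem_id: str
    diffusion_coeff: float  # D, m h⁻¹
    d_fw: float  # fish-water equilibrium distribution ratio, L kg⁻¹
    k2: float  # gill elimination rate constant, h⁻¹
    kb_bcf: float  # in vivo biotransformation rate constant, h⁻¹
    baseline_bcf: float  # equilibrium-partitioning BCF, L kg⁻¹ ww
    kb_clamped: bool = False
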