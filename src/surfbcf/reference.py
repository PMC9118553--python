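"""Published in vivo reference dataset for ten anionic surfactants.

Rate constants, BCFs and membrane lipid-water distribution ratios
measured in juvenile rainbow trout (0.024 kg, 10 °C, 4-day exposure +
7-day depuration), together with the in vitro S9 biotransformation rate
constants for the same chemicals. Columns:

k_u        uptake rate constant, L kg⁻¹ ww h⁻¹ (NaN = not quantifiable)
k_t        overall elimination rate constant, h⁻¹
bcf        bioconcentration factor, L kg⁻¹ ww (steady-state for
           C10SO3/C11SO3, kinetic otherwise)
log_dmlw   log10 membrane lipid-water distribution ratio, L kg⁻¹
d          membrane diffusion coefficient, m h⁻¹
k2         gill elimination rate constant, h⁻¹
kb_bcf     in vivo biotransformation rate constant k_T − k_2, h⁻¹
kb_s9      biotransformation rate constant from the in vitro RT-S9
           depletion assay, h⁻¹
kb_s9_ll   True where no significant S9 depletion was measured and
           kb_s9 is the assay's detection floor divided by 3

These printed values serve as inputs for the mechanistic layer
(regressions, clearance-model fit, internal-consistency checks) and as
ground-truth presets for the synthetic-data generator; the raw
concentration time series behind them are not published.
"""

from __future__ import annotations

import io

import pandas as pd

_TABLE = """\
chem_id,name,nominal_cw,observed_cw,water_rsd,k_u,k_t,bcf,log_dmlw,dmlw_source,d,k2,kb_bcf,kb_s9,kb_s9_ll
C10SO3,decylsulfonate,52,63,0.08,,,0.042,3.01,measured,,,,0.366,False
C11SO3,undecylsulfonate,38,43,0.07,,,0.136,3.39,qsar,,,,0.225,False
C13SO3,tridecylsulfonate,5.9,6.6,0.10,0.25,0.057,4.5,4.46,measured,3.5e-8,0.00071,0.056,0.032,False
C14SO3,tetradecylsulfonate,5.6,7.6,0.12,0.70,0.024,30,4.95,measured,3.1e-8,0.00063,0.023,0.002,True
C16SO3,hexadecylsulfonate,9.9,5.8,0.18,6.3,0.0047,1370,6.19,qsar,1.6e-8,0.00033,0.0043,0.002,True
C11SO4,undecylsulfate,22,24,0.10,0.136,0.178,0.77,4.16,qsar,3.7e-8,0.00076,0.177,0.151,False
C13SO4,tridecylsulfate,7.1,11.9,0.15,1.62,0.048,34,5.21,measured,3.9e-8,0.00080,0.047,0.028,False
C10LAS,1-n-(p-sulfophenyl)decane,6.9,8.1,0.11,0.77,0.047,16.3,5.10,qsar,2.4e-8,0.00049,0.047,0.041,False
C12EO4SO4,dodecyltetraethoxysulfate,25,44,0.17,0.090,0.100,0.89,4.24,qsar,2.0e-8,0.00041,0.100,0.084,False
DOSS,bis(2-ethylhexyl)sulfosuccinate,26,54,0.22,0.090,0.063,1.42,4.58,qsar,9.3e-9,0.00019,0.063,0.011,False
"""

KINETIC_CHEMICALS = (
    "C13SO3", "C14SO3", "C16SO3", "C11SO4", "C13SO4",
    "C10LAS", "C12EO4SO4", "DOSS",
)
STEADY_STATE_CHEMICALS = ("C10SO3", "C11SO3")


def reference_table() -> pd.DataFrame:
    """The reference dataset as a DataFrame indexed by chem_id."""
    df = pd.read_csv(io.StringIO(_TABLE), index_col="chem_id")
    df["kb_s9_ll"] = df["kb_s9_ll"].astype(bool)
    return df


def clearance_dataset() -> pd.DataFrame:
    """(D_MLW, k_B) pairs used to fit the hepatic clearance model.

    k_B is the in vivo kb_bcf where quantifiable and the in vitro kb_s9
    for the two fast-eliminated chemicals for which kb_bcf could not be
    determined.
    """
    df = reference_table()
    kb = df["kb_bcf"].where(df["kb_bcf"].notna(), df["kb_s9"])
    return pd.DataFrame({"log_dmlw": df["log_dmlw"], "kb": kb})
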