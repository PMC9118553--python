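"""End-to-end orchestration: QA → water model → estimator → mechanistic → IVIVE.

Per-chemical method routing (Bayesian kinetic fit vs steady-state
ratio) is explicit configuration rather than auto-detection: the choice
depends on data richness judgements (how fast the chemical eliminates,
how much of the depuration phase is quantifiable) that belong to the
analyst. A stage failure for one chemical is recorded and the run
continues for the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as sio
from .datatypes import FishPhysiology, FitMethod, FitResult
from .inference import (
    InferenceConfig,
    run_mcmc,
    stepwise_fit,
    summarize,
)
from .kinetics import steady_state_bcf
from .mechanistic import mechanistic_result
from .qa import detection_limits, kinetic_inclusion_mask
from .s9 import IviveParams

logger = logging.getLogger("surfbcf")

__all__ = ["ChemicalOverride", "PipelineConfig", "run_pipeline"]


@dataclass
class ChemicalOverride:
    method: FitMethod = FitMethod.BAYES
    exclude_before_h: float = 0.0
    steady_state_window: tuple[float, float] = (6.0, 96.0)


@dataclass
class PipelineConfig:
    physiology: FishPhysiology = field(default_factory=FishPhysiology)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    ivive: IviveParams = field(default_factory=IviveParams)
    overrides: dict[str, ChemicalOverride] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a YAML or JSON config file (missing keys -> defaults)."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        overrides = {
            k: ChemicalOverride(
                method=FitMethod(v.get("method", "bayes")),
                exclude_before_h=float(v.get("exclude_before_h", 0.0)),
                steady_state_window=tuple(
                    v.get("steady_state_window", (6.0, 96.0))
                ),
            )
            for k, v in (raw.get("overrides") or {}).items()
        }
        return cls(
            physiology=FishPhysiology(**(raw.get("physiology") or {})),
            inference=InferenceConfig(**(raw.get("inference") or {})),
            ivive=IviveParams(**(raw.get("ivive") or {})),
            overrides=overrides,
        )


def _qa_filter(subset, override: ChemicalOverride):
    """Apply LOQ inclusion to the fish records of a one-chemical dataset."""
    if len(subset.controls) >= 2:
        limits = detection_limits(
            [r.value for r in subset.controls], subset.chemicals[0].chem_id
        )
        mask = kinetic_inclusion_mask(subset.fish, limits)
        fish = [r for r in subset.fish if mask.get(r.time_h, False)]
    else:
        limits = None
        fish = list(subset.fish)
    fish = [r for r in fish if r.time_h >= override.exclude_before_h]
    subset = dataclasses.replace(subset, fish=fish)
    return subset, limits


def _fit_one(subset, override, config) -> FitResult:
    chem = subset.chemicals[0]
    inf_cfg = dataclasses.replace(
        config.inference, exclude_before_h=override.exclude_before_h
    )
    if override.method is FitMethod.STEADY_STATE:
        bcf = steady_state_bcf(
            subset.fish,
            [r for r in subset.water],
            window=override.steady_state_window,
        )
        return FitResult(
            chem_id=chem.chem_id, method=FitMethod.STEADY_STATE, bcf=bcf,
            n_points_used=len(
                {r.time_h for r in subset.fish
                 if override.steady_state_window[0] <= r.time_h
                 <= override.steady_state_window[1]}
            ),
        )
    if override.method is FitMethod.STEPWISE:
        return stepwise_fit(subset, inf_cfg)
    samples = run_mcmc(subset, inf_cfg)
    return summarize(samples)


def run_pipeline(
    dataset,
    config: Optional[PipelineConfig] = None,
    kb_s9: Optional[dict[str, float]] = None,
    outdir=None,
) -> list[dict]:
    """Run the full per-chemical analysis and return report rows.

    ``kb_s9`` optionally merges externally fitted in vitro rate
    constants into the report. If ``outdir`` is given, results.csv /
    results.json and a run log are written there.
    """
    config = config or PipelineConfig()
    rows: list[dict] = []
    failures: dict[str, str] = {}
    for chem in dataset.chemicals:
        cid = chem.chem_id
        override = config.overrides.get(cid, ChemicalOverride())
        try:
            subset = dataset.subset(cid)
            subset, limits = _qa_filter(subset, override)
            logger.info(
                "%s: method=%s usable_fish=%d", cid, override.method.value,
                len(subset.fish),
            )
            fit = _fit_one(subset, override, config)
            row = {
                "chem_id": cid,
                "method": fit.method.value,
                "k_u": fit.k_u, "k_t": fit.k_t, "bcf": fit.bcf,
                "converged": fit.converged,
                "n_points_used": fit.n_points_used,
                "log_dmlw": chem.log_dmlw,
            }
            for name, ci in [
                ("k_u", fit.k_u_ci), ("k_t", fit.k_t_ci),
                ("bcf", fit.bcf_ci),
            ]:
                row[f"{name}_lo"] = ci.lower if ci else float("nan")
                row[f"{name}_hi"] = ci.upper if ci else float("nan")
            if (
                fit.method is not FitMethod.STEADY_STATE
                and np.isfinite(fit.k_u)
                and fit.k_u > 0
            ):
                mech = mechanistic_result(
                    chem, fit.k_u, fit.k_t, config.physiology
                )
                row.update(
                    diffusion_coeff=mech.diffusion_coeff,
                    k2=mech.k2,
                    kb_bcf=mech.kb_bcf,
                    baseline_bcf=mech.baseline_bcf,
                )
            else:
                row["baseline_bcf"] = (
                    config.physiology.f_mlf * chem.dmlw
                )
            if kb_s9 and cid in kb_s9:
                row["kb_s9"] = kb_s9[cid]
            rows.append(row)
        except Exception as exc:  # keep going for the other chemicals
            logger.error("%s: %s", cid, exc)
            failures[cid] = str(exc)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_results(rows, outdir / "results.csv")
        (outdir / "log.json").write_text(
            json.dumps({"failures": failures}, indent=1) + "\n"
        )
    if failures:
        logger.warning("stage failures: %s", sorted(failures))
    return rows
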