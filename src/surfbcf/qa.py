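"""Quality-assurance screens: detection limits, inclusion rules, outliers.

Detection limits follow the control-fish convention: the limit of
quantitation (LOQ) is the control mean plus ten standard deviations and
the limit of detection (LOD) is the control mean plus three. Kinetic
fitting only uses time points at which every fish is above the LOQ
(sub-LOQ data carry a positive bias that would bias k_T downward);
steady-state estimation additionally keeps sub-LOQ values above the LOD.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datatypes import ConcentrationRecord

__all__ = [
    "DetectionLimits",
    "detection_limits",
    "kinetic_inclusion_mask",
    "flag_outliers",
    "rsd_summary",
]


@dataclass(frozen=True)
class DetectionLimits:
    chem_id: str
    lod: float  # µg kg⁻¹ ww, mean + 3·sd of control fish
    loq: float  # µg kg⁻¹ ww, mean + 10·sd of control fish
    n_controls: int

    def __post_init__(self) -> None:
        if self.lod < 0 or self.loq < 0 or self.lod > self.loq:
            raise ValueError("require 0 <= lod <= loq")


def detection_limits(control_values, chem_id: str = "") -> DetectionLimits:
    """LOQ = mean + 10·sd, LOD = mean + 3·sd of control-fish concentrations."""
    vals = np.asarray(list(control_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 control values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return DetectionLimits(
        chem_id=chem_id, lod=mean + 3 * sd, loq=mean + 10 * sd,
        n_controls=int(vals.size),
    )


def _by_time(records: Iterable[ConcentrationRecord]):
    groups: dict[float, list[ConcentrationRecord]] = defaultdict(list)
    for r in records:
        groups[r.time_h].append(r)
    return dict(sorted(groups.items()))


def kinetic_inclusion_mask(
    fish_records: Sequence[ConcentrationRecord],
    limits: DetectionLimits,
    mode: str = "kinetic",
) -> dict[float, bool]:
    """Usable time points for fitting, keyed by time (h).

    mode="kinetic": a time point is usable iff every fish at that time
    is above the LOQ. mode="steady_state": usable iff every fish is
    above the LOD (sub-LOQ data retained).
    """
    if mode not in ("kinetic", "steady_state"):
        raise ValueError("mode must be 'kinetic' or 'steady_state'")
    threshold = limits.loq if mode == "kinetic" else limits.lod
    return {
        t: all(r.value > threshold for r in recs)
        for t, recs in _by_time(fish_records).items()
    }


def flag_outliers(
    times,
    values,
    mean_rsd: float,
) -> np.ndarray:
    """Spike detection against the mean of the temporal neighbours.

    A point with value v and neighbour mean m (mean of the values at
    the preceding and succeeding time points) is flagged iff the
    relative exceedance (v − m)/m is greater than 10 × ``mean_rsd``
    (``mean_rsd`` as a fraction, e.g. 0.25). Endpoints have only one
    neighbour and are never flagged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times, kind="stable")
    flags = np.zeros(values.shape, dtype=bool)
    if times.size < 3:
        return flags
    ts = times[order]
    vs = values[order]
    # group by time point so replicate fish share neighbour means
    uniq, inv = np.unique(ts, return_inverse=True)
    tp_mean = np.array([vs[inv == i].mean() for i in range(uniq.size)])
    sorted_flags = np.zeros(vs.shape, dtype=bool)
    for i in range(1, uniq.size - 1):
        m = 0.5 * (tp_mean[i - 1] + tp_mean[i + 1])
        if m <= 0:
            continue
        sel = inv == i
        sorted_flags[sel] = (vs[sel] - m) / m > 10.0 * mean_rsd
    flags[order] = sorted_flags
    return flags


def rsd_summary(groups: dict) -> tuple[dict, float]:
    """Per-group RSD (sd/mean) and the mean RSD across groups.

    ``groups`` maps a label (e.g. a time point) to the replicate values
    measured there. Groups with zero mean have undefined RSD and are
    reported as NaN and excluded from the mean.
    """
    per_group: dict = {}
    for key, vals in groups.items():
        vals = np.asarray(list(vals), dtype=float)
        mean = vals.mean()
        if vals.size < 2 or mean == 0:
            per_group[key] = float("nan")
        else:
            per_group[key] = float(np.std(vals, ddof=1) / mean)
    finite = [v for v in per_group.values() if np.isfinite(v)]
    mean_rsd = float(np.mean(finite)) if finite else float("nan")
    return per_group, mean_rsd
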