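"""Growth-curve summaries and the corrinoid-dependence classifier.

Dependence on an exogenous corrinoid is detected by serial passage: each
isolate is carried through paired transfers into medium with the isolation
corrinoid and into no-corrinoid (NOC) medium.  Each ~3 ul -> 200 ul transfer
dilutes carried-over corrinoid ~67-fold, so after four passages a dependent
isolate has effectively no corrinoid left in the NOC arm and stops growing,
while producers and independents keep growing in both arms.

The decision statistic is the corrinoid-specific growth enhancement

    E = log2(1 + (OD_with - OD_noc) / OD_noc) = log2(OD_with / OD_noc)

evaluated at the final passage, compared against a threshold tau derived from
isolates that were themselves isolated in the NOC condition (max control E
plus one sample SD).  Isolate-level calls take a 2-of-3 replicate vote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GrowthCurve",
    "PassageSeries",
    "EnhancementResult",
    "SaturationGroup",
    "growth_enhancement",
    "dependence_threshold",
    "classify_replicate",
    "vote_dependence",
    "time_to_saturation_group",
    "DEFAULT_BLANK_FLOOR",
    "DEFAULT_GROWTH_FLOOR",
    "SATURATION_LADDER_H",
]

#: OD600 below which a reading is treated as blank (clamped before ratios).
DEFAULT_BLANK_FLOOR = 0.01
#: OD600 above which a culture is considered to have grown.
DEFAULT_GROWTH_FLOOR = 0.1
#: Time-to-saturation ladder, hours.
SATURATION_LADDER_H = (24, 48, 168, 336)


@dataclass
class GrowthCurve:
    """One isolate x condition OD600 trajectory."""

    isolate_id: str
    condition: str
    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValueError("times and od600 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError("od600 readings must be non-negative")


@dataclass
class PassageSeries:
    """Paired with-corrinoid / NOC end-point ODs for one isolate replicate.

    ``od_with[k]`` and ``od_noc[k]`` are the end-of-passage ODs after passage
    k+1 (k = 0..K-1).  NaN marks a missing reading.
    """

    isolate_id: str
    replicate: int
    od_with: np.ndarray
    od_noc: np.ndarray

    def __post_init__(self) -> None:
        self.od_with = np.asarray(self.od_with, dtype=float)
        self.od_noc = np.asarray(self.od_noc, dtype=float)
        if self.od_with.shape != self.od_noc.shape or self.od_with.ndim != 1:
            raise ValueError("od_with and od_noc must be 1-D of equal length")
        if self.od_with.size < 1:
            raise ValueError("need at least one completed passage")
        with np.errstate(invalid="ignore"):
            if np.any(self.od_with < 0) or np.any(self.od_noc < 0):
                raise ValueError("ODs must be non-negative")

    @property
    def n_passages(self) -> int:
        return int(self.od_with.size)


@dataclass
class EnhancementResult:
    """Enhancement statistic with its threshold and the resulting flag."""

    E: float
    tau: float
    dependent_flag: bool = field(init=False)
    floor_clamped: bool = False

    def __post_init__(self) -> None:
        self.dependent_flag = self.E >= self.tau


@dataclass
class SaturationGroup:
    isolate_id: str
    group: Optional[int]  # hours, or None when unassigned


def growth_enhancement(
    od_with: float,
    od_without: float,
    blank_floor: float = DEFAULT_BLANK_FLOOR,
) -> float:
    """Corrinoid-specific growth enhancement, log2(OD_with / OD_noc).

    Readings at or below ``blank_floor`` are clamped to the floor before the
    ratio, which keeps near-blank NOC wells from blowing up the statistic.
    Equals 0 when the two (clamped) ODs agree; 1 per doubling of OD due to
    the corrinoid.
    """
    if od_with < 0 or od_without < 0:
        raise ValueError("ODs must be non-negative")
    return math.log2(max(od_with, blank_floor) / max(od_without, blank_floor))


def enhancement_result(
    od_with: float,
    od_without: float,
    tau: float,
    blank_floor: float = DEFAULT_BLANK_FLOOR,
) -> EnhancementResult:
    clamped = od_with < blank_floor or od_without < blank_floor
    e = growth_enhancement(od_with, od_without, blank_floor)
    return EnhancementResult(E=e, tau=tau, floor_clamped=clamped)


def dependence_threshold(noc_control_E: Sequence[float]) -> float:
    """Dependence threshold tau from no-corrinoid control enhancements.

    tau = max(controls) + SD(controls), with the sample SD (n-1 denominator).
    At least two control values are required for the SD to be defined.
    """
    vals = np.asarray(list(noc_control_E), dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 control values to define the SD")
    return float(vals.max() + vals.std(ddof=1))


def classify_replicate(
    series: PassageSeries,
    tau: float,
    growth_floor: float = DEFAULT_GROWTH_FLOOR,
    blank_floor: float = DEFAULT_BLANK_FLOOR,
) -> tuple[str, float]:
    """Classify one replicate's passage series.

    Returns ``(call, E)`` where call is one of ``"dependent"``,
    ``"non-dependent"``, ``"no-growth"`` or ``"incomplete"`` and E is the
    final-passage enhancement statistic (NaN when not computable).

    The final passage is decisive: corrinoid carryover has been washed out by
    then (~67-fold dilution per transfer).  An isolate whose with-corrinoid
    arm never clears the growth floor is "no-growth" and not pursued further.
    A dependent call additionally requires E > 0: zero enhancement (both arms
    identical) can never indicate dependence, whatever the control-derived
    threshold — this only matters when noise-free controls make tau = 0.
    """
    ow = series.od_with[-1]
    on = series.od_noc[-1]
    if math.isnan(ow) or math.isnan(on):
        return "incomplete", math.nan
    if ow < growth_floor:
        return "no-growth", math.nan
    e = growth_enhancement(ow, on, blank_floor)
    return ("dependent" if (e >= tau and e > 0) else "non-dependent"), e


def vote_dependence(replicate_calls: Sequence[str], n_required: Optional[int] = None) -> str:
    """Isolate-level vote over replicate dependence calls.

    With the default three replicates, two or more "dependent" calls make the
    isolate dependent (majority-or-greater rule for other replicate counts).
    "incomplete" replicates make the isolate "inconclusive" unless the
    remaining calls already decide the vote either way; a majority of
    "no-growth" replicates yields "no-growth" (isolate not pursued).
    """
    calls = list(replicate_calls)
    n = len(calls)
    if n == 0:
        raise ValueError("need at least one replicate call")
    valid = {"dependent", "non-dependent", "no-growth", "incomplete"}
    bad = set(calls) - valid
    if bad:
        raise ValueError(f"unknown replicate calls: {sorted(bad)}")
    need = n_required if n_required is not None else n // 2 + 1
    n_dep = calls.count("dependent")
    n_inc = calls.count("incomplete")
    n_ng = calls.count("no-growth")
    if n_ng >= need:
        return "no-growth"
    if n_dep >= need:
        return "dependent"
    if n_dep + n_inc >= need and n_inc > 0:
        return "inconclusive"  # the missing replicates could still decide it
    return "non-dependent"


def time_to_saturation_group(
    curve: GrowthCurve,
    ladder: Sequence[int] = SATURATION_LADDER_H,
    saturation_fraction: float = 0.95,
    growth_floor: float = DEFAULT_GROWTH_FLOOR,
) -> SaturationGroup:
    """Assign a growth curve to the time-to-saturation ladder.

    The group is the smallest ladder time t at which the (interpolated) OD
    has reached ``saturation_fraction`` of the trajectory maximum.  Flat or
    blank curves are unassigned, as are curves still rising at their final
    observation (the plateau has not been seen, so the trajectory maximum
    understates it): "still rising" means the last inter-point increase
    exceeds the (1 - saturation_fraction) tolerance band around the maximum.
    """
    if curve.times.size < 4:
        raise ValueError("need >= 4 time points to assign a saturation group")
    peak = float(curve.od600.max())
    if peak < growth_floor:
        return SaturationGroup(curve.isolate_id, None)
    if curve.od600[-1] - curve.od600[-2] > (1.0 - saturation_fraction) * peak:
        return SaturationGroup(curve.isolate_id, None)
    target = saturation_fraction * peak
    for t in sorted(ladder):
        if t > curve.times[-1]:
            break
        od_t = float(np.interp(t, curve.times, curve.od600))
        if od_t >= target:
            return SaturationGroup(curve.isolate_id, int(t))
    return SaturationGroup(curve.isolate_id, None)
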