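"""E. coli three-strain corrinoid-detection bioassay: metric, calls, quantification.

The bioassay reads each lysed sample with three E. coli strains: the ΔmetE
indicator (grows on either methionine or corrinoid), the ΔmetEΔmetH double
mutant (grows only on methionine, controlling for methionine in the sample)
and the wildtype (normalization).  The "growth due to corrinoid" metric is

    metric = (OD_ΔmetE - OD_ΔmetEΔmetH) / OD_wt

An isolate is called a producer when the metric is >= 2 or when the ΔmetE OD
itself is >= 0.1; otherwise it is a non-producer (hence, for an isolate that
grows without corrinoid, an independent).  A fitted 4PL standard curve turns
bioassay responses into molar corrinoid amounts for supernatant (extracellular)
and pellet (intracellular) fractions, from which the percent of corrinoid
provided is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .doseresponse import DoseResponseDataset, FourPLFit, fit_fourpl, fourpl_inverse

__all__ = [
    "AssayInvalid",
    "BioassayReading",
    "ProductionCall",
    "Quantification",
    "QuantifiedFraction",
    "growth_due_to_corrinoid",
    "call_production",
    "call_production_replicates",
    "fit_standard_curve",
    "quantify_from_standard_curve",
    "percent_provided",
    "growth_repression_flag",
    "DEFAULT_METRIC_THRESHOLD",
    "DEFAULT_INDICATOR_OD_THRESHOLD",
]

DEFAULT_METRIC_THRESHOLD = 2.0
DEFAULT_INDICATOR_OD_THRESHOLD = 0.1
DEFAULT_WT_FLOOR = 0.1


class AssayInvalid(ValueError):
    """The wildtype strain failed to grow, so the assay is uninterpretable."""


@dataclass
class BioassayReading:
    """One sample's ODs across the three assay strains."""

    sample_id: str
    od_dmetE: float
    od_double: float
    od_wt: float

    def __post_init__(self) -> None:
        if min(self.od_dmetE, self.od_double, self.od_wt) < 0:
            raise ValueError("ODs must be non-negative")


@dataclass
class ProductionCall:
    sample_id: str
    metric: float
    call: str  # producer | non-producer | inconclusive
    reason: str = ""


@dataclass
class Quantification:
    """Standard-curve readout: a molar value or an out-of-range sentinel."""

    value: float  # molar; NaN when out of range
    status: str   # ok | below_detection | above_range

    @property
    def detected(self) -> bool:
        return self.status == "ok"


@dataclass
class QuantifiedFraction:
    """Intra/extracellular corrinoid amounts and the provided percentage."""

    isolate_id: str
    intracellular_amount: float
    extracellular_amount: float
    percent_provided: float = field(init=False)
    status: str = field(init=False)  # ok | not_detected | undefined

    def __post_init__(self) -> None:
        self.percent_provided, self.status = percent_provided(
            self.intracellular_amount, self.extracellular_amount
        )


def growth_due_to_corrinoid(r: BioassayReading, wt_floor: float = DEFAULT_WT_FLOOR
                            ) -> float:
    """Corrinoid-specific growth metric, (ΔmetE - ΔmetEΔmetH) / wildtype.

    Raises :class:`AssayInvalid` when the wildtype OD is at or below
    ``wt_floor`` — the sample is then inconclusive, not a number.
    """
    if r.od_wt <= wt_floor:
        raise AssayInvalid(
            f"wildtype OD {r.od_wt:.3f} <= floor {wt_floor}: assay invalid"
        )
    return (r.od_dmetE - r.od_double) / r.od_wt


def call_production(
    metric: float,
    od_dmetE: float,
    metric_threshold: float = DEFAULT_METRIC_THRESHOLD,
    od_threshold: float = DEFAULT_INDICATOR_OD_THRESHOLD,
) -> str:
    """Disjunctive producer rule: metric >= 2 OR indicator OD >= 0.1."""
    if metric >= metric_threshold or od_dmetE >= od_threshold:
        return "producer"
    return "non-producer"


def call_production_replicates(
    readings: Sequence[BioassayReading],
    metric_threshold: float = DEFAULT_METRIC_THRESHOLD,
    od_threshold: float = DEFAULT_INDICATOR_OD_THRESHOLD,
    wt_floor: float = DEFAULT_WT_FLOOR,
) -> ProductionCall:
    """Call production across replicates; disagreement is inconclusive.

    Every replicate must yield a valid assay and the same per-replicate call;
    otherwise the sample is inconclusive with a machine-readable reason
    (``assay-invalid`` or ``replicate-inconsistency``).
    """
    if not readings:
        raise ValueError("need at least one reading")
    sample_id = readings[0].sample_id
    calls, metrics = [], []
    for r in readings:
        try:
            m = growth_due_to_corrinoid(r, wt_floor)
        except AssayInvalid:
            return ProductionCall(sample_id, math.nan, "inconclusive",
                                  reason="assay-invalid")
        metrics.append(m)
        calls.append(call_production(m, r.od_dmetE, metric_threshold, od_threshold))
    mean_metric = float(np.mean(metrics))
    if len(set(calls)) > 1:
        return ProductionCall(sample_id, mean_metric, "inconclusive",
                              reason="replicate-inconsistency")
    return ProductionCall(sample_id, mean_metric, calls[0])


def fit_standard_curve(concentrations, responses, flat_tol: float = 0.05
                       ) -> FourPLFit:
    """Fit the 4PL standard curve used for quantification.

    Replicate responses at the same concentration are averaged in response
    space before fitting (uniform weights).
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    uniq = np.unique(conc)
    mean_resp = np.array([resp[conc == c].mean() for c in uniq])
    data = DoseResponseDataset("standard", "B12", uniq, mean_resp)
    return fit_fourpl(data, growth_floor=-math.inf, flat_tol=flat_tol)


def quantify_from_standard_curve(response: float, curve: FourPLFit) -> Quantification:
    """Invert a fitted standard curve to a molar concentration.

    Responses at or below the curve bottom are below detection; at or above
    the top, above range.  Both return sentinel quantifications rather than
    raising, so batch tables keep their shape.
    """
    if curve.status != "fit":
        raise ValueError("standard curve is not fitted")
    if response <= curve.bottom:
        return Quantification(math.nan, "below_detection")
    if response >= curve.top:
        return Quantification(math.nan, "above_range")
    x = fourpl_inverse(response, curve.bottom, curve.top, curve.hill, curve.ec50)
    return Quantification(x, "ok")


def percent_provided(intra: float, extra: float) -> tuple[float, str]:
    """Extracellular corrinoid as a percentage of the total.

    Returns ``(percentage, status)``: status ``"undefined"`` when both
    amounts are zero, ``"not_detected"`` when no extracellular corrinoid was
    found (0% with an n.d. flag), else ``"ok"``.
    """
    if intra < 0 or extra < 0:
        raise ValueError("amounts must be non-negative")
    total = intra + extra
    if total == 0:
        return math.nan, "undefined"
    if extra == 0:
        return 0.0, "not_detected"
    return 100.0 * extra / total, "ok"


def growth_repression_flag(od_wt: float, plate_wt_median: float,
                           fraction: float = 0.5) -> bool:
    """Flag samples whose lysate repressed E. coli growth.

    True when the wildtype OD falls below ``fraction`` of the plate's
    wildtype median.
    """
    if plate_wt_median <= 0:
        raise ValueError("plate wildtype median must be positive")
    return od_wt < fraction * plate_wt_median
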